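"""Plan strain-specific probes from an insertion annotation table.

Selects insertions long enough (>= 1 kb) to host a probe set, reports
their capacity for non-overlapping 30-mers, enumerates candidate probes
from a toy insertion sequence under the composition filters (Tm 60-100
degC, GC 30-90%, no 7-base homopolymer), screens them for k-mer
uniqueness against both genomes, and assembles the full tailed oligos.
"""

import numpy as np
import pandas as pd

from haplotrace import (
    attach_tails,
    enumerate_probes,
    probe_capacity,
    select_insertions,
    uniqueness_screen,
)

indels = pd.DataFrame(
    {
        "strain": ["N2", "N2", "HI", "HI"],
        "chrom": ["V", "V", "V", "V"],
        "start": [1000, 50_000, 20_000, 90_000],
        "end": [2000, 50_800, 23_500, 91_200],
    }
)
records, summary = select_insertions(indels, min_len=1000)
print("qualifying insertions per strain/chromosome:")
print(summary.to_string(index=False))
for rec in records:
    print(f"  {rec.strain} {rec.chrom}:{rec.start}-{rec.end} "
          f"({rec.length} nt, capacity {probe_capacity(rec.length)} probes)")

rng = np.random.default_rng(0)
insertion_seq = "".join(rng.choice(list("ACGT"), size=200, p=[0.3, 0.2, 0.2, 0.3]))
candidates = enumerate_probes(insertion_seq)
passing = [c for c in candidates if c.passes]
print(f"\n{len(candidates)} windows scored, {len(passing)} pass all filters")

own_genome = ["TTTT" + insertion_seq + "TTTT"]
other_genome = ["".join(rng.choice(list("ACGT"), size=500))]
unique = uniqueness_screen(passing, own_genome, other_genome)
kept = [c for c, u in zip(passing, unique) if u]
print(f"{len(kept)} survive the k-mer uniqueness screen")
if kept:
    oligo = attach_tails(kept[0], "N2")
    print(f"first tailed oligo ({len(oligo)} nt): {oligo}")
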