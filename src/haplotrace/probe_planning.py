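"""Strain-specific FISH probe planning from insertion annotations.

Strain-marking probe sets target insertions private to one strain's
genome: any 30-mer inside such an insertion hybridizes to that strain's
chromosome and not the other's.  The planner selects qualifying insertions
(length >= 1 kb, enough room for a useful probe count), enumerates
candidate 30-mers under composition filters (melting temperature 60-100
degC, GC 30-90%, no homopolymer run of 7+), screens them for exact k-mer
uniqueness against both genomes, and attaches the amplification/readout
tail architecture (forward primer + strain readout site + probe + readout
site + reverse primer).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq
from Bio.SeqUtils import MeltingTemp, gc_fraction

__all__ = [
    "InsertionRecord",
    "ProbeCandidate",
    "ProbeFilters",
    "TailSpec",
    "DEFAULT_TAILS",
    "select_insertions",
    "probe_capacity",
    "enumerate_probes",
    "uniqueness_screen",
    "attach_tails",
]


@dataclass
class InsertionRecord:
    """One strain-specific insertion (0-based half-open coordinates)."""

    strain: str
    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ProbeFilters:
    """Composition filters for candidate probes; bounds are inclusive."""

    probe_len: int = 30
    tm_min: float = 60.0
    tm_max: float = 100.0
    gc_min: float = 0.30
    gc_max: float = 0.90
    max_homopolymer: int = 6  # runs of 7+ identical bases fail
    # Nearest-neighbor Tm conditions (documented constants): 50 mM Na+,
    # 250 nM oligo, SantaLucia 1997 parameter table, no formamide.
    na_mM: float = 50.0
    dnac1_nM: float = 250.0


@dataclass
class ProbeCandidate:
    """A 30-mer window with its filter scores."""

    sequence: str
    offset: int
    gc_frac: float
    tm: float
    pass_flags: dict = field(default_factory=dict)

    @property
    def passes(self) -> bool:
        return all(self.pass_flags.values())


def select_insertions(
    indel_table: pd.DataFrame, min_len: int = 1000
) -> tuple[list[InsertionRecord], pd.DataFrame]:
    """Select insertions long enough to host a probe set.

    ``indel_table`` needs columns strain, chrom, start, end.  Rows with
    ``end - start >= min_len`` are kept (so a 1000-nt insertion qualifies
    at the default threshold).  Returns the records plus a per-strain,
    per-chromosome summary with insertion counts and total inserted length.
    """
    required = {"strain", "chrom", "start", "end"}
    if not required.issubset(indel_table.columns):
        raise ValueError(f"indel table must have columns {sorted(required)}")
    lengths = indel_table["end"] - indel_table["start"]
    if (lengths < 0).any():
        raise ValueError("negative insertion length (end < start)")
    kept = indel_table.loc[lengths >= min_len].copy()
    kept["length"] = kept["end"] - kept["start"]
    records = [
        InsertionRecord(r.strain, r.chrom, int(r.start), int(r.end))
        for r in kept.itertuples()
    ]
    summary = (
        kept.groupby(["strain", "chrom"])["length"]
        .agg(n_insertions="count", total_length="sum")
        .reset_index()
    )
    return records, summary


def probe_capacity(insertion_len: int, probe_len: int = 30) -> int:
    """Number of non-overlapping probes an insertion can accommodate."""
    if probe_len <= 0:
        raise ValueError("probe_len must be positive")
    if insertion_len < 0:
        raise ValueError("insertion_len must be non-negative")
    return insertion_len // probe_len


def _max_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def enumerate_probes(
    insertion_seq: str, filters: ProbeFilters | None = None
) -> list[ProbeCandidate]:
    """Score every probe-length window of an insertion sequence.

    Windows containing N are rejected outright.  Each remaining window is
    scored for GC fraction, nearest-neighbor melting temperature and
    homopolymer runs; ``pass_flags`` records each filter separately and
    ``passes`` is their conjunction.  Filters are independent predicates,
    so their evaluation order never changes the passing set.
    """
    if filters is None:
        filters = ProbeFilters()
    seq = insertion_seq.upper()
    L = filters.probe_len
    out = []
    for off in range(0, len(seq) - L + 1):
        window = seq[off : off + L]
        if set(window) - set("ACGT"):
            continue
        gc = gc_fraction(window)
        tm = MeltingTemp.Tm_NN(
            Seq(window),
            nn_table=MeltingTemp.DNA_NN3,
            Na=filters.na_mM,
            dnac1=filters.dnac1_nM,
            dnac2=0,
        )
        flags = {
            "gc": filters.gc_min <= gc <= filters.gc_max,
            "tm": filters.tm_min <= tm <= filters.tm_max,
            "homopolymer": _max_run(window) <= filters.max_homopolymer,
        }
        out.append(ProbeCandidate(window, off, float(gc), float(tm), flags))
    return out


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _kmer_counts(seqs, k: int) -> dict:
    counts: dict = {}
    for s in seqs:
        s = s.upper()
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k]
            counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def uniqueness_screen(
    probes,
    own_genome_seqs,
    other_genome_seqs,
    k: int = 18,
) -> list[bool]:
    """Exact k-mer uniqueness screen of probe sequences.

    A probe fails when any of its k-mers (or their reverse complements)
    occurs in the *other* strain's genome, or occurs more than once in its
    own genome — a single own-genome hit is the probe's source locus.  The
    screen is conservative: any shared exact k-mer disqualifies the probe
    even if a full-length alignment would not be stable.
    """
    sequences = [p.sequence if isinstance(p, ProbeCandidate) else p for p in probes]
    if any(len(s) < k for s in sequences):
        raise ValueError("k must not exceed the probe length")
    own = _kmer_counts(own_genome_seqs, k)
    other = _kmer_counts(other_genome_seqs, k)
    results = []
    for seq in sequences:
        seq = seq.upper()
        ok = True
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            rc = _revcomp(kmer)
            if other.get(kmer, 0) or other.get(rc, 0):
                ok = False
                break
            if own.get(kmer, 0) + own.get(rc, 0) > 1:
                ok = False
                break
        results.append(ok)
    return results


@dataclass
class TailSpec:
    """Tail architecture for one strain's probe set.

    All probes of one strain share the same readout site, so one
    fluorophore-bearing secondary oligo lights up the whole strain marker;
    the site appears twice per probe to double the secondary binding
    capacity.  The sequences here are synthetic placeholders — real
    libraries supply their own readout/primer sets.
    """

    readout_site: str
    fwd_primer: str = "CGCAAGTCGAACGTGGATCA"
    rev_primer: str = "TGGTCACGGTGTTCGAAGCA"


DEFAULT_TAILS = {
    "N2": TailSpec(readout_site="ATCGCACACGTTCACGGTCA"),
    "HI": TailSpec(readout_site="GTTGCGCAATGTCAGTACCA"),
}


def attach_tails(
    probe, strain: str, tails: dict | None = None
) -> str:
    """Assemble the full oligo: fwd primer + readout + probe + readout +
    rev primer, with the strain's shared readout site on both flanks."""
    if tails is None:
        tails = DEFAULT_TAILS
    if strain not in tails:
        raise ValueError(f"unknown strain {strain!r}")
    seq = probe.sequence if isinstance(probe, ProbeCandidate) else str(probe)
    t = tails[strain]
    return t.fwd_primer + t.readout_site + seq + t.readout_site + t.rev_primer
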