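"""Mean-distance matrices, power-law fitting, group regression, maps."""

import numpy as np
import pytest
from scipy import stats

from haplotrace.conformation_stats import (
    compare_power_laws,
    fit_power_law,
    mean_distance_matrix,
    normalize_observed_expected,
    pairwise_difference_map,
    replicate_correlation,
    MeanDistanceMatrix,
)
from haplotrace.core import Trace
from haplotrace.polymer_sim import PolymerParams, default_region_coords, \
    simulate_traces


def make_trace(positions, tid=0):
    positions = np.asarray(positions, dtype=float)
    return Trace(
        trace_id=tid,
        nucleus_id=tid,
        embryo_id=0,
        region_ids=np.arange(1, positions.shape[0] + 1),
        positions=positions,
    )


def exact_matrix(a, s, coords):
    """Noiseless mean-distance matrix following d = a * g**s exactly."""
    coords = np.asarray(coords, dtype=float)
    g = np.abs(coords[None, :] - coords[:, None])
    with np.errstate(divide="ignore"):
        mean = a * g**s
    n = coords.size
    counts = np.full((n, n), 100)
    valid = ~np.eye(n, dtype=bool)
    mean[~valid] = np.nan
    return MeanDistanceMatrix(mean, counts, valid, coords,
                              np.arange(1, n + 1))


class TestMeanDistanceMatrix:
    def test_identical_traces(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 3, (8, 3))
        traces = [make_trace(pts, tid=i) for i in range(30)]
        m = mean_distance_matrix(traces, np.arange(1, 9), min_pair_count=22)
        single = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        np.testing.assert_allclose(m.mean[m.valid], single[m.valid])

    def test_low_region_trace_excluded(self):
        rng = np.random.default_rng(1)
        full = rng.uniform(0, 3, (10, 3))
        sparse = full.copy()
        sparse[6:] = np.nan  # 6 observed regions -> below the >6 filter
        traces = [make_trace(full, tid=i) for i in range(25)]
        traces.append(make_trace(sparse, tid=99))
        m = mean_distance_matrix(traces, np.arange(1, 11), min_pair_count=1)
        assert m.counts[0, 1] == 25  # sparse trace did not contribute

    def test_pair_count_threshold(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 3, (8, 3))
        for n, expect_valid in [(21, False), (22, True)]:
            traces = [make_trace(pts, tid=i) for i in range(n)]
            m = mean_distance_matrix(traces, np.arange(1, 9))
            assert bool(m.valid[0, 1]) is expect_valid

    def test_no_surviving_traces_all_masked(self):
        pts = np.full((8, 3), np.nan)
        pts[:3] = 0.0
        m = mean_distance_matrix([make_trace(pts)], np.arange(1, 9))
        assert not m.valid.any()


class TestFitPowerLaw:
    def test_noiseless_recovery(self):
        m = exact_matrix(1.0, 0.5, default_region_coords(21))
        fit = fit_power_law(m)
        assert fit.a == pytest.approx(1.0, abs=1e-8)
        assert fit.s == pytest.approx(0.5, abs=1e-8)
        assert fit.ci95_a[0] <= fit.a <= fit.ci95_a[1]

    def test_scale_equivariance(self):
        coords = default_region_coords(12)
        m1 = exact_matrix(0.9, 0.3, coords)
        m2 = exact_matrix(1.8, 0.3, coords)
        f1, f2 = fit_power_law(m1), fit_power_law(m2)
        assert f2.a == pytest.approx(2 * f1.a, rel=1e-6)
        assert f2.s == pytest.approx(f1.s, abs=1e-8)

    def test_simulated_recovery_within_ci(self):
        # coverage of the fitted 95% CI across seeded repetitions
        coords = default_region_coords(21)
        hits_s = 0
        reps = 20
        for seed in range(reps):
            traces = simulate_traces(
                PolymerParams(a=1.03, s=0.198, seed=seed), 400
            )
            fit = fit_power_law(
                mean_distance_matrix(traces, coords), traces=traces
            )
            if fit.ci95_s[0] <= 0.198 <= fit.ci95_s[1]:
                hits_s += 1
        assert hits_s / reps >= 0.9

    def test_insufficient_pairs(self):
        m = exact_matrix(1.0, 0.5, np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            fit_power_law(m)


class TestNormalize:
    def test_exact_data_all_ones(self):
        m = exact_matrix(1.2, 0.4, default_region_coords(10))
        fit = fit_power_law(m)
        ratio = normalize_observed_expected(m, fit)
        np.testing.assert_allclose(ratio[m.valid], 1.0, atol=1e-6)

    def test_half_distance_ratio(self):
        m = exact_matrix(1.0, 0.5, default_region_coords(10))
        fit = fit_power_law(m)
        m.mean[0, 5] = m.mean[5, 0] = 0.5 * fit.expected(5.0)
        ratio = normalize_observed_expected(m, fit)
        assert ratio[0, 5] == pytest.approx(0.5)

    def test_round_trip(self):
        m = exact_matrix(1.0, 0.5, default_region_coords(10))
        m.mean[m.valid] *= np.random.default_rng(0).uniform(
            0.5, 2.0, int(m.valid.sum())
        )
        fit = fit_power_law(m)
        ratio = normalize_observed_expected(m, fit)
        g = np.abs(m.region_coords[None, :] - m.region_coords[:, None])
        with np.errstate(divide="ignore", invalid="ignore"):
            back = ratio * fit.a * g**fit.s
        np.testing.assert_allclose(back[m.valid], m.mean[m.valid])

    def test_elementwise_oracle(self):
        m = exact_matrix(1.1, 0.35, default_region_coords(8))
        fit = fit_power_law(m)
        ratio = normalize_observed_expected(m, fit)
        for i, j, g, d in m.pairs():
            assert ratio[i, j] == pytest.approx(d / (fit.a * g**fit.s))


class TestComparePowerLaws:
    coords = default_region_coords(12)

    def test_identical_groups(self):
        # mild noise keeps the residual variance positive so the t-test
        # is defined; symmetry forces the group terms to exactly zero
        m = exact_matrix(1.0, 0.4, self.coords)
        rng = np.random.default_rng(7)
        m.mean[m.valid] *= np.exp(rng.normal(0, 0.05, int(m.valid.sum())))
        reg = compare_power_laws(m, m)
        assert reg.beta2 == pytest.approx(0.0, abs=1e-10)
        assert reg.beta3 == pytest.approx(0.0, abs=1e-10)
        assert reg.pvalues[2] > 0.99

    def test_doubled_distances(self):
        a = exact_matrix(1.0, 0.4, self.coords)
        b = exact_matrix(2.0, 0.4, self.coords)
        reg = compare_power_laws(a, b)
        assert reg.beta2 == pytest.approx(np.log(2), abs=1e-8)
        assert reg.beta3 == pytest.approx(0.0, abs=1e-8)

    def test_exponent_shift(self):
        a = exact_matrix(1.0, 0.3, self.coords)
        b = exact_matrix(1.0, 0.4, self.coords)
        reg = compare_power_laws(a, b)
        assert reg.beta3 == pytest.approx(0.1, abs=1e-8)

    def test_beta3_equals_slope_difference(self):
        a = exact_matrix(0.9, 0.25, self.coords)
        b = exact_matrix(1.3, 0.45, self.coords)
        reg = compare_power_laws(a, b)
        fa, fb = fit_power_law(a), fit_power_law(b)
        assert reg.beta3 == pytest.approx(
            fb.loglog_slope - fa.loglog_slope, abs=1e-8
        )


class TestPairwiseDifferenceMap:
    coords = default_region_coords(8)

    def sample(self, seed, shift_pair=None):
        traces = simulate_traces(
            PolymerParams(a=0.8, s=0.4, region_coords=self.coords, seed=seed),
            60,
        )
        if shift_pair:
            i, j, amount = shift_pair
            for t in traces:
                t.positions[j] = t.positions[i] + [amount, 0, 0]
        return traces

    def test_identical_groups_zero_delta(self):
        tr = self.sample(0)
        delta, q = pairwise_difference_map(tr, tr, self.coords)
        finite = ~np.isnan(delta)
        np.testing.assert_allclose(delta[finite], 0.0, atol=1e-12)
        assert np.nanmin(q) > 0.99

    def test_null_fdr_calibration(self):
        a, b = self.sample(1), self.sample(2)
        _, q = pairwise_difference_map(a, b, self.coords)
        iu = np.triu_indices(self.coords.size, k=1)
        frac = np.nanmean(q[iu] < 0.05)
        assert frac <= 0.05 + 1e-12

    def test_large_shift_flagged(self):
        a = self.sample(3)
        b = self.sample(4, shift_pair=(0, 1, 5.0))
        _, q = pairwise_difference_map(a, b, self.coords)
        assert q[0, 1] < 0.05


class TestReplicateCorrelation:
    coords = default_region_coords(21)

    def test_identical(self):
        m = exact_matrix(1.0, 0.4, self.coords)
        assert replicate_correlation(m, m) == pytest.approx(1.0)

    def test_anticorrelated(self):
        a = exact_matrix(1.0, 0.4, self.coords)
        b = exact_matrix(1.0, 0.4, self.coords)
        b.mean = np.where(b.valid, 10.0 - a.mean, np.nan)
        assert replicate_correlation(a, b) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(5)
        a = exact_matrix(1.0, 0.4, self.coords)
        b = exact_matrix(1.0, 0.4, self.coords)
        a.mean[a.valid] = rng.uniform(1, 3, int(a.valid.sum()))
        b.mean[b.valid] = rng.uniform(1, 3, int(b.valid.sum()))
        a.mean = (a.mean + a.mean.T) / 2
        b.mean = (b.mean + b.mean.T) / 2
        iu = np.triu_indices(21, k=1)
        x, y = a.mean[iu], b.mean[iu]
        r_expected = (
            ((x - x.mean()) * (y - y.mean())).sum()
            / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        assert replicate_correlation(a, b) == pytest.approx(r_expected)
        assert abs(r_expected) < 0.25  # independent matrices, 210 pairs
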