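"""Undercounting simulations, forward model and true-mean inference."""

import numpy as np
import pytest
from scipy.signal import fftconvolve

from macscount import (
    CellGeometry,
    detected_pmf_given_lambda,
    resolved_clusters,
    undercount_curve,
)
from macscount.overlap import infer_true_lambda


def pair_overlap_probability(geometry, resolution_um=0.25, grid=0.005):
    """Numeric-integration oracle for P(|X1 - X2| < r), X uniform in footprint.

    The displacement density of two uniform points is the normalized
    autocorrelation of the footprint indicator; integrate it over the
    disc of radius r.  Independent of any Monte-Carlo code path.
    """
    a = grid
    reach = geometry.length / 2 + geometry.width * geometry.lateral_scale
    cx, cy = geometry.center
    x = np.arange(cx - reach, cx + reach, a) + a / 2
    y = np.arange(cy - reach, cy + reach, a) + a / 2
    xx, yy = np.meshgrid(x, y)
    ind = geometry.contains(np.column_stack([xx.ravel(), yy.ravel()]))
    ind = ind.reshape(len(y), len(x)).astype(float)
    ac = fftconvolve(ind, ind[::-1, ::-1])
    dy = (np.arange(ac.shape[0]) - (len(y) - 1)) * a
    dx = (np.arange(ac.shape[1]) - (len(x) - 1)) * a
    ddx, ddy = np.meshgrid(dx, dy)
    within = ddx**2 + ddy**2 < resolution_um**2
    area = ind.sum() * a * a
    return ac[within].sum() * a**4 / area**2


class TestResolvedClusters:
    def test_single_point(self):
        assert resolved_clusters(np.array([[1.0, 1.0]])) == 1

    def test_pair_below_and_above_resolution(self):
        close = np.array([[0.0, 0.0], [0.1, 0.0]])  # 100 nm apart
        far = np.array([[0.0, 0.0], [0.3, 0.0]])  # 300 nm apart
        assert resolved_clusters(close, 250.0) == 1
        assert resolved_clusters(far, 250.0) == 2

    def test_chain_merges_transitively(self):
        chain = np.array([[0.0, 0.0], [0.2, 0.0], [0.4, 0.0]])
        assert resolved_clusters(chain, 250.0) == 1

    def test_count_bounded_by_n(self, pressed_cell, rng):
        from macscount import sample_positions

        for n in (2, 5, 12):
            pos = sample_positions(pressed_cell, n, rng).positions
            k = resolved_clusters(pos)
            assert 1 <= k <= n


class TestUndercountCurve:
    def test_single_molecule_always_detected(self, pressed_cell, rng):
        curve = undercount_curve(pressed_cell, [1], reps=200, rng=rng)
        assert curve.table.loc[0, "mean_detected"] == 1.0
        assert curve.table.loc[0, "sd_detected"] == 0.0

    def test_pair_matches_numeric_integration(self, pressed_cell, rng):
        """MC mean at n=2 equals 2 - P(pair closer than the resolution),
        with P from an independent autocorrelation integral."""
        reps = 100_000
        curve = undercount_curve(pressed_cell, [2], reps=reps, rng=rng)
        mc_mean = curve.table.loc[0, "mean_detected"]
        mc_se = curve.table.loc[0, "sd_detected"] / np.sqrt(reps)
        oracle = 2.0 - pair_overlap_probability(pressed_cell)
        assert abs(mc_mean - oracle) < 3 * mc_se + 1e-3  # + grid discretization

    def test_detected_never_exceeds_true_and_monotone(self, pressed_cell, rng):
        curve = undercount_curve(pressed_cell, range(0, 15), reps=1500, rng=rng)
        t = curve.table
        assert (t["mean_detected"] <= t["true_n"] + 1e-12).all()
        assert (np.diff(t["mean_detected"]) > 0).all()

    def test_pressing_reduces_undercounting(self, cell, pressed_cell, rng):
        """The flattened (larger) footprint resolves more of 8 molecules."""
        reps = 4000
        c_un = undercount_curve(cell, [8], reps=reps, rng=rng)
        c_pr = undercount_curve(pressed_cell, [8], reps=reps, rng=rng)
        assert c_pr.table.loc[0, "mean_detected"] > c_un.table.loc[0, "mean_detected"]

    def test_density_dependence(self, rng):
        """At fixed n, a smaller footprint loses more spots to overlap."""
        small = CellGeometry(length=2.0, width=0.8)
        large = CellGeometry(length=4.0, width=1.0)
        c_s = undercount_curve(small, [6], reps=4000, rng=rng)
        c_l = undercount_curve(large, [6], reps=4000, rng=rng)
        assert c_s.table.loc[0, "mean_detected"] < c_l.table.loc[0, "mean_detected"]


class TestDetectedPmf:
    def test_lambda_zero_point_mass(self, pressed_cell):
        pmf = detected_pmf_given_lambda(0.0, pressed_cell)
        np.testing.assert_array_equal(pmf.probabilities, [1.0])

    def test_perfect_resolution_recovers_poisson(self, pressed_cell, rng):
        """As the resolution shrinks the detected pmf tends to Poisson."""
        from scipy import stats as sps

        lam = 4.0
        pmf = detected_pmf_given_lambda(
            lam, pressed_cell, resolution_nm=1.0, reps=20_000, rng=rng
        )
        k = np.arange(len(pmf.probabilities))
        tv = 0.5 * np.abs(pmf.probabilities - sps.poisson.pmf(k, lam)).sum()
        assert tv < 0.01

    def test_sub_poisson_at_high_density(self, rng):
        """Overlap narrows the distribution: Fano < 1 for 7 molecules in a
        small unpressed cell."""
        small = CellGeometry(length=2.55, width=0.9)  # ~2 um^2 footprint
        pmf = detected_pmf_given_lambda(7.0, small, reps=8000, rng=rng)
        assert pmf.fano() < 1.0

    def test_probabilities_normalized(self, pressed_cell, rng):
        pmf = detected_pmf_given_lambda(3.0, pressed_cell, reps=2000, rng=rng)
        assert pmf.probabilities.sum() == pytest.approx(1.0, abs=1e-9)


class TestInferTrueLambda:
    def test_self_consistent_recovery(self, pressed_cell, rng):
        """Counts drawn from the forward model at lambda=7 are inverted to
        within 0.3."""
        lam = 7.0
        pmf = detected_pmf_given_lambda(lam, pressed_cell, reps=4000, rng=rng)
        counts = rng.choice(np.arange(len(pmf.probabilities)), size=5000, p=pmf.probabilities)
        res = infer_true_lambda(counts, pressed_cell, reps=4000, rng=np.random.default_rng(1))
        assert abs(res["lambda_hat"] - lam) < 0.3
        assert res["ci"][0] < res["lambda_hat"] < res["ci"][1]

    def test_perfect_resolution_identity(self, pressed_cell, rng):
        """With no merging the MLE collapses to the sample mean."""
        counts = rng.poisson(5.0, size=3000)
        res = infer_true_lambda(
            counts, pressed_cell, resolution_nm=1.0, reps=2000, rng=np.random.default_rng(2)
        )
        assert res["lambda_hat"] == pytest.approx(counts.mean(), abs=0.1)

    def test_estimate_at_least_observed_mean(self, rng):
        """Undercounting only deflates, so lambda_hat >= <k>."""
        small = CellGeometry(length=2.55, width=0.9)
        pmf = detected_pmf_given_lambda(9.0, small, reps=3000, rng=rng)
        counts = rng.choice(np.arange(len(pmf.probabilities)), size=2000, p=pmf.probabilities)
        res = infer_true_lambda(counts, small, reps=3000, rng=np.random.default_rng(3))
        assert res["lambda_hat"] >= counts.mean()

    def test_all_zero_counts(self, pressed_cell):
        res = infer_true_lambda(np.zeros(100, dtype=int), pressed_cell)
        assert res["lambda_hat"] == 0.0
        assert res["ci"][0] == 0.0 and res["ci"][1] > 0.0
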