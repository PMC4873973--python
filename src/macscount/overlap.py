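"""Spot-overlap undercounting models and true-mean inference.

A diffraction-limited microscope cannot resolve two molecules closer
than roughly the PSF width (~250 nm), so a cell with N molecules shows
at most N spots and usually fewer.  Because cells that by chance hold
more molecules also lose more spots to overlap, undercounting *narrows*
the observed distribution (sub-Poisson Fano factor) rather than just
shifting it.

Two independent simulations quantify the effect, mirroring each other:

* a geometric one — molecules are placed uniformly in the footprint and
  clusters are counted by single-linkage merging at the optical
  resolution (centre-to-centre distance below ``resolution`` merges);
* an image-based one — the same placements are rendered into synthetic
  EMCCD frames and pushed through the actual spot finder.

On top of the geometric model sits a forward model for the distribution
of detected counts given a Poisson true-copy-number mean, and a
maximum-likelihood inversion that recovers the true mean from observed
counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.spatial.distance import pdist, squareform

from .detect import DetectionConfig, bandpass, find_maxima, localize
from .geometry import CellGeometry, sample_positions
from .simulate import CameraModel, OpticsModel, apply_camera, render_expected_photons

__all__ = [
    "OverlapCurve",
    "DetectedPmf",
    "resolved_clusters",
    "undercount_curve",
    "image_based_curve",
    "detected_pmf_given_lambda",
    "infer_true_lambda",
]

DEFAULT_RESOLUTION_NM = 250.0


@dataclass
class OverlapCurve:
    """Mean detected spots vs true molecule number for one geometry."""

    geometry: CellGeometry
    resolution_nm: float
    table: pd.DataFrame  # columns: true_n, mean_detected, sd_detected, reps

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class DetectedPmf:
    """Distribution of detected counts under the overlap forward model."""

    geometry: CellGeometry
    lam: float | None
    true_n: int | None
    probabilities: np.ndarray  # index k = detected count
    reps: int

    def mean(self) -> float:
        k = np.arange(len(self.probabilities))
        return float((k * self.probabilities).sum())

    def var(self) -> float:
        k = np.arange(len(self.probabilities))
        m = self.mean()
        return float(((k - m) ** 2 * self.probabilities).sum())

    def fano(self) -> float:
        m = self.mean()
        return self.var() / m if m > 0 else float("nan")


def _component_count(positions: np.ndarray, resolution_um: float) -> int:
    """Single-linkage component count: pairwise distance < resolution merges."""
    n = len(positions)
    if n <= 1:
        return n
    adj = squareform(pdist(positions)) < resolution_um
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if adj[i, j]:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    return len({find(i) for i in range(n)})


def resolved_clusters(positions_um: np.ndarray, resolution_nm: float = DEFAULT_RESOLUTION_NM) -> int:
    """Number of resolvable spots among point molecules.

    Molecules closer (centre-to-centre) than the optical resolution merge
    into one apparent spot; merging is transitive (single linkage), so a
    chain of close molecules counts once.
    """
    if resolution_nm <= 0:
        raise ValueError("resolution must be > 0")
    pos = np.asarray(positions_um, dtype=float).reshape(-1, 2)
    return _component_count(pos, resolution_nm / 1000.0)


def _closure_component_counts(adjacency: np.ndarray) -> np.ndarray:
    """Component counts per placement from (reps, n, n) boolean adjacency.

    Transitive closure by repeated boolean matrix squaring; in the closed
    matrix every row of a size-s component sums to s, so the number of
    components is sum_i 1/rowsum_i.
    """
    a = adjacency.astype(np.float32)
    n = a.shape[-1]
    steps = max(int(np.ceil(np.log2(max(n, 2)))), 1)
    for _ in range(steps):
        a = np.minimum(a + a @ a, 1.0)
    return np.rint((1.0 / a.sum(axis=2)).sum(axis=1)).astype(int)


def _batch_cluster_counts(
    geometry: CellGeometry,
    n: int,
    reps: int,
    resolution_um: float,
    rng: np.random.Generator,
    chunk: int = 2000,
) -> np.ndarray:
    """Detected-cluster counts for ``reps`` independent uniform placements."""
    if n == 0:
        return np.zeros(reps, dtype=int)
    if n == 1:
        return np.ones(reps, dtype=int)
    out = np.empty(reps, dtype=int)
    done = 0
    r2 = resolution_um**2
    while done < reps:
        m = min(chunk, reps - done)
        # Uniform iid points: one big draw reshaped into m placements.
        pts = sample_positions(geometry, n * m, rng).positions.reshape(m, n, 2)
        diff = pts[:, :, None, :] - pts[:, None, :, :]
        adj = (diff**2).sum(axis=-1) < r2
        out[done : done + m] = _closure_component_counts(adj)
        done += m
    return out


def undercount_curve(
    geometry: CellGeometry,
    n_range=range(0, 21),
    resolution_nm: float = DEFAULT_RESOLUTION_NM,
    reps: int = 10_000,
    rng: np.random.Generator | None = None,
) -> OverlapCurve:
    """Geometric Monte-Carlo undercounting curve.

    For each true molecule number, molecules are placed uniformly in the
    footprint ``reps`` times and the mean and s.d. of the resolved-spot
    count are recorded.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if rng is None:
        rng = np.random.default_rng(0)
    res_um = resolution_nm / 1000.0
    rows = []
    for n in n_range:
        counts = _batch_cluster_counts(geometry, int(n), reps, res_um, rng)
        rows.append(
            {
                "true_n": int(n),
                "mean_detected": float(counts.mean()),
                "sd_detected": float(counts.std(ddof=1)) if reps > 1 else 0.0,
                "reps": reps,
            }
        )
    return OverlapCurve(geometry, resolution_nm, pd.DataFrame(rows))


def _centered_copy(geometry: CellGeometry, frame_um: float) -> CellGeometry:
    from dataclasses import replace

    return replace(geometry, center=(frame_um / 2.0, frame_um / 2.0), orientation=0.0)


def image_based_curve(
    geometry: CellGeometry,
    n_range=range(0, 21),
    optics: OpticsModel | None = None,
    camera: CameraModel | None = None,
    detection: DetectionConfig | None = None,
    reps: int = 200,
    rng: np.random.Generator | None = None,
) -> OverlapCurve:
    """Image-based undercounting curve through the full imaging chain.

    Same contract as :func:`undercount_curve`, but each placement is
    rendered into a synthetic EMCCD frame and counted with the spot
    finder — an end-to-end cross-check of the geometric model.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    optics = optics or OpticsModel()
    camera = camera or CameraModel()
    detection = detection or DetectionConfig()
    px_um = camera.pixel_size_um
    frame_um = geometry.length + 2.0  # margin for PSF tails and the centroid box
    npx = int(np.ceil(frame_um / px_um))
    cell = _centered_copy(geometry, frame_um)
    rows = []
    for n in n_range:
        detected = np.empty(reps, dtype=int)
        for r in range(reps):
            mols = sample_positions(cell, int(n), rng)
            photons = render_expected_photons([cell], [mols], optics, (npx, npx), px_um)
            frame = apply_camera(photons, camera, rng)
            filtered = bandpass(frame, detection)
            peaks = find_maxima(filtered, detection)
            spots = localize(filtered, peaks, detection)
            detected[r] = sum(1 for s in spots if not s.border_clipped)
        rows.append(
            {
                "true_n": int(n),
                "mean_detected": float(detected.mean()),
                "sd_detected": float(detected.std(ddof=1)) if reps > 1 else 0.0,
                "reps": reps,
            }
        )
    return OverlapCurve(geometry, optics.psf_fwhm, pd.DataFrame(rows))


def _conditional_pmf_table(
    geometry: CellGeometry,
    n_max: int,
    resolution_nm: float,
    reps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """P(detected = k | true = n) for n = 0..n_max, MC-estimated.

    Returns an (n_max+1, n_max+1) row-stochastic matrix; detected <= true
    so the matrix is lower triangular.
    """
    res_um = resolution_nm / 1000.0
    table = np.zeros((n_max + 1, n_max + 1))
    table[0, 0] = 1.0
    for n in range(1, n_max + 1):
        counts = _batch_cluster_counts(geometry, n, reps, res_um, rng)
        table[n] = np.bincount(counts, minlength=n_max + 1) / reps
    return table


def detected_pmf_given_lambda(
    lam: float,
    geometry: CellGeometry,
    resolution_nm: float = DEFAULT_RESOLUTION_NM,
    reps: int = 5_000,
    rng: np.random.Generator | None = None,
    n_max: int | None = None,
) -> DetectedPmf:
    """Forward model: detected-count pmf when true counts are Poisson(lam).

    Mixture over n ~ Poisson(lam) of the MC-estimated conditional
    detected-count distributions.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if rng is None:
        rng = np.random.default_rng(0)
    if lam == 0:
        return DetectedPmf(geometry, 0.0, None, np.array([1.0]), reps)
    if n_max is None:
        n_max = int(stats.poisson.ppf(1 - 1e-9, lam)) + 1
    cond = _conditional_pmf_table(geometry, n_max, resolution_nm, reps, rng)
    weights = stats.poisson.pmf(np.arange(n_max + 1), lam)
    weights /= weights.sum()
    pmf = weights @ cond
    pmf /= pmf.sum()
    return DetectedPmf(geometry, lam, None, pmf, reps)


def infer_true_lambda(
    observed_counts,
    geometry: CellGeometry,
    resolution_nm: float = DEFAULT_RESOLUTION_NM,
    reps: int = 5_000,
    rng: np.random.Generator | None = None,
    lam_max: float | None = None,
    ci_level: float = 0.95,
) -> dict:
    """Maximum-likelihood true Poisson mean under the overlap forward model.

    The conditional detected|true table is MC-estimated once; the Poisson
    mixture weights make the likelihood a smooth function of lambda which
    is maximized by bounded scalar optimization.  The confidence interval
    comes from the profile (here one-parameter) likelihood.

    Returns a dict with ``lambda_hat``, ``ci`` (tuple), ``loglik`` and
    ``observed_mean``.
    """
    counts = np.asarray(observed_counts, dtype=int)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if rng is None:
        rng = np.random.default_rng(0)
    obs_mean = float(counts.mean()) if len(counts) else 0.0
    if len(counts) == 0 or counts.max() == 0:
        # all-zero counts: MLE at 0 with a one-sided upper bound
        upper = stats.chi2.ppf(ci_level, 2) / 2.0 / max(len(counts), 1)
        return {
            "lambda_hat": 0.0,
            "ci": (0.0, float(upper)),
            "loglik": 0.0,
            "observed_mean": obs_mean,
        }
    if lam_max is None:
        # undercounting only deflates, so the true mean is at least the
        # observed mean; leave headroom above it
        lam_max = max(2.5 * obs_mean + 4.0, 8.0)
    n_max = int(stats.poisson.ppf(1 - 1e-7, lam_max)) + 1
    n_max = max(n_max, int(counts.max()) + 1)
    cond = _conditional_pmf_table(geometry, n_max, resolution_nm, reps, rng)
    k_hist = np.bincount(counts, minlength=n_max + 1).astype(float)
    n_grid = np.arange(n_max + 1)

    def loglik(lam: float) -> float:
        w = stats.poisson.pmf(n_grid, lam)
        w /= w.sum()
        pmf = np.clip(w @ cond, 1e-300, None)
        return float(k_hist @ np.log(pmf))

    res = optimize.minimize_scalar(
        lambda lam: -loglik(lam), bounds=(1e-6, lam_max), method="bounded",
        options={"xatol": 1e-4},
    )
    lam_hat = float(res.x)
    ll_hat = -float(res.fun)
    drop = stats.chi2.ppf(ci_level, 1) / 2.0

    def shifted(lam: float) -> float:
        return loglik(lam) - (ll_hat - drop)

    lo = 0.0
    if shifted(1e-6) < 0:
        lo = float(optimize.brentq(shifted, 1e-6, lam_hat, xtol=1e-4))
    hi = lam_max
    if shifted(lam_max) < 0:
        hi = float(optimize.brentq(shifted, lam_hat, lam_max, xtol=1e-4))
    return {
        "lambda_hat": lam_hat,
        "ci": (lo, hi),
        "loglik": ll_hat,
        "observed_mean": obs_mean,
    }
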