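"""Per-cell copy-number statistics.

The summaries here are the ones used to characterize low-copy protein
distributions across a population of cells: the mean <p> and standard
deviation sigma_p of counts, the Fano factor sigma_p^2/<p> (exactly 1
for a Poisson distribution, >1 under bursting or extrinsic noise, <1
when overlap merges spots), the coefficient of variation sigma_p/<p>,
the fraction of cells with zero copies, and the count-per-area
concentration.  Conditioning on cell size removes the extrinsic
variability contributed by cells of different sizes holding
proportionally more molecules: pooled counts can look over-dispersed
while each size class is Poisson.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CountStats",
    "summarize",
    "poisson_overlay",
    "poisson_gof",
    "condition_on_size",
    "concentration",
    "maturation_correction",
]


@dataclass
class CountStats:
    """Summary statistics of per-cell counts (unbiased variance)."""

    n_cells: int
    mean: float
    variance: float
    fano: float | None
    cv: float | None
    zero_fraction: float
    size_bin: str | None = None

    def as_dict(self) -> dict:
        return {
            "n_cells": self.n_cells,
            "mean": self.mean,
            "variance": self.variance,
            "fano": self.fano,
            "cv": self.cv,
            "zero_fraction": self.zero_fraction,
            "size_bin": self.size_bin,
        }


def summarize(counts, size_bin: str | None = None) -> CountStats:
    """Mean, variance (n-1), Fano, CV and zero fraction of counts.

    Fano and CV are undefined (None) when the mean is zero; variance
    requires at least two cells.
    """
    c = np.asarray(counts, dtype=float)
    if len(c) < 2:
        raise ValueError("need at least 2 cells for a variance")
    mean = float(c.mean())
    var = float(c.var(ddof=1))
    fano = var / mean if mean > 0 else None
    cv = math.sqrt(var) / mean if mean > 0 else None
    zero_fraction = float((c == 0).mean())
    return CountStats(len(c), mean, var, fano, cv, zero_fraction, size_bin)


def poisson_overlay(counts) -> tuple[float, pd.DataFrame]:
    """ML Poisson fit (lambda = sample mean) with the pmf on the support.

    Returns the fitted mean and a table with the observed normalized
    histogram next to the Poisson pmf — the overlay one plots over a
    count histogram to judge Poisson-ness by eye.
    """
    c = np.asarray(counts, dtype=int)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative integers")
    lam = float(c.mean())
    support = np.arange(0, max(int(c.max()), 1) + 1)
    observed = np.bincount(c, minlength=len(support)) / len(c)
    pmf = sps.poisson.pmf(support, lam)
    table = pd.DataFrame({"count": support, "observed_freq": observed, "poisson_pmf": pmf})
    return lam, table


def poisson_gof(counts, alpha_warn_bins: int = 3) -> dict:
    """Chi-square goodness of fit against Poisson(sample mean).

    Cells are binned by count with right-tail bins pooled until the
    expected frequency is >= 5; degrees of freedom are bins - 2 (one for
    normalization, one for the estimated mean).
    """
    c = np.asarray(counts, dtype=int)
    n = len(c)
    if n < 20:
        raise ValueError("need at least 20 cells for the chi-square test")
    lam = c.mean()
    kmax = int(max(c.max(), sps.poisson.ppf(1 - 1e-4, lam)))
    support = np.arange(kmax + 1)
    expected = sps.poisson.pmf(support, lam) * n
    expected[-1] += sps.poisson.sf(kmax, lam) * n
    observed = np.bincount(c, minlength=kmax + 1).astype(float)

    # greedy pooling left to right until each bin's expectation >= 5;
    # a deficient final bin is merged into its predecessor
    def pool(exp, obs):
        pe, po = [], []
        acc_e = acc_o = 0.0
        for e, o in zip(exp, obs):
            acc_e += e
            acc_o += o
            if acc_e >= 5:
                pe.append(acc_e)
                po.append(acc_o)
                acc_e = acc_o = 0.0
        if acc_e > 0 and pe:
            pe[-1] += acc_e
            po[-1] += acc_o
        return np.array(pe), np.array(po)

    expected, observed = pool(expected, observed)
    if len(expected) < alpha_warn_bins:
        warnings.warn("too few bins after pooling; goodness-of-fit test skipped")
        return {"chi2": float("nan"), "dof": 0, "p": float("nan"), "skipped": True}
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    dof = len(expected) - 2
    p = float(sps.chi2.sf(chi2, dof))
    return {"chi2": chi2, "dof": dof, "p": p, "skipped": False}


def condition_on_size(
    table: pd.DataFrame,
    n_bins: int = 5,
    by: str = "length_um",
    trim: float = 0.01,
) -> list[CountStats]:
    """Per-size-class count statistics.

    Cells are first trimmed at the ``trim``/(1-``trim``) percentiles of
    the size covariate (extreme cell sizes excluded), then split into
    ``n_bins`` quantile bins; counts are summarized per bin.  Bins with
    fewer than 2 cells are reported empty (None stats).
    """
    if by not in table.columns:
        raise ValueError(f"table has no column {by!r}")
    df = table.dropna(subset=[by, "count"]).copy()
    if trim > 0:
        lo, hi = df[by].quantile([trim, 1 - trim])
        df = df[(df[by] >= lo) & (df[by] <= hi)]
    if n_bins == 1:
        return [summarize(df["count"], size_bin="all")]
    df["_bin"] = pd.qcut(df[by], q=n_bins, duplicates="drop")
    out: list[CountStats] = []
    for label, grp in df.groupby("_bin", observed=True, sort=True):
        if len(grp) < 2:
            out.append(CountStats(len(grp), float("nan"), float("nan"), None, None, float("nan"),
                                  size_bin=str(label)))
        else:
            out.append(summarize(grp["count"], size_bin=str(label)))
    return out


def concentration(table: pd.DataFrame) -> tuple[pd.Series, dict]:
    """Per-cell count/area (um^-2) and its mean/sd.

    Rows with non-positive area are rejected; the concentration is the
    size-independent abundance metric.
    """
    if "area_um2" not in table.columns:
        raise ValueError("table needs an area_um2 column")
    ok = table["area_um2"] > 0
    conc = table.loc[ok, "count"] / table.loc[ok, "area_um2"]
    summary = {
        "mean": float(conc.mean()),
        "sd": float(conc.std(ddof=1)) if len(conc) > 1 else float("nan"),
        "n_cells": int(ok.sum()),
        "n_rejected": int((~ok).sum()),
    }
    return conc, summary


def maturation_correction(
    observed_mean: float,
    maturation_time_min: float,
    doubling_time_min: float,
) -> float:
    """Correct an observed mean for immature (dark) fluorescent proteins.

    Irreversible first-order maturation at rate k_m = 1/maturation_time
    competing with dilution at mu = ln2/doubling_time gives a mature
    steady-state fraction f = k_m/(k_m + mu); the corrected mean is
    observed/f.  With maturation ~10 min and doubling >= 25 min, f is
    about 0.78 — i.e. ~80% of molecules are counted and only a minor
    correction is needed.
    """
    if maturation_time_min <= 0 or doubling_time_min <= 0:
        raise ValueError("maturation and doubling times must be > 0")
    k_m = 1.0 / maturation_time_min
    mu = math.log(2.0) / doubling_time_min
    f = k_m / (k_m + mu)
    return observed_mean / f
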