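"""Count-data statistics for the crosstalk pipeline.

Implements the statistical primitives every downstream stage leans on:
median-of-ratios size factors, a negative-binomial Wald test for
differential counts (genes or ChIP fragment counts per site),
Benjamini-Hochberg adjustment, Welch's t-test and PAM (k-medoids)
clustering of expression profiles.

The NB test is a deliberately simple, simulation-calibrated stand-in for
the heavier differential-count machinery commonly used on such data
(per-feature method-of-moments dispersion, no trend shrinkage).  Its
type-I error is verified by the test suite on null NB simulations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "NormalizationError",
    "size_factors",
    "nb_test",
    "bh_adjust",
    "welch_t",
    "pam_cluster",
]

MITO_CHROMS = frozenset({"chrM", "MT", "chrMT", "M"})


class NormalizationError(ValueError):
    """No feature usable as a normalization reference."""


@dataclass
class CountMatrix:
    """Nonnegative integer feature-by-sample count table.

    Parameters
    ----------
    counts
        DataFrame, rows are features, columns are samples.
    conditions
        Mapping sample id -> condition label; every column must be covered.
    lengths
        Optional per-feature lengths in bp (needed for FPKM).
    """

    counts: pd.DataFrame
    conditions: Mapping[str, str]
    lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("feature ids must be unique")
        missing = [s for s in self.counts.columns if s not in self.conditions]
        if missing:
            raise ValueError(f"samples without a condition: {missing}")
        arr = self.counts.to_numpy()
        if not np.isfinite(arr).all() or (arr < 0).any():
            raise ValueError("counts must be finite and nonnegative")
        if self.lengths is not None:
            self.lengths = self.lengths.reindex(self.counts.index)

    @property
    def features(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.conditions[s] == condition]

    def condition_labels(self) -> pd.Series:
        return pd.Series({s: self.conditions[s] for s in self.counts.columns})


def size_factors(m: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    factor_j = median over reference features i of count_ij / geomean_i,
    where the reference set is every feature positive in all samples.
    """
    c = m.counts.to_numpy(dtype=float)
    usable = (c > 0).all(axis=1)
    if not usable.any():
        raise NormalizationError(
            "no feature has positive counts in every sample; "
            "median-of-ratios normalization is undefined"
        )
    logc = np.log(c[usable])
    logref = logc.mean(axis=1)
    f = np.exp(np.median(logc - logref[:, None], axis=0))
    f = f / np.exp(np.mean(np.log(f)))
    return pd.Series(f, index=m.counts.columns, name="size_factor")


_PSEUDOCOUNT = 1.0
_DISPERSION_FLOOR = 1e-8


def nb_test(
    m: CountMatrix,
    contrast: tuple[str, str],
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Two-sided NB Wald test of group B vs group A.

    Per feature: normalize by size factors, estimate the dispersion by
    method of moments on the pooled within-group variance (floored at
    1e-8), and test log2FC = 0 with a Wald statistic whose variance comes
    from the NB mean-variance relation.  The statistic is referred to a t
    distribution with nA + nB - 2 degrees of freedom, which calibrates
    the test at the few-replicate sizes this pipeline runs at (verified
    by simulation in the test suite).

    Fold changes are computed on pseudocounted normalized means,
    FC = (mean_B + 1) / (mean_A + 1).

    Returns a DataFrame with columns baseMeanA, baseMeanB, fc, log2fc, p, q.
    """
    cond_a, cond_b = contrast
    sa = m.samples_of(cond_a)
    sb = m.samples_of(cond_b)
    if not sa or not sb:
        raise ValueError(f"empty contrast group in {contrast!r}")
    if factors is None:
        factors = size_factors(m)
    q = m.counts.to_numpy(dtype=float) / factors.to_numpy()[None, :]
    ia = [m.counts.columns.get_loc(s) for s in sa]
    ib = [m.counts.columns.get_loc(s) for s in sb]
    qa, qb = q[:, ia], q[:, ib]
    na, nb = qa.shape[1], qb.shape[1]

    mu_a = qa.mean(axis=1)
    mu_b = qb.mean(axis=1)
    df = na + nb - 2
    if df >= 1:
        ss = ((qa - mu_a[:, None]) ** 2).sum(axis=1) + ((qb - mu_b[:, None]) ** 2).sum(axis=1)
        s2 = ss / df
    else:
        warnings.warn(
            "single replicate per group: dispersion cannot be estimated, "
            "falling back to Poisson variance and a normal reference",
            stacklevel=2,
        )
        s2 = (mu_a + mu_b) / 2.0
    mu_pool = (na * mu_a + nb * mu_b) / (na + nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = (s2 - mu_pool) / np.maximum(mu_pool, _DISPERSION_FLOOR) ** 2
    disp = np.clip(np.nan_to_num(disp), _DISPERSION_FLOOR, None)

    ma = mu_a + _PSEUDOCOUNT
    mb = mu_b + _PSEUDOCOUNT
    fc = mb / ma
    log2fc = np.log2(fc)
    var_log = (ma + disp * ma**2) / (na * ma**2) + (mb + disp * mb**2) / (nb * mb**2)
    z = np.log(fc) / np.sqrt(var_log)
    if df >= 1:
        p = 2.0 * sps.t.sf(np.abs(z), df)
    else:
        p = 2.0 * sps.norm.sf(np.abs(z))

    allzero = (mu_a == 0) & (mu_b == 0)
    fc[allzero] = 1.0
    log2fc[allzero] = 0.0
    p[allzero] = 1.0
    p = np.clip(p, 0.0, 1.0)

    return pd.DataFrame(
        {
            "baseMeanA": mu_a,
            "baseMeanB": mu_b,
            "fc": fc,
            "log2fc": log2fc,
            "p": p,
            "q": bh_adjust(p),
        },
        index=m.counts.index.rename("feature"),
    )


def bh_adjust(p: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def welch_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Unpaired two-tailed Welch t-test (unequal variances).

    Returns (t, p).  Degenerate zero-variance inputs are resolved by the
    sign of the mean difference rather than returning NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t needs at least 2 observations per group")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return (np.inf if a.mean() > b.mean() else -np.inf), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def _pam_build(d: np.ndarray, k: int) -> list[int]:
    n = d.shape[0]
    medoids = [int(np.argmin(d.sum(axis=1)))]
    nearest = d[:, medoids[0]].copy()
    while len(medoids) < k:
        # gain of adding candidate j: sum of reductions in nearest distance
        gains = np.maximum(nearest[:, None] - d, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        j = int(np.argmax(gains))
        medoids.append(j)
        nearest = np.minimum(nearest, d[:, j])
    return medoids


def pam_cluster(
    x: np.ndarray | pd.DataFrame,
    k: int,
    seed: int = 0,
    max_iter: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Partitioning around medoids (classic BUILD + SWAP), Euclidean distance.

    Input rows are expected already transformed/centered by the caller.
    Returns (labels, medoid_row_indices).  The algorithm is fully
    deterministic; ``seed`` is accepted for interface symmetry with the
    other stochastic operations and for future stochastic variants.

    The SWAP phase repeatedly applies the single (medoid, non-medoid)
    exchange with the largest cost reduction, so the total within-cluster
    cost is non-increasing and the final configuration admits no
    improving single swap.
    """
    del seed
    xv = np.asarray(x, dtype=float)
    n = xv.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds number of rows ({n})")
    d = np.sqrt(np.maximum(((xv[:, None, :] - xv[None, :, :]) ** 2).sum(-1), 0.0))

    medoids = _pam_build(d, k)
    for _ in range(max_iter):
        cost = d[:, medoids].min(axis=1).sum()
        best = (0.0, None)
        for mi, mm in enumerate(medoids):
            trial = list(medoids)
            for h in range(n):
                if h in medoids:
                    continue
                trial[mi] = h
                delta = d[:, trial].min(axis=1).sum() - cost
                if delta < best[0] - 1e-12:
                    best = (delta, (mi, h))
            trial[mi] = mm
        if best[1] is None:
            break
        mi, h = best[1]
        medoids[mi] = h
    medoids_arr = np.array(sorted(medoids))
    labels = np.argmin(d[:, medoids_arr], axis=1)
    return labels, medoids_arr
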