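"""Expression filtering and trimmed-mean-of-M-values (TMM) normalization.

Spike-in rows are excluded before computing normalization factors.  The TMM
implementation follows the canonical published defaults: reference library
chosen by the 75th-percentile rule, 30 % symmetric trimming of M-values and
5 % of A-values, precision weights from the asymptotic binomial variance,
and factors rescaled to geometric mean 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .experiment import TimeCourseExperiment


@dataclass
class NormalizedExpression:
    """TMM factors, effective library sizes, and CPM expression."""

    tmm_factors: pd.Series
    effective_sizes: pd.Series
    cpm: pd.DataFrame
    pseudocount: float = 0.0


def filter_by_expression(exp: TimeCourseExperiment,
                         libraries: list[str] | None = None,
                         min_count: int = 10,
                         min_libraries: int = 3) -> pd.Index:
    """Genes with at least ``min_count`` reads in at least ``min_libraries``.

    ``libraries`` restricts the check to a subset (e.g. the six libraries of
    one pairwise comparison); the rule is applied per comparison upstream of
    each differential test.
    """
    if libraries is None:
        libraries = list(exp.counts.columns)
    if len(libraries) == 0:
        raise ValueError("library subset must be non-empty")
    sub = exp.counts[libraries]
    keep = (sub >= min_count).sum(axis=1) >= min_libraries
    return exp.counts.index[keep]


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              trim_m: float = 0.3, trim_a: float = 0.05) -> float:
    """Log2 TMM factor of one library against the reference."""
    pos = (obs > 0) & (ref > 0)
    obs, ref = obs[pos].astype(float), ref[pos].astype(float)
    if obs.size == 0:
        return 0.0
    po, pr = obs / n_obs, ref / n_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    fin = np.isfinite(m) & np.isfinite(a)
    m, a, w = m[fin], a[fin], w[fin]
    n = m.size
    if n == 0:
        return 0.0
    # double trimming by rank, matching the standard definition
    lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
    rm = pd.Series(m).rank().to_numpy()
    ra = pd.Series(a).rank().to_numpy()
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any() or w[keep].sum() == 0:
        return 0.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return float(f) if np.isfinite(f) else 0.0


def tmm_factors(exp: TimeCourseExperiment) -> pd.Series:
    """Per-library TMM normalization factors (geometric mean 1).

    Spike-in rows are dropped first; library sizes are totals over the
    remaining genes.  The reference library is the one whose upper-quartile
    count fraction is closest to the mean across libraries.
    """
    counts = exp.counts.loc[~exp.spikein]
    mat = counts.to_numpy(dtype=float)
    libsizes = mat.sum(axis=0)
    if np.any(libsizes == 0):
        raise ValueError("library with zero total count")
    f75 = np.quantile(mat, 0.75, axis=0) / libsizes
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    logf = np.array([
        0.0 if j == ref else
        _tmm_pair(mat[:, j], mat[:, ref], libsizes[j], libsizes[ref])
        for j in range(mat.shape[1])
    ])
    factors = 2.0 ** logf
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def cpm(exp: TimeCourseExperiment, factors: pd.Series | None = None,
        pseudocount: float = 0.0) -> NormalizedExpression:
    """Counts per million on TMM-effective library sizes.

    ``cpm[g, l] = (count + pseudocount) / (libsize_l * factor_l) * 1e6``.
    Library sizes exclude spike-in rows; the CPM matrix itself covers all
    rows so spike-ins remain inspectable.
    """
    if factors is None:
        factors = tmm_factors(exp)
    if (factors <= 0).any():
        raise ValueError("TMM factors must be positive")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    libsizes = exp.counts.loc[~exp.spikein].sum(axis=0)
    eff = libsizes * factors.loc[libsizes.index]
    mat = (exp.counts + pseudocount).div(eff, axis=1) * 1e6
    return NormalizedExpression(tmm_factors=factors, effective_sizes=eff,
                                cpm=mat, pseudocount=pseudocount)
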