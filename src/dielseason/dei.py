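"""Daily expression integral (DEI) statistics.

The DEI of a gene in one photoperiod is the area under its 24-h expression
curve, estimated by the trapezoid rule after duplicating the ZT0 value at
ZT24 to close the cycle.  For the equally spaced 4-h design this equals
``4 x (sum of the six sampled values)``.  rDEI is the ratio of DEIs between
two photoperiods (log2 rDEI its antisymmetric form), and the ternary shares
are the exponentiated DEIs normalized across the three photoperiods — the
visual photoperiod-preference metric of the stacked-bar display.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def dei_trapezoid(values_by_zt: np.ndarray, timepoints: np.ndarray) -> float:
    """Wrap-around trapezoid integral of one day of expression.

    ``timepoints`` must be strictly increasing with the first equal to 0;
    the first value is re-appended at t = 24 before integrating.
    """
    t = np.asarray(timepoints, dtype=float)
    v = np.asarray(values_by_zt, dtype=float)
    if t.shape != v.shape:
        raise ValueError("values and timepoints must have equal length")
    if t[0] != 0:
        raise ValueError("the first time point must be ZT0")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time points must be strictly increasing")
    if t[-1] >= 24:
        raise ValueError("time points must lie within one 24-h cycle")
    tt = np.append(t, 24.0)
    vv = np.append(v, v[0])
    return float(np.trapezoid(vv, tt))


def rdei(dei_a: float, dei_b: float, pseudo: float = 0.0
         ) -> tuple[float, float]:
    """(ratio, log2 ratio) of two DEIs; NaN marks undefined ratios.

    With ``pseudo = 0`` a zero denominator yields NaN, and such genes are
    excluded from rankings by the callers.
    """
    if pseudo < 0:
        raise ValueError("pseudo must be >= 0")
    num, den = dei_a + pseudo, dei_b + pseudo
    if den == 0:
        return (float("nan"), float("nan"))
    ratio = num / den
    log2 = float(np.log2(ratio)) if ratio > 0 else float("nan")
    return (float(ratio), log2)


def ternary_shares(dei_sd: float, dei_eq: float, dei_ld: float,
                   exponent: float = 4.0) -> tuple[float, float, float]:
    """Exponentiated-DEI shares (p_SD, p_EQ, p_LD) summing to 1.

    Invariant to multiplying all three DEIs by the same positive constant;
    an all-zero triple is flagged as NaN.
    """
    d = np.array([dei_sd, dei_eq, dei_ld], dtype=float)
    if (d < 0).any():
        raise ValueError("DEI values must be non-negative")
    if (d == 0).all():
        return (float("nan"),) * 3
    scaled = (d / d.max()) ** exponent      # rescale first for stability
    shares = scaled / scaled.sum()
    return tuple(float(s) for s in shares)


_PAIRS = (("SD", "LD"), ("SD", "EQ"), ("EQ", "LD"))


def build_dei_table(mean_expr: pd.DataFrame, exponent: float = 4.0,
                    pseudo: float = 0.0) -> pd.DataFrame:
    """Per-gene DEI per photoperiod, pairwise (log2) rDEI, ternary shares.

    ``mean_expr`` is the replicate-mean expression with MultiIndex columns
    (photoperiod, zt) as produced by :func:`~dielseason.experiment.mean_by_timepoint`.
    """
    photoperiods = list(mean_expr.columns.get_level_values(0).unique())
    out = pd.DataFrame(index=mean_expr.index)
    for pp in photoperiods:
        block = mean_expr[pp]
        t = np.array(sorted(block.columns), dtype=float)
        vals = block[sorted(block.columns)].to_numpy(dtype=float)
        tt = np.append(t, 24.0)
        vv = np.hstack([vals, vals[:, :1]])
        out[f"DEI_{pp}"] = np.trapezoid(vv, tt, axis=1)

    for a, b in _PAIRS:
        if f"DEI_{a}" not in out or f"DEI_{b}" not in out:
            continue
        num = out[f"DEI_{a}"] + pseudo
        den = out[f"DEI_{b}"] + pseudo
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(den > 0, num / den, np.nan)
            out[f"rDEI_{a}_{b}"] = ratio
            out[f"log2_rDEI_{a}_{b}"] = np.where(ratio > 0, np.log2(ratio), np.nan)

    if all(f"DEI_{pp}" in out for pp in ("SD", "EQ", "LD")):
        d = out[["DEI_SD", "DEI_EQ", "DEI_LD"]].to_numpy(dtype=float)
        dmax = d.max(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            scaled = np.where(dmax > 0, (d / dmax) ** exponent, np.nan)
            shares = scaled / scaled.sum(axis=1, keepdims=True)
        out[["p_SD", "p_EQ", "p_LD"]] = shares
    return out
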