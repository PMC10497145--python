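"""Per-gene expression phase estimation at a fixed 24-h period.

Two estimators are combined: a least-squares cosinor fit (phase from the
fitted cosine's peak time, rhythmicity p from the joint F-test of the
harmonic terms) and a template-rank estimator in the style of JTK_CYCLE
(Kendall's tau against cosine templates at integer lags, exact tail p
Bonferroni-scaled over distinct templates).  The combined phase is the
unweighted circular mean of the two estimates; exactly antipodal estimates
are flagged and the cosinor phase reported.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

PERIOD = 24.0


def _wrap(phase: float) -> float:
    """Map a phase in hours to [0, 24), guarding float wrap at 24."""
    p = phase % PERIOD
    return 0.0 if p >= PERIOD - 1e-9 else p


def ls_phase(values, timepoints) -> tuple[float, float]:
    """Cosinor phase (h in [0, 24)) and rhythmicity p for one series.

    Fits ``a + b cos(wt) + c sin(wt)`` (w = 2*pi/24) by least squares; the
    phase is the peak time of the fitted cosine and p comes from the
    F-test of (b, c) jointly zero.  A constant series returns (nan, 1).
    """
    t = np.asarray(timepoints, dtype=float)
    y = np.asarray(values, dtype=float)
    if np.unique(t).size < 4:
        raise ValueError("need at least 4 distinct time points")
    if np.ptp(y) < 1e-12:
        return float("nan"), 1.0
    w = 2.0 * np.pi / PERIOD
    X = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss1 = float(resid @ resid)
    rss0 = float(np.sum((y - y.mean()) ** 2))
    df2 = len(y) - 3
    if df2 <= 0 or rss1 < 1e-300:
        p = 0.0 if rss0 > rss1 else 1.0
    else:
        f = ((rss0 - rss1) / 2.0) / (rss1 / df2)
        p = float(stats.f.sf(f, 2, df2))
    phase = _wrap(float(np.arctan2(beta[2], beta[1]) / w))
    return phase, min(max(p, 0.0), 1.0)


def _distinct_templates(timepoints: np.ndarray) -> dict[int, np.ndarray]:
    """Cosine templates at integer lags, deduplicated by rank signature."""
    seen: dict[tuple, int] = {}
    out: dict[int, np.ndarray] = {}
    w = 2.0 * np.pi / PERIOD
    for lag in range(int(PERIOD)):
        tmpl = np.cos(w * (timepoints - lag))
        sig = tuple(np.round(stats.rankdata(tmpl), 6))
        if sig not in seen:
            seen[sig] = lag
            out[lag] = tmpl
    return out


def template_rank_phase(values, timepoints) -> tuple[float, float]:
    """Template-rank (JTK-style) phase and p for one series.

    Kendall's tau is computed between the observations and cosine
    templates at lags 0..23 h; the phase is the lag of the largest tau
    (ties: circular mean of tied lags) and the p-value is the best lag's
    Kendall tail, Bonferroni-scaled by the number of distinct templates.
    """
    t = np.asarray(timepoints, dtype=float)
    y = np.asarray(values, dtype=float)
    if np.unique(t).size < 4:
        raise ValueError("need at least 4 distinct time points")
    if np.ptp(y) < 1e-12:
        return float("nan"), 1.0
    templates = _distinct_templates(t)
    taus, ps, lags = [], [], []
    for lag, tmpl in templates.items():
        res = stats.kendalltau(y, tmpl)
        taus.append(res.statistic)
        ps.append(res.pvalue)
        lags.append(lag)
    taus = np.asarray(taus)
    best = np.flatnonzero(taus >= taus.max() - 1e-12)
    if best.size == 1:
        phase = float(lags[best[0]])
    else:
        ang = 2.0 * np.pi * np.array([lags[i] for i in best]) / PERIOD
        phase = _wrap(float(np.arctan2(np.sin(ang).sum(), np.cos(ang).sum())
                            / (2.0 * np.pi) * PERIOD))
    # one-sided tail for the best positive association, Bonferroni over
    # distinct templates
    p_best = ps[best[0]] / 2.0 if taus[best[0]] > 0 else 1.0
    p = min(1.0, p_best * len(templates))
    return phase, float(p)


def combine_phases(phase_ls: float, phase_jtk: float
                   ) -> tuple[float, bool]:
    """Unweighted circular mean of two phases (h); flags antipodal input.

    Returns ``(phase, antipodal)``; antipodal estimates (vector sum ~ 0)
    fall back to the cosinor phase.
    """
    a = 2.0 * np.pi * np.array([phase_ls, phase_jtk]) / PERIOD
    x, y = np.cos(a).sum(), np.sin(a).sum()
    if np.hypot(x, y) < 1e-9:
        return _wrap(float(phase_ls)), True
    return _wrap(float(np.arctan2(y, x) / (2.0 * np.pi) * PERIOD)), False


def phase_table(mean_expr: pd.DataFrame) -> pd.DataFrame:
    """Long-format phase table: one row per gene x photoperiod.

    ``mean_expr`` carries MultiIndex columns (photoperiod, zt) of
    replicate-mean expression.  Columns: phase_ls, phase_jtk,
    phase_combined, p_ls, p_jtk, antipodal.
    """
    rows = []
    for pp in mean_expr.columns.get_level_values(0).unique():
        block = mean_expr[pp]
        t = np.array(sorted(block.columns), dtype=float)
        vals = block[sorted(block.columns)].to_numpy(dtype=float)
        for gid, y in zip(mean_expr.index, vals):
            if np.ptp(y) < 1e-12:
                rows.append((gid, pp, np.nan, np.nan, np.nan, 1.0, 1.0, False))
                continue
            pls, p1 = ls_phase(y, t)
            pjt, p2 = template_rank_phase(y, t)
            comb, flag = combine_phases(pls, pjt)
            rows.append((gid, pp, pls, pjt, comb, p1, p2, flag))
    return pd.DataFrame(rows, columns=["gene_id", "photoperiod", "phase_ls",
                                       "phase_jtk", "phase_combined",
                                       "p_ls", "p_jtk", "antipodal"])
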