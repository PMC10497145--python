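"""Pathway-catalog scoring by rDEI.

A curated catalog assigns each gene a pathway role: effect (positive /
negative regulator), molecular function (enzyme, transcription factor,
post-translational) and branch (e.g. lignin vs flavonoid).  Each grouping
is scored by testing the group's log2 rDEI_SD:LD values against zero with
a one-sample Wilcoxon signed-rank test (exact, tie-aware, two-sided), and
each pathway step receives a shading value — the log2 rDEI of its coding
gene, or the mean across listed homologs, flagged unshaded when homologs
disagree in sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

CATALOG_COLUMNS = ("gene_id", "effect", "function", "branch", "step_label")


def wilcoxon_signed_rank(values, mu: float = 0.0) -> tuple[float, float]:
    """One-sample Wilcoxon signed-rank W and two-sided p against ``mu``.

    Differences exactly equal to ``mu`` are excluded before ranking;
    absolute differences are ranked with midranks for ties.  The p-value
    is exact (distribution of W over all sign patterns, computed by
    convolution, tie-aware) for n <= 25 and a tie- and
    continuity-corrected normal approximation otherwise.  All-zero input
    returns ``(nan, 1.0)``.
    """
    d = np.asarray(values, dtype=float) - mu
    d = d[d != 0]
    n = d.size
    if n == 0:
        return float("nan"), 1.0
    ranks = rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    if n <= 25:
        # exact null: each rank contributes to W with probability 1/2.
        # Work on doubled ranks so midranks become integers.
        r2 = np.rint(2 * ranks).astype(int)
        dist = np.zeros(r2.sum() + 1)
        dist[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(dist)
            shifted[r:] = dist[:dist.size - r]
            dist = 0.5 * (dist + shifted)
        w2 = int(round(2 * w))
        p_lo = float(dist[:w2 + 1].sum())
        p_hi = float(dist[w2:].sum())
        p = min(1.0, 2.0 * min(p_lo, p_hi))
    else:
        mean = n * (n + 1) / 4.0
        ties = pd.Series(ranks).value_counts().to_numpy()
        var = n * (n + 1) * (2 * n + 1) / 24.0 - ((ties ** 3 - ties).sum()) / 48.0
        cc = 0.5 * np.sign(w - mean)
        z = (w - mean - cc) / np.sqrt(var)
        p = min(1.0, 2.0 * float(norm.sf(abs(z))))
    return w, p


def _stars(p: float) -> str:
    if p <= 1e-4:
        return "***"
    if p <= 0.05:
        return "*"
    return ""


@dataclass
class CatalogScores:
    groups: pd.DataFrame          # per group: n, mean, median, W, p, stars
    steps: pd.DataFrame           # per step: shading value, consistent flag


def score_catalog(catalog: pd.DataFrame, dei_table: pd.DataFrame,
                  grouping: str = "branch",
                  metric: str = "log2_rDEI_SD_LD") -> CatalogScores:
    """Wilcoxon group scores and per-step shading for one grouping field.

    ``catalog`` needs columns gene_id, effect, function, branch and
    step_label; ``dei_table`` is the per-gene DEI/rDEI table.  Genes absent
    from the DEI table are reported with a warning and skipped.
    """
    if grouping not in ("effect", "function", "branch"):
        raise ValueError("grouping must be effect, function or branch")
    cat = catalog.copy()
    missing = ~cat["gene_id"].isin(dei_table.index)
    if missing.any():
        warnings.warn(f"{int(missing.sum())} catalog genes missing from the "
                      "DEI table; skipped")
        cat = cat[~missing]
    cat = cat.assign(value=dei_table.loc[cat["gene_id"], metric].to_numpy())
    cat = cat[np.isfinite(cat["value"])]

    rows = []
    for name, sub in cat.groupby(grouping, sort=True):
        vals = sub.drop_duplicates("gene_id")["value"].to_numpy()
        if vals.size == 0:
            warnings.warn(f"group {name!r} empty after intersection; skipped")
            continue
        w, p = wilcoxon_signed_rank(vals)
        rows.append((name, vals.size, float(np.mean(vals)),
                     float(np.median(vals)), w, p, _stars(p)))
    groups = pd.DataFrame(rows, columns=[grouping, "n", "mean_log2_rdei",
                                         "median_log2_rdei", "W", "p", "stars"]
                          ).set_index(grouping)

    step_rows = []
    for step, sub in cat.groupby("step_label", sort=True):
        vals = sub.drop_duplicates("gene_id")["value"].to_numpy()
        signs = np.sign(vals[vals != 0])
        consistent = signs.size == 0 or (signs == signs[0]).all()
        shading = float(np.mean(vals)) if consistent else float("nan")
        step_rows.append((step, vals.size, shading, consistent))
    steps = pd.DataFrame(step_rows, columns=["step_label", "n_genes",
                                             "shading", "consistent"]
                         ).set_index("step_label")
    return CatalogScores(groups=groups, steps=steps)
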