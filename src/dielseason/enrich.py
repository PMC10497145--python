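"""Gene-set analytics: preranked GSEA and hypergeometric over-representation.

GSEA ranks all photoperiodic genes by a signed metric (log2 rDEI by
default) and computes the classical weighted Kolmogorov-Smirnov running-sum
enrichment score per set; significance comes from a seeded gene-label
permutation null, with NES normalization by the matching-sign null mean.
Over-representation analysis (ORA) is an exact hypergeometric upper-tail
test of a query gene group against each target set.  Both report
Benjamini-Hochberg adjusted FDRs across sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file: one set per line (name, description, members...)."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up BH adjustment (order-preserving, monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# preranked GSEA
# ---------------------------------------------------------------------------

@dataclass
class GseaResult:
    table: pd.DataFrame                     # per set: size, ES, NES, p, fdr
    leading_edges: dict[str, list[str]]


def _enrichment_score(ranked_abs_w: np.ndarray, hit_mask: np.ndarray
                      ) -> tuple[float, int]:
    """ES and extreme position for one set on a pre-sorted ranking.

    ``ranked_abs_w`` holds |metric|^p in ranking order; hits increment the
    running sum by their normalized weight, misses decrement by 1/(N - m).
    """
    n = ranked_abs_w.size
    m = int(hit_mask.sum())
    if m == 0 or m == n:
        return 0.0, 0
    w_hit = ranked_abs_w * hit_mask
    total = w_hit.sum()
    if total == 0:             # all hit weights zero: fall back to unweighted
        w_hit = hit_mask.astype(float)
        total = float(m)
    step = w_hit / total - (~hit_mask).astype(float) / (n - m)
    running = np.cumsum(step)
    i_max, i_min = int(np.argmax(running)), int(np.argmin(running))
    if running[i_max] >= -running[i_min]:
        return float(running[i_max]), i_max
    return float(running[i_min]), i_min


def gsea_preranked(ranking: pd.Series, sets: dict[str, list[str]],
                   weight: float = 1.0, n_perm: int = 1000, seed: int = 0,
                   min_size: int = 20, max_size: int = 500) -> GseaResult:
    """Weighted-KS preranked GSEA with a gene-label permutation null.

    ``ranking`` maps gene id to a finite signed metric.  Sets are filtered
    to ``[min_size, max_size]`` after intersection with the ranked genes;
    the two-sided p-value uses the matching-sign tail of the null, and NES
    divides ES by the mean |null ES| of that sign.
    """
    ranking = ranking.dropna()
    if not np.isfinite(ranking.to_numpy()).all():
        raise ValueError("ranking metric must be finite")
    order = np.argsort(-ranking.to_numpy(), kind="stable")
    genes = ranking.index.to_numpy()[order]
    absw = np.abs(ranking.to_numpy()[order]) ** weight
    pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    rows, leading = [], {}
    for name, members in sets.items():
        idx = np.array(sorted(pos[g] for g in set(members) if g in pos), dtype=int)
        if not (min_size <= idx.size <= max_size):
            continue
        mask = np.zeros(genes.size, dtype=bool)
        mask[idx] = True
        es, extreme = _enrichment_score(absw, mask)

        null = np.empty(n_perm)
        for b in range(n_perm):
            pm = np.zeros(genes.size, dtype=bool)
            pm[rng.choice(genes.size, size=idx.size, replace=False)] = True
            null[b], _ = _enrichment_score(absw, pm)
        same = null[np.sign(null) == np.sign(es)] if es != 0 else null
        if same.size == 0:
            p, nes = 1.0 / (n_perm + 1), np.nan
        else:
            p = (1 + np.sum(np.abs(same) >= abs(es))) / (1 + same.size)
            denom = np.mean(np.abs(same))
            nes = es / denom if denom > 0 else np.nan

        if es >= 0:
            lead = [g for g in genes[:extreme + 1] if mask[pos[g]]]
        else:
            lead = [g for g in genes[extreme:] if mask[pos[g]]]
        leading[name] = lead
        rows.append((name, idx.size, es, nes, p))

    table = pd.DataFrame(rows, columns=["term", "size", "ES", "NES", "p"]
                         ).set_index("term")
    table["fdr"] = benjamini_hochberg(table["p"].to_numpy()) if len(table) else []
    return GseaResult(table=table, leading_edges=leading)


# ---------------------------------------------------------------------------
# over-representation
# ---------------------------------------------------------------------------

def ora_hypergeometric(query: set[str], target: set[str],
                       universe: set[str]) -> tuple[int, float]:
    """Overlap k and hypergeometric upper-tail p of query vs target."""
    if not universe:
        raise ValueError("universe must be non-empty")
    q = set(query) & universe
    t = set(target) & universe
    k = len(q & t)
    p = float(hypergeom.sf(k - 1, len(universe), len(t), len(q)))
    return k, min(p, 1.0)


def ora_collection(query: set[str], sets: dict[str, list[str]],
                   universe: set[str], min_size: int = 10,
                   max_size: int = 500) -> pd.DataFrame:
    """ORA of one query against a collection, with BH across sets."""
    rows = []
    q = set(query) & set(universe)
    for name, members in sets.items():
        t = set(members) & set(universe)
        if not (min_size <= len(t) <= max_size):
            continue
        k, p = ora_hypergeometric(q, t, set(universe))
        expected = len(t) * len(q) / len(universe)
        fold = (k / expected) if expected > 0 else np.nan
        rows.append((name, len(t), k, expected, fold, p))
    out = pd.DataFrame(rows, columns=["term", "size", "k", "expected",
                                      "fold", "p"]).set_index("term")
    out["fdr"] = benjamini_hochberg(out["p"].to_numpy()) if len(out) else []
    return out
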