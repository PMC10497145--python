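"""Photoperiodic gene identification by per-time-point exact count tests.

For each pair of photoperiods at each sampled zeitgeber time (3 pairs x 6
times = 18 comparisons in the default design), replicate counts of the two
groups are compared with an exact conditional negative-binomial test under
a common dispersion.  A gene is called photoperiodic if it is significant
in at least one comparison; this inclusive union (default p < 0.2,
unadjusted within each comparison) feeds clustering and the DEI statistics,
while the FDR < 0.05 mode provides the stringent variant.

The exact test conditions on the total count of both groups.  With library
sizes equalized, the sum of each group's counts is itself negative binomial,
so the conditional distribution of the group-A sum given the grand total is
a ratio of binomial-type coefficients; two-sided p-values sum the
probabilities of all splits no more likely than the observed one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp

from .experiment import TimeCourseExperiment
from .normalize import filter_by_expression, tmm_factors
from .enrich import benjamini_hochberg


@dataclass
class ComparisonResult:
    """Per-gene statistics for one (photoperiod pair, ZT) comparison."""

    pair: tuple[str, str]
    zt: float
    table: pd.DataFrame          # columns: lfc, p, fdr; index: gene ids
    dispersion: float = 0.0


@dataclass
class PhotoperiodicGeneSet:
    """Union of genes passing the threshold in >= 1 comparison."""

    genes: pd.Index
    passing: dict[str, list[tuple[str, str, float]]] = field(default_factory=dict)
    alpha: float = 0.2
    use_fdr: bool = False


# ---------------------------------------------------------------------------
# exact conditional test
# ---------------------------------------------------------------------------

def _cond_logpmf(total: int, n_a: int, n_b: int, phi: float) -> np.ndarray:
    """Log P(sum_A = k | total) for k = 0..total under the null.

    With dispersion phi the group sums are NB with size ``n/phi``; the
    success probability cancels after conditioning.  phi = 0 is the Poisson
    limit, a Binomial(total, n_a/(n_a+n_b)) split.
    """
    k = np.arange(total + 1, dtype=float)
    if phi <= 0:
        logp = (gammaln(total + 1) - gammaln(k + 1) - gammaln(total - k + 1)
                + k * np.log(n_a / (n_a + n_b))
                + (total - k) * np.log(n_b / (n_a + n_b)))
    else:
        ra, rb = n_a / phi, n_b / phi
        logp = (gammaln(k + ra) - gammaln(k + 1)
                + gammaln(total - k + rb) - gammaln(total - k + 1))
        logp -= logsumexp(logp)
    return logp - logsumexp(logp)


def nb_exact_test(group_a: np.ndarray, group_b: np.ndarray,
                  dispersion: float = 0.0) -> float:
    """Two-sided exact conditional p-value for two groups of counts.

    Counts are rounded to integers (they may carry library-size
    equalization).  The p-value sums conditional probabilities of all
    splits whose probability does not exceed the observed one
    (minimum-likelihood two-sided rule), capped at 1; it is symmetric in
    the group labels.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    a = np.rint(np.asarray(group_a, dtype=float)).astype(int)
    b = np.rint(np.asarray(group_b, dtype=float)).astype(int)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("counts must be non-negative")
    sa, total = int(a.sum()), int(a.sum() + b.sum())
    if total == 0:
        return 1.0
    logp = _cond_logpmf(total, len(a), len(b), dispersion)
    obs = logp[sa]
    p = float(np.exp(logsumexp(logp[logp <= obs + 1e-10])))
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# common dispersion
# ---------------------------------------------------------------------------

def _cond_loglik(counts: np.ndarray, phi: float) -> float:
    """Conditional (on row totals) NB log-likelihood of replicate groups.

    ``counts`` is genes x replicates for one group sharing a mean per gene.
    """
    y = counts
    n = y.shape[1]
    t = y.sum(axis=1)
    if phi <= 1e-12:
        # Poisson limit: symmetric multinomial
        ll = (gammaln(t + 1) - gammaln(y + 1).sum(axis=1) - t * np.log(n))
        return float(ll.sum())
    r = 1.0 / phi
    ll = (gammaln(y + r).sum(axis=1) - n * gammaln(r) - gammaln(y + 1).sum(axis=1)
          - (gammaln(t + n * r) - gammaln(n * r) - gammaln(t + 1)))
    return float(ll.sum())


def estimate_common_dispersion(groups: list[np.ndarray]) -> float:
    """Maximize the summed conditional log-likelihood over log-dispersion.

    ``groups`` holds one genes x replicates integer matrix per experimental
    group.  The search is a bounded 1-D optimization on
    ``log(phi) in [-10, 5]``; degenerate all-zero input returns 0 with a
    warning.
    """
    groups = [np.rint(np.asarray(g, dtype=float)).astype(int) for g in groups
              if g.shape[0] > 0 and g.shape[1] >= 2]
    if not groups or all((g == 0).all() for g in groups):
        warnings.warn("degenerate data for dispersion estimation; returning 0")
        return 0.0

    def neg_ll(log_phi: float) -> float:
        phi = float(np.exp(log_phi))
        return -sum(_cond_loglik(g, phi) for g in groups)

    res = minimize_scalar(neg_ll, bounds=(-10.0, 5.0), method="bounded",
                          options={"xatol": 1e-4})
    phi = float(np.exp(res.x))
    # prefer the Poisson limit when the boundary fits at least as well
    if neg_ll(-10.0) <= res.fun + 1e-9:
        return float(np.exp(-10.0))
    return phi


# ---------------------------------------------------------------------------
# the screen
# ---------------------------------------------------------------------------

def _equalize(counts: pd.DataFrame, eff_sizes: pd.Series) -> pd.DataFrame:
    """Scale counts to a common effective library size (geometric mean)."""
    target = float(np.exp(np.log(eff_sizes).mean()))
    return counts * (target / eff_sizes)


def screen(exp: TimeCourseExperiment, alpha: float = 0.2,
           use_fdr: bool = False, min_count: int = 10, min_libraries: int = 3,
           ) -> tuple[PhotoperiodicGeneSet, list[ComparisonResult]]:
    """Run all pairwise photoperiod comparisons at every time point.

    Spike-ins are excluded; TMM-effective library sizes are computed once
    from the full experiment; filtering is re-applied within each
    comparison.  Returns the union gene set and every per-comparison table.
    """
    work = exp.without_spikeins()
    factors = tmm_factors(exp)
    eff = exp.counts.loc[~exp.spikein].sum(axis=0) * factors

    results: list[ComparisonResult] = []
    passing: dict[str, list[tuple[str, str, float]]] = {}

    for pp_a, pp_b in combinations(work.photoperiods, 2):
        for zt in work.timepoints:
            libs_a = work.libraries_for(pp_a, zt)
            libs_b = work.libraries_for(pp_b, zt)
            libs = libs_a + libs_b
            kept = filter_by_expression(work, libs, min_count, min_libraries)
            if len(kept) == 0:
                results.append(ComparisonResult((pp_a, pp_b), zt,
                                                pd.DataFrame(columns=["lfc", "p", "fdr"])))
                continue
            eq = _equalize(work.counts.loc[kept, libs], eff.loc[libs])
            mat_a = np.rint(eq[libs_a].to_numpy()).astype(int)
            mat_b = np.rint(eq[libs_b].to_numpy()).astype(int)
            phi = estimate_common_dispersion([mat_a, mat_b])

            pvals = np.empty(len(kept))
            cache: dict[int, np.ndarray] = {}
            for i in range(len(kept)):
                total = int(mat_a[i].sum() + mat_b[i].sum())
                logp = cache.get(total)
                if logp is None:
                    logp = _cond_logpmf(total, mat_a.shape[1], mat_b.shape[1], phi)
                    if total <= 20000:
                        cache[total] = logp
                obs = logp[int(mat_a[i].sum())]
                pvals[i] = min(1.0, float(np.exp(
                    logsumexp(logp[logp <= obs + 1e-10]))))

            lfc = np.log2((mat_a.mean(axis=1) + 0.5) / (mat_b.mean(axis=1) + 0.5))
            fdr = benjamini_hochberg(pvals)
            table = pd.DataFrame({"lfc": lfc, "p": pvals, "fdr": fdr}, index=kept)
            results.append(ComparisonResult((pp_a, pp_b), zt, table, phi))

            crit = table["fdr"] if use_fdr else table["p"]
            for gid in table.index[crit < alpha]:
                passing.setdefault(gid, []).append((pp_a, pp_b, zt))

    union = pd.Index(sorted(passing))
    return PhotoperiodicGeneSet(genes=union, passing=passing,
                                alpha=alpha, use_fdr=use_fdr), results
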