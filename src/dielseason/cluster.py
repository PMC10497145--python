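"""Pattern clustering: affinity propagation, exemplar agglomeration, and a
hybrid dynamic tree cut into subgroups.

The pipeline clusters photoperiodic genes on the Pearson correlation of
their concatenated per-photoperiod replicate-mean profiles (SD || EQ || LD,
18 values in the default design).  Affinity propagation (shared preference
= the 0.5 quantile of off-diagonal similarities) yields fine clusters with
exemplar genes; the exemplars are then agglomerated — repeatedly merging
the pair of clusters whose best joint exemplar has the highest mean
similarity to the merged membership — and the resulting dendrogram is cut
at a similarity threshold (0.82 by default) to produce the major clusters
C1..Cn.  Within each major cluster, an average-linkage tree on 1 - r is cut
with a hybrid dynamic procedure whose granularity is set by a deep-split
level, giving the lettered subgroups; each subgroup's exemplar is its
similarity medoid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform
from sklearn.cluster import AffinityPropagation

__all__ = [
    "pattern_matrix", "pearson_similarity", "affinity_propagation",
    "agglomerate_exemplars", "dynamic_tree_cut", "subgroup_exemplar",
    "cluster_genes", "ClusterHierarchy",
]

#: deep-split level -> (maxCoreScatter, minGap) for the hybrid tree cut
DEEP_SPLIT_PARAMS = {1: (0.73, 0.135), 2: (0.82, 0.09), 3: (0.91, 0.045)}


# ---------------------------------------------------------------------------
# patterns and similarity
# ---------------------------------------------------------------------------

def pattern_matrix(mean_expr: pd.DataFrame, genes=None,
                   zscore: bool = False) -> pd.DataFrame:
    """Genes x conditions profile matrix; constant genes are dropped.

    Pearson correlation is affine-invariant per gene, so z-scoring changes
    nothing downstream; it is offered for heatmap export only.
    """
    mat = mean_expr if genes is None else mean_expr.loc[list(genes)]
    vals = mat.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    constant = sd < 1e-12
    if constant.any():
        warnings.warn(f"dropping {int(constant.sum())} constant-profile genes")
        mat = mat.loc[~constant]
        vals, sd = vals[~constant], sd[~constant]
    if zscore:
        vals = (vals - vals.mean(axis=1, keepdims=True)) / sd[:, None]
        mat = pd.DataFrame(vals, index=mat.index, columns=mat.columns)
    return mat


def pearson_similarity(patterns: pd.DataFrame) -> pd.DataFrame:
    """Symmetric gene x gene Pearson correlation matrix (diagonal 1)."""
    vals = patterns.to_numpy(dtype=float)
    if np.any(vals.std(axis=1) < 1e-12):
        raise ValueError("constant gene profiles must be removed first")
    sim = np.corrcoef(vals)
    return pd.DataFrame(sim, index=patterns.index, columns=patterns.index)


# ---------------------------------------------------------------------------
# affinity propagation
# ---------------------------------------------------------------------------

@dataclass
class APResult:
    labels: np.ndarray            # cluster id per gene (0..k-1)
    exemplars: np.ndarray         # row index of each cluster's exemplar
    converged: bool = True


def affinity_propagation(similarity: pd.DataFrame,
                         preference_quantile: float = 0.5,
                         damping: float = 0.9, max_iter: int = 1000,
                         convergence_iter: int = 100,
                         random_state: int = 0) -> APResult:
    """Affinity propagation on a precomputed similarity matrix.

    The shared preference is the given quantile of the off-diagonal
    similarities.  Non-convergence returns the single-cluster fallback with
    ``converged=False`` rather than raising.
    """
    S = similarity.to_numpy(dtype=float)
    n = S.shape[0]
    if n == 1:
        return APResult(labels=np.zeros(1, dtype=int),
                        exemplars=np.zeros(1, dtype=int))
    off = S[~np.eye(n, dtype=bool)]
    pref = float(np.quantile(off, preference_quantile))
    model = AffinityPropagation(affinity="precomputed", damping=damping,
                                max_iter=max_iter,
                                convergence_iter=convergence_iter,
                                preference=pref, random_state=random_state)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        labels = model.fit_predict(S.copy())
    exemplars = model.cluster_centers_indices_
    if exemplars is None or len(exemplars) == 0 or (labels < 0).any():
        medoid = int(np.argmax(S.sum(axis=1)))
        return APResult(labels=np.zeros(n, dtype=int),
                        exemplars=np.array([medoid]), converged=False)
    return APResult(labels=labels, exemplars=np.asarray(exemplars))


# ---------------------------------------------------------------------------
# exemplar agglomeration
# ---------------------------------------------------------------------------

@dataclass
class ExemplarDendrogram:
    merges: list[tuple[frozenset, frozenset, float]]   # (left, right, height)
    initial: list[frozenset]                           # AP cluster memberships

    def to_newick(self, names: dict[frozenset, str] | None = None) -> str:
        """Newick string with branch lengths 1 - merge similarity."""
        label: dict[frozenset, str] = {}
        for i, cl in enumerate(self.initial):
            label[cl] = (names or {}).get(cl, f"AP{i}")
        height: dict[frozenset, float] = {cl: 0.0 for cl in self.initial}
        for left, right, h in self.merges:
            node = left | right
            d = 1.0 - h
            bl = max(d - height[left], 0.0)
            br = max(d - height[right], 0.0)
            label[node] = f"({label[left]}:{bl:.6g},{label[right]}:{br:.6g})"
            height[node] = d
        roots = self._roots()
        if len(roots) == 1:
            return label[roots[0]] + ";"
        return "(" + ",".join(label[r] + ":0" for r in roots) + ");"

    def _roots(self) -> list[frozenset]:
        alive = set(self.initial)
        for left, right, _ in self.merges:
            alive.discard(left)
            alive.discard(right)
            alive.add(left | right)
        return sorted(alive, key=lambda s: -len(s))


def _best_joint_exemplar(members: np.ndarray, S: np.ndarray) -> tuple[int, float]:
    """Member maximizing mean similarity to the other members, and that mean."""
    if members.size == 1:
        return int(members[0]), 1.0
    block = S[np.ix_(members, members)]
    sums = block.sum(axis=1) - 1.0          # drop self-similarity
    means = sums / (members.size - 1)
    best = int(np.argmax(means))
    return int(members[best]), float(means[best])


def agglomerate_exemplars(ap: APResult, similarity: pd.DataFrame,
                          cut: float = 0.82
                          ) -> tuple[np.ndarray, ExemplarDendrogram]:
    """Merge AP clusters bottom-up by best-joint-exemplar similarity.

    At each step the pair whose merged membership admits the best joint
    exemplar (highest mean similarity to the union) is merged and that mean
    recorded as the merge height.  Merges are applied while the best height
    stays at or above ``cut``; the remaining clusters, relabelled by
    descending size, are the major clusters.
    """
    S = similarity.to_numpy(dtype=float)
    clusters: list[np.ndarray] = [np.flatnonzero(ap.labels == k)
                                  for k in range(ap.labels.max() + 1)]
    initial = [frozenset(c.tolist()) for c in clusters]
    merges: list[tuple[frozenset, frozenset, float]] = []
    assignment = [list(c) for c in clusters]

    def merge_height(i: int, j: int) -> float:
        union = np.concatenate([assignment[i], assignment[j]])
        return _best_joint_exemplar(union, S)[1]

    active = list(range(len(clusters)))
    heights: dict[tuple[int, int], float] = {}
    cut_applied = [True] * len(clusters)
    next_sets = {i: initial[i] for i in active}
    passed_cut = True
    while len(active) > 1:
        best, best_h = None, -np.inf
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                key = (min(i, j), max(i, j))
                h = heights.get(key)
                if h is None:
                    h = merge_height(i, j)
                    heights[key] = h
                if h > best_h:
                    best, best_h = (i, j), h
        i, j = best
        merges.append((next_sets[i], next_sets[j], best_h))
        if passed_cut and best_h < cut:
            passed_cut = False
        new_id = len(assignment)
        assignment.append(assignment[i] + assignment[j])
        next_sets[new_id] = next_sets[i] | next_sets[j]
        cut_applied.append(passed_cut)
        active = [a for a in active if a not in (i, j)] + [new_id]
        heights = {k: v for k, v in heights.items() if i not in k and j not in k}

    # replay merges up to the cut to recover the major clusters
    final: list[list[int]] = [list(np.flatnonzero(ap.labels == k))
                              for k in range(ap.labels.max() + 1)]
    comp = list(range(len(final)))           # union-find over initial clusters

    def find(x: int) -> int:
        while comp[x] != x:
            comp[x] = comp[comp[x]]
            x = comp[x]
        return x

    set_to_id = {initial[i]: i for i in range(len(initial))}
    for left, right, h in merges:
        if h < cut:
            break
        li, ri = set_to_id[left], set_to_id[right]
        set_to_id[left | right] = li
        comp[find(ri)] = find(li)

    roots: dict[int, int] = {}
    major = np.empty(len(ap.labels), dtype=int)
    for k in range(len(initial)):
        r = find(k)
        roots.setdefault(r, len(roots))
    for g in range(len(ap.labels)):
        major[g] = roots[find(ap.labels[g])]

    # relabel by descending size (C1 is the largest)
    sizes = pd.Series(major).value_counts()
    remap = {old: rank for rank, old in enumerate(sizes.index)}
    major = np.array([remap[m] for m in major])
    return major, ExemplarDendrogram(merges=merges, initial=initial)


# ---------------------------------------------------------------------------
# hybrid dynamic tree cut
# ---------------------------------------------------------------------------

def _subtree_stats(node, dists: list[float]) -> None:
    if node.is_leaf():
        return
    dists.append(node.dist)
    _subtree_stats(node.left, dists)
    _subtree_stats(node.right, dists)


def dynamic_tree_cut(dissimilarity: np.ndarray, deep_split: int = 2,
                     min_cluster_size: int = 20) -> np.ndarray:
    """Hybrid dynamic cut of an average-linkage tree into subgroups.

    Branch candidates are evaluated top-down with two criteria derived from
    the deep-split level: the *core scatter* (mean of the branch's lowest
    merge heights, in raw 1 - r units) must not exceed ``maxCoreScatter``,
    and the *gap* between the height at which the branch joins its sibling
    and the branch's own top merge (90th percentile of its internal merge
    heights) must be at least ``minGap``.  A node is split only when both children qualify (or
    one qualifies and the other is below the minimum size, in which case
    the small side is later attached to the nearest subgroup by medoid
    correlation).  Deeper split levels relax both criteria, so the deeper
    partition refines the shallower one on the same tree.

    Returns integer labels (0..k-1) per row of ``dissimilarity``.
    """
    if deep_split not in DEEP_SPLIT_PARAMS:
        raise ValueError(f"deep_split must be one of {sorted(DEEP_SPLIT_PARAMS)}")
    max_scatter, min_gap = DEEP_SPLIT_PARAMS[deep_split]
    D = np.asarray(dissimilarity, dtype=float)
    n = D.shape[0]
    if n <= min_cluster_size or n < 2:
        return np.zeros(n, dtype=int)

    Z = linkage(squareform(D, checks=False), method="average")
    root = to_tree(Z)

    def qualifies(node, attach_h: float) -> bool:
        # Heights are raw correlation-dissimilarity (1 - r) units, so the
        # criteria do not depend on which other genes share the tree.  The
        # branch top uses the 90th percentile of internal merge heights:
        # the literal maximum is an extreme statistic that single chained
        # outliers push to the attachment height.
        if node.count < min_cluster_size:
            return False
        dists: list[float] = []
        _subtree_stats(node, dists)
        if not dists:
            return True
        dists = sorted(dists)
        k = min(len(dists), min_cluster_size - 1 + int(np.sqrt(node.count)))
        core = float(np.mean(dists[:k]))
        gap = attach_h - float(np.quantile(dists, 0.90))
        return core <= max_scatter and gap >= min_gap

    clusters: list[list[int]] = []
    unassigned: list[int] = []

    def descend(node) -> list[int] | None:
        """Split recursively; returns leaves if the node stays whole."""
        if node.is_leaf():
            return [node.id]
        left, right = node.left, node.right
        ql = qualifies(left, node.dist)
        qr = qualifies(right, node.dist)
        if ql and qr:
            for child in (left, right):
                whole = descend(child)
                if whole is not None:
                    clusters.append(whole)
            return None
        if ql and right.count < min_cluster_size:
            unassigned.extend(right.pre_order(lambda x: x.id))
            whole = descend(left)
            if whole is not None:
                clusters.append(whole)
            return None
        if qr and left.count < min_cluster_size:
            unassigned.extend(left.pre_order(lambda x: x.id))
            whole = descend(right)
            if whole is not None:
                clusters.append(whole)
            return None
        return node.pre_order(lambda x: x.id)

    whole = descend(root)
    if whole is not None:
        return np.zeros(n, dtype=int)

    labels = np.full(n, -1, dtype=int)
    for k, members in enumerate(clusters):
        labels[members] = k
    if unassigned:
        # attach leftovers to the subgroup whose medoid they resemble most
        S = 1.0 - D
        medoids = []
        for members in clusters:
            members = np.asarray(members)
            medoids.append(members[int(np.argmax(
                S[np.ix_(members, members)].sum(axis=1)))])
        for g in unassigned:
            labels[g] = int(np.argmax([S[g, m] for m in medoids]))
    return labels


def subgroup_exemplar(subgroup_genes: list[str],
                      similarity: pd.DataFrame) -> str:
    """Similarity medoid of a subgroup; ties break to the smallest gene id."""
    if len(subgroup_genes) == 0:
        raise ValueError("subgroup must be non-empty")
    genes = sorted(subgroup_genes)
    block = similarity.loc[genes, genes].to_numpy(dtype=float)
    totals = block.sum(axis=1)
    best = int(np.argmax(totals - 1e-12 * np.arange(len(genes))))
    return genes[best]


# ---------------------------------------------------------------------------
# end-to-end hierarchy
# ---------------------------------------------------------------------------

def _letters(i: int) -> str:
    out = ""
    i += 1
    while i > 0:
        i, r = divmod(i - 1, 26)
        out = chr(ord("A") + r) + out
    return out


@dataclass
class ClusterHierarchy:
    """AP clusters, major clusters, and subgroups at two cut depths."""

    membership: pd.DataFrame       # ap_cluster, major_cluster, subgroup_d2/_d3
    exemplars: dict[str, str] = field(default_factory=dict)
    dendrogram: ExemplarDendrogram | None = None
    ap_converged: bool = True

    def subgroups(self, depth: int = 3) -> dict[str, list[str]]:
        col = f"subgroup_d{depth}"
        return {name: list(idx) for name, idx
                in self.membership.groupby(col).groups.items()}


def cluster_genes(patterns: pd.DataFrame, cut: float = 0.82,
                  preference_quantile: float = 0.5, damping: float = 0.9,
                  max_iter: int = 1000, convergence_iter: int = 100,
                  min_cluster_size: int = 20,
                  deep_splits: tuple[int, ...] = (2, 3)) -> ClusterHierarchy:
    """Full clustering stage: AP -> exemplar agglomeration -> dynamic cut."""
    sim = pearson_similarity(patterns)
    genes = list(patterns.index)
    ap = affinity_propagation(sim, preference_quantile, damping,
                              max_iter, convergence_iter)
    major, dendro = agglomerate_exemplars(ap, sim, cut=cut)

    member = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    member["ap_cluster"] = ap.labels
    member["major_cluster"] = [f"C{m + 1}" for m in major]

    exemplars: dict[str, str] = {}
    S = sim.to_numpy(dtype=float)
    for depth in deep_splits:
        col = f"subgroup_d{depth}"
        member[col] = ""
        for cname, rows in member.groupby("major_cluster").groups.items():
            idx = np.array([genes.index(g) for g in rows])
            D = 1.0 - S[np.ix_(idx, idx)]
            np.fill_diagonal(D, 0.0)
            labels = dynamic_tree_cut(D, deep_split=depth,
                                      min_cluster_size=min_cluster_size)
            num = cname.lstrip("C")
            # letters assigned in dendrogram (leaf-appearance) order
            order: dict[int, int] = {}
            for lab in labels:
                if lab not in order:
                    order[lab] = len(order)
            for g, lab in zip(rows, labels):
                member.loc[g, col] = f"{num}{_letters(order[lab])}"
        for sg, rows in member.groupby(col).groups.items():
            key = f"d{depth}:{sg}"
            exemplars[key] = subgroup_exemplar(list(rows), sim)

    return ClusterHierarchy(membership=member, exemplars=exemplars,
                            dendrogram=dendro, ap_converged=ap.converged)
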