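"""Unsupervised sample clustering: Spearman dissimilarity + Ward linkage.

The sample dissimilarity is ``1 - rho`` with ``rho`` Spearman's rank
correlation computed pairwise-complete (features present in both samples,
average ranks for ties), so ``d`` lives in ``[0, 2]``. Agglomeration follows
Ward's minimum-variance criterion via the Lance-Williams recurrence applied
to the dissimilarities as given (the classic "ward.D" dialect); pass
``squared=True`` to update squared dissimilarities instead ("ward.D2").
Merge ties are broken deterministically in favour of the pair containing the
lexicographically smallest leaf ids.

Also here: rank matrices for heatmap colouring, cluster cutting/naming,
identification of the features driving a two-way split (rank-sum +
Bonferroni, delegated to :mod:`mirgist.diffexp`), removal of a feature block
(e.g. the 14q32 imprinted miRNA cluster) and Newick export of the tree.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import ExpressionMatrix


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample dissimilarities with zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError(f"distance matrix shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-9):
            raise ValueError("distance matrix diagonal is not zero")
        self.values = v


@dataclass
class Dendrogram:
    """Agglomerative merge tree in scipy linkage convention.

    ``leaves[i]`` is node ``i``; merge ``j`` (row ``j`` of ``merges``) joins
    nodes ``(a, b)`` at ``height`` into new node ``n + j``.
    """

    leaves: list[str]
    merges: list[tuple[int, int, float]]

    def __post_init__(self):
        n = len(self.leaves)
        if len(self.merges) != max(n - 1, 0):
            raise ValueError(f"{n} leaves require {n - 1} merges, got {len(self.merges)}")
        heights = [h for _, _, h in self.merges]
        if any(b < a - 1e-9 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-decreasing")

    def cluster_members(self, n_merges: int) -> list[set[str]]:
        """Leaf partition after applying the first ``n_merges`` merges."""
        n = len(self.leaves)
        components: dict[int, set[str]] = {i: {leaf} for i, leaf in enumerate(self.leaves)}
        for j, (a, b, _h) in enumerate(self.merges[:n_merges]):
            components[n + j] = components.pop(a) | components.pop(b)
        return list(components.values())


@dataclass
class ClusterLabels:
    """Sample id -> cluster-name assignment plus how the cut was made."""

    assignments: dict[str, str]
    scheme: str = ""

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sample, name in self.assignments.items():
            out.setdefault(name, []).append(sample)
        return {k: sorted(v) for k, v in out.items()}


def spearman_dissimilarity(expr: ExpressionMatrix, min_overlap: int = 10) -> DistanceMatrix:
    """Pairwise ``1 - rho_spearman`` over features present in both samples.

    A sample pair sharing fewer than ``min_overlap`` detected features is an
    error naming the pair (silent NaN propagation would poison the tree).
    """
    samples = expr.samples
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to compute dissimilarities")
    x = expr.values.to_numpy(dtype=float)
    present = np.isfinite(x)
    n = len(samples)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = present[:, i] & present[:, j]
            if shared.sum() < min_overlap:
                raise ValueError(
                    f"samples ({samples[i]}, {samples[j]}) share only "
                    f"{int(shared.sum())} features (< {min_overlap})"
                )
            rho = stats.spearmanr(x[shared, i], x[shared, j]).statistic
            d[i, j] = d[j, i] = 1.0 - rho
    return DistanceMatrix(list(samples), d)


def ward_hclust(d: DistanceMatrix, squared: bool = False) -> Dendrogram:
    """Ward's-criterion agglomeration by the Lance-Williams recurrence.

    With ``squared=False`` the recurrence updates the dissimilarities as
    given and merge heights are on the input scale (ward.D); with
    ``squared=True`` squared dissimilarities are updated and heights are
    square-rooted back (ward.D2). Deterministic: equal-cost merges pick the
    pair whose clusters contain the lexicographically smallest leaf ids.
    """
    n = len(d.ids)
    if n < 2:
        raise ValueError("need at least 2 samples to cluster")
    work = d.values.astype(float).copy()
    if squared:
        work = work**2

    # active cluster id -> (node index, size, smallest leaf id)
    active: dict[int, tuple[int, int, str]] = {
        i: (i, 1, d.ids[i]) for i in range(n)
    }
    dist: dict[frozenset[int], float] = {
        frozenset((i, j)): work[i, j] for i in range(n) for j in range(i + 1, n)
    }
    merges: list[tuple[int, int, float]] = []
    next_node = n
    for _ in range(n - 1):
        best = None
        for key, cost in dist.items():
            i, j = sorted(key)
            mi, mj = active[i][2], active[j][2]
            rank = (cost, *sorted((mi, mj)))
            if best is None or rank < best[0]:
                best = (rank, i, j, cost)
        _, i, j, cost = best
        node_i, size_i, min_i = active[i]
        node_j, size_j, min_j = active[j]
        height = np.sqrt(cost) if squared else cost
        merges.append((node_i, node_j, float(height)))
        others = [k for k in active if k not in (i, j)]
        for k in others:
            size_k = active[k][1]
            total = size_i + size_j + size_k
            d_new = (
                (size_i + size_k) * dist[frozenset((i, k))]
                + (size_j + size_k) * dist[frozenset((j, k))]
                - size_k * cost
            ) / total
            dist[frozenset((i, k))] = d_new  # reuse slot i for the merged cluster
            del dist[frozenset((j, k))]
        del dist[frozenset((i, j))]
        active[i] = (next_node, size_i + size_j, min(min_i, min_j))
        del active[j]
        next_node += 1
    return Dendrogram(list(d.ids), merges)


def cut_clusters(t: Dendrogram, k: int) -> ClusterLabels:
    """Cut the ``k - 1`` highest merges to obtain ``k`` clusters.

    Clusters are named A, B, C, ... in decreasing size order, ties broken by
    the lexicographically smallest member sample id.
    """
    n = len(t.leaves)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    groups = t.cluster_members(n - k)
    groups.sort(key=lambda g: (-len(g), min(g)))
    if k <= len(string.ascii_uppercase):
        names = list(string.ascii_uppercase[:k])
    else:
        names = [f"C{i + 1:03d}" for i in range(k)]
    assignments = {s: name for name, g in zip(names, groups) for s in g}
    return ClusterLabels(assignments, scheme=f"cut at k={k}")


def subdivide_cluster(
    labels: ClusterLabels,
    cluster: str,
    expr: ExpressionMatrix,
    child_names: Sequence[str],
    *,
    min_overlap: int = 10,
    squared: bool = False,
) -> ClusterLabels:
    """Re-cluster one named cluster's members and split it in two.

    The two children are named ``child_names`` in decreasing size order; all
    other assignments are kept. This is the presentation layer used to build
    nested labels like A / B1 / B2a / B2b.
    """
    if len(child_names) != 2:
        raise ValueError("exactly two child names required")
    members = [s for s, name in labels.assignments.items() if name == cluster]
    if len(members) < 2:
        raise ValueError(f"cluster {cluster!r} has fewer than 2 members")
    sub = replace(expr, values=expr.values[members])
    sub_labels = cut_clusters(ward_hclust(spearman_dissimilarity(sub, min_overlap), squared), 2)
    rename = {"A": child_names[0], "B": child_names[1]}
    assignments = dict(labels.assignments)
    for s, name in sub_labels.assignments.items():
        assignments[s] = rename[name]
    return ClusterLabels(assignments, scheme=f"{labels.scheme}; {cluster} -> {child_names}")


def rank_heatmap_matrix(expr: ExpressionMatrix) -> pd.DataFrame:
    """Per-miRNA ranks of each sample's value (heatmap colouring basis).

    Each feature row is replaced by the ranks of its present values across
    samples (average ranks for ties); missing cells stay missing. Ranks are
    invariant to the ct_max convention since ``2**(ct_max - ct)`` is strictly
    decreasing in Ct.
    """
    if expr.values.size == 0:
        raise ValueError("empty expression matrix")
    return expr.values.rank(axis=1, method="average", na_option="keep")


def identify_split_drivers(
    expr: ExpressionMatrix,
    labels: ClusterLabels,
    alpha: float = 0.05,
) -> set[str]:
    """miRNAs significantly different between the two clusters of a split.

    Runs the rank-sum + Bonferroni procedure between the two groups and
    returns the significant feature ids. Exactly two clusters are required,
    each of size >= 2.
    """
    from . import diffexp

    groups = labels.groups()
    if len(groups) != 2:
        raise ValueError(f"exactly 2 clusters required, got {sorted(groups)}")
    (name_a, group_a), (name_b, group_b) = sorted(groups.items())
    if min(len(group_a), len(group_b)) < 2:
        raise ValueError("each cluster must contain at least 2 samples")
    results = diffexp.rank_sum_table(expr.values, group_a, group_b, alpha=alpha)
    return {r.feature_id for r in results if r.significant}


def drop_feature_block(expr: ExpressionMatrix, block: set[str]) -> ExpressionMatrix:
    """Remove a named feature block (e.g. the dominant 14q32 miRNA cluster).

    The result keeps the original ``ct_max`` and records the removal; the
    matrix minimum may now exceed 1. Removing everything is an error.
    """
    unknown = set(block) - set(expr.features)
    if unknown:
        raise ValueError(f"unknown feature(s) in block: {sorted(unknown)[:5]}")
    keep = [f for f in expr.features if f not in block]
    if not keep:
        raise ValueError("block removal would empty the matrix")
    note = f"removed block of {len(block)} features"
    return replace(expr, values=expr.values.loc[keep], removed_blocks=expr.removed_blocks + [note])


def to_newick(t: Dendrogram) -> str:
    """Dendrogram as a Newick string; branch lengths from merge heights."""
    n = len(t.leaves)
    height: dict[int, float] = {i: 0.0 for i in range(n)}
    text: dict[int, str] = {i: leaf for i, leaf in enumerate(t.leaves)}
    for j, (a, b, h) in enumerate(t.merges):
        node = n + j
        la, lb = max(h - height[a], 0.0), max(h - height[b], 0.0)
        text[node] = f"({text[a]}:{la:.6g},{text[b]}:{lb:.6g})"
        height[node] = h
    root = n + len(t.merges) - 1 if t.merges else 0
    return text[root] + ";"
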