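"""Unsupervised hierarchical clustering of samples.

Sample dissimilarity is 1 - |r| with r the Pearson correlation between two
sample columns, so perfectly correlated and perfectly anti-correlated
samples are equally close (the "absolute correlation" convention used by
microarray suites); a signed 1 - r variant is available.  Trees are built by
UPGMA (average linkage: the unweighted mean of all inter-cluster pairwise
dissimilarities) with a deterministic tie-break on the lexicographically
smallest member id, and exported as ultrametric Newick with branch lengths
derived from merge heights (a leaf under a merge at height h sits at depth
h / 2).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, ValidationError


@dataclass
class ClusterTree:
    """Agglomerative merge tree.

    Leaves are numbered 0..n-1 in ``leaves`` order; merge k creates node
    n + k.  ``merges`` holds (node_a, node_b, height) with heights
    non-decreasing along the merge sequence.
    """

    leaves: list[str]
    merges: list[tuple[int, int, float]]

    def __post_init__(self) -> None:
        n = len(self.leaves)
        if n == 0:
            raise ValidationError("a cluster tree needs at least one leaf")
        if len(self.merges) != n - 1:
            raise ValidationError(f"{n} leaves require {n - 1} merges, got {len(self.merges)}")
        heights = [h for _, _, h in self.merges]
        if any(h < -1e-12 for h in heights):
            raise ValidationError("merge heights must be non-negative")
        if any(b < a - 1e-9 for a, b in zip(heights, heights[1:])):
            raise ValidationError("merge heights must be non-decreasing")

    @property
    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]

    def leaf_sets(self) -> list[set[str]]:
        """Member leaf names for every node (leaves then merges)."""
        n = len(self.leaves)
        sets: list[set[str]] = [{name} for name in self.leaves]
        for a, b, _ in self.merges:
            sets.append(sets[a] | sets[b])
        return sets


def pearson_distance(m: ExpressionMatrix, absolute: bool = True) -> pd.DataFrame:
    """Sample-by-sample dissimilarity 1 - |r| (or 1 - r with
    ``absolute=False``); symmetric with a zero diagonal."""
    if m.n_features < 2:
        raise ValidationError("need >= 2 features to correlate samples")
    values = m.values
    if np.isnan(values).any():
        raise ValidationError("matrix contains missing values")
    sds = values.std(axis=0)
    for j, sd in enumerate(sds):
        if sd == 0:
            raise ValidationError(f"sample {m.sample_ids[j]!r} has zero variance")
    r = np.corrcoef(values, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    d = 1.0 - (np.abs(r) if absolute else r)
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, None)
    return pd.DataFrame(d, index=list(m.sample_ids), columns=list(m.sample_ids))


def abs_pearson_distance(m: ExpressionMatrix) -> pd.DataFrame:
    return pearson_distance(m, absolute=True)


def average_linkage(dist: pd.DataFrame) -> ClusterTree:
    """UPGMA on a dissimilarity matrix.

    At every step the pair of clusters with minimal average dissimilarity is
    merged; exact ties are broken towards the pair whose (lexicographically
    smallest member, then partner's smallest member) sorts first, which makes
    the tree deterministic for any input.
    """
    ids = [str(i) for i in dist.index]
    d = dist.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-9):
        raise ValidationError("dissimilarity matrix must be square and symmetric")
    n = len(ids)
    if n == 1:
        return ClusterTree(leaves=ids, merges=[])

    # active cluster state: node index, size, smallest member id
    active: dict[int, dict] = {
        i: {"size": 1, "key": ids[i]} for i in range(n)
    }
    dmat = {i: {j: d[i, j] for j in range(n) if j != i} for i in range(n)}
    merges: list[tuple[int, int, float]] = []
    next_node = n
    while len(active) > 1:
        best = None
        for i in active:
            for j in dmat[i]:
                if j <= i:
                    continue
                key = tuple(sorted((active[i]["key"], active[j]["key"])))
                cand = (dmat[i][j], key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        h, _, i, j = best
        merges.append((i, j, float(h)))
        size_i, size_j = active[i]["size"], active[j]["size"]
        new = {
            "size": size_i + size_j,
            "key": min(active[i]["key"], active[j]["key"]),
        }
        dmat[next_node] = {}
        for k in active:
            if k in (i, j):
                continue
            dk = (size_i * dmat[i][k] + size_j * dmat[j][k]) / (size_i + size_j)
            dmat[next_node][k] = dk
            dmat[k][next_node] = dk
            del dmat[k][i], dmat[k][j]
        del active[i], active[j], dmat[i], dmat[j]
        active[next_node] = new
        next_node += 1
    return ClusterTree(leaves=ids, merges=merges)


def write_newick(tree: ClusterTree, path: Path | str | None = None) -> str:
    """Serialize an ultrametric merge tree to Newick.

    Node ages are merge heights halved, so two leaves merged at height 0.4
    become ``(A:0.2,B:0.2);``; parsing the string back recovers topology and
    heights."""
    n = len(tree.leaves)
    ages = [0.0] * n + [h / 2.0 for _, _, h in tree.merges]

    def render(node: int, parent_age: float) -> str:
        length = parent_age - ages[node]
        if node < n:
            return f"{tree.leaves[node]}:{length:.10g}"
        a, b, _ = tree.merges[node - n]
        return f"({render(a, ages[node])},{render(b, ages[node])}):{length:.10g}"

    root = n + len(tree.merges) - 1 if tree.merges else 0
    if tree.merges:
        a, b, _ = tree.merges[-1]
        body = f"({render(a, ages[root])},{render(b, ages[root])});"
    else:
        body = f"{tree.leaves[0]};"
    if path is not None:
        Path(path).write_text(body + "\n", encoding="utf-8")
    return body


def cophenetic_matrix(tree: ClusterTree) -> pd.DataFrame:
    """Pairwise merge heights between leaves (the tree-implied
    dissimilarity); useful for comparing clusterings."""
    n = len(tree.leaves)
    members: list[list[int]] = [[i] for i in range(n)]
    out = np.zeros((n, n))
    for a, b, h in tree.merges:
        for i in members[a]:
            for j in members[b]:
                out[i, j] = out[j, i] = h
        members.append(members[a] + members[b])
    return pd.DataFrame(out, index=list(tree.leaves), columns=list(tree.leaves))


def concordance_rand_index(
    tree_a: ClusterTree, tree_b: ClusterTree, k: int = 2
) -> float:
    """Adjusted-Rand-style concordance between two sample trees cut into k
    groups; exposed as a computed report rather than an assertion about any
    particular dataset."""
    from scipy.cluster.hierarchy import fcluster
    from scipy.special import comb

    def cut(tree: ClusterTree) -> np.ndarray:
        link = to_linkage(tree)
        return fcluster(link, t=k, criterion="maxclust")

    la, lb = cut(tree_a), cut(tree_b)
    if list(tree_a.leaves) != list(tree_b.leaves):
        raise ValidationError("trees must share an identical leaf set and order")
    contingency = pd.crosstab(la, lb).to_numpy()
    sum_comb = comb(contingency, 2).sum()
    a_comb = comb(contingency.sum(axis=1), 2).sum()
    b_comb = comb(contingency.sum(axis=0), 2).sum()
    total = comb(len(la), 2)
    expected = a_comb * b_comb / total
    max_index = (a_comb + b_comb) / 2
    if max_index == expected:
        return 1.0
    return float((sum_comb - expected) / (max_index - expected))


def to_linkage(tree: ClusterTree) -> np.ndarray:
    """Convert to a scipy-style linkage array (for dendrogram plotting and
    cluster cutting)."""
    n = len(tree.leaves)
    sizes = [1] * n
    rows = []
    for a, b, h in tree.merges:
        size = sizes[a] + sizes[b]
        sizes.append(size)
        rows.append([a, b, h, size])
    return np.asarray(rows, dtype=float)
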