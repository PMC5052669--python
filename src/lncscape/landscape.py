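"""Subtype landscape: hierarchical clustering of differential lncRNAs,
rule-based cluster labelling, DE-set intersection and candidate
prioritization.

Clustering follows the historical R ``hclust`` "ward" behaviour: the
Lance-Williams Ward update is applied to the supplied dissimilarities
(1 - Pearson r) as-is, without squaring or metric correction. Ties in the
minimum merge distance are broken by the lowest pair of cluster indices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, percentile_expression
from .intervals import induction_category

__all__ = [
    "ClusterResult",
    "pearson_distance",
    "hierarchical_cluster",
    "label_lncrna_clusters",
    "intersect_de_sets",
    "prioritize_candidates",
    "LUMINAL_SUBTYPES",
]

LUMINAL_SUBTYPES = ("LumA", "LumB")


@dataclass
class ClusterResult:
    """Agglomeration of n items: merge list, heights, leaf order, labels.

    ``merges[i] = (a, b)`` uses the scipy encoding: indices < n are leaves,
    index n+i is the cluster created at merge i. ``heights`` are the merge
    dissimilarities (non-decreasing for Ward).
    """
    item_ids: list
    merges: np.ndarray   # (n-1, 2) int
    heights: np.ndarray  # (n-1,)
    order: np.ndarray    # leaf permutation for display

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    def cut(self, k: int) -> pd.Series:
        """Flat cluster labels (0..k-1) from the first n-k merges.

        Labels are renumbered by first appearance in item order.
        """
        n = self.n_items
        if not 1 <= k <= n:
            raise ValueError(f"k must be in [1, {n}]")
        parent = list(range(n + len(self.merges)))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(n - k):
            a, b = self.merges[i]
            parent[find(int(a))] = n + i
            parent[find(int(b))] = n + i
        roots = [find(i) for i in range(n)]
        relabel: dict[int, int] = {}
        labels = []
        for r in roots:
            if r not in relabel:
                relabel[r] = len(relabel)
            labels.append(relabel[r])
        return pd.Series(labels, index=pd.Index(self.item_ids), name="cluster")

    def newick(self) -> str:
        """Dendrogram as a Newick string (branch lengths = merge heights)."""
        n = self.n_items
        reps = {i: (str(self.item_ids[i]), 0.0) for i in range(n)}
        for i, (a, b) in enumerate(self.merges):
            h = float(self.heights[i])
            (sa, ha), (sb, hb) = reps.pop(int(a)), reps.pop(int(b))
            reps[n + i] = (f"({sa}:{max(h - ha, 0.0):g},{sb}:{max(h - hb, 0.0):g})", h)
        (s, _), = reps.values()
        return s + ";"


def pearson_distance(data: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between rows.

    Rows with zero variance (correlation undefined) are assigned distance
    1 to every other row, 0 to themselves.
    """
    x = np.asarray(data, dtype=float)
    sd = x.std(axis=1)
    const = sd == 0
    xc = x - x.mean(axis=1, keepdims=True)
    norm = np.where(const, 1.0, np.sqrt((xc ** 2).sum(axis=1)))
    xn = xc / norm[:, None]
    r = np.clip(xn @ xn.T, -1.0, 1.0)
    d = 1.0 - r
    d[const, :] = 1.0
    d[:, const] = 1.0
    np.fill_diagonal(d, 0.0)
    return d


def _ward_linkage(dist: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Lance-Williams Ward agglomeration on a square dissimilarity matrix.

    d(k, i+j) = [(n_i+n_k) d(k,i) + (n_j+n_k) d(k,j) - n_k d(i,j)] /
                (n_i+n_j+n_k), applied to the input distances directly.
    """
    n = dist.shape[0]
    d = dist.astype(float).copy()
    np.fill_diagonal(d, np.inf)
    size = np.ones(n)
    node = np.arange(n)          # current cluster -> node id in merge encoding
    active = np.ones(n, dtype=bool)
    merges = np.empty((n - 1, 2), dtype=int)
    heights = np.empty(n - 1)
    for step in range(n - 1):
        dm = np.where(active[:, None] & active[None, :], d, np.inf)
        flat = int(np.argmin(dm))        # ties -> lowest (i, j) in row-major order
        i, j = divmod(flat, n)
        if i > j:
            i, j = j, i
        h = dm[i, j]
        heights[step] = h
        lo, hi = sorted((node[i], node[j]))
        merges[step] = (lo, hi)
        ni, nj = size[i], size[j]
        others = active.copy()
        others[[i, j]] = False
        nk = size[others]
        d_new = ((ni + nk) * d[others, i] + (nj + nk) * d[others, j]
                 - nk * h) / (ni + nj + nk)
        d[others, i] = d_new
        d[i, others] = d_new
        size[i] = ni + nj
        node[i] = n + step
        active[j] = False
    return merges, heights


def _leaf_order(n: int, merges: np.ndarray) -> np.ndarray:
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for i, (a, b) in enumerate(merges):
        members[n + i] = members.pop(int(a)) + members.pop(int(b))
    (leaves,) = members.values()
    return np.asarray(leaves)


def hierarchical_cluster(norm_matrix: pd.DataFrame, axis: str = "rows") -> ClusterResult:
    """Agglomerative clustering with Pearson-correlation distance and Ward
    linkage, over the rows (transcripts) or columns (samples) of a
    normalized (e.g. log2-fold) matrix."""
    if axis not in ("rows", "columns"):
        raise ValueError(f"axis must be 'rows' or 'columns', got {axis!r}")
    data = norm_matrix.to_numpy(float) if axis == "rows" else norm_matrix.to_numpy(float).T
    ids = list(norm_matrix.index if axis == "rows" else norm_matrix.columns)
    if len(ids) < 2:
        raise ValueError("clustering requires at least 2 items")
    merges, heights = _ward_linkage(pearson_distance(data))
    return ClusterResult(ids, merges, heights, _leaf_order(len(ids), merges))


def label_lncrna_clusters(log2fc: pd.DataFrame, cluster_labels: pd.Series,
                          sample_annotations: pd.DataFrame,
                          luminal_margin: float = 1.0) -> dict:
    """Assign Luminal / Upregulated / Downregulated labels to lncRNA
    clusters from their median log2 fold change (over normal reference)
    per sample group.

    A cluster is Downregulated when its median over tumor samples is
    negative; Luminal when its luminal-subtype median exceeds the
    non-luminal tumor median by ``luminal_margin`` log2 units; otherwise
    Upregulated.
    """
    for col in ("cohort", "pam50"):
        if col not in sample_annotations.columns:
            raise ValueError(f"sample annotations lack required column {col!r}")
    ann = sample_annotations.reindex(log2fc.columns)
    tumor = ann["cohort"] == "tumor"
    if not tumor.any():
        raise ValueError("no tumor samples in annotation")
    luminal = tumor & ann["pam50"].isin(LUMINAL_SUBTYPES)
    nonluminal = tumor & ~ann["pam50"].isin(LUMINAL_SUBTYPES)
    out = {}
    for cl in sorted(cluster_labels.unique()):
        rows = cluster_labels.index[cluster_labels == cl]
        block = log2fc.loc[rows]
        tumor_med = float(np.median(block.loc[:, tumor.to_numpy()].to_numpy()))
        if tumor_med < 0:
            out[cl] = "Downregulated"
            continue
        lum_med = (float(np.median(block.loc[:, luminal.to_numpy()].to_numpy()))
                   if luminal.any() else -math.inf)
        nonlum_med = (float(np.median(block.loc[:, nonluminal.to_numpy()].to_numpy()))
                      if nonluminal.any() else -math.inf)
        if lum_med - nonlum_med > luminal_margin:
            out[cl] = "Luminal"
        else:
            out[cl] = "Upregulated"
    return out


def intersect_de_sets(up_a, up_b) -> tuple[list, dict]:
    """Intersection of two DE id sets plus Venn counts."""
    a, b = set(up_a), set(up_b)
    both = a & b
    counts = {"a_only": len(a - b), "b_only": len(b - a), "both": len(both)}
    return sorted(both), counts


def prioritize_candidates(intersection_ids, matrix: ExpressionMatrix,
                          binding_flags: pd.DataFrame,
                          induction_folds: pd.Series,
                          n_top: int = 10, percentile_q: float = 0.95) -> pd.DataFrame:
    """Rank intersecting lncRNAs by tissue expression (value of the 95th
    percentile sample, FPKM) and annotate ER promoter binding per cell
    line and estrogen-induction category.

    Ties in the percentile value break lexicographically by transcript id
    (recorded rule). Missing binding/induction entries default to
    False / fold 1.0 ("none").
    """
    ids = list(intersection_ids)
    missing = set(ids) - set(matrix.transcript_ids)
    if missing:
        raise KeyError(f"transcript {sorted(missing)[0]!r} not in expression matrix")
    rows = []
    for tid in ids:
        pct = percentile_expression(matrix.values.loc[tid].to_numpy(), percentile_q)
        fold = float(induction_folds.get(tid, 1.0))
        rec = {"transcript_id": tid, "percentile95_fpkm": pct,
               "induction_fold": fold, "induction_category": induction_category(fold)}
        for cl in binding_flags.columns:
            rec[f"er_bound_{cl}"] = (bool(binding_flags.loc[tid, cl])
                                     if tid in binding_flags.index else False)
        rows.append(rec)
    cols = (["transcript_id", "percentile95_fpkm", "induction_fold",
             "induction_category"] + [f"er_bound_{cl}" for cl in binding_flags.columns])
    table = pd.DataFrame(rows, columns=cols)
    if table.empty:
        table.insert(0, "rank", pd.Series(dtype=int))
        return table
    table = table.sort_values(["percentile95_fpkm", "transcript_id"],
                              ascending=[False, True], kind="stable").reset_index(drop=True)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return table.head(n_top)
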