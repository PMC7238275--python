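"""Replicate-consistency QC.

Selects the common top-expressed gene set, clusters samples with maximum
(Chebyshev) distance and average linkage (UPGMA), and flags replicates that
cluster away from their own (genotype, stage) group.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from podmat.datamodel_io import ExpressionMatrix, SampleDesign, ValidationError

REASON_OTHER_GROUP = "clustered with replicates of another group"
REASON_ISOLATED = "isolated while own group co-clusters"
REASON_NOT_SEPARABLE = "group not separable"


@dataclass
class ClusterTree:
    """Agglomerative merge history over a fixed leaf set.

    ``merges`` follows the scipy linkage convention: entry ``t`` merges
    cluster ids ``(a, b)`` at ``height`` into new cluster ``n + t``; ids
    ``0..n-1`` are the leaves in ``leaves`` order.
    """

    leaves: list[str]
    merges: list[tuple[int, int, float]]

    def __post_init__(self) -> None:
        n = len(self.leaves)
        if len(self.merges) != max(0, n - 1):
            raise ValidationError(
                f"expected {n - 1} merges for {n} leaves, got {len(self.merges)}"
            )
        heights = [h for _, _, h in self.merges]
        if any(h2 < h1 - 1e-12 for h1, h2 in zip(heights, heights[1:])):
            raise ValidationError("merge heights must be nondecreasing")

    def cut(self, n_clusters: int) -> list[set[str]]:
        """Cut into at most ``n_clusters`` clusters.

        Performs the first ``n - n_clusters`` merges; merges tied (equal
        height) with the last performed one are completed as well, so a tied
        block is never split arbitrarily.  With distinct heights this yields
        exactly ``n_clusters`` clusters.
        """
        n = len(self.leaves)
        if n_clusters >= n:
            return [{leaf} for leaf in self.leaves]
        m = n - n_clusters
        tie_h = self.merges[m - 1][2]
        while m < n - 1 and self.merges[m][2] <= tie_h:
            m += 1
        members: dict[int, set[str]] = {i: {leaf} for i, leaf in enumerate(self.leaves)}
        for t, (a, b, _) in enumerate(self.merges[:m]):
            members[n + t] = members.pop(a) | members.pop(b)
        return sorted(members.values(), key=lambda s: min(s))

    def to_newick(self) -> str:
        n = len(self.leaves)
        heights = {i: 0.0 for i in range(n)}
        nodes: dict[int, str] = {i: leaf for i, leaf in enumerate(self.leaves)}
        for t, (a, b, h) in enumerate(self.merges):
            la = h - heights[a]
            lb = h - heights[b]
            nodes[n + t] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
            heights[n + t] = h
        root = n + len(self.merges) - 1 if self.merges else 0
        return nodes[root] + ";"


@dataclass
class QCReport:
    selected_genes: list[str]
    rejected_samples: list[tuple[str, str]]  # (sample_id, reason)
    tree: ClusterTree
    clusters: list[set[str]] = field(default_factory=list)

    @property
    def rejected_ids(self) -> list[str]:
        return [s for s, _ in self.rejected_samples]

    def to_json(self) -> str:
        return json.dumps(
            {
                "selected_genes": self.selected_genes,
                "rejected_samples": [
                    {"sample_id": s, "reason": r} for s, r in self.rejected_samples
                ],
                "clusters": [sorted(c) for c in self.clusters],
            },
            indent=2,
        )


def select_common_top_genes(matrix: ExpressionMatrix, design: SampleDesign,
                            k: int = 100) -> list[str]:
    """Genes in the top-R of every sample, for the smallest feasible R.

    R is grown until the across-sample intersection of per-sample top-R gene
    sets has at least ``k`` members; the final list is the ``k`` of those
    with highest mean expression.  Ties are broken lexicographically by gene
    id, so the result is deterministic.
    """
    genes = matrix.gene_ids
    if k > len(genes):
        raise ValidationError(f"k={k} exceeds number of genes ({len(genes)})")
    if k <= 0:
        raise ValidationError("k must be positive")
    sub = matrix.subset_samples(design.sample_ids)
    values = sub.data.to_numpy(dtype=float)
    gene_arr = np.array(genes)
    # per-sample dense ranks (0 = most expressed), ties broken by gene id
    max_rank = np.zeros(len(genes), dtype=int)
    for j in range(values.shape[1]):
        order = np.lexsort((gene_arr, -values[:, j]))
        ranks = np.empty(len(genes), dtype=int)
        ranks[order] = np.arange(len(genes))
        np.maximum(max_rank, ranks, out=max_rank)
    # smallest R with >= k common genes: k-th smallest max_rank
    r_star = np.partition(max_rank, k - 1)[k - 1]
    common = max_rank <= r_star
    mean_expr = values.mean(axis=1)
    candidates = np.flatnonzero(common)
    order = np.lexsort((gene_arr[candidates], -mean_expr[candidates]))
    return list(gene_arr[candidates[order][:k]])


def max_distance(matrix: ExpressionMatrix, a: str, b: str) -> float:
    """Chebyshev distance between two sample columns."""
    for s in (a, b):
        if s not in matrix.data.columns:
            raise ValidationError(f"unknown sample: {s}")
    diff = matrix.data[a].to_numpy(dtype=float) - matrix.data[b].to_numpy(dtype=float)
    return float(np.abs(diff).max()) if diff.size else 0.0


def pairwise_max_distance(matrix: ExpressionMatrix,
                          sample_ids: list[str] | None = None) -> pd.DataFrame:
    """Symmetric Chebyshev distance matrix over samples."""
    ids = sample_ids if sample_ids is not None else matrix.sample_ids
    x = matrix.subset_samples(ids).data.to_numpy(dtype=float).T  # samples x genes
    d = np.abs(x[:, None, :] - x[None, :, :]).max(axis=2) if x.shape[1] else \
        np.zeros((len(ids), len(ids)))
    return pd.DataFrame(d, index=ids, columns=ids)


def average_linkage(dist: pd.DataFrame) -> ClusterTree:
    """UPGMA agglomeration with deterministic tie-breaking.

    The closest cluster pair is merged; distances to the merged cluster are
    size-weighted means of member distances.  Among tied pairs the one whose
    (lexicographically smallest member id of each side) pair sorts first is
    merged, so the merge order is reproducible.
    """
    ids = list(dist.index)
    d = dist.to_numpy(dtype=float)
    if np.isnan(d).any():
        raise ValidationError("distance matrix contains NaN")
    if d.shape[0] != d.shape[1] or list(dist.columns) != ids:
        raise ValidationError("distance matrix must be square with matching labels")
    if not np.allclose(d, d.T):
        raise ValidationError("distance matrix must be symmetric")
    n = len(ids)
    active: dict[int, dict] = {
        i: {"size": 1, "label": ids[i]} for i in range(n)
    }
    dd: dict[frozenset, float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dd[frozenset((i, j))] = d[i, j]
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        best = None
        for key, val in dd.items():
            a, b = sorted(key)
            tie = tuple(sorted((active[a]["label"], active[b]["label"])))
            cand = (val, tie, a, b)
            if best is None or cand < best:
                best = cand
        height, _, a, b = best
        sa, sb = active[a]["size"], active[b]["size"]
        new = {
            "size": sa + sb,
            "label": min(active[a]["label"], active[b]["label"]),
        }
        for other in active:
            if other in (a, b):
                continue
            da = dd.pop(frozenset((a, other)))
            db = dd.pop(frozenset((b, other)))
            dd[frozenset((next_id, other))] = (sa * da + sb * db) / (sa + sb)
        dd.pop(frozenset((a, b)))
        del active[a], active[b]
        active[next_id] = new
        merges.append((a, b, float(height)))
        next_id += 1
    return ClusterTree(ids, merges)


def flag_discordant_replicates(tree: ClusterTree, design: SampleDesign,
                               selected_genes: list[str] | None = None) -> QCReport:
    """Flag replicates that cluster away from their (genotype, stage) group.

    The tree is cut into G clusters (G = number of groups; fewer when merge
    heights tie).  A replicate is flagged when its cluster contains no other
    member of its own group: with foreign replicates present the reason is
    "clustered with another group"; a singleton is flagged only if the rest
    of its group co-clusters elsewhere.  When every replicate of a group
    ends up flagged the reason becomes "group not separable".
    """
    leaf_set = set(tree.leaves)
    group_of = {s: design.group_of(s) for s in tree.leaves}
    groups: dict[tuple[str, str], list[str]] = {}
    for s in tree.leaves:
        groups.setdefault(group_of[s], []).append(s)
    missing = set(design.sample_ids) - leaf_set
    if missing:
        raise ValidationError(f"design samples missing from tree: {sorted(missing)}")
    n_groups = len(groups)
    clusters = tree.cut(n_groups)
    cluster_of = {s: i for i, members in enumerate(clusters) for s in members}
    flagged: dict[str, str] = {}
    for sample in tree.leaves:
        grp = group_of[sample]
        mates = [s for s in groups[grp] if s != sample]
        if not mates:
            warnings.warn(f"group {grp} has a single replicate; never flagged")
            continue
        cluster = clusters[cluster_of[sample]]
        if any(m in cluster for m in mates):
            continue
        foreigners = [s for s in cluster if s != sample]
        if foreigners:
            flagged[sample] = REASON_OTHER_GROUP
        else:
            mate_clusters = {cluster_of[m] for m in mates}
            if len(mate_clusters) == 1:
                flagged[sample] = REASON_ISOLATED
    for grp, members in groups.items():
        if len(members) > 1 and all(s in flagged for s in members):
            for s in members:
                flagged[s] = REASON_NOT_SEPARABLE
    rejected = sorted(flagged.items())
    return QCReport(selected_genes or [], rejected, tree, clusters)


def run_qc(log_matrix: ExpressionMatrix, design: SampleDesign,
           k: int = 100) -> QCReport:
    """Full QC pass: top-gene selection, clustering, discordance flagging."""
    top = select_common_top_genes(log_matrix, design, k=k)
    sub = ExpressionMatrix(
        log_matrix.data.loc[top, design.sample_ids].copy(), log_matrix.unit
    )
    dist = pairwise_max_distance(sub)
    tree = average_linkage(dist)
    report = flag_discordant_replicates(tree, design, selected_genes=top)
    return report
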