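"""Over-representation statistics: hypergeometric tests, BH adjustment,
term ORA and TFBS enrichment with target assignment.

The upper-tail hypergeometric probability equals the one-sided Fisher exact
test on the corresponding 2x2 table; it is evaluated in log-space so small
p-values stay accurate for large universes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import math

import numpy as np
import pandas as pd

from podmat.datamodel_io import ValidationError


@dataclass(frozen=True)
class ContingencyCounts:
    """Counts for a 2x2 enrichment table.

    k successes in a foreground of size n drawn from a universe of size N
    containing K successes.
    """

    k: int
    n: int
    K: int
    N: int

    def __post_init__(self) -> None:
        ok = (0 <= self.k <= min(self.n, self.K)
              and 0 <= self.n <= self.N and 0 <= self.K <= self.N
              and self.k >= self.n + self.K - self.N)
        if not ok:
            raise ValidationError(f"invalid contingency counts: {self}")


def hypergeom_upper_tail(counts: ContingencyCounts) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), in log-space.

    Summed with plain ``math.lgamma`` log-binomials: tail lengths are short
    in practice and scalar arithmetic is both faster and accurate to well
    below 1e-12 absolute for any universe size.
    """
    k, n, K, N = counts.k, counts.n, counts.K, counts.N
    if k <= max(0, n + K - N):
        return 1.0
    lg = math.lgamma

    def lchoose(a: int, b: int) -> float:
        return lg(a + 1) - lg(b + 1) - lg(a - b + 1)

    log_denom = lchoose(N, n)
    log_terms = [lchoose(K, i) + lchoose(N - K, n - i) - log_denom
                 for i in range(k, min(n, K) + 1)]
    peak = max(log_terms)
    total = sum(math.exp(t - peak) for t in log_terms)
    return min(1.0, math.exp(peak) * total)


def bh_adjust(p_values: Iterable[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if ((p <= 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adjusted
    return list(out)


@dataclass
class EnrichmentResult:
    term_id: str
    counts: ContingencyCounts
    p_raw: float
    p_adj: float
    targets: list[str] | None = None


def _results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    rows = [
        {
            "term_id": r.term_id,
            "k": r.counts.k, "n": r.counts.n, "K": r.counts.K, "N": r.counts.N,
            "p_raw": r.p_raw, "p_adj": r.p_adj,
        }
        for r in results
    ]
    df = pd.DataFrame(rows, columns=["term_id", "k", "n", "K", "N", "p_raw", "p_adj"])
    return df.sort_values(["p_adj", "term_id"]).reset_index(drop=True)


def ora(gene_set: set[str], annotation: Mapping[str, set[str]],
        universe: set[str], alpha_adj: float = 0.01) -> pd.DataFrame:
    """Hypergeometric over-representation of ``gene_set`` across terms.

    One test per term with at least one foreground hit; BH adjustment across
    the tested terms; ``significant`` marks p_adj <= alpha_adj.  Run up- and
    down-regulated sets separately by calling twice.
    """
    if not universe:
        raise ValidationError("empty universe")
    stray = gene_set - universe
    if stray:
        raise ValidationError(f"foreground genes outside universe: {sorted(stray)[:5]}")
    n, N = len(gene_set), len(universe)
    tested: list[EnrichmentResult] = []
    for term_id in sorted(annotation):
        members = annotation[term_id] & universe
        k = len(gene_set & members)
        if k == 0:
            continue
        counts = ContingencyCounts(k, n, len(members), N)
        tested.append(EnrichmentResult(term_id, counts,
                                       hypergeom_upper_tail(counts), 1.0))
    adj = bh_adjust([r.p_raw for r in tested])
    for r, a in zip(tested, adj):
        r.p_adj = a
    df = _results_frame(tested)
    df["significant"] = df["p_adj"] <= alpha_adj
    return df


def tf_targets_from_sites(sites: pd.DataFrame) -> dict[str, set[str]]:
    """Per-TF target sets: gene has >= 1 site for the motif."""
    out: dict[str, set[str]] = {}
    for motif_id, group in sites.groupby("motif_id"):
        out[str(motif_id)] = set(group["gene_id"].astype(str))
    return out


def tfbs_enrichment(maturation_genes: set[str],
                    tf_targets: Mapping[str, set[str]] | pd.DataFrame,
                    universe: set[str], alpha: float = 0.05,
                    adjust: bool = False) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Per-TF Fisher enrichment of binding-site presence in maturation genes.

    The 2x2 table crosses (>= 1 promoter site for the TF) with (maturation
    gene vs rest of universe); presence, not site multiplicity, is counted.
    Significance is raw P <= alpha by default (BH optional).  Returns the
    result table plus maturation-gene target lists of the significant TFs.
    """
    if isinstance(tf_targets, pd.DataFrame):
        tf_targets = tf_targets_from_sites(tf_targets)
    if not universe:
        raise ValidationError("empty universe")
    stray = maturation_genes - universe
    if stray:
        raise ValidationError(
            f"maturation genes outside universe: {sorted(stray)[:5]}"
        )
    n, N = len(maturation_genes), len(universe)
    results: list[EnrichmentResult] = []
    skipped: list[str] = []
    for tf_id in sorted(tf_targets):
        targets = tf_targets[tf_id] & universe
        if not targets:
            skipped.append(tf_id)
            continue
        counts = ContingencyCounts(len(maturation_genes & targets), n,
                                   len(targets), N)
        results.append(EnrichmentResult(
            tf_id, counts, hypergeom_upper_tail(counts), 1.0,
            targets=sorted(maturation_genes & targets)))
    adj = bh_adjust([r.p_raw for r in results])
    for r, a in zip(results, adj):
        r.p_adj = a
    df = _results_frame(results)
    df = df.sort_values(["p_raw", "term_id"]).reset_index(drop=True)
    crit = df["p_adj"] if adjust else df["p_raw"]
    df["significant"] = crit <= alpha
    df.attrs["skipped_tfs"] = skipped
    target_map = {
        r.term_id: r.targets
        for r in results
        if (r.p_adj if adjust else r.p_raw) <= alpha
    }
    return df, target_map


def read_annotation(path) -> dict[str, set[str]]:
    """Read a (term, gene_id) TSV into term -> gene-set form."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns[:2])
    out: dict[str, set[str]] = {}
    for term, gene in df[cols].itertuples(index=False, name=None):
        out.setdefault(term, set()).add(gene)
    return out


def read_gmt(path) -> dict[str, set[str]]:
    """Read GMT (term, description, genes...) into term -> gene-set form."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 3:
                out[fields[0]] = set(fields[2:])
    return out
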