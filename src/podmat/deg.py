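"""Stage-wise fold-change DEG classification.

A gene is called up (down) for a genotype when its signed fold change
exceeds +threshold (falls below -threshold) in *every* (mature stage,
immature stage) pair, strict inequality.  Fold changes are computed on
arithmetic stage means of replicate FPKM values with a small pseudocount.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from podmat.datamodel_io import (
    IMMATURE,
    MATURE,
    ExpressionMatrix,
    SampleDesign,
    Unit,
    ValidationError,
)

UP = "up"
DOWN = "down"
NOT_DE = "not_de"

DEFAULT_THRESHOLD = 2.0
DEFAULT_PSEUDOCOUNT = 0.01


def stage_means(matrix: ExpressionMatrix, design: SampleDesign,
                genotype: str, agg: str = "mean") -> pd.DataFrame:
    """Per-gene arithmetic mean (or median) FPKM of each stage's replicates.

    QC-rejected samples are expected to have been dropped from ``design``
    already.  Returns a genes x stages frame in design stage order.
    """
    if matrix.unit is not Unit.FPKM:
        raise ValidationError(f"expected fpkm matrix, got {matrix.unit.value}")
    if genotype not in design.genotypes:
        raise ValidationError(f"unknown genotype: {genotype}")
    if agg not in ("mean", "median"):
        raise ValidationError(f"unknown aggregation: {agg}")
    cols = {}
    for stage in design.stages():
        samples = design.samples_for(genotype=genotype, stage=stage)
        if not samples:
            raise ValidationError(
                f"stage {stage} of {genotype} has zero surviving replicates"
            )
        block = matrix.subset_samples(samples).data
        cols[stage] = block.mean(axis=1) if agg == "mean" else block.median(axis=1)
    return pd.DataFrame(cols)


def signed_fold_change(mature_mean: float, immature_mean: float,
                       pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """Signed ratio: +a/b when a >= b else -b/a (a, b pseudocounted means).

    Antisymmetric under argument swap; magnitude is symmetric around +-1.
    """
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    a = mature_mean + pseudocount
    b = immature_mean + pseudocount
    if a == 0 and b == 0:
        raise ValidationError("fold change undefined: both means zero, pseudocount 0")
    return a / b if a >= b else -b / a


def fold_change_table(means: pd.DataFrame, design: SampleDesign,
                      pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """All (mature, immature) signed fold changes, one column per stage pair."""
    mature = design.stages(MATURE)
    immature = design.stages(IMMATURE)
    if not mature or not immature:
        raise ValidationError("both maturity classes must contain >= 1 stage")
    out = {}
    for ms in mature:
        for is_ in immature:
            a = means[ms].to_numpy(dtype=float) + pseudocount
            b = means[is_].to_numpy(dtype=float) + pseudocount
            if np.any((a == 0) & (b == 0)):
                raise ValidationError(
                    "fold change undefined for zero means with pseudocount 0"
                )
            with np.errstate(divide="ignore"):
                fc = np.where(a >= b, a / b, -b / a)
            out[f"{ms}/{is_}"] = fc
    return pd.DataFrame(out, index=means.index)


def call_degs(means: pd.DataFrame, design: SampleDesign,
              threshold: float = DEFAULT_THRESHOLD,
              pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """Classify genes as up / down / not_de from stage-mean FPKM.

    Returns a frame indexed by gene id with a ``call`` column plus the full
    signed fold-change evidence (one column per stage pair).
    """
    fc = fold_change_table(means, design, pseudocount=pseudocount)
    arr = fc.to_numpy(dtype=float)
    up = (arr > threshold).all(axis=1)
    down = (arr < -threshold).all(axis=1)
    call = np.where(up, UP, np.where(down, DOWN, NOT_DE))
    result = fc.copy()
    result.insert(0, "call", call)
    return result


@dataclass
class GenotypeIntersection:
    """Cross-genotype partition of DEG calls."""

    shared_up: set[str]
    shared_down: set[str]
    conflicting: set[str]          # DE in all genotypes with mixed directions
    exclusive: dict[str, set[str]]  # DE in exactly one genotype

    @property
    def shared(self) -> set[str]:
        return self.shared_up | self.shared_down


def intersect_genotypes(calls_by_genotype: Mapping[str, pd.DataFrame]) -> GenotypeIntersection:
    """Intersect per-genotype DEG calls into shared / exclusive / conflicting sets."""
    if len(calls_by_genotype) < 2:
        raise ValidationError("need calls for >= 2 genotypes")
    genotypes = list(calls_by_genotype)
    de_sets = {
        g: {gene: row for gene, row in calls[calls["call"] != NOT_DE]["call"].items()}
        for g, calls in calls_by_genotype.items()
    }
    everywhere = set.intersection(*(set(s) for s in de_sets.values()))
    shared_up = {g for g in everywhere
                 if all(de_sets[gt][g] == UP for gt in genotypes)}
    shared_down = {g for g in everywhere
                   if all(de_sets[gt][g] == DOWN for gt in genotypes)}
    conflicting = everywhere - shared_up - shared_down
    exclusive = {}
    for gt in genotypes:
        others = set().union(*(set(de_sets[o]) for o in genotypes if o != gt))
        exclusive[gt] = set(de_sets[gt]) - others
    return GenotypeIntersection(shared_up, shared_down, conflicting, exclusive)


def profile_table(means_by_genotype: Mapping[str, pd.DataFrame],
                  gene_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Tidy (gene, genotype, stage, mean_fpkm) export for profile plotting."""
    rows = []
    for genotype, means in means_by_genotype.items():
        sel = means if gene_ids is None else means.loc[list(gene_ids)]
        for stage in sel.columns:
            for gene, value in sel[stage].items():
                rows.append((gene, genotype, stage, float(value)))
    return pd.DataFrame(rows, columns=["gene_id", "genotype", "stage", "mean_fpkm"])
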