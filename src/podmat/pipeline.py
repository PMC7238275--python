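"""End-to-end orchestration: QC -> DEG -> cross-genotype -> cross-species."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from podmat import deg, qc
from podmat.datamodel_io import (
    ExpressionMatrix,
    SampleDesign,
    compute_fpkm,
    concat_matrices,
    log1p_transform,
)
from podmat.ortho import (
    ConcordanceResult,
    HomologMap,
    concordant_shared_sets,
    final_maturation_set,
)
from podmat.synth import SyntheticDataset


@dataclass
class PipelineResult:
    qc_report: qc.QCReport
    design_after_qc: SampleDesign
    fpkm: ExpressionMatrix
    means_by_genotype: dict[str, pd.DataFrame]
    calls_by_genotype: dict[str, pd.DataFrame]
    intersection: deg.GenotypeIntersection
    concordance: ConcordanceResult | None
    final_set: pd.DataFrame | None


def run_pipeline(counts_by_genotype: dict[str, ExpressionMatrix],
                 design: SampleDesign, models,
                 homolog_map: HomologMap | None = None,
                 ref_up: set[str] | None = None,
                 ref_down: set[str] | None = None,
                 threshold: float = deg.DEFAULT_THRESHOLD,
                 pseudocount: float = deg.DEFAULT_PSEUDOCOUNT,
                 top_k: int = 100) -> PipelineResult:
    combined = concat_matrices(list(counts_by_genotype.values()))
    fpkm = compute_fpkm(combined, models)
    log_matrix = log1p_transform(fpkm)
    k = min(top_k, len(combined.gene_ids))
    report = qc.run_qc(log_matrix, design, k=k)
    design_clean = design.drop_samples(report.rejected_ids)
    means = {}
    calls = {}
    for genotype in design_clean.genotypes:
        m = deg.stage_means(fpkm, design_clean, genotype)
        means[genotype] = m
        calls[genotype] = deg.call_degs(m, design_clean, threshold=threshold,
                                        pseudocount=pseudocount)
    intersection = deg.intersect_genotypes(calls)
    concordance = None
    final = None
    if homolog_map is not None and ref_up is not None and ref_down is not None:
        concordance = concordant_shared_sets(
            intersection.shared_up, intersection.shared_down,
            homolog_map, ref_up, ref_down)
        final = final_maturation_set(concordance.shared_up,
                                     concordance.shared_down)
    return PipelineResult(report, design_clean, fpkm, means, calls,
                          intersection, concordance, final)


def run_pipeline_on_dataset(dataset: SyntheticDataset,
                            threshold: float = deg.DEFAULT_THRESHOLD,
                            pseudocount: float = deg.DEFAULT_PSEUDOCOUNT,
                            top_k: int = 100) -> PipelineResult:
    return run_pipeline(dataset.counts, dataset.design, dataset.models,
                        homolog_map=dataset.homolog_map,
                        ref_up=dataset.ref_up, ref_down=dataset.ref_down,
                        threshold=threshold, pseudocount=pseudocount,
                        top_k=top_k)
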