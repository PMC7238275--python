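import numpy as np
import pandas as pd
import pytest

from podmat.datamodel_io import ExpressionMatrix, SampleDesign, Unit
from podmat.synth import SynthParams, generate_dataset

STAGES = ("ANT5", "ANT10", "ANT20", "ANT30", "ANT45")
IMMATURE_STAGES = ("ANT5", "ANT10")


def small_synth_params(**overrides) -> SynthParams:
    defaults = dict(n_genes=300, n_up=20, n_down=20, n_exclusive=5,
                    n_reference_extra=10, n_terms=5, term_size=10)
    defaults.update(overrides)
    return SynthParams(**defaults)


@pytest.fixture(scope="session")
def noise_free_dataset():
    return generate_dataset(small_synth_params(dispersion=0.0), seed=11)


@pytest.fixture(scope="session")
def noisy_dataset():
    return generate_dataset(small_synth_params(), seed=11)


def make_design(genotypes=("GT1", "GT2"), stages=STAGES,
                immature=IMMATURE_STAGES, n_replicates=3) -> SampleDesign:
    rows = []
    for g in genotypes:
        for s in stages:
            for r in range(1, n_replicates + 1):
                rows.append((f"{g}_{s}_R{r}", g, s, r,
                             "immature" if s in immature else "mature"))
    return SampleDesign(pd.DataFrame(
        rows, columns=["sample_id", "genotype", "stage", "replicate", "maturity"]),
        stage_order=list(stages))


def make_matrix(values, gene_ids, sample_ids, unit=Unit.FPKM) -> ExpressionMatrix:
    return ExpressionMatrix(
        pd.DataFrame(np.asarray(values, dtype=float), index=gene_ids,
                     columns=sample_ids),
        unit,
    )
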