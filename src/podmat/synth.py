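"""Synthetic dataset generator with a ground-truth manifest.

Emulates the study design this toolkit targets: two genotypes, five
developmental stages split into immature/mature classes, three replicates,
negative-binomial counts with lognormal base means, planted up/down
maturation genes, genotype-exclusive DEGs, one discordant replicate
regenerated from another stage's means, a homolog map with concordant and
discordant reference directions, annotation terms with one planted enriched
term, and promoters with motif sites planted for selected TFs.

All randomness flows from a single seeded ``numpy.random.Generator``; the
same seed reproduces the dataset byte-for-byte.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from podmat.datamodel_io import (
    IMMATURE,
    MATURE,
    ExpressionMatrix,
    GeneModel,
    SampleDesign,
    Unit,
    ValidationError,
    write_expression_matrix,
    write_fasta,
    write_gene_models_gff3,
    write_sample_design,
)
from podmat.motif import ALPHABET, PWM, reverse_complement, write_meme
from podmat.ortho import HomologMap

_GENE_SLOT = 1600          # bp of genome reserved per gene
_GENES_PER_CHROM = 500
_PLUS_TSS_OFFSET = 500     # promoter = [slot, slot + 600) for + strand genes
_MINUS_TSS_OFFSET = 1099   # promoter = [slot + 1000, slot + 1600) rev-comp


@dataclass
class SynthParams:
    """Generator parameters; defaults match the study's design scale-down."""

    n_genes: int = 2000
    n_up: int = 30
    n_down: int = 30
    n_exclusive: int = 15            # per genotype
    genotypes: tuple[str, ...] = ("PMB0225", "PHA1037")
    stages: tuple[str, ...] = ("ANT5", "ANT10", "ANT20", "ANT30", "ANT45")
    immature_stages: tuple[str, ...] = ("ANT5", "ANT10")
    n_replicates: int = 3
    effect_ratio: float = 6.0
    background_ratio: float = 1.8    # max pairwise stage-mean ratio, background
    dispersion: float = 0.005        # NB: var = mu + dispersion * mu^2; 0 = noise-free
    base_mean_log_mean: float = math.log(800.0)
    base_mean_log_sigma: float = 0.6
    min_base_mean: float = 300.0
    genotype_log_sigma: float = 0.4
    class_jitter: float = 0.05       # planted genes' within-class stage wobble
    gene_length_range: tuple[int, int] = (300, 600)
    upstream: int = 500
    downstream: int = 100
    n_motifs: int = 5
    motif_width: int = 10
    n_planted_tfs: int = 2
    consensus_prob: float = 0.85
    planting_rate: float = 0.8
    background_site_rate: float = 0.05
    concordant_fraction: float = 0.8
    discordant_fraction: float = 0.1
    n_reference_extra: int = 50
    n_terms: int = 10
    term_size: int = 30
    planted_term_coverage: float = 0.7
    planted_term_noise: int = 5
    discordant_genotype_index: int = 0
    discordant_stage: str = "ANT45"
    discordant_replicate: int = 2
    discordant_source_stage: str = "ANT10"

    def validate(self) -> None:
        if self.n_genes < 50:
            raise ValidationError("n_genes must be >= 50")
        if not (1.0 <= self.background_ratio < 2.0):
            raise ValidationError("background_ratio must lie in [1, 2)")
        if self.effect_ratio <= self.background_ratio:
            raise ValidationError("infeasible: effect_ratio <= background_ratio")
        if self.effect_ratio <= 2:
            raise ValidationError("effect_ratio must exceed 2")
        planted = self.n_up + self.n_down + 2 * self.n_exclusive
        if planted > self.n_genes // 2:
            raise ValidationError("too many planted genes for n_genes")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")
        if self.discordant_stage not in self.stages or \
                self.discordant_source_stage not in self.stages:
            raise ValidationError("discordant stages must be in stages")
        if self.discordant_stage == self.discordant_source_stage:
            raise ValidationError("discordant source must be a different stage")
        if not set(self.immature_stages) < set(self.stages):
            raise ValidationError("immature_stages must be a proper subset of stages")
        if self.n_planted_tfs > self.n_motifs:
            raise ValidationError("n_planted_tfs exceeds n_motifs")
        if (0.25 ** self.motif_width) * 4 > 1e-5:
            raise ValidationError("motif_width too small for the scan threshold")


@dataclass
class FixtureManifest:
    """Ground truth of every planted signal (the acceptance surface)."""

    planted_up: set[str]
    planted_down: set[str]
    genotype_exclusive: dict[str, set[str]]
    exclusive_direction: dict[str, str]
    discordant_replicate: str
    planted_enriched_tfs: set[str]
    planted_enriched_terms: set[str]
    homolog_concordant: set[str]
    homolog_discordant: set[str]
    planted_motif_sites: list[tuple[str, str, int]]  # (motif_id, gene_id, offset)
    seed: int
    params: dict

    def __post_init__(self) -> None:
        if self.planted_up & self.planted_down:
            raise ValidationError("planted_up and planted_down overlap")

    def to_json(self) -> str:
        payload = {
            "planted_up": sorted(self.planted_up),
            "planted_down": sorted(self.planted_down),
            "genotype_exclusive": {g: sorted(s) for g, s in
                                   sorted(self.genotype_exclusive.items())},
            "exclusive_direction": dict(sorted(self.exclusive_direction.items())),
            "discordant_replicate": self.discordant_replicate,
            "planted_enriched_tfs": sorted(self.planted_enriched_tfs),
            "planted_enriched_terms": sorted(self.planted_enriched_terms),
            "homolog_concordant": sorted(self.homolog_concordant),
            "homolog_discordant": sorted(self.homolog_discordant),
            "planted_motif_sites": [list(t) for t in self.planted_motif_sites],
            "seed": self.seed,
            "params": self.params,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "FixtureManifest":
        d = json.loads(text)
        return cls(
            planted_up=set(d["planted_up"]),
            planted_down=set(d["planted_down"]),
            genotype_exclusive={g: set(s) for g, s in d["genotype_exclusive"].items()},
            exclusive_direction=d["exclusive_direction"],
            discordant_replicate=d["discordant_replicate"],
            planted_enriched_tfs=set(d["planted_enriched_tfs"]),
            planted_enriched_terms=set(d["planted_enriched_terms"]),
            homolog_concordant=set(d["homolog_concordant"]),
            homolog_discordant=set(d["homolog_discordant"]),
            planted_motif_sites=[tuple(t) for t in d["planted_motif_sites"]],
            seed=d["seed"],
            params=d["params"],
        )


@dataclass
class SyntheticDataset:
    counts: dict[str, ExpressionMatrix]        # per genotype
    design: SampleDesign
    models: list[GeneModel]
    bodies: dict[str, tuple[int, int]]         # gene body genomic intervals
    genome: dict[str, str]
    promoters: dict[str, str]
    pwms: list[PWM]
    homolog_map: HomologMap
    ref_up: set[str]
    ref_down: set[str]
    annotation: dict[str, set[str]]
    manifest: FixtureManifest


def _stage_mean_matrix(params: SynthParams, rng: np.random.Generator,
                       roles: dict[str, tuple[str, str | None]],
                       gene_ids: list[str]) -> dict[str, np.ndarray]:
    """Per-genotype (gene x stage) mean matrices implementing the planting.

    Up genes rise to ``effect_ratio x`` their immature level at mature
    stages; down genes start ``effect_ratio x`` high and fall back.  The
    extra read mass the two planted groups add at mature vs immature stages
    is rebalanced per genotype so column totals stay stage-stable; FPKM
    fold changes of background genes then see no depth drift.
    """
    n_genes, stages = len(gene_ids), list(params.stages)
    mature = [s for s in stages if s not in params.immature_stages]
    base = np.exp(rng.normal(params.base_mean_log_mean,
                             params.base_mean_log_sigma, n_genes))
    base = np.maximum(base, params.min_base_mean)
    sqrt_bg = math.sqrt(params.background_ratio)
    j = params.class_jitter

    def direction_of(gene: str, genotype: str) -> str | None:
        role, target = roles[gene]
        if role in ("up", "down"):
            return role
        if role == "exclusive" and target is not None:
            excl_genotype, excl_dir = target.split(":")
            if excl_genotype == genotype:
                return excl_dir
        return None

    means: dict[str, np.ndarray] = {}
    for genotype in params.genotypes:
        geno_factor = np.exp(rng.normal(0.0, params.genotype_log_sigma, n_genes))
        level = base * geno_factor
        directions = [direction_of(g, genotype) for g in gene_ids]
        for group in ("planted", "exclusive"):
            up_idx = [i for i, g in enumerate(gene_ids)
                      if directions[i] == "up"
                      and (roles[g][0] == "up") == (group == "planted")]
            down_idx = [i for i, g in enumerate(gene_ids)
                        if directions[i] == "down"
                        and (roles[g][0] == "down") == (group == "planted")]
            if up_idx and down_idx:
                level[down_idx] *= level[up_idx].sum() / level[down_idx].sum()
        m = np.empty((n_genes, len(stages)))
        for gi, gene in enumerate(gene_ids):
            role, _ = roles[gene]
            direction = directions[gi]
            for si, stage in enumerate(stages):
                if direction is None and role != "background":
                    # planted gene, flat in this genotype
                    m[gi, si] = level[gi] * rng.uniform(1 - j, 1 + j)
                elif direction is None:
                    # background: stage factor at +-sqrt(bg ratio)
                    sign = 1.0 if rng.random() < 0.5 else -1.0
                    m[gi, si] = level[gi] * (sqrt_bg ** sign)
                else:
                    wobble = rng.uniform(1 - j, 1 + j)
                    is_mature = stage in mature
                    if direction == "up":
                        eff = params.effect_ratio if is_mature else 1.0
                    else:
                        eff = 1.0 if is_mature else params.effect_ratio
                    m[gi, si] = level[gi] * eff * wobble
        means[genotype] = m
    return means


def _sample_counts(mean: np.ndarray, dispersion: float,
                   rng: np.random.Generator) -> np.ndarray:
    if dispersion == 0:
        return np.rint(mean).astype(np.int64)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p).astype(np.int64)


def generate_dataset(params: SynthParams | None = None, seed: int = 0) -> SyntheticDataset:
    """Generate the full synthetic dataset for a seed.  Deterministic."""
    params = params or SynthParams()
    params.validate()
    rng = np.random.default_rng(seed)
    width = max(5, len(str(params.n_genes)))
    gene_ids = [f"G{i + 1:0{width}d}" for i in range(params.n_genes)]

    # --- role assignment -------------------------------------------------
    n_special = params.n_up + params.n_down + 2 * params.n_exclusive
    special = rng.choice(params.n_genes, size=n_special, replace=False)
    planted_up = {gene_ids[i] for i in special[:params.n_up]}
    planted_down = {gene_ids[i] for i in
                    special[params.n_up:params.n_up + params.n_down]}
    exclusive: dict[str, set[str]] = {g: set() for g in params.genotypes[:2]}
    exclusive_direction: dict[str, str] = {}
    cursor = params.n_up + params.n_down
    for k, genotype in enumerate(params.genotypes[:2]):
        block = special[cursor + k * params.n_exclusive:
                        cursor + (k + 1) * params.n_exclusive]
        # alternate directions so exclusive genes add stage-balanced mass
        for pos, i in enumerate(block):
            gene = gene_ids[i]
            exclusive[genotype].add(gene)
            exclusive_direction[gene] = "up" if pos % 2 == 0 else "down"
    roles: dict[str, tuple[str, str | None]] = {}
    for gene in gene_ids:
        if gene in planted_up:
            roles[gene] = ("up", None)
        elif gene in planted_down:
            roles[gene] = ("down", None)
        else:
            for genotype in params.genotypes[:2]:
                if gene in exclusive[genotype]:
                    roles[gene] = ("exclusive",
                                   f"{genotype}:{exclusive_direction[gene]}")
                    break
            else:
                roles[gene] = ("background", None)

    # --- counts and design ------------------------------------------------
    means = _stage_mean_matrix(params, rng, roles, gene_ids)
    stages = list(params.stages)
    maturity = {s: IMMATURE if s in params.immature_stages else MATURE
                for s in stages}
    disc_genotype = params.genotypes[params.discordant_genotype_index]
    disc_sample = (f"{disc_genotype}_{params.discordant_stage}"
                   f"_R{params.discordant_replicate}")
    design_rows = []
    counts: dict[str, ExpressionMatrix] = {}
    for genotype in params.genotypes:
        columns = {}
        for si, stage in enumerate(stages):
            for rep in range(1, params.n_replicates + 1):
                sample_id = f"{genotype}_{stage}_R{rep}"
                mu = means[genotype][:, si]
                if sample_id == disc_sample:
                    src = stages.index(params.discordant_source_stage)
                    mu = means[genotype][:, src]
                columns[sample_id] = _sample_counts(mu, params.dispersion, rng)
                design_rows.append((sample_id, genotype, stage, rep,
                                    maturity[stage]))
        counts[genotype] = ExpressionMatrix(
            pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene_id")),
            Unit.COUNTS,
        )
    design = SampleDesign(
        pd.DataFrame(design_rows, columns=["sample_id", "genotype", "stage",
                                           "replicate", "maturity"]),
        stage_order=stages,
    )

    # --- homolog map and reference lists ---------------------------------
    ref_counter = 0

    def next_ref() -> str:
        nonlocal ref_counter
        ref_counter += 1
        return f"AT1G{ref_counter:05d}"

    map_rows: list[tuple[str, str]] = []
    ref_up: set[str] = set()
    ref_down: set[str] = set()
    homolog_concordant: set[str] = set()
    homolog_discordant: set[str] = set()
    for gene in sorted(planted_up | planted_down):
        direction = "up" if gene in planted_up else "down"
        u = rng.random()
        if u < params.concordant_fraction:
            ref = next_ref()
            map_rows.append((gene, ref))
            (ref_up if direction == "up" else ref_down).add(ref)
            homolog_concordant.add(gene)
        elif u < params.concordant_fraction + params.discordant_fraction:
            ref = next_ref()
            map_rows.append((gene, ref))
            (ref_down if direction == "up" else ref_up).add(ref)
            homolog_discordant.add(gene)
        # else: unmapped
    background_genes = [g for g in gene_ids if roles[g][0] == "background"]
    for gene in background_genes:
        if rng.random() < 0.1:  # neutral homology, reference not in any list
            map_rows.append((gene, next_ref()))
    for _ in range(params.n_reference_extra):
        ref = next_ref()
        (ref_up if rng.random() < 0.5 else ref_down).add(ref)
    homolog_map = HomologMap(pd.DataFrame(map_rows,
                                          columns=["gene_id", "ref_gene_id"]))

    # --- annotation terms -------------------------------------------------
    annotation: dict[str, set[str]] = {}
    planted_term = "T0000"
    planted_pool = sorted(planted_up | planted_down)
    n_cover = int(round(params.planted_term_coverage * len(planted_pool)))
    covered = rng.choice(len(planted_pool), size=n_cover, replace=False)
    term_members = {planted_pool[i] for i in covered}
    noise = rng.choice(len(background_genes),
                       size=min(params.planted_term_noise, len(background_genes)),
                       replace=False)
    term_members |= {background_genes[i] for i in noise}
    annotation[planted_term] = term_members
    for t in range(1, params.n_terms):
        size = min(params.term_size, params.n_genes)
        members = rng.choice(params.n_genes, size=size, replace=False)
        annotation[f"T{t:04d}"] = {gene_ids[i] for i in members}

    # --- motifs and promoters --------------------------------------------
    pwms: list[PWM] = []
    off_prob = (1.0 - params.consensus_prob) / 3.0
    for m in range(params.n_motifs):
        consensus = rng.integers(0, 4, size=params.motif_width)
        probs = np.full((params.motif_width, 4), off_prob)
        probs[np.arange(params.motif_width), consensus] = params.consensus_prob
        pwms.append(PWM(f"M{m + 1:03d}", probs))
    planted_tf_idx = rng.choice(params.n_motifs, size=params.n_planted_tfs,
                                replace=False)
    planted_tfs = {pwms[i].motif_id for i in planted_tf_idx}
    promoter_len = params.upstream + params.downstream
    letters = np.array(list(ALPHABET))
    promoters: dict[str, str] = {}
    planted_sites: list[tuple[str, str, int]] = []
    for gene in gene_ids:
        seq = letters[rng.integers(0, 4, size=promoter_len)]
        used: list[tuple[int, int]] = []
        for pwm in pwms:
            rate = (params.planting_rate
                    if pwm.motif_id in planted_tfs and gene in homolog_concordant
                    else params.background_site_rate)
            if rng.random() >= rate:
                continue
            w = pwm.width
            for _attempt in range(20):
                off = int(rng.integers(0, promoter_len - w + 1))
                if all(off + w <= lo or off >= hi for lo, hi in used):
                    used.append((off, off + w))
                    seq[off:off + w] = list(pwm.consensus)
                    planted_sites.append((pwm.motif_id, gene, off))
                    break
        promoters[gene] = "".join(seq)

    # --- genome and gene models -------------------------------------------
    models: list[GeneModel] = []
    bodies: dict[str, tuple[int, int]] = {}
    genome: dict[str, str] = {}
    lo_len, hi_len = params.gene_length_range
    chrom_arrays: dict[str, np.ndarray] = {}
    for gi, gene in enumerate(gene_ids):
        chrom = f"Chr{gi // _GENES_PER_CHROM + 1:02d}"
        if chrom not in chrom_arrays:
            n_here = min(_GENES_PER_CHROM,
                         params.n_genes - (gi // _GENES_PER_CHROM) * _GENES_PER_CHROM)
            chrom_arrays[chrom] = letters[rng.integers(0, 4,
                                                       size=n_here * _GENE_SLOT)]
        slot = (gi % _GENES_PER_CHROM) * _GENE_SLOT
        strand = "+" if gi % 2 == 0 else "-"
        length = int(rng.integers(lo_len, hi_len + 1))
        arr = chrom_arrays[chrom]
        if strand == "+":
            tss = slot + _PLUS_TSS_OFFSET
            body = (tss, tss + length)
            window = promoters[gene]
            arr[tss - params.upstream:tss + params.downstream] = list(window)
        else:
            tss = slot + _MINUS_TSS_OFFSET
            body = (tss - length + 1, tss + 1)
            window = reverse_complement(promoters[gene])
            arr[tss - params.downstream + 1:tss + params.upstream + 1] = list(window)
        models.append(GeneModel(gene, chrom, strand, tss, length))
        bodies[gene] = body
    genome = {chrom: "".join(arr) for chrom, arr in chrom_arrays.items()}

    manifest = FixtureManifest(
        planted_up=planted_up,
        planted_down=planted_down,
        genotype_exclusive=exclusive,
        exclusive_direction=exclusive_direction,
        discordant_replicate=disc_sample,
        planted_enriched_tfs=planted_tfs,
        planted_enriched_terms={planted_term},
        homolog_concordant=homolog_concordant,
        homolog_discordant=homolog_discordant,
        planted_motif_sites=planted_sites,
        seed=seed,
        params=_params_dict(params),
    )
    return SyntheticDataset(counts, design, models, bodies, genome, promoters,
                            pwms, homolog_map, ref_up, ref_down, annotation,
                            manifest)


def _params_dict(params: SynthParams) -> dict:
    d = asdict(params)
    for key, value in d.items():
        if isinstance(value, tuple):
            d[key] = list(value)
    return d


def write_fixture_bundle(dataset: SyntheticDataset, out_dir: str | Path) -> list[Path]:
    """Write all standard-format files plus the manifest JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    for genotype, matrix in dataset.counts.items():
        path = out / f"counts_{genotype}.tsv"
        write_expression_matrix(matrix, path)
        written.append(path)
    path = out / "design.tsv"
    write_sample_design(dataset.design, path)
    written.append(path)
    path = out / "genes.gff3"
    write_gene_models_gff3(dataset.models, dataset.bodies, path)
    written.append(path)
    path = out / "genome.fa"
    write_fasta(dataset.genome, path)
    written.append(path)
    path = out / "promoters.fa"
    write_fasta(dataset.promoters, path)
    written.append(path)
    path = out / "motifs.meme"
    write_meme(dataset.pwms, path)
    written.append(path)
    path = out / "homolog_map.tsv"
    dataset.homolog_map.pairs.to_csv(path, sep="\t", index=False,
                                     lineterminator="\n")
    written.append(path)
    path = out / "reference_lists.tsv"
    ref_rows = [(r, "up") for r in sorted(dataset.ref_up)] + \
               [(r, "down") for r in sorted(dataset.ref_down)]
    pd.DataFrame(ref_rows, columns=["ref_gene_id", "direction"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n")
    written.append(path)
    path = out / "annotation.tsv"
    ann_rows = [(term, gene) for term in sorted(dataset.annotation)
                for gene in sorted(dataset.annotation[term])]
    pd.DataFrame(ann_rows, columns=["term_id", "gene_id"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n")
    written.append(path)
    path = out / "manifest.json"
    path.write_text(dataset.manifest.to_json() + "\n")
    written.append(path)
    return written
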