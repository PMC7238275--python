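"""Core data types and file I/O for the pod-maturation pipeline.

All genomic coordinates are 0-based, half-open internally.  GFF3 input
(1-based, closed) is converted at the boundary.  Expression matrices are
genes x samples tables carrying an explicit unit tag (``counts``, ``fpkm``
or ``log1p_fpkm``); the unit is never guessed from the values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class PodmatError(Exception):
    """Base class for all podmat errors."""


class ParseError(PodmatError):
    """A file could not be parsed."""


class ValidationError(PodmatError):
    """A data-structure invariant was violated."""


class Unit(str, Enum):
    """Measurement unit of an expression matrix."""

    COUNTS = "counts"
    FPKM = "fpkm"
    LOG1P_FPKM = "log1p_fpkm"


IMMATURE = "immature"
MATURE = "mature"


# ---------------------------------------------------------------------------
# Sample design
# ---------------------------------------------------------------------------

@dataclass
class SampleDesign:
    """Mapping of samples to genotype, developmental stage and replicate.

    Parameters
    ----------
    table
        Data frame with columns ``sample_id``, ``genotype``, ``stage``,
        ``replicate`` and ``maturity`` (``immature`` or ``mature``).
    stage_order
        Ordered stage labels (earliest first).  Defaults to order of first
        appearance in ``table``.
    """

    table: pd.DataFrame
    stage_order: list[str] = field(default_factory=list)

    REQUIRED_COLUMNS = ("sample_id", "genotype", "stage", "replicate", "maturity")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"design table missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)
        ids = self.table["sample_id"]
        if ids.duplicated().any():
            dups = sorted(ids[ids.duplicated()].unique())
            raise ValidationError(f"duplicate sample ids: {dups}")
        bad = set(self.table["maturity"].unique()) - {IMMATURE, MATURE}
        if bad:
            raise ValidationError(f"unknown maturity labels: {sorted(bad)}")
        # stage -> maturity must be consistent across genotypes
        by_stage = self.table.groupby("stage")["maturity"].nunique()
        if (by_stage > 1).any():
            raise ValidationError(
                f"inconsistent stage->maturity mapping for: "
                f"{sorted(by_stage[by_stage > 1].index)}"
            )
        if not self.stage_order:
            self.stage_order = list(dict.fromkeys(self.table["stage"]))
        unknown = set(self.table["stage"]) - set(self.stage_order)
        if unknown:
            raise ValidationError(f"stages missing from stage_order: {sorted(unknown)}")
        for m in (IMMATURE, MATURE):
            if m not in set(self.table["maturity"]):
                raise ValidationError(f"maturity class {m!r} has no stage")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def genotypes(self) -> list[str]:
        return list(dict.fromkeys(self.table["genotype"]))

    @property
    def maturity_map(self) -> dict[str, str]:
        return dict(
            self.table.drop_duplicates("stage")[["stage", "maturity"]].itertuples(
                index=False, name=None
            )
        )

    def stages(self, maturity: str | None = None) -> list[str]:
        mm = self.maturity_map
        return [s for s in self.stage_order if maturity is None or mm[s] == maturity]

    def groups(self) -> list[tuple[str, str]]:
        """All (genotype, stage) groups present, in design order."""
        seen = dict.fromkeys(
            self.table[["genotype", "stage"]].itertuples(index=False, name=None)
        )
        return list(seen)

    def samples_for(self, genotype: str | None = None, stage: str | None = None) -> list[str]:
        t = self.table
        if genotype is not None:
            t = t[t["genotype"] == genotype]
        if stage is not None:
            t = t[t["stage"] == stage]
        return list(t["sample_id"])

    def group_of(self, sample_id: str) -> tuple[str, str]:
        row = self.table[self.table["sample_id"] == sample_id]
        if row.empty:
            raise ValidationError(f"unknown sample id: {sample_id}")
        return (row.iloc[0]["genotype"], row.iloc[0]["stage"])

    def drop_samples(self, sample_ids: Iterable[str]) -> "SampleDesign":
        drop = set(sample_ids)
        unknown = drop - set(self.sample_ids)
        if unknown:
            raise ValidationError(f"cannot drop unknown samples: {sorted(unknown)}")
        kept = self.table[~self.table["sample_id"].isin(drop)].copy()
        return SampleDesign(kept, stage_order=list(self.stage_order))


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples abundance table with an explicit unit tag."""

    data: pd.DataFrame
    unit: Unit

    def __post_init__(self) -> None:
        self.unit = Unit(self.unit)
        idx = self.data.index
        if idx.duplicated().any():
            dups = sorted(idx[idx.duplicated()].unique())
            raise ValidationError(f"duplicate gene ids: {dups}")
        cols = self.data.columns
        if cols.duplicated().any():
            raise ValidationError(
                f"duplicate sample ids: {sorted(cols[cols.duplicated()].unique())}"
            )
        values = self.data.to_numpy()
        if values.size:
            if not np.issubdtype(values.dtype, np.number):
                raise ValidationError("expression matrix must be numeric")
            if np.isnan(values).any():
                raise ValidationError("expression matrix contains NaN")
            if (values < 0).any():
                raise ValidationError("expression matrix contains negative values")
            if self.unit is Unit.COUNTS and not np.allclose(values, np.rint(values)):
                raise ValidationError("counts matrix contains non-integer values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = set(sample_ids) - set(self.sample_ids)
        if missing:
            raise ValidationError(f"unknown samples: {sorted(missing)}")
        return ExpressionMatrix(self.data[list(sample_ids)].copy(), self.unit)


def concat_matrices(matrices: Sequence[ExpressionMatrix]) -> ExpressionMatrix:
    """Column-concatenate matrices sharing an identical gene index."""
    if not matrices:
        raise ValidationError("nothing to concatenate")
    units = {m.unit for m in matrices}
    if len(units) > 1:
        raise ValidationError(f"mixed units: {sorted(u.value for u in units)}")
    first = matrices[0].data.index
    for m in matrices[1:]:
        if not first.equals(m.data.index):
            raise ValidationError("gene indices differ between matrices")
    return ExpressionMatrix(pd.concat([m.data for m in matrices], axis=1), matrices[0].unit)


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """Minimal gene model: TSS, strand and summed exon length.

    ``tss`` is a 0-based coordinate: the start of a + strand gene, or
    ``end - 1`` of a - strand gene.  ``length_bp`` is the length of the
    union of exon intervals (used for FPKM normalization).
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    length_bp: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: invalid strand {self.strand!r}")
        if self.length_bp < 1:
            raise ValidationError(f"{self.gene_id}: length_bp must be >= 1")
        if self.tss < 0:
            raise ValidationError(f"{self.gene_id}: negative TSS")


def merged_interval_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Total length of the union of half-open intervals."""
    total = 0
    end_prev = -1
    for start, end in sorted(intervals):
        if start > end_prev:
            total += end - start
            end_prev = end
        elif end > end_prev:
            total += end - end_prev
            end_prev = end
    return total


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_expression_matrix(path: str | Path, unit: Unit | str) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column gene id, header samples)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: cannot read TSV: {exc}") from exc
    df.index = df.index.astype(str)
    numeric = pd.DataFrame(index=df.index)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad.to_numpy().argmax()]
            raise ParseError(
                f"{path}: malformed numeric value in column {col!r}, row {gene!r}"
            )
        if converted.isna().any():
            gene = df.index[converted.isna().to_numpy().argmax()]
            raise ParseError(f"{path}: missing value in column {col!r}, row {gene!r}")
        numeric[col] = converted
    return ExpressionMatrix(numeric, Unit(unit))


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.data
    if matrix.unit is Unit.COUNTS:
        df = df.astype(np.int64)
    df.to_csv(path, sep="\t", index_label="gene_id", lineterminator="\n")


def read_sample_design(path: str | Path) -> SampleDesign:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "genotype": str,
                                            "stage": str, "maturity": str})
    return SampleDesign(df)


def write_sample_design(design: SampleDesign, path: str | Path) -> None:
    design.table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 (``.gff``/``.gff3``) or BED6.

    GFF3: TSS and strand come from ``gene`` features; length is the merged
    exon span of all exons below the gene (the gene span when no exons are
    annotated).  BED6: length is the interval length.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".gff", ".gff3"):
        return _read_gene_models_gff3(path)
    if suffix == ".bed":
        return _read_gene_models_bed(path)
    raise ParseError(f"{path}: unrecognized gene-model format {suffix!r}")


def _gff3_attributes(raw: str) -> dict[str, str]:
    out = {}
    for part in raw.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _read_gene_models_gff3(path: Path) -> list[GeneModel]:
    genes: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    parent_gene: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _, ftype, start, end, _, strand, _, attrs_raw = fields
            try:
                start0, end0 = int(start) - 1, int(end)  # to 0-based half-open
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad coordinates") from exc
            attrs = _gff3_attributes(attrs_raw)
            if ftype == "gene":
                gid = attrs.get("ID")
                if not gid:
                    raise ParseError(f"{path}:{lineno}: gene without ID attribute")
                if strand not in ("+", "-"):
                    raise ParseError(f"{path}:{lineno}: gene {gid} missing strand")
                if gid in genes:
                    raise ValidationError(f"{path}: duplicate gene id {gid!r}")
                genes[gid] = {"chrom": chrom, "strand": strand,
                              "start": start0, "end": end0}
            elif ftype == "mRNA":
                gid = attrs.get("Parent")
                tid = attrs.get("ID")
                if gid and tid:
                    parent_gene[tid] = gid
            elif ftype == "exon":
                parent = attrs.get("Parent", "")
                for p in parent.split(","):
                    gid = parent_gene.get(p, p)
                    exons.setdefault(gid, []).append((start0, end0))
    models = []
    for gid, info in genes.items():
        tss = info["start"] if info["strand"] == "+" else info["end"] - 1
        ivals = exons.get(gid) or [(info["start"], info["end"])]
        models.append(GeneModel(gid, info["chrom"], info["strand"], tss,
                                merged_interval_length(ivals)))
    return models


def _read_gene_models_bed(path: Path) -> list[GeneModel]:
    models = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: BED6 requires 6 columns")
            chrom, start, end, name, _, strand = fields[:6]
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: missing strand for {name!r}")
            if name in seen:
                raise ValidationError(f"{path}: duplicate gene id {name!r}")
            seen.add(name)
            start0, end0 = int(start), int(end)
            tss = start0 if strand == "+" else end0 - 1
            models.append(GeneModel(name, chrom, strand, tss, end0 - start0))
    return models


def write_gene_models_gff3(models: Sequence[GeneModel],
                           bodies: Mapping[str, tuple[int, int]],
                           path: str | Path) -> None:
    """Write single-exon gene models as GFF3.

    ``bodies`` maps gene id to its 0-based half-open genomic interval.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            start0, end0 = bodies[m.gene_id]
            start1, end1 = start0 + 1, end0  # 1-based closed
            fh.write(f"{m.chrom}\tpodmat\tgene\t{start1}\t{end1}\t.\t{m.strand}\t.\t"
                     f"ID={m.gene_id}\n")
            fh.write(f"{m.chrom}\tpodmat\tmRNA\t{start1}\t{end1}\t.\t{m.strand}\t.\t"
                     f"ID={m.gene_id}.1;Parent={m.gene_id}\n")
            fh.write(f"{m.chrom}\tpodmat\texon\t{start1}\t{end1}\t.\t{m.strand}\t.\t"
                     f"ID={m.gene_id}.1.exon1;Parent={m.gene_id}.1\n")


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a whole FASTA file into an ordered dict of upper-case strings."""
    out: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    out[name] = "".join(chunks).upper()
                name = line[1:].split()[0]
                chunks = []
            elif name is not None:
                chunks.append(line.strip())
    if name is not None:
        out[name] = "".join(chunks).upper()
    return out


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def compute_fpkm(counts: ExpressionMatrix, models: Sequence[GeneModel]) -> ExpressionMatrix:
    """Fragments per kilobase of transcript per million mapped fragments.

    ``fpkm[g, s] = counts[g, s] * 1e9 / (length_bp[g] * colsum[s])`` with the
    per-sample column sum standing in for total mapped fragments.  A sample
    with zero total yields an all-zero column.
    """
    if counts.unit is not Unit.COUNTS:
        raise ValidationError(f"expected counts matrix, got {counts.unit.value}")
    lengths = {m.gene_id: m.length_bp for m in models}
    missing = [g for g in counts.gene_ids if g not in lengths]
    if missing:
        raise ValidationError(f"missing gene lengths for: {missing[:10]}"
                              + ("..." if len(missing) > 10 else ""))
    values = counts.data.to_numpy(dtype=float)
    length_vec = np.array([lengths[g] for g in counts.gene_ids], dtype=float)
    colsum = values.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fpkm = values * 1e9 / (length_vec[:, None] * colsum[None, :])
    fpkm[:, colsum == 0] = 0.0
    return ExpressionMatrix(
        pd.DataFrame(fpkm, index=counts.data.index, columns=counts.data.columns),
        Unit.FPKM,
    )


def log1p_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise natural log of (1 + FPKM)."""
    if matrix.unit is not Unit.FPKM:
        raise ValidationError(f"expected fpkm matrix, got {matrix.unit.value}")
    return ExpressionMatrix(np.log1p(matrix.data), Unit.LOG1P_FPKM)
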