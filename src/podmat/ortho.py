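"""Direction-concordant cross-species comparison of maturation candidates.

Candidate genes shared across genotypes are kept only when at least one of
their reference-species homologs appears in the reference list of the same
direction; opposite-direction-only homology is reported as discordant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from podmat.datamodel_io import ValidationError


@dataclass
class HomologMap:
    """Many-to-many (bean gene, reference gene) pairs."""

    pairs: pd.DataFrame  # columns: gene_id, ref_gene_id

    def __post_init__(self) -> None:
        required = {"gene_id", "ref_gene_id"}
        if not required.issubset(self.pairs.columns):
            raise ValidationError(f"homolog map needs columns {sorted(required)}")
        self.pairs = self.pairs[["gene_id", "ref_gene_id"]].astype(str).reset_index(drop=True)
        if (self.pairs["gene_id"].str.len() == 0).any() or \
           (self.pairs["ref_gene_id"].str.len() == 0).any():
            raise ValidationError("homolog map contains empty ids")
        if self.pairs.duplicated().any():
            raise ValidationError("homolog map contains duplicate pairs")

    def homologs_of(self, gene_id: str) -> set[str]:
        sel = self.pairs["gene_id"] == gene_id
        return set(self.pairs.loc[sel, "ref_gene_id"])

    @classmethod
    def from_tsv(cls, path) -> "HomologMap":
        return cls(pd.read_csv(path, sep="\t", dtype=str))


@dataclass
class ConcordanceResult:
    shared_up: set[str]
    shared_down: set[str]
    discordant: set[str]    # homologs only in the opposite-direction list
    ambiguous: set[str] = field(default_factory=set)  # homologs in both lists
    n_pairs_up: int = 0     # concordant (bean, reference) pair counts
    n_pairs_down: int = 0


def concordant_shared_sets(shared_up: set[str], shared_down: set[str],
                           homolog_map: HomologMap,
                           ref_up: set[str], ref_down: set[str]) -> ConcordanceResult:
    """Keep shared DEGs whose homologs support the same direction.

    A bean gene enters the output when any of its reference homologs sits in
    the same-direction reference list; genes whose homologs appear in both
    lists are kept but flagged ambiguous; genes whose homologs appear only
    in the opposite list are excluded and reported as discordant.
    """
    overlap = shared_up & shared_down
    if overlap:
        raise ValidationError(f"genes in both directions: {sorted(overlap)[:5]}")
    if homolog_map.pairs.empty:
        warnings.warn("empty homolog map: no concordant genes can be found")
    out_up: set[str] = set()
    out_down: set[str] = set()
    discordant: set[str] = set()
    ambiguous: set[str] = set()
    n_pairs = {"up": 0, "down": 0}
    for genes, same_ref, other_ref, out, direction in (
        (shared_up, ref_up, ref_down, out_up, "up"),
        (shared_down, ref_down, ref_up, out_down, "down"),
    ):
        for gene in genes:
            homologs = homolog_map.homologs_of(gene)
            same = homologs & same_ref
            other = homologs & other_ref
            if same:
                out.add(gene)
                n_pairs[direction] += len(same)
                if other:
                    ambiguous.add(gene)
            elif other:
                discordant.add(gene)
    return ConcordanceResult(out_up, out_down, discordant, ambiguous,
                             n_pairs["up"], n_pairs["down"])


def final_maturation_set(shared_up: set[str], shared_down: set[str]) -> pd.DataFrame:
    """Deduplicated union of concordant up/down genes with direction labels."""
    both = shared_up & shared_down
    if both:
        raise ValidationError(
            f"genes listed in both directions (upstream invariant breach): "
            f"{sorted(both)[:5]}"
        )
    records = [(g, "up") for g in sorted(shared_up)] + \
              [(g, "down") for g in sorted(shared_down)]
    return pd.DataFrame(records, columns=["gene_id", "direction"])


def read_reference_lists(path) -> tuple[set[str], set[str]]:
    """Read a reference list TSV with columns ``ref_gene_id``, ``direction``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("ref_gene_id", "direction"):
        if col not in df.columns:
            raise ValidationError(f"reference list missing column {col!r}")
    bad = set(df["direction"]) - {"up", "down"}
    if bad:
        raise ValidationError(f"unknown directions in reference list: {sorted(bad)}")
    up = set(df.loc[df["direction"] == "up", "ref_gene_id"])
    down = set(df.loc[df["direction"] == "down", "ref_gene_id"])
    return up, down
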