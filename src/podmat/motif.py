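"""Strand-aware promoter extraction and PWM scanning with exact p-values.

Scoring is log2 odds of motif probabilities (zero entries regularized by a
pseudo-probability) against a 0-order background.  P-values are computed by
dynamic programming over discretized per-position score distributions; the
score of a query is rounded down before accumulation so the reported
p-value is a guaranteed upper bound on the exact one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from podmat.datamodel_io import (
    GeneModel,
    ParseError,
    ValidationError,
    read_fasta,
)

ALPHABET = "ACGT"
_LETTER_INDEX = {c: i for i, c in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

EVIDENCE_MOTIF = "motif"
EVIDENCE_MOTIF_CE = "motif_CE"
EVIDENCE_FUNTFBS = "FunTFBS"

SITE_COLUMNS = ["motif_id", "gene_id", "offset", "strand", "score", "p_value", "evidence"]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PWM:
    """Position probability matrix with background and pseudo-probability.

    ``probs`` is W x 4 over ACGT with rows summing to 1.  Zero entries are
    regularized as ``p' = p * (1 - 4 * pseudo) + pseudo`` before taking log
    odds, so a pseudo of 0.001 turns a probability of 1 into 0.997.
    """

    motif_id: str
    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudo: float = 0.001

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 or self.probs.shape[0] < 1:
            raise ValidationError(f"{self.motif_id}: probs must be W x 4 with W >= 1")
        if (self.probs < 0).any():
            raise ValidationError(f"{self.motif_id}: negative probabilities")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError(f"{self.motif_id}: rows must sum to 1")
        if self.background.shape != (4,) or (self.background < 0).any() or \
                not math.isclose(self.background.sum(), 1.0, abs_tol=1e-9):
            raise ValidationError(f"{self.motif_id}: invalid background")
        if (self.background == 0).any():
            raise ValidationError(f"{self.motif_id}: zero background frequency")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds_matrix(self) -> np.ndarray:
        adjusted = self.probs * (1.0 - 4.0 * self.pseudo) + self.pseudo
        with np.errstate(divide="ignore"):
            return np.log2(adjusted / self.background[None, :])

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(self.motif_id, self.probs[::-1, ::-1].copy(),
                   self.background[::-1].copy(), self.pseudo)


def log_odds(pwm: PWM, word: str) -> float:
    """Log2-odds score of a length-W word (ACGT only)."""
    if len(word) != pwm.width:
        raise ValidationError(
            f"word length {len(word)} != motif width {pwm.width}"
        )
    lom = pwm.log_odds_matrix
    total = 0.0
    for i, ch in enumerate(word.upper()):
        if ch not in _LETTER_INDEX:
            raise ValidationError(f"invalid letter {ch!r} in word")
        total += lom[i, _LETTER_INDEX[ch]]
    return float(total)


class ScoreDistribution:
    """Discretized null distribution of PWM scores under the background.

    Per-position scores are floored onto a grid of ``bins`` steps spanning
    the total score range; the tail array gives P(discrete score >= t).
    Querying uses threshold ``ceil(s/w) - W`` so the result upper-bounds the
    exact p-value and undershoots it by at most the mass between ``s`` and
    ``s - W * bin_width``.
    """

    def __init__(self, pwm: PWM, bins: int = 1000) -> None:
        if bins < 100:
            raise ValidationError("bins must be >= 100")
        lom = pwm.log_odds_matrix
        if not np.isfinite(lom).all():
            raise ValidationError(f"{pwm.motif_id}: degenerate PWM scores")
        self.width = pwm.width
        self.mins = lom.min(axis=1)
        self.offset = float(self.mins.sum())
        score_range = float((lom.max(axis=1) - self.mins).sum())
        self.bin_width = score_range / bins if score_range > 0 else 1.0
        self.int_scores = np.floor(
            (lom - self.mins[:, None]) / self.bin_width + 1e-12
        ).astype(np.int64)
        pmf = np.array([1.0])
        for i in range(self.width):
            limit = pmf.size + int(self.int_scores[i].max())
            nxt = np.zeros(limit, dtype=float)
            for letter in range(4):
                nxt[self.int_scores[i, letter]:
                    self.int_scores[i, letter] + pmf.size] += \
                    pwm.background[letter] * pmf
            pmf = nxt
        self.tail = np.minimum(np.cumsum(pmf[::-1])[::-1], 1.0)

    def _threshold_index(self, score: float | np.ndarray) -> np.ndarray:
        shifted = np.asarray(score, dtype=float) - self.offset
        t = np.ceil(shifted / self.bin_width - 1e-9).astype(np.int64) - self.width
        return np.clip(t, 0, self.tail.size - 1)

    def pvalue(self, score: float | np.ndarray):
        """Upper-bound p-value P(random word score >= ``score``)."""
        p = self.tail[self._threshold_index(score)]
        if np.ndim(score) == 0:
            return float(p)
        return p

    def score_at_pvalue(self, p_threshold: float) -> float:
        """Smallest real score guaranteed to satisfy p <= threshold."""
        idx = int(np.searchsorted(-self.tail, -p_threshold))
        if idx >= self.tail.size:
            return math.inf
        return self.offset + (idx + self.width) * self.bin_width


def pwm_pvalue_dp(pwm: PWM, score: float, bins: int = 1000) -> float:
    """Convenience wrapper: p-value of ``score`` under the background model."""
    return ScoreDistribution(pwm, bins=bins).pvalue(score)


# ---------------------------------------------------------------------------
# Promoter extraction
# ---------------------------------------------------------------------------

def extract_promoters(models: Sequence[GeneModel], genome: Mapping[str, str] | str | Path,
                      upstream: int = 500, downstream: int = 100) -> dict[str, str]:
    """Promoter window of each gene, 5'->3' relative to the gene.

    + strand: ``[tss - upstream, tss + downstream)`` on the forward strand;
    - strand: reverse complement of ``[tss - downstream + 1, tss + upstream + 1)``.
    Windows are clipped at contig bounds.
    """
    if not isinstance(genome, Mapping):
        genome = read_fasta(genome)
    out: dict[str, str] = {}
    for m in models:
        if m.chrom not in genome:
            raise ValidationError(f"{m.gene_id}: contig {m.chrom!r} not in genome")
        contig = genome[m.chrom]
        if m.strand == "+":
            lo, hi = m.tss - upstream, m.tss + downstream
        else:
            lo, hi = m.tss - downstream + 1, m.tss + upstream + 1
        lo, hi = max(0, lo), min(len(contig), hi)
        seq = contig[lo:hi].upper()
        out[m.gene_id] = seq if m.strand == "+" else reverse_complement(seq)
    return out


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    table = np.full(128, 4, dtype=np.int8)
    for ch, idx in _LETTER_INDEX.items():
        table[ord(ch)] = idx
    return table[arr]


def _window_scores(lom5: np.ndarray, encoded: np.ndarray) -> np.ndarray:
    width = lom5.shape[0]
    if encoded.size < width:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(encoded, width)
    return lom5[np.arange(width)[None, :], windows].sum(axis=1)


def scan_sites(pwms: Iterable[PWM], promoters: Mapping[str, str],
               p_threshold: float = 1e-5, bins: int = 1000) -> pd.DataFrame:
    """Scan both strands of every promoter; report sites with p <= threshold.

    Offsets are 0-based window starts within the promoter for both strands
    (a - strand site is the reverse complement of the window).  Windows
    containing non-ACGT letters are skipped.  Evidence is ``motif``.
    """
    records = []
    for pwm in pwms:
        dist = ScoreDistribution(pwm, bins=bins)
        lom = pwm.log_odds_matrix
        lom_fwd = np.hstack([lom, np.full((pwm.width, 1), np.nan)])
        lom_rev = np.hstack([lom[::-1, ::-1], np.full((pwm.width, 1), np.nan)])
        for gene_id, seq in promoters.items():
            encoded = _encode(seq)
            for strand, lom5 in (("+", lom_fwd), ("-", lom_rev)):
                scores = _window_scores(lom5, encoded)
                if not scores.size:
                    continue
                valid = np.isfinite(scores)
                if not valid.any():
                    continue
                pvals = np.full(scores.shape, np.nan)
                pvals[valid] = dist.pvalue(scores[valid])
                hits = np.flatnonzero(valid & (pvals <= p_threshold))
                for o in hits:
                    records.append((pwm.motif_id, gene_id, int(o), strand,
                                    float(scores[o]), float(pvals[o]),
                                    EVIDENCE_MOTIF))
    table = pd.DataFrame(records, columns=SITE_COLUMNS)
    return table.sort_values(
        ["motif_id", "gene_id", "offset", "strand"]
    ).reset_index(drop=True)


def filter_evidence(sites: pd.DataFrame,
                    conserved: pd.DataFrame | None = None,
                    functional: pd.DataFrame | set | None = None,
                    mode: str = EVIDENCE_MOTIF,
                    widths: Mapping[str, int] | None = None) -> pd.DataFrame:
    """Restrict a site table to an evidence class.

    ``motif`` returns the table unchanged.  ``motif_CE`` keeps sites whose
    overlap with any conserved interval (promoter-relative, per gene)
    strictly exceeds 50% of site length; ``conserved`` needs columns
    ``gene_id``, ``start``, ``end``.  ``FunTFBS`` keeps sites carrying a
    functional label: rows of (motif_id, gene_id, offset, strand).
    """
    if mode == EVIDENCE_MOTIF:
        return sites.copy()
    if mode == EVIDENCE_MOTIF_CE:
        if conserved is None:
            raise ValidationError("motif_CE mode requires a conserved-element track")
        if widths is None:
            raise ValidationError("motif_CE mode requires motif widths")
        by_gene: dict[str, list[tuple[int, int]]] = {}
        for row in conserved.itertuples(index=False):
            by_gene.setdefault(str(row.gene_id), []).append((int(row.start), int(row.end)))
        keep = []
        for i, row in sites.iterrows():
            width = widths[row["motif_id"]]
            lo, hi = int(row["offset"]), int(row["offset"]) + width
            best = 0
            for start, end in by_gene.get(row["gene_id"], ()):
                best = max(best, min(hi, end) - max(lo, start))
            if best * 2 > width:  # strict > 50%
                keep.append(i)
        out = sites.loc[keep].copy()
        out["evidence"] = EVIDENCE_MOTIF_CE
        return out.reset_index(drop=True)
    if mode == EVIDENCE_FUNTFBS:
        if functional is None:
            raise ValidationError("FunTFBS mode requires functional labels")
        if isinstance(functional, pd.DataFrame):
            labels = set(functional[["motif_id", "gene_id", "offset", "strand"]]
                         .itertuples(index=False, name=None))
        else:
            labels = set(functional)
        mask = [
            (row["motif_id"], row["gene_id"], int(row["offset"]), row["strand"]) in labels
            for _, row in sites.iterrows()
        ]
        out = sites.loc[mask].copy()
        out["evidence"] = EVIDENCE_FUNTFBS
        return out.reset_index(drop=True)
    raise ValidationError(f"unknown evidence mode: {mode!r}")


# ---------------------------------------------------------------------------
# MEME minimal format
# ---------------------------------------------------------------------------

def read_meme(path: str | Path, pseudo: float = 0.001) -> list[PWM]:
    """Parse a MEME minimal motif file into PWMs."""
    path = Path(path)
    background = np.full(4, 0.25)
    pwms: list[PWM] = []
    lines = path.read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.lower().startswith("background letter frequencies"):
            i += 1
            tokens = lines[i].split()
            freqs = dict(zip(tokens[::2], map(float, tokens[1::2])))
            background = np.array([freqs.get(c, 0.25) for c in ALPHABET])
        elif line.startswith("MOTIF"):
            parts = line.split()
            if len(parts) < 2:
                raise ParseError(f"{path}: MOTIF line without identifier")
            motif_id = parts[1]
            i += 1
            while i < len(lines) and not lines[i].strip().lower().startswith(
                    "letter-probability matrix"):
                if lines[i].strip().startswith("MOTIF"):
                    raise ParseError(f"{path}: motif {motif_id} has no matrix")
                i += 1
            if i >= len(lines):
                raise ParseError(f"{path}: motif {motif_id} has no matrix")
            header = lines[i]
            width = None
            tokens = header.replace("=", " = ").split()
            for j, tok in enumerate(tokens):
                if tok == "w" and j + 2 < len(tokens):
                    width = int(tokens[j + 2])
            rows = []
            i += 1
            while i < len(lines):
                stripped = lines[i].strip()
                if not stripped or stripped.startswith(("MOTIF", "URL")):
                    break
                rows.append([float(x) for x in stripped.split()])
                i += 1
            if width is not None and len(rows) != width:
                raise ParseError(
                    f"{path}: motif {motif_id} expects {width} rows, got {len(rows)}"
                )
            probs = np.array(rows)
            sums = probs.sum(axis=1)
            if np.abs(sums - 1.0).max() > 1e-3:
                raise ParseError(f"{path}: motif {motif_id} rows do not sum to 1")
            probs = probs / sums[:, None]  # absorb fixed-precision rounding
            pwms.append(PWM(motif_id, probs, background.copy(), pseudo))
            continue
        i += 1
    return pwms


def write_meme(pwms: Sequence[PWM], path: str | Path) -> None:
    """Write PWMs in MEME minimal format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        if pwms:
            bg = pwms[0].background
            fh.write("Background letter frequencies\n")
            fh.write(" ".join(f"{c} {bg[i]:.6f}" for i, c in enumerate(ALPHABET)) + "\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.motif_id}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {pwm.width} "
                     f"nsites= 20 E= 0\n")
            for row in pwm.probs:
                fh.write(" " + " ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")
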