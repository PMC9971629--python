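"""Core domain types shared by every stage of the pipeline.

Coordinate convention: GTF files are 1-based inclusive on disk; in memory all
intervals are 0-based half-open ``[start, end)``. Sequences are stored in DNA
letters (``U`` is normalised to ``T`` on input, with a per-record flag keeping
the original alphabet).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_CLASS_CODES = frozenset("=ixuoecjkmnpsry.")
LNCRNA_CLASS_CODES = frozenset("ixuoe")

DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ValidationError(ValueError):
    """Raised when a record violates a domain-type invariant."""


class IntegrityError(ValueError):
    """Raised when records contradict each other (e.g. duplicated ids)."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA-letter sequence."""
    return seq.translate(DNA_COMPLEMENT)[::-1]


@dataclass
class TranscriptModel:
    """One assembled transcript: exon structure plus optional spliced sequence.

    ``class_code`` uses the gffcompare vocabulary relating an assembled
    transcript to reference annotation ("=" exact match, "u" intergenic,
    "x" antisense, "i" intronic, "o"/"e" sense overlap, ...).
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    class_code: str = "="
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r} "
                "(the pipeline assumes a strand-specific library)"
            )
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: transcript has no exons")
        exons = sorted((int(s), int(e)) for s, e in self.exons)
        prev_end = None
        for s, e in exons:
            if e <= s or s < 0:
                raise ValidationError(
                    f"{self.transcript_id}: bad exon interval [{s},{e})"
                )
            if prev_end is not None and s < prev_end:
                raise ValidationError(
                    f"{self.transcript_id}: overlapping exons at {s} < {prev_end}"
                )
            prev_end = e
        self.exons = exons
        if len(self.class_code) != 1:
            raise ValidationError(
                f"{self.transcript_id}: class_code must be one character, "
                f"got {self.class_code!r}"
            )
        if self.sequence is not None and len(self.sequence) != self.spliced_length:
            raise ValidationError(
                f"{self.transcript_id}: sequence length {len(self.sequence)} != "
                f"spliced length {self.spliced_length}"
            )

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic span (first exon start, last exon end), half-open."""
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class ExpressionMatrix:
    """Features x samples expression values with group labels.

    ``units`` is "counts" or "fpkm". ``groups`` maps each sample id to its
    experimental group (control "CK" vs drought "DR" in the reference design).
    """

    values: pd.DataFrame  # index = feature ids, columns = sample ids
    groups: dict[str, str]
    units: str = "counts"

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        arr = self.values.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if arr.size and (np.asarray(arr) < 0).any():
            raise ValidationError("expression values must be non-negative")
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise ValidationError(f"samples without a group label: {missing}")
        if self.units not in ("counts", "fpkm"):
            raise ValidationError(f"unknown units tag {self.units!r}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_of(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]

    def group_names(self) -> list[str]:
        seen: list[str] = []
        for s in self.values.columns:
            g = self.groups[s]
            if g not in seen:
                seen.append(g)
        return seen


@dataclass
class FastaRecord:
    """A sequence normalised to DNA letters, remembering its input alphabet."""

    seq_id: str
    sequence: str
    was_rna: bool = False


@dataclass
class DEResult:
    feature_id: str
    base_mean_ck: float
    base_mean_dr: float
    log2fc: float
    p_value: float
    fdr: float = float("nan")
    status: str = "ns"


@dataclass
class TargetPair:
    lncrna_id: str
    gene_id: str
    mode: str  # "cis" or "trans"
    distance_bp: int | None = None
    ndg: float | None = None
    site: tuple[int, int] | None = None


@dataclass
class MRESite:
    """A miRNA response element on a transcript.

    ``kind`` is "cleavage_target" for canonical near-perfect complementarity
    or "mimic" for an endogenous target mimic carrying the 3-nt bulge opposite
    miRNA positions 9-11.
    """

    molecule_id: str
    mirna_id: str
    start: int
    end: int
    penalty_score: float
    kind: str
    alignment: tuple[str, str, str]
    non_bulge_penalty: float = float("nan")
    has_canonical_bulge: bool = False


@dataclass
class CeRNATriplet:
    lncrna_id: str
    mrna_id: str
    shared_mirnas: frozenset[str]
    cerna_score: float
    p_value: float
    fdr: float = float("nan")
    corr_lnc_mrna: float = float("nan")
    mirna_correlations: dict[str, tuple[float, float]] = field(default_factory=dict)


@dataclass
class EnrichmentResult:
    term_id: str
    term_label: str
    k: int
    n: int
    K: int
    N: int
    p_value: float
    fdr: float
    fold_enrichment: float
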