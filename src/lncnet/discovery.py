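"""Candidate lncRNA screening, coding-potential consensus and summaries.

The screen keeps assembled transcripts that (1) carry a gffcompare class code
in {i, x, u, o, e}, (2) are >= 200 nt spliced with >= 2 exons, and (3) reach
FPKM >= 0.1 in at least one sample. Candidates surviving the screen are then
required to be called non-coding by every configured coding-potential tool
(set intersection, the three-tool Venn design). A built-in ORF-length scorer
stands in for external classifiers; externally produced call tables can be
slotted into the consensus unchanged.

Note the exon-count filter is a config switch: most plant lncRNAs are
single-exon, so pipelines differ on whether to require >= 2 exons. The
default applies it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .types import (
    LNCRNA_CLASS_CODES,
    ExpressionMatrix,
    TranscriptModel,
    ValidationError,
)

STOP_CODONS = {"TAA", "TAG", "TGA"}

CATEGORY_BY_CODE = {
    "u": "lincRNA",
    "x": "antisense",
    "o": "sense_overlap",
    "e": "sense_overlap",
    "i": "intronic",
}

LENGTH_BIN_LABELS = ("<1000", "1000-2000", ">2000")


@dataclass
class CodingPotentialCall:
    transcript_id: str
    tool_name: str
    is_noncoding: bool
    score: float


@dataclass
class LncRNARecord:
    transcript_id: str
    category: str
    length_nt: int
    n_exons: int
    max_fpkm: float


# ---------------------------------------------------------------------------
# Basic screen


def basic_screen(
    transcripts: list[TranscriptModel],
    fpkm: ExpressionMatrix,
    config: RunConfig,
) -> tuple[list[TranscriptModel], pd.DataFrame]:
    """Apply the structural/class-code/expression filters.

    Returns retained transcripts plus a per-transcript log naming the first
    failing rule ("retained" if none). Every transcript in the FPKM matrix
    must exist among the transcript models and vice versa for the transcripts
    being judged.
    """
    missing = [t.transcript_id for t in transcripts if t.transcript_id not in fpkm.values.index]
    if missing:
        raise ValidationError(f"transcripts missing from FPKM matrix: {missing[:10]}")
    max_fpkm = fpkm.values.max(axis=1)
    retained = []
    log_rows = []
    for t in transcripts:
        rule = _screen_verdict(t, float(max_fpkm[t.transcript_id]), config)
        log_rows.append((t.transcript_id, rule))
        if rule == "retained":
            retained.append(t)
    log = pd.DataFrame(log_rows, columns=["transcript_id", "verdict"])
    return retained, log


def _screen_verdict(t: TranscriptModel, max_fpkm: float, config: RunConfig) -> str:
    if t.class_code not in LNCRNA_CLASS_CODES:
        return "class_code"
    if t.spliced_length < config.min_length_nt:
        return "length"
    if config.exon_filter_enabled and t.n_exons < config.min_exons:
        return "exon_count"
    if max_fpkm < config.min_fpkm:
        return "fpkm"
    return "retained"


# ---------------------------------------------------------------------------
# Coding-potential stub


def longest_orf_codons(sequence: str) -> int:
    """Longest forward-strand ATG->stop ORF length in codons (ATG included,
    stop excluded); 0 when no complete ORF exists."""
    seq = sequence.upper().replace("U", "T")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValidationError(f"non-nucleotide characters {sorted(bad)}")
    best = 0
    n = len(seq)
    for frame in range(3):
        start = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in STOP_CODONS:
                best = max(best, (i - start) // 3)
                start = None
        # an ORF still open at the 3' end has no stop and does not count
    return best


def coding_potential_stub(
    transcript_id: str,
    sequence: str,
    config: RunConfig | None = None,
    tool_name: str = "orf_stub",
) -> CodingPotentialCall:
    """ORF-length classifier standing in for external coding-potential tools.

    A transcript is coding when its longest complete ORF reaches
    ``orf_max_codons`` (default 100, the classical lncRNA convention;
    ``novel_gene_min_aa`` = 50 aa is the separate novel-gene cutoff and is
    not applied here).
    """
    if not sequence:
        raise ValidationError(f"{transcript_id}: empty sequence")
    cutoff = (config or RunConfig()).orf_max_codons
    score = longest_orf_codons(sequence)
    return CodingPotentialCall(transcript_id, tool_name, score < cutoff, float(score))


# ---------------------------------------------------------------------------
# Consensus


def consensus_noncoding(
    calls: list[CodingPotentialCall],
    required_tools: list[str],
) -> tuple[set[str], dict[frozenset[str], int]]:
    """Intersection of per-tool non-coding calls, plus Venn region counts.

    Every transcript must have exactly one call per required tool. The Venn
    counts partition the transcripts called non-coding by >= 1 tool by the
    exact tool subset that called them non-coding.
    """
    by_transcript: dict[str, dict[str, bool]] = {}
    for c in calls:
        tools = by_transcript.setdefault(c.transcript_id, {})
        if c.tool_name in tools:
            raise ValidationError(
                f"duplicate call for ({c.transcript_id}, {c.tool_name})"
            )
        tools[c.tool_name] = c.is_noncoding
    required = list(required_tools)
    retained: set[str] = set()
    venn: dict[frozenset[str], int] = {}
    for tid, tools in by_transcript.items():
        missing = [t for t in required if t not in tools]
        if missing:
            raise ValidationError(f"{tid}: missing calls from tools {missing}")
        noncoding_by = frozenset(t for t in required if tools[t])
        if noncoding_by:
            venn[noncoding_by] = venn.get(noncoding_by, 0) + 1
        if len(noncoding_by) == len(required):
            retained.add(tid)
    return retained, venn


# ---------------------------------------------------------------------------
# Classification and summaries


def classify_category(class_code: str) -> str:
    """Map a lncRNA class code to its positional category."""
    try:
        return CATEGORY_BY_CODE[class_code]
    except KeyError:
        raise ValidationError(
            f"class code {class_code!r} is not a lncRNA code "
            f"(expected one of {sorted(CATEGORY_BY_CODE)})"
        ) from None


def length_bin(length_nt: int) -> str:
    """Short/medium/long bins with edges at 1000 and 2000 nt; the lower bin
    is closed at 999 so a 1000-nt transcript is medium-length."""
    if length_nt <= 999:
        return LENGTH_BIN_LABELS[0]
    if length_nt <= 2000:
        return LENGTH_BIN_LABELS[1]
    return LENGTH_BIN_LABELS[2]


def make_records(
    transcripts: list[TranscriptModel],
    fpkm: ExpressionMatrix,
) -> list[LncRNARecord]:
    max_fpkm = fpkm.values.max(axis=1)
    return [
        LncRNARecord(
            transcript_id=t.transcript_id,
            category=classify_category(t.class_code),
            length_nt=t.spliced_length,
            n_exons=t.n_exons,
            max_fpkm=float(max_fpkm[t.transcript_id]),
        )
        for t in transcripts
    ]


def summarize_lncrnas(records: list[LncRNARecord]) -> dict[str, pd.Series]:
    """Category proportions, length-bin fractions, exon histogram, FPKM stats."""
    if not records:
        raise ValidationError("cannot summarise an empty lncRNA set")
    df = pd.DataFrame(
        [(r.category, r.length_nt, r.n_exons, r.max_fpkm) for r in records],
        columns=["category", "length_nt", "n_exons", "max_fpkm"],
    )
    categories = df["category"].value_counts(normalize=True).sort_index()
    bins = (
        df["length_nt"].map(length_bin).value_counts(normalize=True)
        .reindex(list(LENGTH_BIN_LABELS), fill_value=0.0)
    )
    exons = df["n_exons"].value_counts(normalize=True).sort_index()
    fpkm_stats = df["max_fpkm"].describe()[["min", "25%", "50%", "75%", "max"]]
    return {
        "category_proportions": categories,
        "length_bin_proportions": bins,
        "exon_count_proportions": exons,
        "fpkm_box_stats": fpkm_stats,
    }


def group_presence_venn(
    fpkm: ExpressionMatrix,
    config: RunConfig,
    group_a: str = "CK",
    group_b: str = "DR",
) -> tuple[set[str], set[str], set[str]]:
    """Split features into (shared, A-only, B-only) by group presence.

    A feature is present in a group when FPKM >= min_fpkm in at least one of
    that group's replicates. The three sets are disjoint and cover every
    feature present anywhere.
    """
    for g in (group_a, group_b):
        if not fpkm.samples_of(g):
            raise ValidationError(f"group {g!r} has no samples")
    vals = fpkm.values
    in_a = (vals[fpkm.samples_of(group_a)] >= config.min_fpkm).any(axis=1)
    in_b = (vals[fpkm.samples_of(group_b)] >= config.min_fpkm).any(axis=1)
    idx = np.asarray(vals.index)
    shared = set(idx[(in_a & in_b).to_numpy()])
    a_only = set(idx[(in_a & ~in_b).to_numpy()])
    b_only = set(idx[(~in_a & in_b).to_numpy()])
    return shared, a_only, b_only
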