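"""Readers and writers for the standard formats the pipeline consumes.

GTF coordinates are 1-based inclusive on disk and converted to 0-based
half-open in memory. Readers reject invalid records instead of coercing them;
``writer o reader`` is the identity on every persisted field.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd
from Bio import SeqIO
from gffutils.feature import feature_from_line

from .types import (
    ExpressionMatrix,
    FastaRecord,
    IntegrityError,
    TranscriptModel,
    ValidationError,
)

_SEQ_ALPHABET = set("ACGTUN")


class ParseError(ValueError):
    """Raised for malformed input files, naming the offending line."""


# ---------------------------------------------------------------------------
# GTF


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read transcript models from a GTF file.

    Exon features are grouped by their ``transcript_id`` attribute; a
    ``class_code`` attribute is honoured when present (default "=").
    Transcripts that have no exon rows are rejected.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str, str]] = {}  # tid -> (gene, chrom, strand, code)
    seen_ids: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.count("\t") != 8:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-separated fields")
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises assorted types
                raise ParseError(f"{path}:{lineno}: malformed GTF line ({exc})") from exc
            try:
                tid = feat.attributes["transcript_id"][0]
            except (KeyError, IndexError):
                raise ParseError(f"{path}:{lineno}: missing transcript_id attribute")
            gene = (feat.attributes.get("gene_id") or [tid])[0]
            code = (feat.attributes.get("class_code") or ["="])[0]
            key = (gene, feat.seqid, feat.strand, code)
            if tid in meta:
                old = meta[tid]
                if old[1] != feat.seqid or old[2] != feat.strand:
                    raise IntegrityError(
                        f"{path}:{lineno}: transcript {tid} re-declared on "
                        f"{feat.seqid}{feat.strand} (was {old[1]}{old[2]})"
                    )
            else:
                meta[tid] = key
                seen_ids.append(tid)
            if feat.featuretype == "exon":
                # GTF 1-based inclusive -> 0-based half-open
                exons.setdefault(tid, []).append((feat.start - 1, feat.end))
    models = []
    for tid in seen_ids:
        gene, chrom, strand, code = meta[tid]
        if tid not in exons:
            raise ValidationError(f"{path}: transcript {tid} has no exon rows")
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gene,
                chrom=chrom,
                strand=strand,
                exons=exons[tid],
                class_code=code,
            )
        )
    return models


def write_gtf(models: list[TranscriptModel], path: str | Path) -> None:
    """Write transcript + exon rows; inverse of :func:`read_gtf`."""
    with open(path, "w") as fh:
        for m in models:
            attrs = (
                f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
                f'class_code "{m.class_code}";'
            )
            span = m.span
            fh.write(
                f"{m.chrom}\tlncnet\ttranscript\t{span[0] + 1}\t{span[1]}\t.\t"
                f"{m.strand}\t.\t{attrs}\n"
            )
            for s, e in m.exons:
                fh.write(
                    f"{m.chrom}\tlncnet\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, FastaRecord]:
    """Read FASTA into id -> record, normalising RNA (U) to DNA letters.

    Characters outside {A,C,G,T,U,N} (case-insensitive) are rejected.
    """
    out: dict[str, FastaRecord] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValidationError(f"{path}: empty sequence for {rec.id}")
        bad = set(seq) - _SEQ_ALPHABET
        if bad:
            raise ValidationError(
                f"{path}: record {rec.id} has non-nucleotide characters {sorted(bad)}"
            )
        was_rna = "U" in seq
        if was_rna and "T" in seq:
            raise ValidationError(f"{path}: record {rec.id} mixes T and U")
        out[rec.id] = FastaRecord(rec.id, seq.replace("U", "T"), was_rna)
    return out


def write_fasta(records: dict[str, str] | dict[str, FastaRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in records:
            rec = records[name]
            seq = rec.sequence if isinstance(rec, FastaRecord) else rec
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# Count / annotation tables


def read_counts(
    path: str | Path,
    groups: dict[str, str] | None = None,
    units: str = "counts",
) -> ExpressionMatrix:
    """Read a features x samples TSV with a header row of sample ids.

    Group labels default to the leading alphabetic prefix of each sample id
    (CK1 -> CK), the convention of the 2 x 3 reference design.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.columns.empty:
        raise ParseError(f"{path}: no sample columns found")
    if df.isna().to_numpy().any():
        raise ParseError(f"{path}: ragged or non-numeric rows (NaN after parse)")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ParseError(f"{path}: non-numeric values in column {col}")
    if (df.to_numpy() < 0).any():
        raise ValidationError(f"{path}: negative expression values")
    if groups is None:
        groups = {s: _group_prefix(s) for s in df.columns}
    return ExpressionMatrix(values=df, groups=groups, units=units)


def _group_prefix(sample_id: str) -> str:
    prefix = sample_id.rstrip("0123456789")
    return prefix or sample_id


def read_groups(path: str | Path) -> dict[str, str]:
    """Two-column TSV sample_id<TAB>group."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"])
    return dict(zip(df["sample"].astype(str), df["group"].astype(str)))


def read_term_map(path: str | Path) -> dict[str, set[str]]:
    """term_id<TAB>gene_id (one pair per line) -> term -> gene set."""
    df = pd.read_csv(path, sep="\t", header=None, names=["term", "gene"])
    out: dict[str, set[str]] = {}
    for term, gene in zip(df["term"], df["gene"]):
        out.setdefault(str(term), set()).add(str(gene))
    return out


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Deterministic TSV export (fixed float format, no platform newlines)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, lineterminator="\n", float_format="%.6g")


# ---------------------------------------------------------------------------
# Network export


def write_network(graph: nx.Graph, outdir: str | Path, prefix: str = "cerna") -> None:
    """Export node TSV + edge TSV + GraphML for a typed ceRNA graph."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nodes = pd.DataFrame(
        [(n, graph.nodes[n].get("kind", "")) for n in sorted(graph.nodes)],
        columns=["node_id", "kind"],
    )
    edges = pd.DataFrame(
        sorted(
            (u, v, d.get("kind", "")) if u <= v else (v, u, d.get("kind", ""))
            for u, v, d in graph.edges(data=True)
        ),
        columns=["source", "target", "kind"],
    )
    write_table(nodes, outdir / f"{prefix}_nodes.tsv")
    write_table(edges, outdir / f"{prefix}_edges.tsv")
    nx.write_graphml(graph, outdir / f"{prefix}.graphml")
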