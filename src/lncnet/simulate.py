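"""Synthetic dataset generator with planted ground truth.

Emulates the statistical structure the analysis assumes at desk scale: a
two-chromosome genome carrying protein-coding genes (each with a long ORF so
the coding-potential scorer recognises them) and planted lncRNAs drawn from
the gffcompare class-code categories, with the field-typical length profile
(≈88.5% < 1000 nt, 7.9% 1000-2000 nt, 3.6% > 2000 nt); negative-binomial
fragment counts for a 2-group x 3-replicate design (CK1-3 / DR1-3) with
planted drought effects spanning |log2FC| in {2, 4, 13}; planted miRNA
response elements (perfect cleavage sites and canonically bulged target-mimic
sites); and planted ceRNA triplets whose lncRNA and mRNA hosts share five
miRNAs and are co-regulated, next to decoy pairs sharing only two.

Everything is generated from one seeded RNG: a fixed seed reproduces the
dataset byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as lio
from .discovery import STOP_CODONS, longest_orf_codons
from .types import ExpressionMatrix, TranscriptModel, ValidationError, revcomp

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_WOBBLE_PARTNERS = {"A": set(), "C": set(), "G": {"T"}, "T": {"G"}}


class GenerationError(RuntimeError):
    """Raised when a placement constraint cannot be satisfied."""


@dataclass
class SimulationSpec:
    """Defaults define the miniature study conditions; see the methods note."""

    # genome / annotation
    n_chrom: int = 2
    chrom_length: int = 1_000_000
    n_coding_genes: int = 80
    n_lncrna_by_code: dict[str, int] = field(
        default_factory=lambda: {"u": 90, "x": 26, "o": 2, "e": 2, "i": 4}
    )
    length_bin_props: tuple[float, float, float] = (0.885, 0.079, 0.036)
    length_bin_ranges: tuple[tuple[int, int], ...] = (
        (200, 999),
        (1000, 2000),
        (2001, 3000),
    )
    lnc_exon_probs: dict[int, float] = field(
        default_factory=lambda: {1: 0.20, 2: 0.55, 3: 0.20, 4: 0.05}
    )
    gc_content: float = 0.45
    # counts
    n_samples_per_group: int = 3
    nb_dispersion: float = 0.05
    base_mean_log: float = float(np.log(80.0))
    base_mean_sigma: float = 0.6
    de_base_mean_range: tuple[float, float] = (100.0, 400.0)
    size_factor_sigma: float = 0.05
    n_silent_lncrna: int = 4
    # planted effects (count per signed log2FC)
    lnc_de_plan: dict[float, int] = field(
        default_factory=lambda: {4.0: 8, -4.0: 4, 2.0: 3, -2.0: 2, 13.0: 2, -13.0: 2}
    )
    mrna_de_plan: dict[float, int] = field(
        default_factory=lambda: {4.0: 10, -4.0: 6, 2.0: 5, -2.0: 4, 13.0: 3, -13.0: 2}
    )
    # miRNAs and planted sites
    n_mirnas: int = 30
    mirna_length: int = 21
    n_free_cleavage_sites: int = 12
    n_free_mimic_sites: int = 12
    # ceRNA triplets
    n_triplets: int = 6
    triplet_shared_mirnas: int = 5
    n_decoys: int = 6
    decoy_shared_mirnas: int = 2
    # planted trans-target complementarity
    n_trans_pairs: int = 4
    trans_segment_nt: int = 120
    # annotation terms
    n_terms: int = 12
    # reproducibility
    rng_seed: int = 0
    max_placement_retries: int = 200

    def __post_init__(self) -> None:
        if abs(sum(self.length_bin_props) - 1.0) > 1e-9:
            raise ValidationError("length_bin_props must sum to 1")
        if abs(sum(self.lnc_exon_probs.values()) - 1.0) > 1e-9:
            raise ValidationError("lnc_exon_probs must sum to 1")
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be positive")
        if min(self.n_chrom, self.n_coding_genes, self.n_mirnas) < 1:
            raise ValidationError("n_chrom, n_coding_genes, n_mirnas must be >= 1")


@dataclass
class GroundTruth:
    """Machine-readable record of everything that was planted."""

    lncrnas: pd.DataFrame  # transcript_id, class_code, expected_detectable, ...
    de: pd.DataFrame  # feature_id, kind, log2fc
    mres: pd.DataFrame  # molecule_id, mirna_id, start, end, kind
    triplets: pd.DataFrame  # lncrna_id, mrna_id, shared_mirnas, is_decoy
    trans: pd.DataFrame  # lncrna_id, mrna_id, lnc_start, lnc_end


@dataclass
class SimulatedDataset:
    spec: SimulationSpec
    models: list[TranscriptModel]
    sequences: dict[str, str]
    mirnas: dict[str, str]
    counts: ExpressionMatrix
    term_map: dict[str, set[str]]
    truth: GroundTruth


# ---------------------------------------------------------------------------
# sequence helpers


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p))


_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]


def _coding_sequence(rng: np.random.Generator, length: int, utr3_min: int) -> tuple[str, int]:
    """Random sequence of `length` nt embedding a long ORF; returns the
    sequence and the ORF end (so later edits can stay 3' of it)."""
    utr5 = int(rng.integers(20, 60))
    max_codons = (length - utr5 - 3 - utr3_min) // 3 - 1
    if max_codons < 110:
        raise GenerationError(
            f"coding gene of {length} nt cannot host a >=110-codon ORF "
            f"with a {utr3_min}-nt 3' region"
        )
    n_codons = int(rng.integers(110, min(max_codons, 300) + 1))
    codons = rng.choice(_NONSTOP_CODONS, size=n_codons - 1)
    orf = "ATG" + "".join(codons) + "TAA"
    head = _random_seq(rng, utr5, 0.45)
    tail = _random_seq(rng, length - utr5 - len(orf), 0.45)
    return head + orf + tail, utr5 + len(orf)


def _break_long_orfs(
    seq: str,
    max_codons: int,
    rng: np.random.Generator,
    protected: list[tuple[int, int]] | None = None,
) -> str:
    """Mutate codons to stops until no forward-strand ORF reaches max_codons,
    never touching protected intervals."""
    protected = protected or []
    s = list(seq)
    for _ in range(200):
        hit = _find_long_orf("".join(s), max_codons)
        if hit is None:
            return "".join(s)
        start, end = hit
        # candidate codon slots strictly inside the ORF, outside protections
        slots = [
            i
            for i in range(start + 3, end - 3, 3)
            if not any(p0 < i + 3 and i < p1 for p0, p1 in protected)
        ]
        if not slots:
            raise GenerationError(
                "cannot break a long ORF without damaging a planted site"
            )
        i = int(rng.choice(slots))
        s[i : i + 3] = "TAA"
    raise GenerationError("ORF repair did not converge")


def _find_long_orf(seq: str, max_codons: int) -> tuple[int, int] | None:
    n = len(seq)
    for frame in range(3):
        start = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in STOP_CODONS:
                if (i - start) // 3 >= max_codons:
                    return start, i + 3
                start = None
    return None


def make_cleavage_site(mirna: str) -> str:
    """A perfect miRNA complementary site (cleavage-type MRE)."""
    return revcomp(mirna)


def make_mimic_site(mirna: str, rng: np.random.Generator) -> str:
    """A target-mimic site: perfect complement with a 3-nt bulge between
    miRNA positions 10 and 11. The inserted bases are chosen unable to pair
    with the surrounding miRNA bases so the bulge is unambiguous."""
    comp_53 = [_COMP[c] for c in mirna]  # target 3'->5' order
    context = set(mirna[8:13])
    viable = [
        b
        for b in "ACGT"
        if all(b != _COMP[m] and b not in _WOBBLE_PARTNERS[m] for m in context)
    ]
    if not viable:
        viable = [
            b for b in "ACGT" if all(b != _COMP[m] for m in context)
        ] or list("ACGT")
    ins = "".join(rng.choice(viable, size=3))
    bulged_35 = "".join(comp_53[:10]) + ins + "".join(comp_53[10:])
    return bulged_35[::-1]  # back to 5'->3'


# ---------------------------------------------------------------------------
# annotation


def _draw_lnc_length(spec: SimulationSpec, rng: np.random.Generator) -> int:
    b = rng.choice(len(spec.length_bin_props), p=list(spec.length_bin_props))
    lo, hi = spec.length_bin_ranges[b]
    return int(rng.integers(lo, hi + 1))


def _split_exons(
    total: int,
    n_exons: int,
    start: int,
    rng: np.random.Generator,
    intron_range: tuple[int, int] = (50, 400),
) -> list[tuple[int, int]]:
    """Split a spliced length into n_exons exons separated by introns."""
    if n_exons == 1:
        return [(start, start + total)]
    cuts = np.sort(rng.choice(np.arange(1, total), size=n_exons - 1, replace=False))
    sizes = np.diff([0, *cuts.tolist(), total])
    introns = rng.integers(intron_range[0], intron_range[1], size=n_exons - 1)
    exons = []
    pos = start
    for i, size in enumerate(sizes):
        exons.append((pos, pos + int(size)))
        pos += int(size) + (int(introns[i]) if i < n_exons - 1 else 0)
    return exons


def simulate_annotation(
    spec: SimulationSpec, rng: np.random.Generator
) -> tuple[list[TranscriptModel], dict[str, str], dict[str, int]]:
    """Place coding genes and class-coded lncRNAs on the synthetic genome.

    Returns transcript models, spliced sequences, and per-coding-gene ORF end
    offsets (sites planted later must stay 3' of the ORF).
    """
    models: list[TranscriptModel] = []
    seqs: dict[str, str] = {}
    orf_ends: dict[str, int] = {}
    gene_spans: dict[str, list[tuple[int, int, str, str]]] = {
        f"chr{i + 1}": [] for i in range(spec.n_chrom)
    }
    chroms = sorted(gene_spans)

    # coding genes: random sparse placement, 2-4 exons, embedded long ORF
    for g in range(spec.n_coding_genes):
        chrom = chroms[g % len(chroms)]
        length = int(rng.integers(800, 2500))
        n_exons = int(rng.integers(2, 5))
        strand = "+" if rng.random() < 0.5 else "-"
        for _ in range(spec.max_placement_retries):
            start = int(rng.integers(0, spec.chrom_length - length - 12000))
            exons = _split_exons(length, n_exons, start, rng, intron_range=(300, 3500))
            span = (exons[0][0], exons[-1][1])
            if all(
                span[1] <= s or span[0] >= e for s, e, _, _ in gene_spans[chrom]
            ):
                break
        else:
            raise GenerationError(
                f"could not place coding gene {g} without overlap on {chrom}"
            )
        gid = f"GENE{g + 1:04d}"
        tid = f"MRNA{g + 1:04d}"
        gene_spans[chrom].append((span[0], span[1], strand, gid))
        seq, orf_end = _coding_sequence(rng, length, utr3_min=400)
        models.append(
            TranscriptModel(tid, gid, chrom, strand, exons, class_code="=", sequence=seq)
        )
        seqs[tid] = seq
        orf_ends[tid] = orf_end

    # lncRNAs per class code
    counter = 0
    for code in sorted(spec.n_lncrna_by_code):
        for _ in range(spec.n_lncrna_by_code[code]):
            counter += 1
            tid = f"LNC{counter:04d}"
            length = _draw_lnc_length(spec, rng)
            n_exons = int(
                rng.choice(
                    sorted(spec.lnc_exon_probs),
                    p=[spec.lnc_exon_probs[k] for k in sorted(spec.lnc_exon_probs)],
                )
            )
            model = _place_lncrna(
                spec, rng, tid, code, length, n_exons, gene_spans, chroms, models
            )
            seq = _random_seq(rng, length, spec.gc_content)
            seq = _break_long_orfs(seq, max_codons=100, rng=rng)
            model.sequence = seq
            models.append(model)
            seqs[tid] = seq
    return models, seqs, orf_ends


def _place_lncrna(
    spec: SimulationSpec,
    rng: np.random.Generator,
    tid: str,
    code: str,
    length: int,
    n_exons: int,
    gene_spans: dict[str, list[tuple[int, int, str, str]]],
    chroms: list[str],
    models: list[TranscriptModel],
) -> TranscriptModel:
    gene_models = {m.transcript_id: m for m in models if m.class_code == "="}
    for _ in range(spec.max_placement_retries):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        spans = gene_spans[chrom]
        if code == "u":
            start = int(rng.integers(0, spec.chrom_length - length - 2500))
            exons = _split_exons(length, n_exons, start, rng)
            span = (exons[0][0], exons[-1][1])
            if any(span[1] > s and span[0] < e for s, e, _, _ in spans):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            return TranscriptModel(tid, tid, chrom, strand, exons, class_code=code)
        if not spans:
            continue
        s, e, gstrand, gid = spans[int(rng.integers(0, len(spans)))]
        if code == "x":
            # overlap the gene on the opposite strand
            start = int(rng.integers(max(0, s - length // 2), e - 50))
            strand = "-" if gstrand == "+" else "+"
        elif code in ("o", "e"):
            # partial same-strand overlap across the gene boundary
            start = max(0, s - length // 2)
            strand = gstrand
        elif code == "i":
            # fully inside an intron of the host gene, same strand
            host = next(
                (m for m in gene_models.values() if m.gene_id == gid), None
            )
            if host is None or host.n_exons < 2:
                continue
            introns = [
                (host.exons[k][1], host.exons[k + 1][0])
                for k in range(host.n_exons - 1)
            ]
            i0, i1 = max(introns, key=lambda iv: iv[1] - iv[0])
            footprint = length + 60 * (n_exons - 1)
            if i1 - i0 - 10 < footprint:
                continue
            start = int(rng.integers(i0 + 5, i1 - footprint - 4))
            exons = [(start, start + length)] if n_exons == 1 else _split_exons(
                length, n_exons, start, rng, intron_range=(40, 60)
            )
            if exons[-1][1] >= i1:
                continue
            return TranscriptModel(tid, tid, host.chrom, host.strand, exons, class_code=code)
        else:
            raise ValidationError(f"unsupported planted class code {code!r}")
        exons = _split_exons(length, n_exons, start, rng)
        span = (exons[0][0], exons[-1][1])
        if span[1] > spec.chrom_length:
            continue
        if not (span[1] > s and span[0] < e):  # must actually overlap the gene
            continue
        return TranscriptModel(tid, tid, chrom, strand, exons, class_code=code)
    raise GenerationError(f"could not place lncRNA {tid} (class {code!r})")


# ---------------------------------------------------------------------------
# miRNAs and planted sites


def simulate_mirnas(spec: SimulationSpec, rng: np.random.Generator) -> dict[str, str]:
    """Synthetic miRNA catalog (DNA letters internally; exported as RNA)."""
    return {
        f"ath-miR{150 + i}-like": _random_seq(rng, spec.mirna_length, 0.5)
        for i in range(spec.n_mirnas)
    }


def _plant_window(
    seqs: dict[str, str],
    occupied: dict[str, list[tuple[int, int]]],
    mol_id: str,
    site: str,
    lo: int,
    hi: int,
    rng: np.random.Generator,
    retries: int,
) -> tuple[int, int]:
    """Overwrite a free window of seqs[mol_id][lo:hi] with `site`."""
    n = len(site)
    if hi - lo < n:
        raise GenerationError(
            f"{mol_id}: region [{lo},{hi}) too short for a {n}-nt site"
        )
    taken = sorted(occupied.setdefault(mol_id, []))
    # enumerate free gaps and every feasible start within them
    feasible: list[int] = []
    cursor = lo
    for s, e in taken + [(hi, hi)]:
        gap_hi = min(s, hi)
        if gap_hi - cursor >= n:
            feasible.extend(range(cursor, gap_hi - n + 1))
        cursor = max(cursor, e)
    if not feasible:
        raise GenerationError(f"{mol_id}: no free window for planted site")
    start = int(rng.choice(feasible))
    end = start + n
    seqs[mol_id] = seqs[mol_id][:start] + site + seqs[mol_id][end:]
    occupied[mol_id].append((start, end))
    return start, end


def plant_mres(
    spec: SimulationSpec,
    seqs: dict[str, str],
    mirnas: dict[str, str],
    lnc_hosts: list[str],
    mrna_hosts: list[str],
    orf_ends: dict[str, int],
    rng: np.random.Generator,
    triplet_lncs: list[str],
    triplet_mrnas: list[str],
    decoy_lncs: list[str],
    decoy_mrnas: list[str],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Plant trans-complementarity segments, free-standing MREs, and the
    ceRNA triplet/decoy site sets.

    Triplet hosts receive mimic sites (lncRNA side) and cleavage sites (mRNA
    side) for `triplet_shared_mirnas` common miRNAs; decoy pairs share only
    `decoy_shared_mirnas`. Returns (MRE truth, triplet truth, trans truth).
    """
    occupied: dict[str, list[tuple[int, int]]] = {}
    mir_ids = sorted(mirnas)
    mre_rows: list[tuple[str, str, int, int, str]] = []
    trip_rows: list[tuple[str, str, str, bool]] = []
    trans_rows: list[tuple[str, str, int, int]] = []
    retries = spec.max_placement_retries

    # trans-target pairs first (they need the longest contiguous windows):
    # a DE lncRNA receives the reverse complement of an mRNA segment so
    # sequence-based trans prediction has planted positives
    for i in range(spec.n_trans_pairs):
        lnc = triplet_lncs[i % len(triplet_lncs)]
        mrna = mrna_hosts[-(i % len(mrna_hosts)) - 1]
        seg_len = min(spec.trans_segment_nt, len(seqs[lnc]) - 40)
        # draw the source 5' of the mRNA ORF end so later MRE planting
        # (confined to the 3' region) cannot erode the complementarity
        src_hi = min(orf_ends.get(mrna, len(seqs[mrna])), len(seqs[mrna]) - seg_len)
        src = int(rng.integers(0, src_hi + 1))
        segment = revcomp(seqs[mrna][src : src + seg_len])
        start, end = _plant_window(
            seqs, occupied, lnc, segment, 0, len(seqs[lnc]), rng, retries
        )
        trans_rows.append((lnc, mrna, start, end))

    def plant(mol: str, mir_id: str, kind: str) -> None:
        site = (
            make_cleavage_site(mirnas[mir_id])
            if kind == "cleavage_target"
            else make_mimic_site(mirnas[mir_id], rng)
        )
        lo = orf_ends.get(mol, 0)
        start, end = _plant_window(
            seqs, occupied, mol, site, lo, len(seqs[mol]), rng, retries
        )
        mre_rows.append((mol, mir_id, start, end, kind))

    # ceRNA triplets: one distinct miRNA block per triplet
    needed = spec.n_triplets * spec.triplet_shared_mirnas
    if needed > len(mir_ids):
        raise GenerationError(
            f"triplets need {needed} distinct miRNAs, catalog has {len(mir_ids)}"
        )
    for t in range(spec.n_triplets):
        lnc, mrna = triplet_lncs[t], triplet_mrnas[t]
        block = mir_ids[
            t * spec.triplet_shared_mirnas : (t + 1) * spec.triplet_shared_mirnas
        ]
        for mir_id in block:
            plant(lnc, mir_id, "mimic")
            plant(mrna, mir_id, "cleavage_target")
        trip_rows.append((lnc, mrna, ",".join(block), False))

    # decoys share too few miRNAs to survive the network filter
    for d in range(spec.n_decoys):
        lnc, mrna = decoy_lncs[d], decoy_mrnas[d]
        block = [mir_ids[(d + i) % len(mir_ids)] for i in range(spec.decoy_shared_mirnas)]
        for mir_id in block:
            plant(lnc, mir_id, "mimic")
            plant(mrna, mir_id, "cleavage_target")
        trip_rows.append((lnc, mrna, ",".join(sorted(block)), True))

    # free-standing sites
    for i in range(spec.n_free_mimic_sites):
        plant(lnc_hosts[i % len(lnc_hosts)], mir_ids[int(rng.integers(len(mir_ids)))], "mimic")
    for i in range(spec.n_free_cleavage_sites):
        plant(mrna_hosts[i % len(mrna_hosts)], mir_ids[int(rng.integers(len(mir_ids)))], "cleavage_target")

    # planting may have opened a long ORF in a lncRNA: repair around the sites
    for mol in sorted(set(r[0] for r in mre_rows)):
        if mol.startswith("LNC"):
            seqs[mol] = _break_long_orfs(
                seqs[mol], 100, rng, protected=occupied.get(mol, [])
            )
    mres = pd.DataFrame(
        mre_rows, columns=["molecule_id", "mirna_id", "start", "end", "kind"]
    )
    triplets = pd.DataFrame(
        trip_rows, columns=["lncrna_id", "mrna_id", "shared_mirnas", "is_decoy"]
    )
    trans = pd.DataFrame(
        trans_rows, columns=["lncrna_id", "mrna_id", "lnc_start", "lnc_end"]
    )
    return mres, triplets, trans


# ---------------------------------------------------------------------------
# counts


def simulate_counts(
    spec: SimulationSpec,
    models: list[TranscriptModel],
    de_truth: pd.DataFrame,
    silent_ids: set[str],
    rng: np.random.Generator,
) -> ExpressionMatrix:
    """NB counts for the CK/DR design with planted group effects.

    counts(f, j) ~ NB(mean mu_f(group_j) * s_j, dispersion alpha) with
    Var = mu + alpha * mu^2; planted features have DR mean mu * 2^log2FC.
    """
    if spec.nb_dispersion <= 0:
        raise ValidationError("dispersion must be positive")
    ids = [m.transcript_id for m in models]
    lfc = de_truth.set_index("feature_id")["log2fc"] if len(de_truth) else pd.Series(dtype=float)
    base = np.exp(rng.normal(spec.base_mean_log, spec.base_mean_sigma, size=len(ids)))
    base = np.clip(base, 5.0, 2000.0)
    lo, hi = spec.de_base_mean_range
    for i, tid in enumerate(ids):
        if tid in lfc.index:
            base[i] = rng.uniform(lo, hi)
        if tid in silent_ids:
            base[i] = 0.01
    n_rep = spec.n_samples_per_group
    samples = [f"CK{j + 1}" for j in range(n_rep)] + [f"DR{j + 1}" for j in range(n_rep)]
    s = np.exp(rng.normal(0.0, spec.size_factor_sigma, size=2 * n_rep))
    alpha = spec.nb_dispersion
    mat = np.zeros((len(ids), 2 * n_rep), dtype=np.int64)
    for i, tid in enumerate(ids):
        mu_ck = base[i]
        mu_dr = base[i] * 2.0 ** float(lfc.get(tid, 0.0))
        mus = np.array([mu_ck] * n_rep + [mu_dr] * n_rep) * s
        r = 1.0 / alpha
        p = r / (r + np.maximum(mus, 1e-9))
        mat[i] = rng.negative_binomial(r, p)
    df = pd.DataFrame(mat, index=ids, columns=samples)
    groups = {c: ("CK" if c.startswith("CK") else "DR") for c in samples}
    return ExpressionMatrix(values=df, groups=groups, units="counts")


# ---------------------------------------------------------------------------
# terms


def simulate_terms(
    spec: SimulationSpec,
    models: list[TranscriptModel],
    de_lnc_ids: list[str],
    rng: np.random.Generator,
) -> dict[str, set[str]]:
    """Random term->gene map with one term enriched near planted DE lncRNAs.

    Genes within the cis window of a planted DE lncRNA preferentially carry
    TERM_drought, so target-set enrichment has signal to find.
    """
    genes = [m for m in models if m.class_code == "="]
    de_spans = {
        (m.chrom, m.span) for m in models if m.transcript_id in set(de_lnc_ids)
    }
    term_map: dict[str, set[str]] = {
        f"TERM{i + 1:02d}": set() for i in range(spec.n_terms)
    }
    term_map["TERM_drought"] = set()
    names = sorted(term_map)
    for g in genes:
        near_de = any(
            chrom == g.chrom
            and max(0, max(span[0], g.span[0]) - min(span[1], g.span[1])) <= 100_000
            for chrom, span in de_spans
        )
        if near_de and rng.random() < 0.8:
            term_map["TERM_drought"].add(g.gene_id)
        elif rng.random() < 0.05:
            term_map["TERM_drought"].add(g.gene_id)
        for t in rng.choice(
            [n for n in names if n != "TERM_drought"],
            size=int(rng.integers(1, 4)),
            replace=False,
        ):
            term_map[t].add(g.gene_id)
    return {t: s for t, s in term_map.items() if s}


# ---------------------------------------------------------------------------
# top-level


def _assign_de(
    spec: SimulationSpec,
    models: list[TranscriptModel],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, list[str], list[str], list[str], list[str]]:
    """Choose planted DE features and the triplet/decoy hosts among them."""
    lnc_ok = [
        m.transcript_id
        for m in models
        if m.class_code != "=" and m.n_exons >= 2 and m.spliced_length >= 400
    ]
    mrna_ids = [m.transcript_id for m in models if m.class_code == "="]
    rows = []
    lnc_pool = list(lnc_ok)
    rng.shuffle(lnc_pool)
    mrna_pool = list(mrna_ids)
    rng.shuffle(mrna_pool)
    for plan, pool, kind in (
        (spec.lnc_de_plan, lnc_pool, "lncRNA"),
        (spec.mrna_de_plan, mrna_pool, "mRNA"),
    ):
        need = sum(plan.values())
        if need > len(pool):
            raise GenerationError(
                f"DE plan needs {need} {kind} features, only {len(pool)} available"
            )
        it = iter(pool)
        for lfc_value in sorted(plan, key=lambda v: (-abs(v), v)):
            for _ in range(plan[lfc_value]):
                rows.append((next(it), kind, float(lfc_value)))
    de = pd.DataFrame(rows, columns=["feature_id", "kind", "log2fc"])
    up4_lnc = de[(de.kind == "lncRNA") & (de.log2fc == 4.0)].feature_id.tolist()
    up4_mrna = de[(de.kind == "mRNA") & (de.log2fc == 4.0)].feature_id.tolist()
    if len(up4_lnc) < spec.n_triplets or len(up4_mrna) < spec.n_triplets:
        raise GenerationError("not enough +4 planted features to host triplets")
    triplet_lncs = up4_lnc[: spec.n_triplets]
    triplet_mrnas = up4_mrna[: spec.n_triplets]
    other_lnc = [f for f in de[de.kind == "lncRNA"].feature_id if f not in triplet_lncs]
    other_mrna = [f for f in de[de.kind == "mRNA"].feature_id if f not in triplet_mrnas]
    decoy_lncs = (other_lnc * 3)[: spec.n_decoys]
    decoy_mrnas = (other_mrna * 3)[: spec.n_decoys]
    return de, triplet_lncs, triplet_mrnas, decoy_lncs, decoy_mrnas


def simulate_dataset(spec: SimulationSpec | None = None) -> SimulatedDataset:
    """Generate the full miniature dataset with ground truth."""
    spec = spec or SimulationSpec()
    rng = np.random.default_rng(spec.rng_seed)
    models, seqs, orf_ends = simulate_annotation(spec, rng)
    mirnas = simulate_mirnas(spec, rng)
    de, trip_lncs, trip_mrnas, decoy_lncs, decoy_mrnas = _assign_de(spec, models, rng)

    lnc_ids = [m.transcript_id for m in models if m.class_code != "="]
    mrna_ids = [m.transcript_id for m in models if m.class_code == "="]
    de_ids = set(de.feature_id)
    by_id = {m.transcript_id: m for m in models}
    # free-site hosts must survive the structural screen, otherwise the
    # planted site sits on a molecule the analysis never scans
    free_lnc_hosts = [
        t
        for t in lnc_ids
        if t not in de_ids
        and by_id[t].n_exons >= 2
        and by_id[t].spliced_length >= 240
    ] or lnc_ids
    free_mrna_hosts = [t for t in mrna_ids if t not in de_ids] or mrna_ids
    mres, triplets, trans = plant_mres(
        spec, seqs, mirnas, free_lnc_hosts, free_mrna_hosts, orf_ends, rng,
        trip_lncs, trip_mrnas, decoy_lncs, decoy_mrnas,
    )
    for m in models:  # sync planted sequences back onto the models
        m.sequence = seqs[m.transcript_id]

    non_de_lnc = [t for t in lnc_ids if t not in de_ids and t not in set(mres.molecule_id)]
    silent = set(non_de_lnc[: spec.n_silent_lncrna])
    counts = simulate_counts(spec, models, de, silent, rng)
    de_lnc_ids = de[de.kind == "lncRNA"].feature_id.tolist()
    term_map = simulate_terms(spec, models, de_lnc_ids, rng)

    by_id = {m.transcript_id: m for m in models}
    lnc_truth = pd.DataFrame(
        {
            "transcript_id": lnc_ids,
            "class_code": [by_id[t].class_code for t in lnc_ids],
            "length_nt": [by_id[t].spliced_length for t in lnc_ids],
            "n_exons": [by_id[t].n_exons for t in lnc_ids],
            "is_silent": [t in silent for t in lnc_ids],
            "expected_detectable": [
                by_id[t].n_exons >= 2
                and by_id[t].spliced_length >= 200
                and t not in silent
                for t in lnc_ids
            ],
        }
    )
    truth = GroundTruth(lncrnas=lnc_truth, de=de, mres=mres, triplets=triplets, trans=trans)
    return SimulatedDataset(spec, models, seqs, mirnas, counts, term_map, truth)


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> None:
    """Emit GTF, FASTA, counts TSV, term map and the truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lio.write_gtf(ds.models, outdir / "transcripts.gtf")
    lio.write_fasta(ds.sequences, outdir / "transcripts.fa")
    # miRNA catalogs are RNA: export with U
    lio.write_fasta(
        {k: v.replace("T", "U") for k, v in sorted(ds.mirnas.items())},
        outdir / "mirnas.fa",
    )
    counts_df = ds.counts.values.copy()
    counts_df.insert(0, "feature_id", counts_df.index)
    lio.write_table(counts_df, outdir / "counts.tsv")
    groups = pd.DataFrame(
        sorted(ds.counts.groups.items()), columns=["sample", "group"]
    )
    groups.to_csv(outdir / "groups.tsv", sep="\t", index=False, header=False)
    terms = pd.DataFrame(
        [(t, g) for t in sorted(ds.term_map) for g in sorted(ds.term_map[t])],
        columns=["term", "gene"],
    )
    terms.to_csv(outdir / "terms.tsv", sep="\t", index=False, header=False)
    lio.write_table(ds.truth.lncrnas, outdir / "truth_lncrnas.tsv")
    lio.write_table(ds.truth.de, outdir / "truth_de.tsv")
    lio.write_table(ds.truth.mres, outdir / "truth_mres.tsv")
    lio.write_table(ds.truth.triplets, outdir / "truth_triplets.tsv")
    lio.write_table(ds.truth.trans, outdir / "truth_trans.tsv")


def audit_ground_truth(ds: SimulatedDataset) -> None:
    """Verify every truth record against the emitted data (self-consistency).

    Raises ValidationError on the first inconsistency.
    """
    from .mimicry import classify_window  # local import to avoid cycle

    by_id = {m.transcript_id: m for m in ds.models}
    for _, row in ds.truth.lncrnas.iterrows():
        m = by_id.get(row.transcript_id)
        if m is None or m.class_code != row.class_code:
            raise ValidationError(f"truth lncRNA {row.transcript_id} mismatch")
    for _, row in ds.truth.mres.iterrows():
        seq = ds.sequences[row.molecule_id]
        window = seq[row.start : row.end]
        mir = ds.mirnas[row.mirna_id]
        if classify_window(window, mir)[0] != row.kind:
            raise ValidationError(
                f"planted {row.kind} site on {row.molecule_id} does not "
                f"classify as planted"
            )
    lnc_mirs: dict[str, set[str]] = {}
    for _, row in ds.truth.mres.iterrows():
        lnc_mirs.setdefault(row.molecule_id, set()).add(row.mirna_id)
    for _, row in ds.truth.triplets.iterrows():
        shared = set(row.shared_mirnas.split(","))
        if not shared <= lnc_mirs.get(row.lncrna_id, set()):
            raise ValidationError(f"triplet {row.lncrna_id} misses planted miRNAs")
        if not shared <= lnc_mirs.get(row.mrna_id, set()):
            raise ValidationError(f"triplet {row.mrna_id} misses planted miRNAs")
    for _, row in ds.truth.trans.iterrows():
        segment = ds.sequences[row.lncrna_id][row.lnc_start : row.lnc_end]
        if revcomp(segment) not in ds.sequences[row.mrna_id]:
            raise ValidationError(
                f"planted trans segment {row.lncrna_id}->{row.mrna_id} is not "
                f"complementary to the mRNA"
            )
    for fid in ds.truth.de.feature_id:
        if fid not in ds.counts.values.index:
            raise ValidationError(f"DE truth feature {fid} missing from counts")
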