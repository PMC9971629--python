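"""cis- and trans-target prediction for lncRNAs.

cis targets are protein-coding genes whose genomic span lies within a fixed
window (default 100 kb) of the lncRNA span on the same chromosome, strand
agnostic; overlapping spans have distance 0 and the window boundary is
inclusive ("within 100 kb").

trans targets are called from sequence alone with a simplified additive
duplex energy model: the two molecules are paired antiparallel at every
offset, per-position energies are G:C -3, A:T -2, G:T (wobble) -1, mismatch
+2, and the best fixed-length pairing window (min(len_a, len_b, 100) nt) is
normalised by its length to give ndG. A pair is a trans target when
ndG <= trans_ndg_cutoff (default -1.0 on this scale, calibrated so perfect
>= 20-mer complements always pass while random kilobase pairs essentially
never do).
"""

from __future__ import annotations

import numpy as np

from .config import RunConfig
from .types import TargetPair, TranscriptModel, ValidationError

# pair energy lookup, indexed by (base_a, base_b) codes; N never pairs
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_ENERGY = np.full((5, 5), 2.0)
for a, b, e in [
    ("G", "C", -3.0),
    ("C", "G", -3.0),
    ("A", "T", -2.0),
    ("T", "A", -2.0),
    ("G", "T", -1.0),
    ("T", "G", -1.0),
]:
    _ENERGY[_CODE[a], _CODE[b]] = e


def encode(seq: str) -> np.ndarray:
    try:
        return np.array([_CODE[c] for c in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValidationError(f"non-nucleotide character {exc} in sequence") from exc


def span_distance(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Gap between two half-open genomic spans; 0 when they overlap."""
    return max(0, max(a[0], b[0]) - min(a[1], b[1]))


def cis_targets(
    lncrnas: list[TranscriptModel],
    genes: list[TranscriptModel],
    window: int | None = None,
    config: RunConfig | None = None,
) -> list[TargetPair]:
    """All (lncRNA, gene) pairs within ``window`` bp on the same chromosome.

    One pair per (lncRNA, gene_id); when a gene has several transcript
    models the smallest distance wins.
    """
    if window is None:
        window = (config or RunConfig()).cis_window_bp
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    pairs: dict[tuple[str, str], int] = {}
    for ln in lncrnas:
        for g in by_chrom.get(ln.chrom, []):
            if g.gene_id == ln.gene_id:
                continue
            d = span_distance(ln.span, g.span)
            if d <= window:
                key = (ln.transcript_id, g.gene_id)
                if key not in pairs or d < pairs[key]:
                    pairs[key] = d
    return [
        TargetPair(lncrna_id=l, gene_id=g, mode="cis", distance_bp=d)
        for (l, g), d in sorted(pairs.items())
    ]


def duplex_ndg(seq_a: str, seq_b: str, max_window: int = 100) -> tuple[float, tuple[int, int]]:
    """Best normalised duplex energy between two sequences and the pairing
    site on ``seq_b`` (0-based half-open, in seq_b coordinates).

    ``seq_a`` is slid along the reverse complement of ``seq_b`` (antiparallel
    pairing); the score is the minimum sum of per-position energies over all
    contiguous windows of length w = min(len_a, len_b, max_window), divided
    by w. Symmetric in its two arguments.
    """
    if len(seq_a) < 20 or len(seq_b) < 20:
        raise ValidationError("sequences must be >= 20 nt for trans scoring")
    a = encode(seq_a)
    # pairing a[i] with b[j] antiparallel = comparing a to reversed b, with
    # the pair energy table handling complementarity directly
    b_rev = encode(seq_b)[::-1]
    w = min(len(a), len(b_rev), max_window)
    best, js = _best_window(a, b_rev, _ENERGY, w)
    best_site = (len(b_rev) - js - w, len(b_rev) - js)
    return best / w, best_site


def _best_window_py(
    a: np.ndarray, b_rev: np.ndarray, energy: np.ndarray, w: int
) -> tuple[float, int]:
    """Minimum length-w diagonal window sum over all ungapped antiparallel
    alignments; returns (sum, window start in b_rev coordinates)."""
    la, lb = len(a), len(b_rev)
    best = np.inf
    best_j = 0
    for o in range(-(la - w), lb - w + 1):
        i0 = max(0, -o)
        i1 = min(la, lb - o)
        if i1 - i0 < w:
            continue
        run = 0.0
        for i in range(i0, i0 + w):
            run += energy[a[i], b_rev[i + o]]
        if run < best:
            best, best_j = run, i0 + o
        for i in range(i0 + w, i1):
            run += energy[a[i], b_rev[i + o]] - energy[a[i - w], b_rev[i - w + o]]
            if run < best:
                best, best_j = run, i - w + 1 + o
    return float(best), best_j


try:  # jit-compiled rolling scan; the pure-python kernel is the fallback
    from numba import njit

    _best_window = njit(cache=False)(_best_window_py)
except ImportError:  # pragma: no cover
    _best_window = _best_window_py


def trans_targets(
    lnc_seqs: dict[str, str],
    mrna_seqs: dict[str, str],
    config: RunConfig | None = None,
) -> list[TargetPair]:
    """Trans-target pairs with ndG <= trans_ndg_cutoff."""
    config = config or RunConfig()
    out: list[TargetPair] = []
    for lnc_id in sorted(lnc_seqs):
        for mrna_id in sorted(mrna_seqs):
            ndg, site = duplex_ndg(
                lnc_seqs[lnc_id], mrna_seqs[mrna_id], config.trans_max_window
            )
            if ndg <= config.trans_ndg_cutoff:
                out.append(
                    TargetPair(
                        lncrna_id=lnc_id,
                        gene_id=mrna_id,
                        mode="trans",
                        ndg=ndg,
                        site=site,
                    )
                )
    return out
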