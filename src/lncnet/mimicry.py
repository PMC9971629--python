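"""miRNA response element (MRE) detection and endogenous target-mimic calls.

Sites are scored with a plant-style penalty model: the target window is
aligned antiparallel to the miRNA allowing target-side insertions, with
penalties mismatch 1.0, G:U wobble 0.5 and insertion 1.0 per nt, all doubled
opposite miRNA positions 2-13 (the functionally critical 5' region). miRNA
positions are numbered 1..n from the miRNA 5' end, so position 1 pairs with
the 3'-most base of the target site.

An endogenous target mimic (eTM) carries a 3-nt target-side bulge opposite
miRNA positions 9-11 — it binds the miRNA but places the slicing site across
an unpairable loop — while pairing essentially perfectly elsewhere. Mimic
classification therefore asks whether the window aligns well under a FORCED
canonical bulge (a constrained alignment with exactly 3 insertions opposite
positions 9-11): the site is a "mimic" when that alignment has no mismatch
opposite positions 2-8 and a non-bulge penalty <= mimic_non_bulge_max, and a
"cleavage_target" otherwise. When a bulged site is tested against the
reporting cutoff the bulge's own insertion penalty is waived, since the
bulge is the defining feature of a mimic rather than a defect.
"""

from __future__ import annotations

import numpy as np

from .config import RunConfig
from .types import MRESite, ValidationError

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_WOBBLE = {("G", "T"), ("T", "G")}  # target base, miRNA base (U stored as T)

MAX_INSERTIONS = 5
CRITICAL_REGION = (2, 13)  # penalties doubled opposite these miRNA positions
BULGE_POSITIONS = (9, 10, 11)  # forced-bulge insertions sit before these
BULGE_LEN = 3
BULGE_PENALTY = 6.0  # 3 insertions x 1.0, doubled inside the critical region
SEED_REGION = (2, 8)  # no mismatch allowed here for a mimic


def _pair_penalty(t: str, m: str, pos: int) -> float:
    """Penalty for target base t opposite miRNA base m at miRNA position pos."""
    if t == _COMP[m] and t != "N":
        return 0.0
    w = 2.0 if CRITICAL_REGION[0] <= pos <= CRITICAL_REGION[1] else 1.0
    return (0.5 if (t, m) in _WOBBLE else 1.0) * w


def _insertion_penalty(next_pos: int) -> float:
    """Penalty for one inserted target base before miRNA position next_pos."""
    w = 2.0 if CRITICAL_REGION[0] <= next_pos <= CRITICAL_REGION[1] else 1.0
    return 1.0 * w


class _Alignment:
    """DP result: total penalty plus per-column structure."""

    __slots__ = ("score", "columns", "consumed", "mirna")

    def __init__(
        self, score: float, columns: list[tuple[str | None, int | None]], mirna: str
    ):
        self.score = score
        self.columns = columns  # (target base, miRNA pos or None=insertion)
        self.consumed = sum(1 for t, _ in columns if t is not None)
        self.mirna = mirna

    def insertion_runs(self) -> list[tuple[int, int]]:
        """(miRNA position preceding the run, run length) per insertion run."""
        runs = []
        last_pos = 0
        i = 0
        cols = self.columns
        while i < len(cols):
            if cols[i][1] is None:
                j = i
                while j < len(cols) and cols[j][1] is None:
                    j += 1
                runs.append((last_pos, j - i))
                i = j
            else:
                last_pos = cols[i][1]
                i += 1
        return runs

    def mismatch_positions(self) -> list[int]:
        """miRNA positions paired with a non-complementary, non-wobble base."""
        out = []
        for t, pos in self.columns:
            if t is None or pos is None:
                continue
            m = self.mirna[pos - 1]
            if (t != _COMP[m] or t == "N") and (t, m) not in _WOBBLE:
                out.append(pos)
        return out


def _align(
    rev_window: str, mirna: str, require_full: bool, forced_bulge: bool = False
) -> _Alignment | None:
    """Anchored DP aligning rev_window (target read 3'->5') to the miRNA
    5'->3', target-side insertions only.

    ``require_full`` forces every target base to be consumed (scoring a fixed
    window); otherwise the best prefix consuming the whole miRNA wins.
    ``forced_bulge`` restricts insertions to exactly BULGE_LEN, all opposite
    BULGE_POSITIONS; returns None when that is infeasible for this window.
    """
    L, n = len(rev_window), len(mirna)
    INF = float("inf")
    dp = np.full((L + 1, n + 1), INF)
    dp[0, 0] = 0.0
    back = np.zeros((L + 1, n + 1), dtype=np.int8)  # 1=align, 2=insert
    max_ins = BULGE_LEN if forced_bulge else MAX_INSERTIONS
    for i in range(L + 1):
        for j in range(n + 1):
            cur = dp[i, j]
            if cur == INF:
                continue
            if i < L and j < n:
                c = cur + _pair_penalty(rev_window[i], mirna[j], j + 1)
                if c < dp[i + 1, j + 1]:
                    dp[i + 1, j + 1] = c
                    back[i + 1, j + 1] = 1
            if i < L and (i - j) < max_ins:
                if forced_bulge and (j + 1) not in BULGE_POSITIONS:
                    continue
                c = cur + _insertion_penalty(j + 1)
                if c < dp[i + 1, j]:
                    dp[i + 1, j] = c
                    back[i + 1, j] = 2
    if require_full:
        candidates = [L] if not forced_bulge else ([L] if L == n + BULGE_LEN else [])
    else:
        lo = n + BULGE_LEN if forced_bulge else n
        hi = n + (BULGE_LEN if forced_bulge else MAX_INSERTIONS)
        candidates = list(range(lo, min(L, hi) + 1))
    candidates = [i for i in candidates if dp[i, n] < INF]
    if not candidates:
        if forced_bulge:
            return None
        raise ValidationError("window cannot be aligned within insertion budget")
    end_i = min(candidates, key=lambda i: (dp[i, n], i))
    cols: list[tuple[str | None, int | None]] = []
    i, j = end_i, n
    while i > 0 or j > 0:
        if back[i, j] == 1:
            cols.append((rev_window[i - 1], j))
            i, j = i - 1, j - 1
        else:
            cols.append((rev_window[i - 1], None))
            i = i - 1
    cols.reverse()
    return _Alignment(float(dp[end_i, n]), cols, mirna)


def _alignment_strings(aln: _Alignment) -> tuple[str, str, str]:
    """(target 3'->5', pairing row, miRNA 5'->3'); '|' pair, 'o' wobble,
    '.' mismatch, '-' gap."""
    top, mid, bot = [], [], []
    for t, pos in aln.columns:
        if pos is None:
            top.append(t)
            mid.append(" ")
            bot.append("-")
        else:
            m = aln.mirna[pos - 1]
            top.append(t)
            bot.append(m)
            if t == _COMP[m] and t != "N":
                mid.append("|")
            elif (t, m) in _WOBBLE:
                mid.append("o")
            else:
                mid.append(".")
    return "".join(top), "".join(mid), "".join(bot)


def _norm(seq: str) -> str:
    return seq.upper().replace("U", "T")


def score_site(target_window: str, mirna_seq: str) -> tuple[float, tuple[str, str, str]]:
    """Penalty score and alignment for one target window vs one miRNA.

    The window is given 5'->3' in transcript coordinates and must be between
    len(miRNA) and len(miRNA)+5 nt long.
    """
    target_window = _norm(target_window)
    mirna_seq = _norm(mirna_seq)
    n = len(mirna_seq)
    if not (n <= len(target_window) <= n + MAX_INSERTIONS):
        raise ValidationError(
            f"window length {len(target_window)} outside [{n}, {n + MAX_INSERTIONS}]"
        )
    aln = _align(target_window[::-1], mirna_seq, require_full=True)
    return aln.score, _alignment_strings(aln)


def classify_window(
    target_window: str, mirna_seq: str, config: RunConfig | None = None
) -> tuple[str, float]:
    """Classify a site window as "mimic" or "cleavage_target".

    Returns (kind, non-bulge penalty of the forced-bulge alignment; inf when
    no such alignment exists, e.g. for a perfect-length cleavage window).
    """
    config = config or RunConfig()
    target_window = _norm(target_window)
    mirna_seq = _norm(mirna_seq)
    aln = _align(target_window[::-1], mirna_seq, require_full=True, forced_bulge=True)
    if aln is None:
        return "cleavage_target", float("inf")
    non_bulge = aln.score - BULGE_PENALTY
    if non_bulge > config.mimic_non_bulge_max:
        return "cleavage_target", non_bulge
    if any(SEED_REGION[0] <= p <= SEED_REGION[1] for p in aln.mismatch_positions()):
        return "cleavage_target", non_bulge
    return "mimic", non_bulge


def classify_site(site: MRESite, config: RunConfig | None = None) -> str:
    """Re-derive the kind of a reported site from its window coordinates."""
    return classify_window(site.alignment[0][::-1], site.alignment[2].replace("-", ""), config)[0]


# ---------------------------------------------------------------------------
# Genome-wide scan


_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMP_CODE = np.array([3, 2, 1, 0, 5], dtype=np.int8)  # N complements nothing


def _candidate_starts(rev_codes: np.ndarray, comp_codes: np.ndarray) -> np.ndarray:
    """Positions in the reversed transcript worth full alignment, found by
    counting non-complementary positions under ungapped and 3-nt-bulged
    templates (generous bound: a reportable site has few defects)."""
    n = len(comp_codes)
    L = len(rev_codes)
    if L < n:
        return np.empty(0, dtype=int)
    win = np.lib.stride_tricks.sliding_window_view(rev_codes, n)
    mism = (win != comp_codes).sum(axis=1)
    cand = mism <= 8
    for j in (p - 1 for p in BULGE_POSITIONS):
        if L < n + BULGE_LEN:
            break
        head = (
            np.lib.stride_tricks.sliding_window_view(rev_codes[: L - BULGE_LEN], j)[
                : L - n - BULGE_LEN + 1, :
            ]
            != comp_codes[:j]
        ).sum(axis=1)
        tail_view = np.lib.stride_tricks.sliding_window_view(rev_codes, n - j)
        tail = (
            tail_view[j + BULGE_LEN : j + BULGE_LEN + len(head)] != comp_codes[j:]
        ).sum(axis=1)
        m = head + tail
        cand[: len(m)] |= m <= 8
    return np.nonzero(cand)[0]


def find_mres(
    transcripts: dict[str, str],
    mirnas: dict[str, str],
    config: RunConfig | None = None,
) -> list[MRESite]:
    """Scan every transcript for reportable miRNA sites.

    A window is reported when its effective penalty <= mimic_score_cutoff,
    the effective penalty being the plain alignment score for cleavage-style
    sites and the non-bulge penalty for mimic-eligible ones. Overlapping hits
    of the same miRNA on one transcript keep only the best-scoring site.
    """
    config = config or RunConfig()
    out: list[MRESite] = []
    mirna_items = sorted((k, _norm(v)) for k, v in mirnas.items())
    for mol_id in sorted(transcripts):
        seq = _norm(transcripts[mol_id])
        rev = seq[::-1]
        rev_codes = np.array([_ENC.get(c, 4) for c in rev], dtype=np.int8)
        hits: list[MRESite] = []
        for mir_id, mir_seq in mirna_items:
            n = len(mir_seq)
            comp_codes = _COMP_CODE[
                np.array([_ENC.get(c, 4) for c in mir_seq], dtype=np.int8)
            ]
            for p in _candidate_starts(rev_codes, comp_codes):
                window = rev[p : p + n + MAX_INSERTIONS]
                if len(window) < n:
                    continue
                aln = _align(window, mir_seq, require_full=False)
                bulge_aln = (
                    _align(rev[p : p + n + BULGE_LEN], mir_seq, require_full=False, forced_bulge=True)
                    if len(rev) - p >= n + BULGE_LEN
                    else None
                )
                kind, non_bulge = "cleavage_target", float("inf")
                if bulge_aln is not None:
                    window_53 = rev[p : p + n + BULGE_LEN][::-1]
                    kind, non_bulge = classify_window(window_53, mir_seq, config)
                if kind == "mimic":
                    effective = non_bulge
                    score = non_bulge + BULGE_PENALTY
                    consumed = n + BULGE_LEN
                    rep_aln = bulge_aln
                else:
                    effective = aln.score
                    score = aln.score
                    consumed = aln.consumed
                    rep_aln = aln
                if effective > config.mimic_score_cutoff:
                    continue
                hits.append(
                    MRESite(
                        molecule_id=mol_id,
                        mirna_id=mir_id,
                        start=len(seq) - p - consumed,
                        end=len(seq) - p,
                        penalty_score=score,
                        kind=kind,
                        alignment=_alignment_strings(rep_aln),
                        non_bulge_penalty=non_bulge,
                        has_canonical_bulge=kind == "mimic",
                    )
                )
        out.extend(_dedup_overlaps(hits))
    return out


def _dedup_overlaps(hits: list[MRESite]) -> list[MRESite]:
    """Keep the best-scoring site among overlapping same-miRNA hits."""
    kept: list[MRESite] = []
    by_mirna: dict[str, list[MRESite]] = {}
    for h in hits:
        by_mirna.setdefault(h.mirna_id, []).append(h)
    for mir_id in sorted(by_mirna):
        group = sorted(
            by_mirna[mir_id],
            key=lambda h: (
                h.non_bulge_penalty if h.has_canonical_bulge else h.penalty_score,
                h.start,
            ),
        )
        chosen: list[MRESite] = []
        for h in group:
            if all(h.end <= c.start or h.start >= c.end for c in chosen):
                chosen.append(h)
        chosen.sort(key=lambda h: h.start)
        kept.extend(chosen)
    return kept
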