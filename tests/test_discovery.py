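"""Candidate screen, ORF-based coding-potential scoring, consensus and
summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lncnet import discovery
from lncnet.config import RunConfig
from lncnet.types import ExpressionMatrix, TranscriptModel, ValidationError


def _tx(tid, code="u", length=500, n_exons=2, chrom="chr1", start=1000):
    exons = []
    pos = start
    per = length // n_exons
    for i in range(n_exons):
        size = per if i < n_exons - 1 else length - per * (n_exons - 1)
        exons.append((pos, pos + size))
        pos += size + 100
    return TranscriptModel(tid, tid, chrom, "+", exons, class_code=code)


def _fpkm(values: dict[str, list[float]]) -> ExpressionMatrix:
    cols = ["CK1", "CK2", "CK3", "DR1", "DR2", "DR3"]
    df = pd.DataFrame.from_dict(values, orient="index", columns=cols)
    return ExpressionMatrix(values=df, groups={c: c[:2] for c in cols}, units="fpkm")


class TestBasicScreen:
    @pytest.mark.parametrize(
        "code,length,n_exons,fpkm_max,kept,rule",
        [
            ("u", 500, 2, 0.5, True, "retained"),
            ("=", 500, 2, 0.5, False, "class_code"),
            ("x", 150, 2, 0.5, False, "length"),
            ("u", 500, 1, 0.5, False, "exon_count"),
            ("u", 500, 2, 0.05, False, "fpkm"),
        ],
    )
    def test_each_rule(self, code, length, n_exons, fpkm_max, kept, rule):
        tx = _tx("t1", code, length, n_exons)
        fpkm = _fpkm({"t1": [fpkm_max, 0, 0, 0, 0, 0]})
        retained, log = discovery.basic_screen([tx], fpkm, RunConfig())
        assert (len(retained) == 1) == kept
        assert log.loc[0, "verdict"] == rule

    def test_exon_filter_can_be_disabled(self):
        tx = _tx("t1", "u", 500, 1)
        fpkm = _fpkm({"t1": [1, 0, 0, 0, 0, 0]})
        cfg = RunConfig(exon_filter_enabled=False)
        retained, _ = discovery.basic_screen([tx], fpkm, cfg)
        assert len(retained) == 1

    def test_missing_fpkm_feature_is_error(self):
        tx = _tx("t1")
        fpkm = _fpkm({"other": [1, 0, 0, 0, 0, 0]})
        with pytest.raises(ValidationError, match="t1"):
            discovery.basic_screen([tx], fpkm, RunConfig())

    def test_order_independence(self):
        txs = [_tx(f"t{i}", "u", 300 + i, 2, start=1000 + 5000 * i) for i in range(8)]
        fpkm = _fpkm({t.transcript_id: [1, 0, 0, 0, 0, 0] for t in txs})
        fwd, _ = discovery.basic_screen(txs, fpkm, RunConfig())
        rev, _ = discovery.basic_screen(txs[::-1], fpkm, RunConfig())
        assert {t.transcript_id for t in fwd} == {t.transcript_id for t in rev}


class TestOrfScorer:
    def test_no_atg_means_score_zero(self):
        assert discovery.longest_orf_codons("CCCCCCGGGGGG") == 0
        call = discovery.coding_potential_stub("t", "CCCCCCGGGGGG")
        assert call.is_noncoding and call.score == 0

    def test_constructed_orf_counts_codons(self):
        # ATG + 150 non-stop codons + stop: 151 codons -> coding
        rng = np.random.default_rng(1)
        codons = [
            c
            for c in ("".join(rng.choice(list("ACGT"), 3)) for _ in range(400))
            if c not in discovery.STOP_CODONS
        ][:150]
        seq = "CC" + "ATG" + "".join(codons) + "TAA" + "GG"
        assert discovery.longest_orf_codons(seq) == 151
        assert not discovery.coding_potential_stub("t", seq).is_noncoding

    def test_orf_without_stop_does_not_count(self):
        seq = "ATG" + "AAA" * 200  # open-ended: no stop codon
        assert discovery.longest_orf_codons(seq) == 0

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_short_sequences_are_always_noncoding(self, seed):
        # ATG + 99 codons + stop needs 303 nt, so 299 nt can never reach
        # the 100-codon cutoff
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), 299))
        assert discovery.coding_potential_stub("t", seq).is_noncoding

    def test_non_nucleotide_rejected(self):
        with pytest.raises(ValidationError):
            discovery.longest_orf_codons("ACGTXZ")


class TestConsensus:
    @staticmethod
    def _calls(table: dict[str, tuple[bool, ...]], tools=("A", "B", "C")):
        return [
            discovery.CodingPotentialCall(tid, tool, flag, 0.0)
            for tid, flags in table.items()
            for tool, flag in zip(tools, flags)
        ]

    def test_intersection_rule(self):
        calls = self._calls({"t1": (True, True, True), "t2": (True, True, False)})
        retained, venn = discovery.consensus_noncoding(calls, ["A", "B", "C"])
        assert retained == {"t1"}
        assert venn[frozenset("ABC")] == 1 and venn[frozenset("AB")] == 1

    def test_venn_partition_law(self):
        rng = np.random.default_rng(5)
        table = {
            f"t{i}": tuple(bool(b) for b in rng.integers(0, 2, 3)) for i in range(200)
        }
        calls = self._calls(table)
        _, venn = discovery.consensus_noncoding(calls, ["A", "B", "C"])
        called_by_any = sum(1 for flags in table.values() if any(flags))
        assert sum(venn.values()) == called_by_any

    def test_adding_a_tool_never_grows_the_set(self):
        rng = np.random.default_rng(7)
        table = {
            f"t{i}": tuple(bool(b) for b in rng.integers(0, 2, 3)) for i in range(100)
        }
        calls = self._calls(table)
        two, _ = discovery.consensus_noncoding(
            [c for c in calls if c.tool_name in "AB"], ["A", "B"]
        )
        three, _ = discovery.consensus_noncoding(calls, ["A", "B", "C"])
        assert three <= two

    def test_missing_tool_call_is_error(self):
        calls = self._calls({"t1": (True, True)}, tools=("A", "B"))
        with pytest.raises(ValidationError, match="missing"):
            discovery.consensus_noncoding(calls, ["A", "B", "C"])


class TestClassification:
    @pytest.mark.parametrize(
        "code,category",
        [("u", "lincRNA"), ("x", "antisense"), ("o", "sense_overlap"),
         ("e", "sense_overlap"), ("i", "intronic")],
    )
    def test_category_map(self, code, category):
        assert discovery.classify_category(code) == category

    def test_non_lncrna_code_is_error(self):
        with pytest.raises(ValidationError):
            discovery.classify_category("=")

    def test_length_bins_with_boundary(self):
        assert discovery.length_bin(999) == "<1000"
        assert discovery.length_bin(1000) == "1000-2000"
        assert discovery.length_bin(2000) == "1000-2000"
        assert discovery.length_bin(2001) == ">2000"


class TestSummaries:
    def test_even_length_bins(self):
        recs = [
            discovery.LncRNARecord(f"t{i}", "lincRNA", length, 2, 1.0)
            for i, length in enumerate((500, 1500, 2500))
        ]
        s = discovery.summarize_lncrnas(recs)
        assert s["length_bin_proportions"].tolist() == pytest.approx([1 / 3] * 3)
        assert s["category_proportions"]["lincRNA"] == 1.0

    def test_empty_input_is_error(self):
        with pytest.raises(ValidationError):
            discovery.summarize_lncrnas([])


class TestGroupPresence:
    def test_examples_and_partition_law(self):
        fpkm = _fpkm(
            {
                "dr_only": [0, 0, 0, 1, 2, 0],
                "shared": [0.2, 0, 0, 0.2, 0, 0],
                "ck_only": [5, 5, 5, 0, 0, 0],
                "absent": [0, 0, 0, 0, 0, 0],
            }
        )
        shared, ck, dr = discovery.group_presence_venn(fpkm, RunConfig())
        assert dr == {"dr_only"} and shared == {"shared"} and ck == {"ck_only"}
        present = {
            f
            for f in fpkm.values.index
            if (fpkm.values.loc[f] >= 0.1).any()
        }
        assert shared | ck | dr == present
        assert not (shared & ck or shared & dr or ck & dr)

    def test_unknown_group_is_error(self):
        fpkm = _fpkm({"t": [1, 1, 1, 1, 1, 1]})
        with pytest.raises(ValidationError, match="XX"):
            discovery.group_presence_venn(fpkm, RunConfig(), group_a="XX")
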