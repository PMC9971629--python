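"""FPKM, size factors, NB testing, BH adjustment and DE calling rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lncnet import de as de_mod
from lncnet.config import RunConfig
from lncnet.types import ExpressionMatrix, ValidationError

COLS = ["CK1", "CK2", "CK3", "DR1", "DR2", "DR3"]


def _em(rows: dict[str, list[float]], units="counts") -> ExpressionMatrix:
    df = pd.DataFrame.from_dict(rows, orient="index", columns=COLS[: len(next(iter(rows.values())))])
    return ExpressionMatrix(values=df, groups={c: c[:2] for c in df.columns}, units=units)


def bh_bruteforce(p: np.ndarray) -> np.ndarray:
    """Literal step-up definition: q_(i) = min_{j>=i} min(1, m*p_(j)/j)."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.minimum(1.0, p[order] * m / np.arange(1, m + 1))
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    out = np.empty(m)
    out[order] = q_sorted
    return out


class TestFpkm:
    def test_definition_arithmetic(self):
        counts = _em({"f1": [100.0], "f2": [0.0], "filler": [10_000_000 - 100]})
        fpkm = de_mod.compute_fpkm(counts, {"f1": 1000, "f2": 500, "filler": 1000})
        assert fpkm.values.loc["f1", "CK1"] == pytest.approx(10.0, rel=1e-6)
        assert fpkm.values.loc["f2", "CK1"] == 0.0

    def test_scale_invariance_within_sample(self):
        rng = np.random.default_rng(0)
        base = rng.integers(1, 100, size=(5, 6)).astype(float)
        lengths = {f"f{i}": int(l) for i, l in enumerate(rng.integers(200, 3000, 5))}
        em1 = _em({f"f{i}": base[i].tolist() for i in range(5)})
        doubled = base.copy()
        doubled[:, 0] *= 2  # double every count in sample CK1
        em2 = _em({f"f{i}": doubled[i].tolist() for i in range(5)})
        f1 = de_mod.compute_fpkm(em1, lengths)
        f2 = de_mod.compute_fpkm(em2, lengths)
        np.testing.assert_allclose(
            f1.values["CK1"].to_numpy(), f2.values["CK1"].to_numpy(), rtol=1e-12
        )

    def test_zero_total_sample_is_error(self):
        counts = _em({"f1": [0.0, 5, 5, 5, 5, 5]})
        with pytest.raises(ValidationError, match="zero total"):
            de_mod.compute_fpkm(counts, {"f1": 1000})

    def test_zero_length_feature_is_error(self):
        counts = _em({"f1": [1.0, 1, 1, 1, 1, 1]})
        with pytest.raises(ValidationError, match="length"):
            de_mod.compute_fpkm(counts, {"f1": 0})


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = _em({"f1": [10.0] * 6, "f2": [33.0] * 6})
        s = de_mod.size_factors_median_ratio(counts)
        np.testing.assert_allclose(s.to_numpy(), np.ones(6))

    def test_doubled_sample_hand_computation(self):
        # B = 2A: geometric mean sqrt(2)*A, ratios (1/sqrt2, sqrt2)
        counts = _em({"f1": [10.0, 20.0], "f2": [7.0, 14.0], "f3": [100.0, 200.0]})
        s = de_mod.size_factors_median_ratio(counts)
        np.testing.assert_allclose(
            s.to_numpy(), [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12
        )
        assert np.prod(s.to_numpy()) == pytest.approx(1.0)

    def test_no_reference_feature_is_error(self):
        counts = _em({"f1": [0.0, 5, 5, 5, 5, 5], "f2": [1, 0, 1, 1, 1, 1]})
        with pytest.raises(ValidationError, match="pseudo-reference"):
            de_mod.size_factors_median_ratio(counts)


class TestNbTest:
    def test_exact_null_feature(self):
        counts = _em({"f1": [50.0] * 6, "f2": [10, 20, 15, 30, 11, 9]})
        res = de_mod.nb_test(counts, pd.Series(1.0, index=COLS))
        assert res.loc["f1", "log2fc"] == 0.0
        assert res.loc["f1", "p_value"] >= 0.99

    def test_zero_group_pseudocount_rule(self):
        counts = _em({"f1": [0.0, 0, 0, 50, 60, 55], "f2": [20.0] * 6})
        res = de_mod.nb_test(counts, pd.Series(1.0, index=COLS))
        assert res.loc["f1", "log2fc"] == pytest.approx(np.log2(56.0), abs=0.1)

    def test_single_replicate_group_rejected(self):
        df = pd.DataFrame([[1, 2, 3]], index=["f"], columns=["CK1", "CK2", "DR1"])
        em = ExpressionMatrix(values=df, groups={"CK1": "CK", "CK2": "CK", "DR1": "DR"})
        with pytest.raises(ValidationError, match=">= 2 samples"):
            de_mod.nb_test(em, pd.Series(1.0, index=df.columns))


class TestBhAdjust:
    def test_hand_worked_example(self):
        out = de_mod.bh_adjust([0.002, 0.01, 0.03, 0.04])
        np.testing.assert_allclose(out, [0.008, 0.02, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert de_mod.bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_all_equal_stay_equal(self):
        np.testing.assert_allclose(de_mod.bh_adjust([0.2] * 7), [0.2] * 7)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            de_mod.bh_adjust([0.5, 1.5])

    def test_matches_step_up_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(
                de_mod.bh_adjust(p), bh_bruteforce(p), atol=1e-12
            )

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_adjusted_never_below_raw(self, p):
        out = de_mod.bh_adjust(p)
        assert np.all(out >= np.asarray(p) - 1e-12)


class TestCallDe:
    def _results(self):
        return pd.DataFrame(
            {
                "base_mean_ck": [10.0, 10, 10],
                "base_mean_dr": [60.0, 1, 90],
                "log2fc": [2.5, -2.5, 3.0],
                "p_value": [0.01, 0.2, 0.01],
            },
            index=["a", "b", "c"],
        )

    def test_lncrna_rule_uses_raw_p(self):
        out = de_mod.call_de(self._results(), "lncRNA", RunConfig())
        assert out.loc["a", "status"] == "up"
        assert out.loc["b", "status"] == "ns"  # p too large

    def test_mrna_rule_uses_fdr(self):
        res = self._results()
        # many null features dilute the FDR so raw p 0.01 no longer survives
        filler = pd.DataFrame(
            {
                "base_mean_ck": 10.0,
                "base_mean_dr": 10.0,
                "log2fc": 3.0,
                "p_value": np.linspace(0.011, 0.9, 200),
            },
            index=[f"n{i}" for i in range(200)],
        )
        out = de_mod.call_de(pd.concat([res, filler]), "mRNA", RunConfig())
        assert out.loc["c", "fdr"] > 0.05
        assert out.loc["c", "status"] == "ns"

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValidationError):
            de_mod.call_de(self._results(), "protein", RunConfig())

    def test_raising_lfc_threshold_never_adds_calls(self):
        res = self._results()
        loose = de_mod.call_de(res, "lncRNA", RunConfig(lfc_threshold=1.0))
        strict = de_mod.call_de(res, "lncRNA", RunConfig(lfc_threshold=2.8))
        loose_set = set(loose.index[loose.status != "ns"])
        strict_set = set(strict.index[strict.status != "ns"])
        assert strict_set <= loose_set


class TestPowerRecovery:
    def test_planted_lfc4_recovered_at_depth(self):
        """|log2FC| = 4 at mu >= 100, 3 vs 3: >= 90% of planted features
        pass the lncRNA rule."""
        rng = np.random.default_rng(42)
        n, alpha, mu = 2000, 0.05, 100.0
        planted = 100
        r = 1.0 / alpha
        ck = rng.negative_binomial(r, r / (r + mu), size=(n, 3)).astype(float)
        mu_dr = np.full(n, mu)
        mu_dr[:planted] = mu * 16
        dr = np.stack(
            [rng.negative_binomial(r, r / (r + m), size=3).astype(float) for m in mu_dr]
        )
        em = _em({f"f{i}": np.concatenate([ck[i], dr[i]]).tolist() for i in range(n)})
        res = de_mod.call_de(de_mod.nb_test(em), "lncRNA", RunConfig())
        recovered = (res.status[:planted] == "up").mean()
        assert recovered >= 0.90
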