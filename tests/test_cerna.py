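"""ceRNA score, shared-miRNA test, correlation filters and network assembly."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from lncnet import cerna
from lncnet.config import RunConfig
from lncnet.types import CeRNATriplet, ExpressionMatrix, MRESite, ValidationError

COLS = ["CK1", "CK2", "CK3", "DR1", "DR2", "DR3"]


def _expr(rows: dict[str, list[float]]) -> ExpressionMatrix:
    df = pd.DataFrame.from_dict(rows, orient="index", columns=COLS)
    return ExpressionMatrix(values=df, groups={c: c[:2] for c in COLS}, units="fpkm")


def _site(mol, mir):
    return MRESite(mol, mir, 0, 21, 0.0, "cleavage_target", ("", "", ""))


def hypergeom_tail_bruteforce(k, N, K, n):
    """P(X >= k) by direct enumeration of the hypergeometric pmf."""
    total = comb(N, n)
    return sum(comb(K, x) * comb(N - K, n - x) for x in range(k, min(K, n) + 1)) / total


class TestCernaScore:
    def test_ratio_examples(self):
        lnc = {f"m{i}" for i in range(5)}
        assert cerna.cerna_score(lnc, {"m0", "m1", "m2", "m3", "x"}) == pytest.approx(0.8)
        assert cerna.cerna_score(lnc, lnc | {"y"}) == 1.0
        assert cerna.cerna_score(lnc, {"z"}) == 0.0

    def test_empty_lnc_set_is_error(self):
        with pytest.raises(ValidationError):
            cerna.cerna_score(set(), {"m"})


class TestSharedMirnaTest:
    def test_exact_small_case(self):
        # all 3 of the lncRNA's miRNAs drawn into the mRNA's 3: 1/C(10,3)
        assert cerna.shared_mirna_test(3, 3, 3, 10) == pytest.approx(1 / 120)

    def test_zero_shared_is_certain(self):
        assert cerna.shared_mirna_test(0, 4, 5, 20) == 1.0

    def test_matches_enumeration_for_small_universes(self):
        rng = np.random.default_rng(31)
        for _ in range(1000):
            N = int(rng.integers(2, 16))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, K + 1))
            k = int(rng.integers(0, min(n, K) + 1))
            assert cerna.shared_mirna_test(k, n, K, N) == pytest.approx(
                hypergeom_tail_bruteforce(k, N, K, n), rel=1e-9
            )

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValidationError):
            cerna.shared_mirna_test(5, 3, 3, 10)


class TestCorrelationFilter:
    def _triplet(self, lnc="L", mrna="M"):
        return CeRNATriplet(lnc, mrna, frozenset({"m1"}), 1.0, 0.01)

    def test_positive_correlation_retained(self):
        expr = _expr({"L": [1, 2, 3, 4, 5, 6], "M": [2, 4, 6, 8, 10, 12]})
        kept = cerna.correlation_filter([self._triplet()], expr)
        assert len(kept) == 1 and kept[0].corr_lnc_mrna == pytest.approx(1.0)

    def test_negative_correlation_dropped(self):
        expr = _expr({"L": [1, 2, 3, 4, 5, 6], "M": [12, 10, 8, 6, 4, 2]})
        assert cerna.correlation_filter([self._triplet()], expr) == []

    def test_constant_vector_dropped_with_warning(self, caplog):
        expr = _expr({"L": [1, 2, 3, 4, 5, 6], "M": [3, 3, 3, 3, 3, 3]})
        with caplog.at_level("WARNING"):
            assert cerna.correlation_filter([self._triplet()], expr) == []
        assert "zero variance" in caplog.text

    def test_mirna_anticorrelation_when_supplied(self):
        expr = _expr({"L": [1, 2, 3, 4, 5, 6], "M": [2, 4, 6, 8, 10, 12]})
        sponge_down = _expr({"m1": [6, 5, 4, 3, 2, 1]})
        sponge_up = _expr({"m1": [1, 2, 3, 4, 5, 6]})
        assert len(cerna.correlation_filter([self._triplet()], expr, sponge_down)) == 1
        assert cerna.correlation_filter([self._triplet()], expr, sponge_up) == []


class TestBuildNetwork:
    def _catalog(self, shared_counts: dict[tuple[str, str], int], n_universe=12):
        """lnc/mRNA pairs sharing the first k of a fixed miRNA universe."""
        sites = []
        mirs = [f"mir{i}" for i in range(n_universe)]
        for (lnc, mrna), k in shared_counts.items():
            for m in mirs[:k]:
                sites.append(_site(lnc, m))
                sites.append(_site(mrna, m))
        # one extra site per universe miRNA so the universe is complete
        for m in mirs:
            sites.append(_site("filler", m))
        return sites

    def test_strictly_greater_than_three(self):
        expr = _expr(
            {
                "L1": [1, 2, 3, 10, 11, 12],
                "M1": [2, 3, 4, 20, 21, 22],
                "L2": [1, 2, 3, 10, 11, 12],
                "M2": [2, 3, 4, 20, 21, 22],
            }
        )
        catalog = self._catalog({("L1", "M1"): 4, ("L2", "M2"): 3})
        triplets, _ = cerna.build_network(
            catalog, ["L1", "L2"], ["M1", "M2"], expr, RunConfig()
        )
        assert {(t.lncrna_id, t.mrna_id) for t in triplets} == {("L1", "M1")}

    def test_graph_shape_follows_triplets(self):
        expr = _expr(
            {
                "L1": [1, 2, 3, 10, 11, 12],
                "M1": [2, 3, 4, 20, 21, 22],
            }
        )
        catalog = self._catalog({("L1", "M1"): 5})
        triplets, graph = cerna.build_network(catalog, ["L1"], ["M1"], expr, RunConfig())
        (t,) = triplets
        assert graph.number_of_nodes() == 2 + len(t.shared_mirnas)
        assert graph.number_of_edges() == 2 * len(t.shared_mirnas)
        kinds = {d["kind"] for _, _, d in graph.edges(data=True)}
        assert kinds == {"lncRNA-miRNA", "miRNA-mRNA"}

    def test_empty_de_sets_give_empty_network(self):
        expr = _expr({"L1": [1, 2, 3, 4, 5, 6]})
        triplets, graph = cerna.build_network(
            self._catalog({}), [], [], expr, RunConfig()
        )
        assert triplets == [] and graph.number_of_nodes() == 0

    def test_relaxing_filters_only_grows_the_set(self):
        rng = np.random.default_rng(77)
        lncs = [f"L{i}" for i in range(6)]
        mrnas = [f"M{i}" for i in range(6)]
        shared = {
            (ln, mr): int(rng.integers(0, 7)) for ln in lncs for mr in mrnas
        }
        catalog = self._catalog(shared, n_universe=10)
        expr = _expr(
            {x: (rng.uniform(1, 5, 6) + [0, 0, 0, 5, 5, 5]).tolist()
             for x in lncs + mrnas}
        )
        strict, _ = cerna.build_network(catalog, lncs, mrnas, expr, RunConfig())
        relaxed_cfg = RunConfig(cerna_min_shared=0, cerna_alpha=1.0, cerna_fdr=1.1)
        relaxed, _ = cerna.build_network(catalog, lncs, mrnas, expr, relaxed_cfg)
        strict_pairs = {(t.lncrna_id, t.mrna_id) for t in strict}
        relaxed_pairs = {(t.lncrna_id, t.mrna_id) for t in relaxed}
        assert strict_pairs <= relaxed_pairs

    def test_fdr_matches_bruteforce_bh_over_tested_pairs(self):
        from test_de import bh_bruteforce

        rng = np.random.default_rng(13)
        lncs = [f"L{i}" for i in range(5)]
        mrnas = [f"M{i}" for i in range(5)]
        shared = {(ln, mr): int(rng.integers(1, 6)) for ln in lncs for mr in mrnas}
        catalog = self._catalog(shared, n_universe=9)
        # shared group shift keeps every pairwise correlation positive, so
        # no tested pair is lost to the correlation filter
        expr = _expr(
            {x: (rng.uniform(1, 5, 6) + np.array([0, 0, 0, 5, 5, 5])).tolist()
             for x in lncs + mrnas}
        )
        cfg = RunConfig(cerna_min_shared=0, cerna_alpha=1.0, cerna_fdr=2.0)
        triplets, _ = cerna.build_network(catalog, lncs, mrnas, expr, cfg)
        assert len(triplets) == len(lncs) * len(mrnas)
        # recompute every tested pair's p and apply the literal BH definition
        sets = cerna.mirna_sets(catalog)
        universe = len({s.mirna_id for s in catalog})
        ordered = sorted(triplets, key=lambda t: (t.lncrna_id, t.mrna_id))
        ps = [
            cerna.shared_mirna_test(
                len(t.shared_mirnas), len(sets[t.lncrna_id]),
                len(sets[t.mrna_id]), universe,
            )
            for t in ordered
        ]
        expected = bh_bruteforce(np.array(ps))
        np.testing.assert_allclose([t.fdr for t in ordered], expected, atol=1e-12)
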