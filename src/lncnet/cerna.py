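"""Competing-endogenous-RNA (ceRNA) network inference.

A lncRNA and an mRNA compete for the same miRNAs when they carry response
elements for an improbably large common miRNA set. For each differentially
expressed lncRNA-mRNA pair the module computes:

* the ceRNA score |shared miRNAs| / |miRNAs targeting the lncRNA| (distinct
  miRNA identities, so a miRNA with several sites counts once);
* a hypergeometric upper-tail p-value for the shared count, with the
  universe = all miRNAs holding at least one site in the MRE catalog;
* BH FDR across all tested pairs.

Pairs are retained when shared count > cerna_min_shared (strictly greater
than), p < cerna_alpha, FDR < cerna_fdr, and the lncRNA-mRNA expression
correlation is positive (plus miRNA anticorrelation filters when a miRNA
expression matrix is available). Retained triplets are assembled into a
typed graph with lncRNA-miRNA and miRNA-mRNA edges.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig
from .de import bh_adjust
from .types import CeRNATriplet, ExpressionMatrix, MRESite, ValidationError

log = logging.getLogger(__name__)


def cerna_score(lnc_mirnas: set[str], mrna_mirnas: set[str]) -> float:
    """|shared| / |lncRNA miRNA set| in [0, 1]."""
    if not lnc_mirnas:
        raise ValidationError("lncRNA miRNA set is empty")
    return len(lnc_mirnas & mrna_mirnas) / len(lnc_mirnas)


def shared_mirna_test(k_shared: int, n_lnc: int, n_mrna: int, n_universe: int) -> float:
    """Hypergeometric upper tail P(X >= k) for the shared-miRNA count.

    Population of n_universe miRNAs, n_mrna "successes" (the mRNA's set),
    n_lnc draws (the lncRNA's set).
    """
    if not (0 <= k_shared <= min(n_lnc, n_mrna) <= n_universe):
        raise ValidationError(
            f"inconsistent counts k={k_shared}, n_lnc={n_lnc}, "
            f"n_mrna={n_mrna}, N={n_universe}"
        )
    return float(stats.hypergeom.sf(k_shared - 1, n_universe, n_mrna, n_lnc))


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r; NaN when either vector has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def mirna_sets(catalog: list[MRESite]) -> dict[str, set[str]]:
    """molecule -> set of distinct miRNAs with >= 1 site on it."""
    out: dict[str, set[str]] = {}
    for site in catalog:
        out.setdefault(site.molecule_id, set()).add(site.mirna_id)
    return out


def correlation_filter(
    triplets: list[CeRNATriplet],
    expr: ExpressionMatrix,
    mirna_expr: ExpressionMatrix | None = None,
) -> list[CeRNATriplet]:
    """Keep triplets with r(lncRNA, mRNA) > 0; when miRNA expression is
    available additionally require r(miRNA, lncRNA) < 0 and
    r(miRNA, mRNA) < 0 for every shared miRNA. Zero-variance vectors make r
    undefined and drop the triplet with a warning."""
    kept = []
    vals = expr.values
    for t in triplets:
        if t.lncrna_id not in vals.index or t.mrna_id not in vals.index:
            raise ValidationError(
                f"expression matrix lacks {t.lncrna_id} or {t.mrna_id}"
            )
        r = pearson(vals.loc[t.lncrna_id].to_numpy(), vals.loc[t.mrna_id].to_numpy())
        if np.isnan(r):
            log.warning(
                "dropping %s-%s: correlation undefined (zero variance)",
                t.lncrna_id, t.mrna_id,
            )
            continue
        t.corr_lnc_mrna = r
        if r <= 0:
            continue
        if mirna_expr is not None:
            ok = True
            for mir in sorted(t.shared_mirnas):
                if mir not in mirna_expr.values.index:
                    continue
                mv = mirna_expr.values.loc[mir].to_numpy()
                r_lnc = pearson(mv, vals.loc[t.lncrna_id].to_numpy())
                r_mrna = pearson(mv, vals.loc[t.mrna_id].to_numpy())
                t.mirna_correlations[mir] = (r_lnc, r_mrna)
                if np.isnan(r_lnc) or np.isnan(r_mrna) or r_lnc >= 0 or r_mrna >= 0:
                    ok = False
                    break
            if not ok:
                continue
        kept.append(t)
    return kept


def build_network(
    mre_catalog: list[MRESite],
    de_lnc_ids: list[str],
    de_mrna_ids: list[str],
    expr: ExpressionMatrix,
    config: RunConfig | None = None,
    mirna_expr: ExpressionMatrix | None = None,
) -> tuple[list[CeRNATriplet], nx.Graph]:
    """Assemble the ceRNA network over DE lncRNAs and DE mRNAs.

    Empty DE sets yield an empty network (logged, not an error).
    """
    config = config or RunConfig()
    sets = mirna_sets(mre_catalog)
    universe = sorted({s.mirna_id for s in mre_catalog})
    n_universe = len(universe)
    lncs = [x for x in sorted(de_lnc_ids) if sets.get(x)]
    mrnas = [x for x in sorted(de_mrna_ids) if sets.get(x)]
    if not lncs or not mrnas:
        log.info("empty DE lncRNA or mRNA set: returning empty network")
        return [], nx.Graph()
    candidates: list[CeRNATriplet] = []
    pvals: list[float] = []
    for ln in lncs:
        for mr in mrnas:
            shared = sets[ln] & sets[mr]
            candidates.append(
                CeRNATriplet(
                    lncrna_id=ln,
                    mrna_id=mr,
                    shared_mirnas=frozenset(shared),
                    cerna_score=cerna_score(sets[ln], sets[mr]),
                    p_value=shared_mirna_test(
                        len(shared), len(sets[ln]), len(sets[mr]), n_universe
                    ),
                )
            )
            pvals.append(candidates[-1].p_value)
    fdrs = bh_adjust(pvals)
    for t, f in zip(candidates, fdrs):
        t.fdr = float(f)
    retained = [
        t
        for t in candidates
        if len(t.shared_mirnas) > config.cerna_min_shared
        and t.p_value < config.cerna_alpha
        and t.fdr < config.cerna_fdr
    ]
    retained = correlation_filter(retained, expr, mirna_expr)
    graph = nx.Graph()
    for t in retained:
        graph.add_node(t.lncrna_id, kind="lncRNA")
        graph.add_node(t.mrna_id, kind="mRNA")
        for mir in sorted(t.shared_mirnas):
            graph.add_node(mir, kind="miRNA")
            graph.add_edge(t.lncrna_id, mir, kind="lncRNA-miRNA")
            graph.add_edge(mir, t.mrna_id, kind="miRNA-mRNA")
    return retained, graph


def triplets_table(triplets: list[CeRNATriplet]) -> pd.DataFrame:
    rows = [
        (
            t.lncrna_id,
            t.mrna_id,
            ",".join(sorted(t.shared_mirnas)),
            len(t.shared_mirnas),
            t.cerna_score,
            t.p_value,
            t.fdr,
            t.corr_lnc_mrna,
        )
        for t in sorted(triplets, key=lambda t: (t.p_value, t.lncrna_id, t.mrna_id))
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "lncrna_id",
            "mrna_id",
            "shared_mirnas",
            "n_shared",
            "cerna_score",
            "p_value",
            "fdr",
            "corr_lnc_mrna",
        ],
    )
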