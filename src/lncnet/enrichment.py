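"""Term enrichment of gene sets by the classic hypergeometric test.

For a study set of n genes drawn from a background of N, and a term
annotating K background genes of which k are in the study set, the
enrichment p-value is the hypergeometric upper tail P(X >= k); BH FDR is
applied across terms and results are ranked by p (ties broken by term id).
This is the GO/KEGG-style over-representation analysis, without ontology
graph decorrelation.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

from .config import RunConfig
from .types import EnrichmentResult, ValidationError


def enrich(
    study_genes: set[str],
    background_genes: set[str],
    term_map: dict[str, set[str]],
    config: RunConfig | None = None,
    term_labels: dict[str, str] | None = None,
) -> list[EnrichmentResult]:
    """Ranked enrichment of ``study_genes`` against ``background_genes``.

    The study set must be a subset of the background; term gene sets are
    clipped to the background. Returns all terms sorted by ascending p (ties
    by term id); the CLI and drivers report the top ``enrich_top_n``.
    """
    from .de import bh_adjust  # local import to keep module load cheap

    config = config or RunConfig()
    study = set(study_genes)
    background = set(background_genes)
    outside = sorted(study - background)
    if outside:
        raise ValidationError(f"study genes absent from background: {outside[:10]}")
    N = len(background)
    n = len(study)
    rows = []
    for term_id in sorted(term_map):
        genes = term_map[term_id] & background
        K = len(genes)
        if K == 0:
            continue
        k = len(genes & study)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        fold = (k / n) / (K / N) if n > 0 else 0.0
        rows.append((term_id, k, n, K, N, p, fold))
    if not rows:
        return []
    fdrs = bh_adjust([r[5] for r in rows])
    labels = term_labels or {}
    results = [
        EnrichmentResult(
            term_id=r[0],
            term_label=labels.get(r[0], r[0]),
            k=r[1],
            n=r[2],
            K=r[3],
            N=r[4],
            p_value=r[5],
            fdr=float(f),
            fold_enrichment=r[6],
        )
        for r, f in zip(rows, fdrs)
    ]
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def enrichment_table(results: list[EnrichmentResult], top_n: int | None = None) -> pd.DataFrame:
    rows = [
        (r.term_id, r.term_label, r.k, r.n, r.K, r.N, r.fold_enrichment, r.p_value, r.fdr)
        for r in (results[:top_n] if top_n else results)
    ]
    return pd.DataFrame(
        rows,
        columns=["term_id", "term_label", "k", "n", "K", "N", "fold_enrichment", "p_value", "fdr"],
    )
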