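"""Differential expression: FPKM, median-of-ratios normalisation, a
negative-binomial Wald test, BH adjustment, and the study's calling rules.

The test follows the classical count-based DE recipe: per-sample size factors
by the median-of-ratios method; per-feature dispersion by method of moments
under the NB mean/dispersion parameterisation Var = mu + alpha*mu^2, stabilised
against a parametric mean-dispersion trend (alpha(mu) = a0 + a1/mu, taking the
maximum of the per-feature and trend estimates, which is deliberately
conservative at 3 replicates per group); and a two-sided Wald test on the
difference of log group means.

Calling rules differ by feature kind, as in the reference design: lncRNAs are
significant at raw p < alpha, mRNAs at BH FDR < mrna_fdr, both with an
absolute log2 fold-change threshold.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import RunConfig
from .types import ExpressionMatrix, ValidationError

_DISP_FLOOR = 1e-8


def compute_fpkm(
    counts: ExpressionMatrix, lengths: dict[str, int] | pd.Series
) -> ExpressionMatrix:
    """FPKM(f, j) = count(f, j) * 1e9 / (length_f * total_j).

    ``total_j`` is the column sum of the count matrix (mapped fragments).
    """
    lengths = pd.Series(lengths, dtype=float)
    missing = counts.values.index.difference(lengths.index)
    if len(missing):
        raise ValidationError(f"features without a length: {list(missing[:10])}")
    lengths = lengths.reindex(counts.values.index)
    if (lengths <= 0).any():
        bad = list(lengths.index[lengths <= 0][:10])
        raise ValidationError(f"non-positive transcript lengths: {bad}")
    totals = counts.values.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValidationError(f"samples with zero total counts: {bad}")
    fpkm = counts.values.mul(1e9).div(lengths, axis=0).div(totals, axis=1)
    return ExpressionMatrix(values=fpkm, groups=dict(counts.groups), units="fpkm")


def size_factors_median_ratio(counts: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    s_j = median over reference features of count(f, j) / geometric-mean_f;
    features with a zero in any sample are excluded from the reference set.
    """
    mat = counts.values.to_numpy(dtype=float)
    all_nonzero = (mat > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValidationError(
            "no feature has nonzero counts in every sample; supply a "
            "pseudo-reference or filter samples"
        )
    ref = mat[all_nonzero]
    log_geomean = np.mean(np.log(ref), axis=1)
    factors = np.exp(np.median(np.log(ref) - log_geomean[:, None], axis=0))
    return pd.Series(factors, index=counts.values.columns, name="size_factor")


def _fit_dispersion_trend(base_mean: np.ndarray, disp: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of alpha(mu) = a0 + a1/mu on informative features."""
    ok = (base_mean > 0) & (disp > _DISP_FLOOR * 10)
    if ok.sum() < 10:
        return float(np.median(disp[disp > 0]) if (disp > 0).any() else _DISP_FLOOR), 0.0
    x = 1.0 / base_mean[ok]
    y = disp[ok]
    A = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    a0 = max(float(coef[0]), _DISP_FLOOR)
    a1 = max(float(coef[1]), 0.0)
    return a0, a1


def nb_test(
    counts: ExpressionMatrix,
    size_factors: pd.Series | None = None,
    config: RunConfig | None = None,
    group_ref: str = "CK",
    group_alt: str = "DR",
) -> pd.DataFrame:
    """Per-feature log2 fold change (alt vs ref) and two-sided Wald p-value.

    Returns a DataFrame indexed by feature with columns base_mean_ck,
    base_mean_dr, log2fc, dispersion, p_value.
    """
    config = config or RunConfig()
    ref_samples = counts.samples_of(group_ref)
    alt_samples = counts.samples_of(group_alt)
    if len(ref_samples) < 2 or len(alt_samples) < 2:
        raise ValidationError(
            f"need >= 2 samples per group, got {len(ref_samples)} {group_ref} / "
            f"{len(alt_samples)} {group_alt}"
        )
    if size_factors is None:
        size_factors = size_factors_median_ratio(counts)
    s = size_factors.reindex(counts.values.columns).to_numpy(dtype=float)
    if np.any(~np.isfinite(s)) or np.any(s <= 0):
        raise ValidationError("size factors must be finite and positive")
    norm = counts.values.to_numpy(dtype=float) / s[None, :]
    ref_idx = [counts.sample_ids.index(x) for x in ref_samples]
    alt_idx = [counts.sample_ids.index(x) for x in alt_samples]
    k_ref, k_alt = norm[:, ref_idx], norm[:, alt_idx]
    n_ref, n_alt = k_ref.shape[1], k_alt.shape[1]

    m_ref = k_ref.mean(axis=1)
    m_alt = k_alt.mean(axis=1)
    base_mean = norm.mean(axis=1)

    # method-of-moments dispersion from pooled within-group variance
    var_within = (
        k_ref.var(axis=1, ddof=1) * (n_ref - 1) + k_alt.var(axis=1, ddof=1) * (n_alt - 1)
    ) / (n_ref + n_alt - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp_mom = np.where(
            base_mean > 0, (var_within - base_mean) / base_mean**2, _DISP_FLOOR
        )
    disp_mom = np.clip(disp_mom, _DISP_FLOOR, None)
    a0, a1 = _fit_dispersion_trend(base_mean, disp_mom)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp_trend = np.where(base_mean > 0, a0 + a1 / np.maximum(base_mean, 1e-12), a0)
    disp = np.maximum(disp_mom, disp_trend)  # conservative sharing

    eps = config.fc_pseudocount
    log2fc = np.log2((m_alt + eps) / (m_ref + eps))

    # Wald test on the difference of log group means (delta method SEs)
    inv_s_ref = np.mean(1.0 / s[ref_idx])
    inv_s_alt = np.mean(1.0 / s[alt_idx])
    var_mean_ref = (m_ref * inv_s_ref + disp * m_ref**2) / n_ref
    var_mean_alt = (m_alt * inv_s_alt + disp * m_alt**2) / n_alt
    se = np.sqrt(
        var_mean_ref / (m_ref + eps) ** 2 + var_mean_alt / (m_alt + eps) ** 2
    )
    beta = np.log(m_alt + eps) - np.log(m_ref + eps)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, 0.0, 1.0)

    return pd.DataFrame(
        {
            "base_mean_ck": m_ref,
            "base_mean_dr": m_alt,
            "log2fc": log2fc,
            "dispersion": disp,
            "p_value": p,
        },
        index=counts.values.index,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(results: pd.DataFrame, feature_kind: str, config: RunConfig) -> pd.DataFrame:
    """Annotate an nb_test table with FDR and up/down/ns status.

    lncRNA rule: p < alpha and |log2fc| >= lfc_threshold.
    mRNA rule:   FDR < mrna_fdr and |log2fc| >= lfc_threshold.
    """
    if feature_kind not in ("lncRNA", "mRNA"):
        raise ValidationError(f"unknown feature kind {feature_kind!r}")
    out = results.copy()
    out["fdr"] = bh_adjust(out["p_value"].to_numpy())
    if feature_kind == "lncRNA":
        significant = out["p_value"] < config.alpha
    else:
        significant = out["fdr"] < config.mrna_fdr
    significant &= out["log2fc"].abs() >= config.lfc_threshold
    status = np.where(
        significant & (out["log2fc"] > 0),
        "up",
        np.where(significant & (out["log2fc"] < 0), "down", "ns"),
    )
    out["status"] = status
    return out
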