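"""Negative-binomial two-group differential expression (original-DESeq scheme).

The model is NB with Var = mu + alpha * mu^2.  Normalisation uses
median-of-ratios size factors; dispersions are per-gene method-of-moments
estimates combined with a fitted mean-dispersion trend by taking the
gene-wise maximum (the conservative choice of the original method, before
shrinkage estimators existed); testing is the exact-style conditional test
on the summed counts of the two groups, with a normal approximation of the
conditional distribution above a configurable total-count limit.

DESeq2-style fold-change shrinkage, GLM designs and outlier handling are
deliberately out of scope; results therefore differ from a modern DESeq2
run by design.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .counts_io import CountMatrix, DE_RESULT_COLUMNS

STATUS_UP = "up"
STATUS_DOWN = "down"
STATUS_UNCHANGED = "unchanged"
STATUS_NOT_TESTED = "not_tested"

_MIN_ALPHA = 1e-8


class NormalizationError(ValueError):
    pass


@dataclass
class DEResult:
    """Per-gene differential expression record (contrast B vs A)."""

    gene_id: str
    mean_A: float
    mean_B: float
    log2fc: float
    pvalue: float
    qvalue: float
    status: str


def estimate_size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample j, s_j = median over genes with all-positive counts of
    count[g, j] / geometric-mean over samples of count[g, .].  Requires at
    least one gene positive in every sample.
    """
    k = counts.counts.to_numpy(dtype=float)
    all_pos = (k > 0).all(axis=1)
    if not all_pos.any():
        raise NormalizationError(
            "no gene has positive counts in every sample; cannot compute "
            "median-of-ratios size factors"
        )
    logs = np.log(k[all_pos])
    geomean = np.exp(logs.mean(axis=1, keepdims=True))
    # median taken on the linear ratios: an even number of reference genes
    # averages the two central order statistics
    factors = np.median(k[all_pos] / geomean, axis=0)
    return pd.Series(factors, index=counts.sample_ids, name="size_factor")


def _group_indices(cm: CountMatrix, groups: Tuple[str, str]) -> Tuple[np.ndarray, np.ndarray]:
    cond = cm.sample_meta["condition"].to_numpy()
    a = np.flatnonzero(cond == groups[0])
    b = np.flatnonzero(cond == groups[1])
    if len(a) == 0 or len(b) == 0:
        raise ValueError(f"contrast groups {groups} not both present in sample sheet")
    return a, b


def estimate_dispersions(
    counts: CountMatrix,
    size_factors: pd.Series,
    groups: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Method-of-moments NB dispersions with a fitted mean-dispersion trend.

    Per gene, with q = normalized counts k/s: the pooled within-group
    variance v and the overall normalized mean m give
    ``raw = max(0, (v - m * xi) / m^2)`` where ``xi = mean(1/s_j)`` is the
    shot-noise correction for unequal library sizes.  A trend
    ``alpha(m) = a0 + a1/m`` is fitted to the raw estimates by
    gamma-weighted least squares, and ``used = max(raw, fitted)``.

    Returns a frame (gene_id, base_mean, raw_dispersion, fitted_dispersion,
    used_dispersion).  Raises if no group has replicates.
    """
    s = size_factors.loc[counts.sample_ids].to_numpy()
    q = counts.counts.to_numpy(dtype=float) / s
    cond = counts.sample_meta["condition"].to_numpy()
    labels = list(groups) if groups is not None else list(dict.fromkeys(cond))
    ss_within = np.zeros(q.shape[0])
    df_within = 0
    rep_mask = np.zeros(len(s), dtype=bool)
    for g in labels:
        idx = np.flatnonzero(cond == g)
        if len(idx) >= 2:
            sub = q[:, idx]
            ss_within += sub.var(axis=1, ddof=1) * (len(idx) - 1)
            df_within += len(idx) - 1
            rep_mask[idx] = True
    if df_within == 0:
        raise ValueError(
            "no contrast group has >= 2 replicates; within-group variance is "
            "undefined (blind dispersion across all samples would be needed, "
            "which this module requires as an explicit opt-in via `groups`)"
        )
    v = ss_within / df_within
    m = q[:, rep_mask].mean(axis=1)
    xi = float(np.mean(1.0 / s[rep_mask]))
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(m > 0, (v - m * xi) / np.where(m > 0, m, 1.0) ** 2, 0.0)
    raw = np.maximum(raw, 0.0)

    fitted = _fit_dispersion_trend(m, raw)
    used = np.maximum(raw, fitted)
    return pd.DataFrame(
        {
            "gene_id": counts.gene_ids,
            "base_mean": m,
            "raw_dispersion": raw,
            "fitted_dispersion": fitted,
            "used_dispersion": used,
        }
    )


def _fit_dispersion_trend(mean: np.ndarray, raw: np.ndarray) -> np.ndarray:
    """Fit alpha(m) = a0 + a1/m by two rounds of gamma-weighted least squares.

    Only genes with positive mean and strictly positive raw estimate inform
    the fit (zeros are floor artefacts of the max(0, .) truncation).  Falls
    back to the median positive raw dispersion if the regression is
    degenerate (< 10 usable genes).
    """
    use = (mean > 0) & (raw > 0)
    out = np.zeros_like(mean)
    pos_mean = mean > 0
    if use.sum() < 10:
        fill = float(np.median(raw[use])) if use.any() else 0.0
        out[pos_mean] = fill
        return out
    x = np.column_stack([np.ones(use.sum()), 1.0 / mean[use]])
    y = raw[use]
    w = np.ones_like(y)
    coef = np.array([np.median(y), 0.0])
    for _ in range(2):
        xw = x * w[:, None]
        coef, *_ = np.linalg.lstsq(xw, y * w, rcond=None)
        pred = np.maximum(x @ coef, 1e-10)
        w = 1.0 / pred  # gamma-family weighting: sd proportional to mean
    a0, a1 = max(coef[0], 0.0), max(coef[1], 0.0)
    out[pos_mean] = a0 + a1 / mean[pos_mean]
    return out


def _nb_size(mu: float, var: float) -> float:
    """NB `n` (size) parameter from mean/variance; variance must exceed mean."""
    return mu * mu / (var - mu)


def _exact_conditional_pvalue(
    k_a: int, k_b: int, mu_a: float, var_a: float, mu_b: float, var_b: float
) -> float:
    """Exact-style conditional two-sided p-value on the summed counts.

    Conditions on k_a + k_b; sums the probabilities of all splits no more
    likely than the observed one (doubling is implicit in the enumeration).
    """
    ks = k_a + k_b
    a = np.arange(ks + 1)
    size_a, p_a = _nb_size(mu_a, var_a), None
    size_b = _nb_size(mu_b, var_b)
    p_a = size_a / (size_a + mu_a)
    p_b = size_b / (size_b + mu_b)
    logp = stats.nbinom.logpmf(a, size_a, p_a) + stats.nbinom.logpmf(ks - a, size_b, p_b)
    logp -= logp.max()
    probs = np.exp(logp)
    total = probs.sum()
    if total <= 0 or not np.isfinite(total):
        return 1.0
    obs = probs[k_a]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-7)].sum() / total))


def _normal_conditional_pvalue(
    k_a: float, mu_a: float, var_a: float, mu_b: float, var_b: float, k_s: float
) -> float:
    """Normal approximation of the conditional split distribution.

    Given approximately normal K_A ~ N(mu_a, var_a) and K_B ~ N(mu_b, var_b),
    K_A | K_A + K_B = k_s is normal with the usual conditional moments; a
    continuity-corrected two-sided tail is returned.
    """
    w = var_a / (var_a + var_b)
    mc = mu_a + w * (k_s - mu_a - mu_b)
    vc = var_a * var_b / (var_a + var_b)
    sd = np.sqrt(vc)
    lo = stats.norm.cdf((k_a + 0.5 - mc) / sd)
    hi = stats.norm.sf((k_a - 0.5 - mc) / sd)
    return float(min(1.0, 2.0 * min(lo, hi)))


def test_differential(
    counts: CountMatrix,
    size_factors: pd.Series,
    dispersions: pd.DataFrame,
    contrast: Tuple[str, str],
    pseudocount: float = 0.5,
    exact_total_limit: int = 5000,
) -> pd.DataFrame:
    """Per-gene NB test of condition B vs A; returns a DEResult frame.

    log2fc is computed from the normalized group means with ``pseudocount``
    added to both; genes with zero counts in both groups get status
    ``not_tested`` and p-value 1.0 (documented convention).  Genes whose
    summed counts exceed ``exact_total_limit`` are tested with the normal
    approximation of the conditional distribution.  q-values are BH across
    all tested genes.
    """
    idx_a, idx_b = _group_indices(counts, contrast)
    s = size_factors.loc[counts.sample_ids].to_numpy()
    k = counts.counts.to_numpy(dtype=float)
    q = k / s
    alpha = np.maximum(
        dispersions.set_index("gene_id").loc[counts.gene_ids, "used_dispersion"].to_numpy(),
        _MIN_ALPHA,
    )

    sa, sb = s[idx_a], s[idx_b]
    ka = k[:, idx_a].sum(axis=1)
    kb = k[:, idx_b].sum(axis=1)
    mean_a = q[:, idx_a].mean(axis=1)
    mean_b = q[:, idx_b].mean(axis=1)
    log2fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))
    q0 = q.mean(axis=1)  # pooled null mean per size-factor unit

    s_a1, s_a2 = sa.sum(), (sa ** 2).sum()
    s_b1, s_b2 = sb.sum(), (sb ** 2).sum()
    pvals = np.ones(len(q0))
    status = np.full(len(q0), STATUS_UNCHANGED, dtype=object)
    for i in range(len(q0)):
        ks = ka[i] + kb[i]
        if ks == 0:
            status[i] = STATUS_NOT_TESTED
            continue
        mu_a = q0[i] * s_a1
        mu_b = q0[i] * s_b1
        var_a = mu_a + alpha[i] * q0[i] ** 2 * s_a2
        var_b = mu_b + alpha[i] * q0[i] ** 2 * s_b2
        if ks <= exact_total_limit:
            pvals[i] = _exact_conditional_pvalue(
                int(ka[i]), int(kb[i]), mu_a, var_a, mu_b, var_b
            )
        else:
            pvals[i] = _normal_conditional_pvalue(ka[i], mu_a, var_a, mu_b, var_b, ks)

    tested = status != STATUS_NOT_TESTED
    qvals = np.ones(len(q0))
    if tested.any():
        qvals[tested] = adjust_bh(pvals[tested])
    return pd.DataFrame(
        {
            "gene_id": counts.gene_ids,
            "mean_A": mean_a,
            "mean_B": mean_b,
            "log2fc": log2fc,
            "pvalue": pvals,
            "qvalue": qvals,
            "status": status,
        },
        columns=DE_RESULT_COLUMNS,
    )


def label_status(
    de: pd.DataFrame, fdr: float = 0.1, min_abs_log2fc: float = 0.0
) -> pd.DataFrame:
    """Fill the status column (up/down/unchanged) at an FDR and optional fold floor."""
    de = de.copy()
    tested = de["status"] != STATUS_NOT_TESTED
    sig = tested & (de["qvalue"] <= fdr) & (de["log2fc"].abs() >= min_abs_log2fc)
    de.loc[tested, "status"] = STATUS_UNCHANGED
    de.loc[sig & (de["log2fc"] > 0), "status"] = STATUS_UP
    de.loc[sig & (de["log2fc"] < 0), "status"] = STATUS_DOWN
    return de


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_de(
    counts: CountMatrix,
    contrast: Tuple[str, str],
    fdr: float = 0.1,
    pseudocount: float = 0.5,
    exact_total_limit: int = 5000,
) -> pd.DataFrame:
    """Convenience wrapper: size factors -> dispersions -> test -> status labels."""
    sf = estimate_size_factors(counts)
    disp = estimate_dispersions(counts, sf, groups=contrast)
    de = test_differential(
        counts, sf, disp, contrast,
        pseudocount=pseudocount, exact_total_limit=exact_total_limit,
    )
    return label_status(de, fdr=fdr)
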