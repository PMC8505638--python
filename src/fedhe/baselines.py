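"""Reference analyses: pooled cleartext OLS, per-site GWAS, weighted-Z meta.

``pooled_ols`` is the package's oracle: per-variant least squares on the
full design ``[1, X, g]`` solved by QR (``numpy.linalg.lstsq``), a route
deliberately different from the Schur-complement algebra used by the
federated pipelines, so agreement between the two is informative.

``independent_gwas`` is the same analysis restricted to one site;
``meta_weighted_z`` combines per-site z-scores with sample-size weights
(the classic Stouffer scheme, w_i = sqrt(n_i)):

    Z_meta = sum_i sqrt(n_i) z_i / sqrt(sum_i n_i)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _st

from .errors import ValidationError
from .gwas_exact import AssocStats, GwasDataset, P_UNDERFLOW

__all__ = ["StudyStats", "pooled_ols", "independent_gwas", "meta_weighted_z", "compare_methods"]


@dataclass
class StudyStats:
    """Per-variant summary statistics from one study/site."""

    variant_ids: list
    beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    n: int


def pooled_ols(ds: GwasDataset, df_mode: str = "unbiased", reference: str = "normal") -> AssocStats:
    """Per-variant OLS on [1, X, g] via QR least squares (the oracle path)."""
    p, f, v = ds.p, ds.f, ds.v
    df = p - (f + 2) if df_mode == "unbiased" else p
    Xt = ds.design()
    beta = np.full(v, np.nan)
    se = np.full(v, np.nan)
    stat = np.full(v, np.nan)
    pval = np.full(v, np.nan)
    flags = [""] * v
    if df <= 0:
        return AssocStats(list(ds.variant_ids), beta, se, stat, pval,
                          np.full(v, np.nan), ["insufficient_samples"] * v)
    for i in range(v):
        D = np.column_stack([Xt, ds.G[:, i]])
        if np.linalg.matrix_rank(D.T @ D) < D.shape[1]:
            flags[i] = "singular"
            continue
        w, _, _, _ = np.linalg.lstsq(D, ds.y, rcond=None)
        resid = ds.y - D @ w
        mse = resid @ resid / df
        cov_last = np.linalg.inv(D.T @ D)[-1, -1]
        beta[i] = w[-1]
        se[i] = np.sqrt(mse * cov_last)
        if se[i] > 0:
            stat[i] = beta[i] / se[i]
        else:
            stat[i] = np.inf * np.sign(beta[i]) if beta[i] else 0.0
        if reference == "normal":
            pv = 2.0 * _st.norm.sf(abs(stat[i]))
        else:
            pv = 2.0 * _st.t.sf(abs(stat[i]), df)
        pval[i] = min(max(pv, P_UNDERFLOW), 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        nlp = -np.log10(pval)
    return AssocStats(list(ds.variant_ids), beta, se, stat, pval, nlp, flags)


def independent_gwas(ds: GwasDataset, **kwargs) -> StudyStats:
    """One site's own GWAS (pooled analysis restricted to its samples)."""
    if ds.p <= ds.f + 2:
        nan = np.full(ds.v, np.nan)
        return StudyStats(list(ds.variant_ids), nan, nan.copy(), nan.copy(), ds.p)
    res = pooled_ols(ds, **kwargs)
    return StudyStats(res.variant_ids, res.beta, res.se, res.stat, ds.p)


def meta_weighted_z(studies) -> AssocStats:
    """Sample-size-weighted Z meta-analysis across per-site summary statistics."""
    studies = list(studies)
    if not studies:
        raise ValidationError("meta-analysis needs at least one study")
    ids = studies[0].variant_ids
    for s in studies[1:]:
        if list(s.variant_ids) != list(ids):
            raise ValidationError("studies disagree on the variant list")
    v = len(ids)
    num = np.zeros(v)
    den = np.zeros(v)
    for s in studies:
        valid = ~np.isnan(s.z)
        num[valid] += np.sqrt(s.n) * s.z[valid]
        den[valid] += s.n
    z = np.full(v, np.nan)
    ok = den > 0
    z[ok] = num[ok] / np.sqrt(den[ok])
    pval = np.full(v, np.nan)
    pval[ok] = np.clip(2.0 * _st.norm.sf(np.abs(z[ok])), P_UNDERFLOW, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        nlp = -np.log10(pval)
    nan = np.full(v, np.nan)
    flags = ["" if o else "all_na" for o in ok]
    return AssocStats(list(ids), nan, nan.copy(), z, pval, nlp, flags)


def compare_methods(reference: AssocStats, methods: dict) -> pd.DataFrame:
    """Per-method error table vs the pooled reference.

    Rows: method name; columns: mean/max absolute error in -log10(P) and
    in beta (beta errors are NaN for methods that do not report betas).
    """
    ref_nlp = reference.neg_log10_p
    ref_beta = reference.beta
    rows = []
    for name, res in methods.items():
        d_nlp = np.abs(res.neg_log10_p - ref_nlp)
        d_beta = np.abs(res.beta - ref_beta)
        rows.append(
            {
                "method": name,
                "mean_abs_dlog10p": float(np.nanmean(d_nlp)),
                "max_abs_dlog10p": float(np.nanmax(d_nlp)),
                "mean_abs_dbeta": float(np.nanmean(d_beta)) if not np.all(np.isnan(d_beta)) else np.nan,
                "max_abs_dbeta": float(np.nanmax(d_beta)) if not np.all(np.isnan(d_beta)) else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("method")
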