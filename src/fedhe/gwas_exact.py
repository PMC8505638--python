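"""Exact federated linear-regression GWAS under emulated multiparty HE.

For each variant ``i`` the association model is ordinary least squares on
the augmented design ``X' = [1, X, g_i]`` (intercept, f covariates, the
variant dosage): ``w = (X'^T X')^{-1} X'^T y``, with the two-sided P value
computed from the variant weight over its standard error.

Because the covariate block is shared by all variants, the pipeline
aggregates encrypted sufficient statistics once —

    A = X~^T X~   (Gram matrix of X~ = [1, X]),  X~^T y,  y^T y,
    and per variant:  b_i = X~^T g_i,  c_i = g_i^T g_i,  g_i^T y

— inverts ``A`` a single time under encryption (Gauss-Jordan with the
Chebyshev reciprocal), and then, via the bordered-inverse / Schur
complement identity for a rank-one bordered Gram matrix, derives for every
variant only two scalars:

    u_i = g_i^T y - b_i^T A^{-1} X~^T y      (coefficient numerator)
    s_i = c_i - b_i^T A^{-1} b_i             (Schur complement)

with ``beta_i = u_i / s_i`` and ``se_i^2 = MSE_i / s_i``.  The division by
``s_i`` is never performed under encryption: ``u_i`` and ``s_i`` are key-
switched and decrypted by the querier, who finishes the arithmetic in
cleartext.  All per-variant scalars are packed variant-major so one SIMD
operation covers a whole batch of variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _st

from . import mhe
from .approxmath import (
    DEFAULT_CHEB_DEGREE,
    DEFAULT_CHEB_INTERVAL,
    EncMatrix,
    broadcast_slot,
    chebyshev_fit_reciprocal,
    gj_invert,
    precondition_spd,
)
from .errors import NumericalError, ValidationError
from .protocol import Collaboration, DataProvider, collective_aggregate, setup_collaboration

__all__ = [
    "GwasDataset",
    "CrossProducts",
    "AssocStats",
    "local_crossproducts",
    "bordered_variant_stats",
    "finalize_assoc",
    "gwas_exact_pipeline",
]

P_UNDERFLOW = 1e-320
COLLINEARITY_REL_TOL = 1e-8


@dataclass
class GwasDataset:
    """Site-local GWAS inputs: covariates X (p x f), phenotype y, dosages G (p x v)."""

    X: np.ndarray
    y: np.ndarray
    G: np.ndarray
    variant_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.G = np.atleast_2d(np.asarray(self.G, dtype=float))
        p = self.y.shape[0]
        if self.X.shape[0] != p or self.G.shape[0] != p:
            raise ValidationError("X, y, G must agree on the number of samples")
        if not self.variant_ids:
            self.variant_ids = [f"v{i}" for i in range(self.G.shape[1])]
        if len(self.variant_ids) != self.G.shape[1]:
            raise ValidationError("variant_ids length must match the genotype columns")
        for name, arr in (("X", self.X), ("y", self.y), ("G", self.G)):
            if np.isnan(arr).any():
                raise ValidationError(f"missing values in {name}; impute upstream")

    @property
    def p(self) -> int:
        return self.y.shape[0]

    @property
    def f(self) -> int:
        return self.X.shape[1]

    @property
    def v(self) -> int:
        return self.G.shape[1]

    def design(self) -> np.ndarray:
        """X~ = [1, X]."""
        return np.column_stack([np.ones(self.p), self.X])


@dataclass
class CrossProducts:
    """Cleartext sufficient statistics of one site (all additively aggregable)."""

    A: np.ndarray  # (f+1) x (f+1)
    Xty: np.ndarray  # (f+1,)
    yty: float
    B: np.ndarray  # (f+1) x v  (columns are b_i = X~^T g_i)
    c: np.ndarray  # (v,)  g_i^T g_i
    gty: np.ndarray  # (v,)  g_i^T y
    p: int


def cleartext_crossproducts(ds: GwasDataset) -> CrossProducts:
    Xt = ds.design()
    return CrossProducts(
        A=Xt.T @ Xt,
        Xty=Xt.T @ ds.y,
        yty=float(ds.y @ ds.y),
        B=Xt.T @ ds.G,
        c=np.einsum("ij,ij->j", ds.G, ds.G),
        gty=ds.G.T @ ds.y,
        p=ds.p,
    )


@dataclass
class AssocStats:
    """Per-variant association results (Manhattan-plot ready)."""

    variant_ids: list
    beta: np.ndarray
    se: np.ndarray
    stat: np.ndarray
    p: np.ndarray
    neg_log10_p: np.ndarray
    flag: list

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "VARIANT_ID": self.variant_ids,
                "BETA": self.beta,
                "SE": self.se,
                "STAT": self.stat,
                "P": self.p,
                "NEG_LOG10_P": self.neg_log10_p,
                "FLAG": self.flag,
            }
        )


def _check_schema(datasets) -> tuple:
    f = datasets[0].f
    ids = list(datasets[0].variant_ids)
    for ds in datasets[1:]:
        if ds.f != f or list(ds.variant_ids) != ids:
            raise ValidationError("covariate/variant schema differs across data providers")
    return f, ids


def local_crossproducts(ds: GwasDataset, key, params, batch_size=None) -> dict:
    """Compute sufficient statistics on cleartext, then encrypt them.

    Per-variant scalars are packed variant-major, ``batch_size`` variants
    per ciphertext (default: the full slot count).  Returns the encrypted
    contribution of one site.
    """
    cp = cleartext_crossproducts(ds)
    B = batch_size or params.num_slots
    if B > params.num_slots:
        raise ValidationError("batch size exceeds ciphertext slots")
    n_batches = -(-ds.v // B)
    enc = {
        "A_rows": [mhe.encrypt(cp.A[j], key, params) for j in range(ds.f + 1)],
        "Xty": mhe.encrypt(cp.Xty, key, params),
        "yty": mhe.encrypt([cp.yty], key, params),
        "b": [],  # per batch: list over j of ciphertexts
        "c": [],
        "gty": [],
    }
    for t in range(n_batches):
        sl = slice(t * B, min((t + 1) * B, ds.v))
        enc["b"].append([mhe.encrypt(cp.B[j, sl], key, params) for j in range(ds.f + 1)])
        enc["c"].append(mhe.encrypt(cp.c[sl], key, params))
        enc["gty"].append(mhe.encrypt(cp.gty[sl], key, params))
    return enc


def _slot_sum(ct, refresher=None):
    """Rotate-and-add fold: every slot becomes the sum over all slots."""
    shift = 1
    while shift < ct.params.num_slots:
        ct = mhe.add(ct, mhe.rotate(ct, shift))
        shift *= 2
    return ct


def bordered_variant_stats(Ainv: EncMatrix, Xty_ct, b_cts, c_ct, gty_ct, refresher):
    """Encrypted per-variant (u_i, s_i) plus the shared scalar q0.

    u_i = gty_i - b_i^T A^{-1} Xty ; s_i = c_i - b_i^T A^{-1} b_i ;
    q0 = Xty^T A^{-1} Xty.  Uses only SIMD add/mul/rotate; no division.
    Returns ``(u_ct, s_ct, q0_ct)``.
    """
    k = Ainv.dim[0]
    mul = refresher.mul
    # t_j = (A^{-1} Xty)_j, broadcast over all slots
    t_bc = [_slot_sum(mul(Ainv.rows[j], Xty_ct)) for j in range(k)]
    # u = gty - sum_j t_j * b_j
    acc = None
    for j in range(k):
        term = mul(b_cts[j], t_bc[j])
        acc = term if acc is None else mhe.add(acc, term)
    u_ct = mhe.sub(gty_ct, acc)
    # q0 = sum_j Xty_j * t_j : repack t into a vector, inner product with Xty
    params = Xty_ct.params
    t_vec = None
    for j in range(k):
        e = np.zeros(params.num_slots)
        e[j] = 1.0
        masked = mul(t_bc[j], e)
        t_vec = masked if t_vec is None else mhe.add(t_vec, masked)
    q0_ct = _slot_sum(mul(t_vec, Xty_ct))
    # s = c - sum_{j,l} Ainv[j,l] * b_j * b_l  (broadcast each matrix entry)
    acc = None
    for j in range(k):
        bj = b_cts[j]
        for l in range(j, k):
            m_bc = broadcast_slot(Ainv.rows[j], l, refresher)
            term = mul(mul(bj, b_cts[l]), m_bc)
            if l > j:  # symmetric off-diagonal counted twice
                term = mhe.add(term, term)
            acc = term if acc is None else mhe.add(acc, term)
    s_ct = mhe.sub(c_ct, acc)
    return u_ct, s_ct, q0_ct


def finalize_assoc(
    u,
    s,
    yty: float,
    q0: float,
    p: int,
    f: int,
    variant_ids=None,
    df_mode: str = "unbiased",
    reference: str = "normal",
) -> AssocStats:
    """Querier-side completion of the association statistics.

    All divisions and square roots happen here, on decrypted aggregates:
    ``beta = u/s``; ``RSS = yty - q0 - u^2/s``; ``MSE = RSS/df`` with
    ``df = p-(f+2)`` (config ``df_mode="n"`` uses ``p``); ``se =
    sqrt(MSE/s)``; two-sided P from the standard normal by default or a
    t reference with ``p-(f+2)`` degrees of freedom.
    """
    u = np.asarray(u, dtype=float)
    s = np.asarray(s, dtype=float)
    v = u.shape[0]
    if variant_ids is None:
        variant_ids = [f"v{i}" for i in range(v)]
    df = p - (f + 2) if df_mode == "unbiased" else p
    if df <= 0:
        raise ValidationError(f"nonpositive degrees of freedom (p={p}, f={f})")

    beta = np.full(v, np.nan)
    se = np.full(v, np.nan)
    stat = np.full(v, np.nan)
    pval = np.full(v, np.nan)
    flags = [""] * v
    s_scale = float(np.nanmax(np.abs(s))) if v else 0.0
    estimable = s > COLLINEARITY_REL_TOL * max(s_scale, 1e-300)
    for i in np.flatnonzero(~estimable):
        flags[i] = "collinear"

    idx = np.flatnonzero(estimable)
    if idx.size:
        beta[idx] = u[idx] / s[idx]
        rss = yty - q0 - u[idx] ** 2 / s[idx]
        tol = 1e-6 * max(abs(yty), 1.0)
        if np.any(rss < -tol):
            raise NumericalError("negative residual sum of squares beyond tolerance")
        rss = np.maximum(rss, 0.0)
        mse = rss / df
        se[idx] = np.sqrt(mse / s[idx])
        with np.errstate(divide="ignore", invalid="ignore"):
            stat[idx] = beta[idx] / se[idx]  # se=0 -> signed inf; p clamps below
        if reference == "normal":
            pv = 2.0 * _st.norm.sf(np.abs(stat[idx]))
        elif reference == "t":
            pv = 2.0 * _st.t.sf(np.abs(stat[idx]), df)
        else:
            raise ValidationError(f"unknown reference distribution {reference!r}")
        pval[idx] = np.clip(pv, P_UNDERFLOW, 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        nlp = -np.log10(pval)
    return AssocStats(list(variant_ids), beta, se, stat, pval, nlp, flags)


def gwas_exact_pipeline(
    dps,
    config: mhe.CryptoParams | None = None,
    collab: Collaboration | None = None,
    querier_key=None,
    cheb_degree: int = DEFAULT_CHEB_DEGREE,
    cheb_interval=DEFAULT_CHEB_INTERVAL,
    batch_size=None,
    fanout: int = 2,
    seed: int = 0,
    df_mode: str = "unbiased",
    reference: str = "normal",
):
    """End-to-end exact federated GWAS; returns ``(AssocStats, transcript)``.

    Encrypted sufficient statistics are aggregated up the DP tree, the
    covariate Gram matrix is trace-preconditioned and inverted once under
    encryption, per-variant ``(u_i, s_i)`` are computed in SIMD batches,
    and the minimal payload ``{u_i, s_i, yty, q0}`` is key-switched to the
    querier, who finalizes betas, standard errors and P values.
    """
    dps = [dp if isinstance(dp, DataProvider) else DataProvider(*dp) for dp in dps]
    datasets = [dp.local_store for dp in dps]
    f, variant_ids = _check_schema(datasets)
    v = len(variant_ids)
    total_p = sum(ds.p for ds in datasets)

    if collab is None:
        collab = setup_collaboration([dp.dp_id for dp in dps], params=config, fanout=fanout, seed=seed)
    params, tr, refresher = collab.params, collab.transcript, collab.refresher
    B = batch_size or params.num_slots
    n_batches = -(-v // B)

    for dp in dps:
        tr.record("querier", dp.dp_id, "query", "public_query", f"gwas_exact:f={f},v={v}")

    contribs = {
        dp.dp_id: local_crossproducts(dp.local_store, collab.collective_key, params, B)
        for dp in dps
    }

    def agg(extract):
        return collective_aggregate({d: extract(c) for d, c in contribs.items()}, collab.topology, tr)

    A_rows = [agg(lambda c, j=j: c["A_rows"][j]) for j in range(f + 1)]
    Xty_ct = agg(lambda c: c["Xty"])
    yty_ct = agg(lambda c: c["yty"])

    # trace preconditioning from per-site public scalars
    s_factor = precondition_spd([np.trace(cleartext_crossproducts(ds).A) for ds in datasets])
    A_scaled = EncMatrix(rows=[refresher.mul(r, s_factor) for r in A_rows], dim=(f + 1, f + 1))
    recip = chebyshev_fit_reciprocal(cheb_interval, cheb_degree)
    Ainv_scaled = gj_invert(A_scaled, recip, refresher)
    # (A)^{-1} = s * (s A)^{-1}
    Ainv = EncMatrix(rows=[refresher.mul(r, s_factor) for r in Ainv_scaled.rows], dim=(f + 1, f + 1))

    u_parts, s_parts = [], []
    q0_ct = None
    for t in range(n_batches):
        b_cts = [agg(lambda c, t=t, j=j: c["b"][t][j]) for j in range(f + 1)]
        c_ct = agg(lambda c, t=t: c["c"][t])
        gty_ct = agg(lambda c, t=t: c["gty"][t])
        u_ct, s_ct, q0_ct = bordered_variant_stats(Ainv, Xty_ct, b_cts, c_ct, gty_ct, refresher)
        u_parts.append(mhe.collective_key_switch(u_ct, collab.all_shares, collab.querier_key, tr))
        s_parts.append(mhe.collective_key_switch(s_ct, collab.all_shares, collab.querier_key, tr))
    yty_sw = mhe.collective_key_switch(yty_ct, collab.all_shares, collab.querier_key, tr)
    q0_sw = mhe.collective_key_switch(q0_ct, collab.all_shares, collab.querier_key, tr)

    u = np.concatenate([mhe.decrypt(ct, collab.querier_key)[:B] for ct in u_parts])[:v]
    s = np.concatenate([mhe.decrypt(ct, collab.querier_key)[:B] for ct in s_parts])[:v]
    yty = float(mhe.decrypt(yty_sw, collab.querier_key)[0])
    q0 = float(mhe.decrypt(q0_sw, collab.querier_key)[0])
    tr.record("querier", "querier", "decrypt", "final_result", "gwas_exact_stats")

    res = finalize_assoc(u, s, yty, q0, total_p, f, variant_ids, df_mode, reference)
    return res, tr
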