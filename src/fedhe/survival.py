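"""Federated Kaplan-Meier survival estimation.

Each site reduces its records to a vector of per-time-point count triplets
``(n_j, c_j, d_j)`` — patients at risk just before ``t_j``, censored at
``t_j``, events at ``t_j`` — packed as ``n_0, c_0, d_0, ..., n_T, c_T,
d_T`` on a shared integer time grid.  The encrypted vectors are summed
across sites, switched to the querier's key, and only then decrypted; the
querier forms the product-limit curve

    S(t) = prod_{j : t_j <= t} (1 - d_j / n_j)

so the only division in the whole pipeline happens on the querier's side,
on aggregate counts.  Summing count triplets site-wise is exactly what a
pooled analysis would compute, so the federated curve equals the
centralized one (integer-exactly in exact mode).

Tie convention: deaths at ``t_j`` are counted against an at-risk set that
still includes patients censored at the same ``t_j`` (the standard
"deaths before censoring" rule used by mainstream survival software).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import mhe
from .errors import ValidationError
from .protocol import Collaboration, DataProvider, collective_aggregate, setup_collaboration

__all__ = [
    "SurvivalRecord",
    "TimeGrid",
    "KMLocalVector",
    "KMCurve",
    "local_km_counts",
    "km_finalize",
    "km_pipeline",
    "at_risk_table",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient: follow-up time (grid units), event flag, stratum label."""

    time: int
    event: bool
    stratum: str = ""


@dataclass(frozen=True)
class TimeGrid:
    """Integer time grid 0..T (e.g. months since treatment start)."""

    T: int
    resolution: str = "month"

    def __post_init__(self):
        if self.T < 0:
            raise ValidationError("grid maximum T must be nonnegative")

    @property
    def n_points(self) -> int:
        return self.T + 1


@dataclass
class KMLocalVector:
    """Per-site counts over the grid, in the interleaved (n, c, d) packing."""

    n: np.ndarray
    c: np.ndarray
    d: np.ndarray

    def pack(self) -> np.ndarray:
        out = np.empty(3 * len(self.n))
        out[0::3], out[1::3], out[2::3] = self.n, self.c, self.d
        return out

    @classmethod
    def unpack(cls, vec) -> "KMLocalVector":
        vec = np.asarray(vec, dtype=float)
        if len(vec) % 3:
            raise ValidationError("triplet vector length must be a multiple of 3")
        return cls(n=vec[0::3].copy(), c=vec[1::3].copy(), d=vec[2::3].copy())

    def validate(self) -> None:
        n, c, d = self.n, self.c, self.d
        if np.any(n < 0) or np.any(c < 0) or np.any(d < 0):
            raise ValidationError("negative count in KM triplet vector")
        if len(n) > 1 and not np.allclose(n[1:], n[:-1] - d[:-1] - c[:-1]):
            raise ValidationError("at-risk recursion n_{j+1} = n_j - d_j - c_j violated")


@dataclass
class KMCurve:
    """Querier-side survival curve with the aggregate count columns."""

    t: np.ndarray
    S: np.ndarray
    n_at_risk: np.ndarray
    d: np.ndarray
    c: np.ndarray
    stratum: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.t, "S": self.S, "n_at_risk": self.n_at_risk, "d": self.d, "c": self.c}
        )


def local_km_counts(records, grid: TimeGrid, stratum: str | None = None) -> KMLocalVector:
    """Reduce one site's records to the (n, c, d) triplet vector.

    ``stratum=None`` keeps all records; otherwise only matching ones.
    """
    if stratum is not None:
        records = [r for r in records if r.stratum == stratum]
    T = grid.T
    d = np.zeros(T + 1)
    c = np.zeros(T + 1)
    for r in records:
        t = int(r.time)
        if t < 0:
            raise ValidationError(f"negative survival time {t}")
        if t > T:
            raise ValidationError(f"time {t} beyond grid maximum {T}; extend the grid")
        if r.event:
            d[t] += 1
        else:
            c[t] += 1
    n = np.zeros(T + 1)
    n[0] = len(records)
    for j in range(T):
        n[j + 1] = n[j] - d[j] - c[j]
    out = KMLocalVector(n=n, c=c, d=d)
    out.validate()
    return out


def km_finalize(aggregated, stratum: str = "") -> KMCurve:
    """Build the product-limit curve from decrypted aggregate triplets.

    Counts are rounded to integers first (they are exact integers in exact
    mode and recover integers after rounding at default precision in noisy
    mode).  This is the only place the ``d_j / n_j`` division happens.
    """
    local = KMLocalVector.unpack(aggregated)
    n = np.rint(local.n)
    c = np.rint(local.c)
    d = np.rint(local.d)
    if np.any((d > 0) & (n <= 0)):
        raise ValidationError("events recorded at a time with nobody at risk")
    factors = np.ones_like(n)
    mask = d > 0
    factors[mask] = 1.0 - d[mask] / n[mask]
    S = np.cumprod(factors)
    return KMCurve(t=np.arange(len(n)), S=S, n_at_risk=n, d=d, c=c, stratum=stratum)


def _strata_of(dps) -> list:
    labels = set()
    for dp in dps:
        for r in dp.local_store:
            labels.add(r.stratum)
    return sorted(labels)


def km_pipeline(
    dps,
    grid: TimeGrid,
    strata=None,
    config: mhe.CryptoParams | None = None,
    collab: Collaboration | None = None,
    querier_key=None,
    fanout: int = 2,
    seed: int = 0,
):
    """End-to-end federated Kaplan-Meier run over simulated DPs.

    Steps per stratum: each DP packs and encrypts its triplet vector
    (split across ciphertexts when 3*(T+1) exceeds the slot count), the
    tree aggregates, the result is collectively switched to the querier's
    key, and the querier decrypts and finalizes.  Returns
    ``(curves: dict stratum -> KMCurve, transcript)``.
    """
    dps = [dp if isinstance(dp, DataProvider) else DataProvider(*dp) for dp in dps]
    if collab is None:
        collab = setup_collaboration([dp.dp_id for dp in dps], params=config, fanout=fanout, seed=seed)
    params, tr = collab.params, collab.transcript
    if strata is None:
        strata = _strata_of(dps)
    width = 3 * grid.n_points
    n_chunks = -(-width // params.num_slots)

    for dp in dps:
        tr.record("querier", dp.dp_id, "query", "public_query", f"km:T={grid.T}")

    curves = {}
    for stratum in strata:
        chunks_clear = []
        for chunk in range(n_chunks):
            local_cts = {}
            for dp in dps:
                vec = local_km_counts(dp.local_store, grid, stratum).pack()
                lo = chunk * params.num_slots
                part = vec[lo : lo + params.num_slots]
                local_cts[dp.dp_id] = mhe.encrypt(part, collab.collective_key, params)
            agg = collective_aggregate(local_cts, collab.topology, tr)
            switched = mhe.collective_key_switch(agg, collab.all_shares, collab.querier_key, tr)
            chunks_clear.append(mhe.decrypt(switched, collab.querier_key))
        flat = np.concatenate(chunks_clear)[:width]
        if np.rint(flat[0]) == 0:
            raise ValidationError(f"stratum {stratum!r} is empty at every data provider")
        curves[stratum] = km_finalize(flat, stratum=stratum)
    # one logical decryption of the final (multi-ciphertext) result, at the querier
    tr.record("querier", "querier", "decrypt", "final_result", "km_curves")
    return curves, tr


def at_risk_table(curves: dict, checkpoints) -> pd.DataFrame:
    """Numbers at risk at caller-chosen time checkpoints, per stratum."""
    checkpoints = list(checkpoints)
    rows = {}
    for stratum, curve in curves.items():
        rows[stratum] = [
            int(curve.n_at_risk[t]) if t < len(curve.n_at_risk) else 0 for t in checkpoints
        ]
    return pd.DataFrame(rows, index=pd.Index(checkpoints, name="t")).T


def pooled_km(records, grid: TimeGrid, stratum: str | None = None) -> KMCurve:
    """Centralized cleartext Kaplan-Meier on pooled records (oracle/baseline)."""
    return km_finalize(local_km_counts(records, grid, stratum).pack(),
                       stratum=stratum or "")
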