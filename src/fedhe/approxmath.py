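"""Encrypted-domain numerical kernels.

Homomorphic arithmetic offers only slot-wise addition, multiplication and
rotation, so any non-polynomial function — above all the division needed
by matrix inversion — must be replaced by a polynomial surrogate.  This
module provides:

* Chebyshev interpolation of the reciprocal ``1/x`` on an interval
  excluding zero (near-minimax, so the approximation cannot blow up at
  interval edges the way a least-squares fit can);
* polynomial evaluation on ciphertexts with logarithmic multiplicative
  depth, via a baby-step/giant-step (Paterson–Stockmeyer) scheme in the
  Chebyshev basis;
* Gauss–Jordan inversion of an encrypted symmetric positive-definite
  matrix, with one ciphertext per matrix row so every row operation is a
  single SIMD instruction, pivot reciprocals evaluated through the
  Chebyshev surrogate (optionally sharpened by Newton reciprocal steps,
  which are themselves pure add/mul), and every other division deferred
  to the querier after decryption;
* trace preconditioning that maps an SPD matrix's spectrum into the
  reciprocal's approximation interval using only additively-aggregable
  per-site scalars.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import chebyshev as _cheb

from . import mhe
from .errors import ConfigurationError, NumericalError, ValidationError

__all__ = [
    "ChebyshevPoly",
    "EncMatrix",
    "chebyshev_fit_reciprocal",
    "poly_eval_encrypted",
    "encrypt_matrix",
    "decrypt_matrix",
    "broadcast_slot",
    "precondition_spd",
    "gj_invert",
    "gj_invert_exact_division",
]

DEFAULT_CHEB_DEGREE = 63
DEFAULT_CHEB_INTERVAL = (0.01, 2.0)
DEFAULT_NEWTON_STEPS = 2


@dataclass(frozen=True)
class ChebyshevPoly:
    """Polynomial in the Chebyshev basis on ``interval`` (mapped to [-1, 1])."""

    coefficients: tuple
    interval: tuple

    @property
    def degree(self) -> int:
        return len(self.coefficients) - 1

    def _to_unit(self, x):
        a, b = self.interval
        return (2.0 * np.asarray(x, dtype=float) - (a + b)) / (b - a)

    def eval_clear(self, x):
        """Cleartext evaluation (reference for the encrypted path)."""
        return _cheb.chebval(self._to_unit(x), np.asarray(self.coefficients))

    def max_error(self, f, n_grid: int = 4001) -> float:
        """Max |poly - f| on a dense grid over the interval."""
        a, b = self.interval
        xs = np.linspace(a, b, n_grid)
        return float(np.max(np.abs(self.eval_clear(xs) - f(xs))))


def chebyshev_fit_reciprocal(interval, degree: int) -> ChebyshevPoly:
    """Interpolate ``1/x`` at Chebyshev nodes on ``[a, b]``, ``0 < a < b``.

    Interpolation at Chebyshev points is within a small factor of the true
    minimax polynomial, which is what matters here: the worst-case error
    over the whole pivot range is controlled, not just the average.
    """
    a, b = float(interval[0]), float(interval[1])
    if not (0.0 < a < b):
        raise ConfigurationError(
            f"reciprocal approximation needs 0 < a < b, got interval [{a}, {b}]"
        )
    if degree < 1:
        raise ConfigurationError("degree must be >= 1")
    mid, half = (a + b) / 2.0, (b - a) / 2.0
    coeffs = _cheb.chebinterpolate(lambda u: 1.0 / (mid + half * u), degree)
    return ChebyshevPoly(coefficients=tuple(coeffs), interval=(a, b))


# --------------------------------------------------------------------------
# Encrypted polynomial evaluation (baby-step / giant-step, log depth)
# --------------------------------------------------------------------------


def _dbl(ct):
    # multiplication by the integer 2 as an addition: no depth cost
    return mhe.add(ct, ct)


def _cheb_divmod(c: np.ndarray, q: int):
    """Divide a Chebyshev series by T_q: ``c = Q*T_q + R`` with deg R < q.

    Uses the product rule T_i T_q = (T_{i+q} + T_{|i-q|}) / 2.  Requires
    deg(c) < 2q so that deg(Q) < q.
    """
    n = len(c) - 1
    assert q <= n < 2 * q
    R = np.array(c, dtype=float)
    Q = np.zeros(n - q + 1)
    for i in range(n, q - 1, -1):
        j = i - q
        if j == 0:
            Q[0] = R[i]
        else:
            Q[j] = 2.0 * R[i]
            R[q - j] -= R[i]
        R[i] = 0.0
    return Q, R[:q]


def poly_eval_encrypted(poly: ChebyshevPoly, x: mhe.CipherVector, refresher=None) -> mhe.CipherVector:
    """Evaluate ``poly`` slot-wise on a ciphertext using only add/mul/rotate.

    Baby-step/giant-step in the Chebyshev basis keeps the multiplicative
    depth at ``ceil(log2(degree)) + 2`` instead of the linear depth of a
    naive Clenshaw recurrence.  The caller guarantees payloads lie inside
    ``poly.interval``.  When a :class:`~fedhe.protocol.RefreshPolicy` is
    supplied, collective refreshes are inserted as the depth budget
    requires; otherwise a depth overflow raises.
    """
    _mul = refresher.mul if refresher is not None else mhe.mul
    coeffs = np.array(poly.coefficients, dtype=float)
    d = len(coeffs) - 1
    a, b = poly.interval

    def zero_like(ct):
        return mhe.sub(ct, ct)

    if d == 0:
        return mhe.add(zero_like(x), float(coeffs[0]))

    # map payload to u in [-1, 1]
    u = mhe.add(_mul(x, 2.0 / (b - a)), -(a + b) / (b - a))

    # baby steps T_1 .. T_m, m = 2^ceil(log2(d+1)/2)
    ell = max(1, math.ceil(math.log2(d + 1) / 2))
    m = 2 ** ell
    T = {1: u}

    def cheb_T(j):
        if j in T:
            return T[j]
        h = j // 2
        k = j - h
        prod = _dbl(_mul(cheb_T(h), cheb_T(k)))
        T[j] = mhe.add(prod, -1.0) if h == k else mhe.sub(prod, cheb_T(k - h))
        return T[j]

    for j in range(2, min(m, d) + 1):
        cheb_T(j)
    # giant steps T_{2m}, T_{4m}, ...
    q = m
    while 2 * q <= d:
        cheb_T(2 * q)
        q *= 2

    def combine(c: np.ndarray) -> mhe.CipherVector:
        n = len(c) - 1
        if n <= m:
            acc = None
            for j in range(1, n + 1):
                if c[j] != 0.0:
                    term = _mul(cheb_T(j), float(c[j]))
                    acc = term if acc is None else mhe.add(acc, term)
            if acc is None:
                acc = zero_like(u)
            return mhe.add(acc, float(c[0]))
        qq = m
        while 2 * qq <= n:
            qq *= 2
        Q, R = _cheb_divmod(c, qq)
        return mhe.add(_mul(combine(Q), cheb_T(qq)), combine(R))

    return combine(coeffs)


# --------------------------------------------------------------------------
# Encrypted matrices and Gauss-Jordan inversion
# --------------------------------------------------------------------------


@dataclass
class EncMatrix:
    """Row-major encrypted matrix: one zero-padded ciphertext per row."""

    rows: list
    dim: tuple

    def __post_init__(self):
        n_rows, n_cols = self.dim
        if len(self.rows) != n_rows:
            raise ValidationError("row count does not match declared dimension")
        if self.rows and n_cols > self.rows[0].params.num_slots:
            raise ValidationError("matrix wider than the ciphertext slot count")


def encrypt_matrix(M, key, params) -> EncMatrix:
    M = np.atleast_2d(np.asarray(M, dtype=float))
    rows = [mhe.encrypt(M[i], key, params) for i in range(M.shape[0])]
    return EncMatrix(rows=rows, dim=M.shape)


def decrypt_matrix(em: EncMatrix, credentials) -> np.ndarray:
    n_rows, n_cols = em.dim
    return np.vstack([mhe.decrypt(r, credentials)[:n_cols] for r in em.rows])


def broadcast_slot(ct: mhe.CipherVector, idx: int, refresher=None) -> mhe.CipherVector:
    """Replicate the value at slot ``idx`` into every slot.

    Mask (one plaintext multiplication), rotate the value to slot 0, then
    fill by log2(num_slots) rotate-and-add doublings — the standard SIMD
    duplication trick; rotations are depth-free.
    """
    _mul = refresher.mul if refresher is not None else mhe.mul
    num_slots = ct.params.num_slots
    mask = np.zeros(num_slots)
    mask[idx] = 1.0
    out = mhe.rotate(_mul(ct, mask), idx)
    shift = 1
    while shift < num_slots:
        out = mhe.add(out, mhe.rotate(out, -shift))
        shift *= 2
    return out


def precondition_spd(trace_contributions) -> float:
    """Scaling factor ``s = 2 / trace(A)`` from per-site cleartext traces.

    The trace of a Gram matrix is a sum of per-site scalars, so it can be
    aggregated without exposing patient-level data.  For SPD ``A``, the
    scaled matrix ``s*A`` has eigenvalues in ``(0, 2]``, which places all
    Gauss-Jordan pivots inside the default reciprocal interval.
    """
    traces = [
        float(np.trace(t)) if np.ndim(t) >= 2 else float(t) for t in trace_contributions
    ]
    total = sum(traces)
    if total <= 0:
        raise NumericalError("nonpositive aggregate trace: degenerate Gram matrix")
    return 2.0 / total


def _newton_recip(inv_p, x_bc, steps: int, _mul):
    # r <- r*(2 - x*r): squares the relative error, add/mul only
    for _ in range(steps):
        corr = mhe.add(mhe.neg(_mul(x_bc, inv_p)), 2.0)
        inv_p = _mul(inv_p, corr)
    return inv_p


def gj_invert(
    A: EncMatrix,
    recip: ChebyshevPoly,
    refresher,
    newton_steps: int = DEFAULT_NEWTON_STEPS,
    validation_credentials=None,
) -> EncMatrix:
    """Invert an encrypted SPD matrix by Gauss-Jordan elimination.

    Works on the augmented system ``[A | I]`` with one ciphertext per row.
    Each pivot's reciprocal is evaluated through the Chebyshev surrogate
    (plus optional Newton sharpening); row eliminations are single SIMD
    multiply-subtracts.  The caller preconditions ``A`` (see
    :func:`precondition_spd`) so that every pivot falls inside
    ``recip.interval``.  ``validation_credentials`` (synthetic runs only)
    enables cleartext pivot-range checking.

    Only the pivot reciprocal is approximated; no other division happens
    under encryption.
    """
    n, n_cols = A.dim
    if n != n_cols:
        raise ValidationError("matrix must be square")
    if n > 32:
        raise ValidationError("Gauss-Jordan inversion limited to dim <= 32")
    params = A.rows[0].params
    if 2 * n > params.num_slots:
        raise ValidationError("augmented rows do not fit the ciphertext slots")
    _mul = refresher.mul if refresher is not None else mhe.mul
    lo, hi = recip.interval

    # augmented rows [A | I]
    rows = []
    for i in range(n):
        e = np.zeros(params.num_slots)
        e[n + i] = 1.0
        rows.append(mhe.add(A.rows[i], e))

    for k in range(n):
        pivot_bc = broadcast_slot(rows[k], k, refresher)
        if validation_credentials is not None:
            pv = float(mhe.decrypt(pivot_bc, validation_credentials)[0])
            if not (lo <= pv <= hi):
                raise NumericalError(
                    f"pivot {pv:.6g} outside reciprocal interval [{lo}, {hi}]; "
                    "precondition the matrix"
                )
        inv_p = poly_eval_encrypted(recip, pivot_bc, refresher)
        if newton_steps > 0:
            inv_p = _newton_recip(inv_p, pivot_bc, newton_steps, _mul)
        rows[k] = _mul(rows[k], inv_p)
        for i in range(n):
            if i == k:
                continue
            f_bc = broadcast_slot(rows[i], k, refresher)
            rows[i] = mhe.sub(rows[i], _mul(f_bc, rows[k]))

    # extract the right half (the inverse) back into columns 0..n-1
    keep = np.zeros(params.num_slots)
    keep[:n] = 1.0
    inv_rows = [_mul(mhe.rotate(r, n), keep) for r in rows]
    return EncMatrix(rows=inv_rows, dim=(n, n))


def gj_invert_exact_division(A: EncMatrix, refresher, credentials) -> EncMatrix:
    """Diagnostic variant: exact slot-wise pivot reciprocal.

    Replaces the polynomial surrogate with an exact reciprocal computed by
    decrypt-and-re-encrypt of the (scalar) pivot.  Not part of the secure
    protocol — it exists to separate Gauss-Jordan algorithmic error from
    reciprocal-approximation error in tests.
    """
    n, _ = A.dim
    params = A.rows[0].params
    _mul = refresher.mul if refresher is not None else mhe.mul
    rows = []
    for i in range(n):
        e = np.zeros(params.num_slots)
        e[n + i] = 1.0
        rows.append(mhe.add(A.rows[i], e))
    for k in range(n):
        pivot_bc = broadcast_slot(rows[k], k, refresher)
        pv = float(mhe.decrypt(pivot_bc, credentials)[0])
        rows[k] = _mul(rows[k], 1.0 / pv)
        for i in range(n):
            if i == k:
                continue
            f_bc = broadcast_slot(rows[i], k, refresher)
            rows[i] = mhe.sub(rows[i], _mul(f_bc, rows[k]))
    keep = np.zeros(params.num_slots)
    keep[:n] = 1.0
    return EncMatrix(rows=[_mul(mhe.rotate(r, n), keep) for r in rows], dim=(n, n))
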