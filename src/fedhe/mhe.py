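"""Emulation of multiparty CKKS-style homomorphic encryption.

This layer reproduces the *semantics* that constrain federated pipelines
built on multiparty HE — SIMD slot packing, an operation set restricted to
slot-wise addition/multiplication and cyclic rotation, multiplicative-depth
accounting with interactive refresh, collective key switching, and
all-shares decryption — without implementing lattice cryptography.  The
payload of a ciphertext is held in a private attribute and is reachable
only through :func:`decrypt` with valid key material, so information-flow
properties of a pipeline can be asserted by construction.

Two arithmetic modes are provided:

* ``exact`` — operations are performed in double precision; useful for
  verifying that an algorithm is *algebraically* correct.
* ``noisy`` — every encryption and multiplication perturbs each slot with
  an independent zero-mean relative error of scale ``2**-precision_bits``,
  emulating the precision loss of approximate (CKKS-style) arithmetic.

A real HE backend can be substituted by re-implementing this module's
public surface.
"""

from __future__ import annotations

import hashlib
import secrets
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    AccessControlError,
    ConfigurationError,
    DepthError,
    PackingError,
    ProtocolError,
)

__all__ = [
    "CryptoParams",
    "CollectiveKey",
    "QuerierKey",
    "KeyShare",
    "CipherVector",
    "keygen_collective",
    "encrypt",
    "add",
    "sub",
    "mul",
    "neg",
    "rotate",
    "collective_refresh",
    "collective_key_switch",
    "decrypt",
]


# --------------------------------------------------------------------------
# Parameters and keys
# --------------------------------------------------------------------------

DEFAULT_NUM_SLOTS = 4096
DEFAULT_DEPTH_BUDGET = 5
DEFAULT_PRECISION_BITS = 40


@dataclass
class CryptoParams:
    """Emulated cryptosystem parameters.

    num_slots
        Number of SIMD slots per ciphertext (power of two).
    depth_budget
        Sequential ciphertext multiplications allowed before a refresh.
    precision_bits
        Fixed-point fractional precision emulated in ``noisy`` mode.
    mode
        ``"exact"`` or ``"noisy"``.
    noise_seed
        Seed for the noise stream in ``noisy`` mode (deterministic runs).
    """

    num_slots: int = DEFAULT_NUM_SLOTS
    depth_budget: int = DEFAULT_DEPTH_BUDGET
    precision_bits: int = DEFAULT_PRECISION_BITS
    mode: str = "exact"
    noise_seed: int = 0

    def __post_init__(self) -> None:
        if self.num_slots < 1 or (self.num_slots & (self.num_slots - 1)) != 0:
            raise ConfigurationError(
                f"num_slots must be a positive power of two, got {self.num_slots}"
            )
        if self.depth_budget < 1:
            raise ConfigurationError("depth_budget must be >= 1")
        if not 20 <= self.precision_bits <= 60:
            raise ConfigurationError("precision_bits must lie in [20, 60]")
        if self.mode not in ("exact", "noisy"):
            raise ConfigurationError(f"mode must be 'exact' or 'noisy', got {self.mode!r}")
        self._rng = np.random.default_rng(self.noise_seed)

    @property
    def noise_scale(self) -> float:
        return 2.0 ** (-self.precision_bits)

    def _perturb(self, values: np.ndarray) -> np.ndarray:
        """Apply one layer of relative CKKS-style noise (noisy mode only)."""
        if self.mode == "exact":
            return values
        rel = self._rng.normal(0.0, self.noise_scale, size=values.shape)
        return values * (1.0 + rel)


@dataclass(frozen=True)
class CollectiveKey:
    """Public collective key; decryption needs every listed share."""

    key_id: str
    required_share_ids: frozenset


@dataclass(frozen=True)
class KeyShare:
    """One party's fragment of the collective secret key."""

    party_id: str
    key_id: str


@dataclass(frozen=True)
class QuerierKey:
    """The querier's personal key pair; holding the object is the secret."""

    key_id: str
    _secret: str = field(repr=False, default="")


# key_id -> required share ids, so ciphertexts can be validated against the
# key they claim without carrying the key object around.
_KEY_REGISTRY: dict = {}


def keygen_collective(party_ids, seed: int):
    """Generate a collective key (one share per party) plus a querier key.

    The collective secret never exists in full: it is represented only by
    the per-party shares, all of which are needed for decryption, refresh,
    or key switching.  Deterministic under ``seed``.
    """
    party_ids = list(party_ids)
    if len(party_ids) < 2:
        raise ConfigurationError("collective keygen requires at least 2 parties")
    if len(set(party_ids)) != len(party_ids):
        raise ConfigurationError("duplicate party identifiers")
    h = hashlib.sha256(
        (f"collective|{seed}|" + "|".join(map(str, party_ids))).encode()
    ).hexdigest()
    ck = CollectiveKey(key_id=f"ck-{h[:16]}", required_share_ids=frozenset(party_ids))
    shares = [KeyShare(party_id=p, key_id=ck.key_id) for p in party_ids]
    qh = hashlib.sha256((f"querier|{seed}").encode()).hexdigest()
    qk = QuerierKey(key_id=f"qk-{qh[:16]}", _secret=qh[16:48])
    _KEY_REGISTRY[ck.key_id] = ck.required_share_ids
    _KEY_REGISTRY[qk.key_id] = frozenset()
    return ck, shares, qk


# --------------------------------------------------------------------------
# Ciphertexts
# --------------------------------------------------------------------------


class CipherVector:
    """A packed ciphertext: fixed-width slot vector under a single key.

    The payload is intentionally private.  All public state is the key id,
    the depth counter, and the parameter set; reading ``.slots`` raises.
    """

    __slots__ = ("__payload", "key_id", "depth_used", "params")

    def __init__(self, payload: np.ndarray, key_id: str, depth_used: int, params: CryptoParams):
        self.__payload = np.asarray(payload, dtype=float).copy()
        self.key_id = key_id
        self.depth_used = int(depth_used)
        self.params = params

    @property
    def slots(self):
        raise AccessControlError(
            "ciphertext payload is not readable; use decrypt() with valid credentials"
        )

    def __repr__(self) -> str:  # payload never shown
        return (
            f"CipherVector(key_id={self.key_id!r}, depth_used={self.depth_used}, "
            f"num_slots={self.params.num_slots})"
        )

    def __len__(self) -> int:
        return self.params.num_slots

    def digest(self) -> str:
        """Opaque content digest for audit transcripts (not a payload leak)."""
        return hashlib.sha256(self.__payload.tobytes()).hexdigest()[:16]

    # internal accessor, used only by module functions below
    def _raw(self) -> np.ndarray:
        return self.__payload


def _payload(ct: CipherVector) -> np.ndarray:
    return ct._CipherVector__payload  # type: ignore[attr-defined]


def _pack(values, params: CryptoParams) -> np.ndarray:
    values = np.atleast_1d(np.asarray(values, dtype=float))
    if values.ndim != 1:
        raise PackingError("only 1-D vectors can be packed into a ciphertext")
    if values.size > params.num_slots:
        raise PackingError(
            f"vector of length {values.size} exceeds {params.num_slots} slots; split it"
        )
    out = np.zeros(params.num_slots)
    out[: values.size] = values
    return out


def encrypt(values, key, params: CryptoParams) -> CipherVector:
    """Encrypt a vector (zero-padded to ``num_slots``) under ``key``."""
    if not isinstance(key, (CollectiveKey, QuerierKey)):
        raise ProtocolError("encryption key must be a CollectiveKey or QuerierKey")
    packed = params._perturb(_pack(values, params))
    return CipherVector(packed, key.key_id, 0, params)


def _check_pair(a: CipherVector, b: CipherVector) -> None:
    if a.key_id != b.key_id:
        raise ProtocolError(
            f"ciphertext key mismatch: {a.key_id} vs {b.key_id} (pipeline bug)"
        )
    if a.params is not b.params and a.params != b.params:
        raise ProtocolError("ciphertext parameter mismatch")


def add(a: CipherVector, b) -> CipherVector:
    """Slot-wise sum; second operand may be a cleartext vector or scalar."""
    if isinstance(b, CipherVector):
        _check_pair(a, b)
        return CipherVector(
            _payload(a) + _payload(b), a.key_id, max(a.depth_used, b.depth_used), a.params
        )
    if np.isscalar(b):
        return CipherVector(_payload(a) + float(b), a.key_id, a.depth_used, a.params)
    return CipherVector(_payload(a) + _pack(b, a.params), a.key_id, a.depth_used, a.params)


def sub(a: CipherVector, b) -> CipherVector:
    """Slot-wise difference (addition of the negation; no depth cost)."""
    if isinstance(b, CipherVector):
        _check_pair(a, b)
        return CipherVector(
            _payload(a) - _payload(b), a.key_id, max(a.depth_used, b.depth_used), a.params
        )
    if np.isscalar(b):
        return CipherVector(_payload(a) - float(b), a.key_id, a.depth_used, a.params)
    return CipherVector(_payload(a) - _pack(b, a.params), a.key_id, a.depth_used, a.params)


def mul(a: CipherVector, b) -> CipherVector:
    """Slot-wise product; consumes one level of multiplicative depth.

    Raises :class:`DepthError` when the result would exceed the depth
    budget — the caller must interpose a collective refresh.
    """
    if isinstance(b, CipherVector):
        _check_pair(a, b)
        depth = max(a.depth_used, b.depth_used) + 1
        prod = _payload(a) * _payload(b)
    elif np.isscalar(b):
        depth = a.depth_used + 1
        prod = _payload(a) * float(b)
    else:
        depth = a.depth_used + 1
        prod = _payload(a) * _pack(b, a.params)
    if depth > a.params.depth_budget:
        raise DepthError(
            f"multiplicative depth {depth} exceeds budget {a.params.depth_budget}; "
            "a collective refresh is required"
        )
    return CipherVector(a.params._perturb(prod), a.key_id, depth, a.params)


def neg(a: CipherVector) -> CipherVector:
    """Slot-wise negation (free: consumes no multiplicative depth)."""
    return CipherVector(-_payload(a), a.key_id, a.depth_used, a.params)


def rotate(a: CipherVector, k: int) -> CipherVector:
    """Cyclic left rotation of the slot vector by ``k`` (negative = right)."""
    return CipherVector(np.roll(_payload(a), -int(k)), a.key_id, a.depth_used, a.params)


# --------------------------------------------------------------------------
# Interactive (multiparty) operations
# --------------------------------------------------------------------------


def _verify_shares(key_id: str, shares) -> None:
    required = _KEY_REGISTRY.get(key_id)
    if required is None:
        raise ProtocolError(f"unknown key id {key_id!r}")
    presented = {s.party_id for s in shares if isinstance(s, KeyShare) and s.key_id == key_id}
    missing = required - presented
    if missing:
        raise AccessControlError(
            f"missing key shares for parties {sorted(missing)}; all shares are required"
        )


def collective_refresh(a: CipherVector, shares, transcript=None) -> CipherVector:
    """Interactive refresh: resets the depth counter, payload unchanged.

    Requires every share of the collective key (one dishonest-but-curious
    party cannot refresh alone).  Logged as an interactive round when a
    transcript is supplied.
    """
    _verify_shares(a.key_id, shares)
    if transcript is not None:
        transcript.record("all-DPs", "all-DPs", "collective_refresh", "ciphertext", a.digest())
    return CipherVector(a.params._perturb(_payload(a)), a.key_id, 0, a.params)


def collective_key_switch(a: CipherVector, shares, target: QuerierKey, transcript=None) -> CipherVector:
    """Re-encrypt from the collective key to the querier's key.

    No intermediate decryption occurs; afterwards only the querier can
    decrypt.  Requires all collective key shares.
    """
    if a.key_id == target.key_id:
        raise ProtocolError("ciphertext is already under the target key")
    required = _KEY_REGISTRY.get(a.key_id)
    if not required:
        raise ProtocolError("key switch input must be under a collective key")
    _verify_shares(a.key_id, shares)
    if transcript is not None:
        transcript.record("all-DPs", "querier", "collective_key_switch", "ciphertext", a.digest())
    return CipherVector(_payload(a), target.key_id, a.depth_used, a.params)


def decrypt(a: CipherVector, credentials, transcript=None) -> np.ndarray:
    """Decrypt with valid credentials: all collective shares, or the querier key.

    The only path from ciphertext to cleartext in the package.
    """
    if isinstance(credentials, QuerierKey):
        if credentials.key_id != a.key_id:
            raise AccessControlError("querier key does not match this ciphertext's key")
    else:
        try:
            shares = list(credentials)
        except TypeError:
            raise AccessControlError("credentials must be key shares or a QuerierKey")
        required = _KEY_REGISTRY.get(a.key_id, None)
        if required is not None and not required:
            # querier-keyed ciphertext: shares can never decrypt it
            raise AccessControlError("ciphertext under querier key; shares cannot decrypt")
        _verify_shares(a.key_id, shares)
    if transcript is not None:
        transcript.record("querier", "querier", "decrypt", "final_result", a.digest())
    return _payload(a).copy()


def fresh_token() -> str:
    """Unpredictable identifier (used for ad-hoc keys in tests)."""
    return secrets.token_hex(8)
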