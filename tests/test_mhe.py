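"""Contracts of the multiparty-HE emulation layer."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fedhe import mhe
from fedhe.errors import (
    AccessControlError,
    ConfigurationError,
    DepthError,
    PackingError,
    ProtocolError,
)


@pytest.fixture
def keys():
    return mhe.keygen_collective(["a", "b", "c"], seed=5)


class TestKeygen:
    def test_one_share_per_party(self, keys):
        ck, shares, qk = keys
        assert ck.required_share_ids == {"a", "b", "c"}
        assert {s.party_id for s in shares} == {"a", "b", "c"}
        assert qk.key_id != ck.key_id

    def test_deterministic_under_seed(self):
        ck1, _, qk1 = mhe.keygen_collective(["a", "b"], seed=9)
        ck2, _, qk2 = mhe.keygen_collective(["a", "b"], seed=9)
        ck3, _, _ = mhe.keygen_collective(["a", "b"], seed=10)
        assert ck1.key_id == ck2.key_id and qk1.key_id == qk2.key_id
        assert ck1.key_id != ck3.key_id

    def test_single_party_rejected(self):
        with pytest.raises(ConfigurationError):
            mhe.keygen_collective(["solo"], seed=0)


class TestEncryptDecrypt:
    def test_round_trip_zero_pads(self, keys, small_params):
        ck, shares, _ = keys
        ct = mhe.encrypt([1, 2, 3], ck, small_params)
        out = mhe.decrypt(ct, shares)
        assert out.shape == (64,)
        np.testing.assert_array_equal(out[:4], [1, 2, 3, 0])

    def test_empty_vector_encrypts_to_zeros(self, keys, small_params):
        ck, shares, _ = keys
        np.testing.assert_array_equal(mhe.decrypt(mhe.encrypt([], ck, small_params), shares), 0.0)

    def test_oversized_vector_rejected(self, keys, small_params):
        ck, _, _ = keys
        with pytest.raises(PackingError):
            mhe.encrypt(np.ones(65), ck, small_params)

    def test_noisy_round_trip_within_precision(self, keys):
        ck, shares, _ = keys
        params = mhe.CryptoParams(num_slots=64, precision_bits=40, mode="noisy", noise_seed=1)
        vals = np.linspace(1, 50, 50)
        out = mhe.decrypt(mhe.encrypt(vals, ck, params), shares)[:50]
        assert np.all(np.abs(out - vals) / vals < 2**-34)


class TestArithmetic:
    def test_add_homomorphism(self, keys, small_params):
        ck, shares, _ = keys
        a = mhe.encrypt([1, 2], ck, small_params)
        b = mhe.encrypt([3, 4], ck, small_params)
        np.testing.assert_array_equal(mhe.decrypt(mhe.add(a, b), shares)[:2], [4, 6])
        np.testing.assert_array_equal(mhe.decrypt(mhe.add(a, np.zeros(2)), shares)[:2], [1, 2])

    def test_mul_plaintext_and_depth(self, keys, small_params):
        ck, shares, _ = keys
        a = mhe.encrypt([2, 3], ck, small_params)
        out = mhe.mul(a, [10, 10])
        assert out.depth_used == 1
        np.testing.assert_array_equal(mhe.decrypt(out, shares)[:2], [20, 30])

    def test_key_mismatch_rejected(self, small_params):
        ck1, _, _ = mhe.keygen_collective(["a", "b"], seed=1)
        ck2, _, _ = mhe.keygen_collective(["a", "b"], seed=2)
        a = mhe.encrypt([1], ck1, small_params)
        b = mhe.encrypt([1], ck2, small_params)
        with pytest.raises(ProtocolError):
            mhe.add(a, b)
        with pytest.raises(ProtocolError):
            mhe.mul(a, b)

    def test_depth_budget_enforced(self, keys, small_params):
        ck, _, _ = keys
        ct = mhe.encrypt(np.ones(4), ck, small_params)
        for _ in range(small_params.depth_budget):
            ct = mhe.mul(ct, ct)
        with pytest.raises(DepthError):
            mhe.mul(ct, ct)

    @pytest.mark.parametrize("k,expect", [(1, [2, 3, 4, 1]), (0, [1, 2, 3, 4]), (4, [1, 2, 3, 4])])
    def test_rotation_convention(self, keys, k, expect):
        ck, shares, _ = keys
        params = mhe.CryptoParams(num_slots=4, depth_budget=3)
        out = mhe.decrypt(mhe.rotate(mhe.encrypt([1, 2, 3, 4], ck, params), k), shares)
        np.testing.assert_array_equal(out, expect)


class TestInteractiveOps:
    def test_refresh_resets_depth_keeps_payload(self, keys, small_params):
        ck, shares, _ = keys
        ct = mhe.mul(mhe.encrypt([5, 6], ck, small_params), 2.0)
        ref = mhe.collective_refresh(ct, shares)
        assert ref.depth_used == 0
        np.testing.assert_array_equal(mhe.decrypt(ref, shares)[:2], [10, 12])

    def test_refresh_missing_share_rejected(self, keys, small_params):
        ck, shares, _ = keys
        ct = mhe.encrypt([1], ck, small_params)
        with pytest.raises(AccessControlError):
            mhe.collective_refresh(ct, shares[:2])

    def test_key_switch_then_querier_decrypt(self, keys, small_params):
        ck, shares, qk = keys
        ct = mhe.encrypt([7, 8], ck, small_params)
        sw = mhe.collective_key_switch(ct, shares, qk)
        np.testing.assert_array_equal(mhe.decrypt(sw, qk)[:2], [7, 8])
        # the DPs' shares can no longer decrypt
        with pytest.raises(AccessControlError):
            mhe.decrypt(sw, shares)

    def test_key_switch_requires_all_shares(self, keys, small_params):
        ck, shares, qk = keys
        ct = mhe.encrypt([1], ck, small_params)
        with pytest.raises(AccessControlError):
            mhe.collective_key_switch(ct, shares[1:], qk)

    def test_switch_of_querier_ciphertext_rejected(self, keys, small_params):
        ck, shares, qk = keys
        sw = mhe.collective_key_switch(mhe.encrypt([1], ck, small_params), shares, qk)
        with pytest.raises(ProtocolError):
            mhe.collective_key_switch(sw, shares, qk)


class TestAccessControl:
    def test_no_public_accessor_exposes_payload(self, keys, small_params):
        ck, _, _ = keys
        ct = mhe.encrypt([42.0], ck, small_params)
        with pytest.raises(AccessControlError):
            _ = ct.slots
        assert "42" not in repr(ct)

    def test_querier_secret_fails_on_collective_ciphertext(self, keys, small_params):
        ck, _, qk = keys
        ct = mhe.encrypt([1], ck, small_params)
        with pytest.raises(AccessControlError):
            mhe.decrypt(ct, qk)

    def test_partial_shares_fail(self, keys, small_params):
        ck, shares, _ = keys
        ct = mhe.encrypt([1], ck, small_params)
        with pytest.raises(AccessControlError):
            mhe.decrypt(ct, shares[:1])


@settings(max_examples=100, derandomize=True, deadline=None)
@given(
    seed=st.integers(0, 2**20),
    ops=st.lists(st.sampled_from(["add", "mul", "rot", "mulc"]), min_size=1, max_size=4),
)
def test_homomorphism_random_circuits(seed, ops):
    """decrypt(f(Enc(u), Enc(v))) == f(u, v) for random add/mul/rotate circuits.

    Exact in exact mode; within 2^-(precision_bits-4) relative error in
    noisy mode.
    """
    rng = np.random.default_rng(seed)
    u = rng.uniform(0.5, 2.0, 16)
    v = rng.uniform(0.5, 2.0, 16)
    ck, shares, _ = mhe.keygen_collective(["a", "b"], seed=3)
    for mode in ("exact", "noisy"):
        params = mhe.CryptoParams(num_slots=16, depth_budget=10, precision_bits=40,
                                  mode=mode, noise_seed=seed)
        ct, clear = mhe.encrypt(u, ck, params), u.copy()
        ct_v = mhe.encrypt(v, ck, params)
        for op in ops:
            if op == "add":
                ct, clear = mhe.add(ct, ct_v), clear + v
            elif op == "mul":
                ct, clear = mhe.mul(ct, ct_v), clear * v
            elif op == "mulc":
                ct, clear = mhe.mul(ct, 1.5), clear * 1.5
            else:
                ct, clear = mhe.rotate(ct, 3), np.roll(clear, -3)
        out = mhe.decrypt(ct, shares)
        tol = 0.0 if mode == "exact" else 2.0 ** -(params.precision_bits - 4)
        assert np.all(np.abs(out - clear) <= tol * np.maximum(np.abs(clear), 1.0))


@pytest.mark.parametrize("mode", ["exact", "noisy"])
def test_integer_count_fidelity(mode):
    """Integer counts up to 1e6 summed across 128 parties round-trip exactly."""
    rng = np.random.default_rng(7)
    params = mhe.CryptoParams(num_slots=32, precision_bits=30, mode=mode, noise_seed=7)
    parties = [f"p{i}" for i in range(128)]
    ck, shares, _ = mhe.keygen_collective(parties, seed=0)
    vectors = rng.integers(0, 10**6, size=(128, 32))
    acc = mhe.encrypt(vectors[0], ck, params)
    for row in vectors[1:]:
        acc = mhe.add(acc, mhe.encrypt(row, ck, params))
    out = np.rint(mhe.decrypt(acc, shares))
    np.testing.assert_array_equal(out, vectors.sum(axis=0))
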