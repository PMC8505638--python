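"""Chebyshev reciprocal, encrypted polynomial evaluation, Gauss-Jordan inversion."""

import math

import numpy as np
import pytest

from fedhe import mhe
from fedhe.approxmath import (
    chebyshev_fit_reciprocal,
    decrypt_matrix,
    encrypt_matrix,
    gj_invert,
    gj_invert_exact_division,
    poly_eval_encrypted,
    precondition_spd,
)
from fedhe.errors import ConfigurationError, NumericalError
from fedhe.protocol import setup_collaboration


def _collab(num_slots=128, depth_budget=5, seed=1):
    return setup_collaboration(
        ["a", "b", "c"], params=mhe.CryptoParams(num_slots=num_slots, depth_budget=depth_budget),
        seed=seed,
    )


class TestReciprocalFit:
    def test_interval_containing_zero_rejected(self):
        for interval in [(-1.0, 1.0), (0.0, 2.0), (1.0, 1.0)]:
            with pytest.raises(ConfigurationError):
                chebyshev_fit_reciprocal(interval, 7)

    def test_max_error_monotone_in_degree(self):
        """On [0.01, 2], grid max-error is non-increasing over degrees 7..63."""
        errors = [
            chebyshev_fit_reciprocal((0.01, 2.0), d).max_error(lambda x: 1.0 / x)
            for d in (7, 15, 31, 63)
        ]
        assert all(e2 <= e1 for e1, e2 in zip(errors, errors[1:]))

    def test_degree31_error_matches_dense_grid_oracle(self):
        """Regression: brute-force dense-grid max error of the degree-31 fit on [0.1, 2]."""
        poly = chebyshev_fit_reciprocal((0.1, 2.0), 31)
        xs = np.linspace(0.1, 2.0, 50_001)
        oracle_bound = float(np.max(np.abs(poly.eval_clear(xs) - 1.0 / xs)))
        assert poly.max_error(lambda x: 1.0 / x) <= oracle_bound * 1.01
        # value at x=1 is within the fitted max error
        assert abs(poly.eval_clear(1.0) - 1.0) <= oracle_bound


class TestEncryptedEval:
    def test_constant_poly_fills_slots(self, collab3):
        from fedhe.approxmath import ChebyshevPoly

        poly = ChebyshevPoly(coefficients=(2.5,), interval=(0.5, 1.5))
        x = mhe.encrypt([1.0, 1.2], collab3.collective_key, collab3.params)
        out = mhe.decrypt(poly_eval_encrypted(poly, x, collab3.refresher), collab3.all_shares)
        np.testing.assert_allclose(out, 2.5)

    @pytest.mark.parametrize("degree", [3, 15, 63])
    def test_matches_cleartext_on_random_points(self, degree):
        collab = _collab(num_slots=128, depth_budget=30)
        poly = chebyshev_fit_reciprocal((0.1, 2.0), degree)
        rng = np.random.default_rng(degree)
        xs = rng.uniform(0.1, 2.0, 100)
        ct = mhe.encrypt(xs, collab.collective_key, collab.params)
        out = mhe.decrypt(poly_eval_encrypted(poly, ct), collab.all_shares)[:100]
        np.testing.assert_allclose(out, poly.eval_clear(xs), rtol=1e-9, atol=1e-12)

    @pytest.mark.parametrize("degree", [7, 31, 63, 127])
    def test_depth_bound_logarithmic(self, degree):
        """Degree-d evaluation consumes at most ceil(log2 d) + 2 depth levels."""
        collab = _collab(num_slots=32, depth_budget=40)
        poly = chebyshev_fit_reciprocal((0.1, 2.0), degree)
        ct = mhe.encrypt(np.full(8, 1.0), collab.collective_key, collab.params)
        out = poly_eval_encrypted(poly, ct)
        assert out.depth_used <= math.ceil(math.log2(degree)) + 2

    def test_budget_respected_via_refresher(self):
        collab = _collab(num_slots=32, depth_budget=3)
        poly = chebyshev_fit_reciprocal((0.1, 2.0), 63)
        ct = mhe.encrypt([1.0], collab.collective_key, collab.params)
        out = poly_eval_encrypted(poly, ct, collab.refresher)
        assert collab.refresher.n_refreshes > 0
        np.testing.assert_allclose(
            mhe.decrypt(out, collab.all_shares)[0], poly.eval_clear(1.0), rtol=1e-9
        )


class TestPrecondition:
    def test_trace_scaling_examples(self):
        assert precondition_spd([np.eye(4)]) == pytest.approx(0.5)
        assert precondition_spd([np.diag([1.0, 3.0])]) == pytest.approx(0.5)
        assert precondition_spd([2.0, 2.0]) == pytest.approx(0.5)  # per-site scalar traces

    def test_zero_trace_rejected(self):
        with pytest.raises(NumericalError):
            precondition_spd([0.0])

    def test_scale_invert_rescale_recovers_inverse(self):
        rng = np.random.default_rng(2)
        B = rng.standard_normal((30, 5))
        A = B.T @ B + np.eye(5)
        s = precondition_spd([np.trace(A)])
        np.testing.assert_allclose(s * np.linalg.inv(s * A), np.linalg.inv(A))


class TestGaussJordan:
    def _invert(self, A, degree=63, newton_steps=2, num_slots=128, validate=False):
        collab = _collab(num_slots=num_slots)
        s = precondition_spd([np.trace(A)])
        enc = encrypt_matrix(np.asarray(A, dtype=float) * s, collab.collective_key, collab.params)
        recip = chebyshev_fit_reciprocal((0.01, 2.0), degree)
        inv = gj_invert(enc, recip, collab.refresher, newton_steps=newton_steps,
                        validation_credentials=collab.all_shares if validate else None)
        return decrypt_matrix(inv, collab.all_shares) * s

    def test_identity_inverts_to_identity(self):
        np.testing.assert_allclose(self._invert(np.eye(3)), np.eye(3), atol=1e-9)

    def test_diagonal_example(self):
        out = self._invert(np.diag([2.0, 4.0]))
        np.testing.assert_allclose(out, np.diag([0.5, 0.25]), atol=1e-9)

    def test_random_spd_13x13_high_accuracy(self):
        rng = np.random.default_rng(13)
        X = rng.standard_normal((800, 13))
        A = X.T @ X
        err = np.abs(self._invert(A, validate=True) - np.linalg.inv(A)).max()
        assert err < 1e-6

    @pytest.mark.parametrize("dim", [3, 8, 14])
    def test_inverse_consistency_shrinks_with_degree(self, dim):
        """||inv(A) @ A - I|| decreases (non-strictly) as degree grows."""
        rng = np.random.default_rng(dim)
        X = rng.standard_normal((50 * dim, dim))
        A = X.T @ X
        errs = []
        for degree in (15, 63):
            Ainv = self._invert(A, degree=degree, newton_steps=0)
            errs.append(np.linalg.norm(Ainv @ A - np.eye(dim), 2))
        assert errs[1] <= errs[0]
        assert errs[1] < 1e-2

    def test_exact_division_equals_cleartext_inverse(self):
        """With exact division substituted, GJ is the cleartext inverse to float precision."""
        rng = np.random.default_rng(5)
        X = rng.standard_normal((100, 6))
        A = X.T @ X
        collab = _collab()
        s = precondition_spd([np.trace(A)])
        enc = encrypt_matrix(A * s, collab.collective_key, collab.params)
        inv = gj_invert_exact_division(enc, collab.refresher, collab.all_shares)
        out = decrypt_matrix(inv, collab.all_shares) * s
        np.testing.assert_allclose(out, np.linalg.inv(A), rtol=1e-9, atol=1e-12)

    def test_pivot_outside_interval_detected_in_validation_mode(self):
        # unconditioned matrix: pivots far above the interval
        rng = np.random.default_rng(0)
        X = rng.standard_normal((100, 4))
        A = X.T @ X  # pivots ~100
        collab = _collab()
        enc = encrypt_matrix(A, collab.collective_key, collab.params)
        recip = chebyshev_fit_reciprocal((0.01, 2.0), 63)
        with pytest.raises(NumericalError):
            gj_invert(enc, recip, collab.refresher, validation_credentials=collab.all_shares)
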