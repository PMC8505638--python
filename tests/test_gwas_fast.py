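"""Fast federated GWAS: gradient descent, residualization, univariate stage."""

import numpy as np
import pytest

from conftest import make_dps
from fedhe import mhe
from fedhe.baselines import pooled_ols
from fedhe.gwas_fast import (
    FgdConfig,
    _site_designs,
    federated_gd,
    gwas_fast_pipeline,
    residualize,
)
from fedhe.protocol import audit_check, setup_collaboration
from fedhe.simulate import GwasSimConfig, gen_gwas


def _collab_for(dps, seed=0, num_slots=512):
    return setup_collaboration(
        [dp.dp_id for dp in dps], params=mhe.CryptoParams(num_slots=num_slots), seed=seed
    )


class TestFederatedGd:
    def test_zero_phenotype_fixed_point(self, gwas_cohort):
        ds, _ = gwas_cohort
        from fedhe.gwas_exact import GwasDataset

        ds0 = GwasDataset(X=ds.X, y=np.zeros(ds.p), G=ds.G)
        dps = make_dps(ds0, 3, seed=1)
        collab = _collab_for(dps)
        w = federated_gd(dps, FgdConfig(iterations=7), collab)
        np.testing.assert_allclose(mhe.decrypt(w, collab.all_shares), 0.0, atol=1e-12)

    def test_zero_iterations_keeps_zero_weights(self, gwas_cohort):
        ds, _ = gwas_cohort
        dps = make_dps(ds, 3, seed=1)
        collab = _collab_for(dps)
        w = federated_gd(dps, FgdConfig(iterations=0), collab)
        np.testing.assert_allclose(mhe.decrypt(w, collab.all_shares), 0.0)

    def test_one_step_closed_form(self, gwas_cohort):
        """From w=0, one update is (lr/p) * X~^T y on the standardized design."""
        ds, _ = gwas_cohort
        dps = make_dps(ds, 3, seed=2)
        collab = _collab_for(dps)
        fgd = FgdConfig(iterations=1, learning_rate=0.7)
        w = mhe.decrypt(federated_gd(dps, fgd, collab), collab.all_shares)[: ds.f + 1]
        designs = _site_designs([dp.local_store for dp in dps], True)
        expected = (0.7 / ds.p) * sum(
            D.T @ dp.local_store.y for D, dp in zip(designs, dps)
        )
        np.testing.assert_allclose(w, expected, rtol=1e-9, atol=1e-12)

    def test_converges_to_ols_covariate_fit(self, gwas_cohort):
        ds, _ = gwas_cohort
        dps = make_dps(ds, 3, seed=3)
        collab = _collab_for(dps)
        w = mhe.decrypt(
            federated_gd(dps, FgdConfig(iterations=50), collab), collab.all_shares
        )[: ds.f + 1]
        designs = _site_designs([dp.local_store for dp in dps], True)
        D = np.vstack(designs)
        y = np.concatenate([dp.local_store.y for dp in dps])
        w_ols, *_ = np.linalg.lstsq(D, y, rcond=None)
        assert np.abs(w - w_ols).max() < 1e-3

    def test_no_decryption_before_key_switch(self, gwas_cohort):
        ds, _ = gwas_cohort
        dps = make_dps(ds, 3, seed=4)
        collab = _collab_for(dps)
        federated_gd(dps, FgdConfig(iterations=5), collab)
        assert all(e.step_label != "decrypt" for e in collab.transcript.events)
        assert all(e.payload_class == "ciphertext" for e in collab.transcript.events)


class TestResidualize:
    def test_zero_weights_give_back_phenotype(self, gwas_cohort):
        ds, _ = gwas_cohort
        dps = make_dps(ds, 2, seed=5)
        collab = _collab_for(dps, num_slots=512)
        w0 = mhe.encrypt(np.zeros(ds.f + 1), collab.collective_key, collab.params)
        res = residualize(dps, w0, collab)
        for dp, chunks in zip(dps, res):
            got = np.concatenate([mhe.decrypt(c, collab.all_shares) for c in chunks])
            np.testing.assert_allclose(got[: dp.local_store.p], dp.local_store.y, atol=1e-12)

    def test_ols_weights_give_orthogonal_residuals(self, gwas_cohort):
        """Injecting the exact OLS fit: sum(y'') ~ 0 and X~^T y'' ~ 0."""
        ds, _ = gwas_cohort
        dps = make_dps(ds, 2, seed=6)
        collab = _collab_for(dps, num_slots=512)
        designs = _site_designs([dp.local_store for dp in dps], True)
        D = np.vstack(designs)
        y = np.concatenate([dp.local_store.y for dp in dps])
        w_ols, *_ = np.linalg.lstsq(D, y, rcond=None)
        w_ct = mhe.encrypt(w_ols, collab.collective_key, collab.params)
        res = residualize(dps, w_ct, collab)
        resid = np.concatenate(
            [
                np.concatenate([mhe.decrypt(c, collab.all_shares) for c in chunks])[: dp.local_store.p]
                for dp, chunks in zip(dps, res)
            ]
        )
        assert abs(resid.sum()) < 1e-6
        assert np.abs(D.T @ resid).max() < 1e-6


class TestPipeline:
    def test_oracle_agreement(self, gwas_cohort):
        """Mean |delta -log10 P| vs pooled OLS below 1e-2 at default FGD settings."""
        ds, _ = gwas_cohort
        res, tr = gwas_fast_pipeline(make_dps(ds, 6, seed=7), seed=7)
        ref = pooled_ols(ds)
        d = np.abs(res.neg_log10_p - ref.neg_log10_p)
        assert np.nanmean(d) < 1e-2
        assert audit_check(tr).passed

    def test_monomorphic_variant_flagged(self):
        ds, _ = gen_gwas(GwasSimConfig(p=100, f=2, v=8, n_causal=0, seed=8))
        ds.G[:, 3] = 0.0  # monomorphic
        res, _ = gwas_fast_pipeline(make_dps(ds, 2, seed=8), seed=8)
        assert res.flag[3] == "zero_variance" and np.isnan(res.beta[3])
        assert all(f == "" for i, f in enumerate(res.flag) if i != 3)

    def test_planted_effect_within_confidence(self):
        ds, truth = gen_gwas(GwasSimConfig(p=800, f=4, v=32, n_causal=3,
                                           effect_sd=0.3, seed=9))
        res, _ = gwas_fast_pipeline(make_dps(ds, 4, seed=9), seed=9)
        for idx, b in zip(truth["causal_indices"], truth["causal_betas"]):
            assert abs(res.beta[idx] - b) < 3.5 * res.se[idx]

    def test_fast_error_at_least_exact_error(self, gwas_cohort):
        """Accuracy ordering: the gradient/residual shortcut cannot beat exact."""
        from fedhe.gwas_exact import gwas_exact_pipeline

        ds, _ = gwas_cohort
        dps = make_dps(ds, 6, seed=10)
        ref = pooled_ols(ds)
        exact_res, _ = gwas_exact_pipeline(dps, seed=10)
        fast_res, _ = gwas_fast_pipeline(dps, seed=10)
        err_exact = np.nanmean(np.abs(exact_res.neg_log10_p - ref.neg_log10_p))
        err_fast = np.nanmean(np.abs(fast_res.neg_log10_p - ref.neg_log10_p))
        assert err_exact <= err_fast
        assert err_fast < 1e-1

    def test_fgd_config_validation(self):
        with pytest.raises(Exception):
            FgdConfig(learning_rate=-1.0)
        with pytest.raises(Exception):
            FgdConfig(refresh_every=0)
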