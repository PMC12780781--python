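"""G-estimation of additive structural mean models."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from lifemr import (
    EstimandRegime,
    bootstrap_se,
    sandwich_se,
    smm_multivariable,
    smm_univariable,
)
from lifemr.smm import REGIME_REGISTRY

from .conftest import tsls_oracle


class TestUnivariable:
    def test_hand_example(self):
        est = smm_univariable(
            np.array([0, 0, 1, 1.0]),
            np.array([1, 1, 2, 2.0]),
            np.array([0, 0, 1, 1.0]),
        )
        assert est.psi[0] == pytest.approx(1.0)
        assert est.method == "smm-univariable"

    def test_constant_outcome_gives_zero(self, rng):
        z = rng.normal(size=50)
        x = z + rng.normal(size=50)
        est = smm_univariable(z, x, np.ones(50))
        assert est.psi[0] == pytest.approx(0.0, abs=1e-14)

    def test_constant_instrument_errors(self, rng):
        with pytest.raises(ValueError, match="relevance"):
            smm_univariable(np.ones(20), rng.normal(size=20), rng.normal(size=20))

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        arrays(np.float64, 25, elements=st.floats(-5, 5)),
        arrays(np.float64, 25, elements=st.floats(-5, 5)),
        arrays(np.float64, 25, elements=st.floats(0, 1)),
    )
    def test_wald_equivalence(self, z, x, y):
        """The g-estimate equals cov(z, y)/cov(z, x) to machine precision."""
        denom = np.cov(z, x)[0, 1]
        if abs(denom) < 1e-6 or np.std(z) < 1e-3 or np.std(x) < 1e-3:
            return
        wald = np.cov(z, y)[0, 1] / denom
        est = smm_univariable(z, x, y)
        assert est.psi[0] == pytest.approx(wald, rel=1e-10, abs=1e-12)

    def test_instrument_rescaling_invariance(self, rng):
        z = rng.normal(size=200)
        x = 0.5 * z + rng.normal(size=200)
        y = (rng.random(200) < 0.3 + 0.05 * x).astype(float)
        base = smm_univariable(z, x, y).psi[0]
        for c in (-3.0, 1e-4, 250.0):
            assert smm_univariable(c * z, x, y).psi[0] == pytest.approx(base, rel=1e-12)

    def test_first_stage_f_reported(self, rng):
        z = rng.normal(size=500)
        x = z + rng.normal(size=500)
        est = smm_univariable(z, x, rng.random(500))
        # R^2 ~ 0.5 at n=500 gives a very large F
        assert est.first_stage_F[0] > 100


class TestMultivariable:
    def test_identity_cross_covariance_system(self):
        """Data built so the sample cross-covariances form the identity."""
        c1 = np.array([1.0, 1, -1, -1])
        c2 = np.array([1.0, -1, 1, -1])
        z = np.column_stack([c1, c2])
        x = z.copy()  # S_ZX = Z'Z/n = I
        y = 0.3 * c1 - 0.2 * c2 + 5.0
        est = smm_multivariable(z, x, y)
        np.testing.assert_allclose(est.psi, [0.3, -0.2], atol=1e-12)

    def test_collinear_exposures_error(self, rng):
        z = rng.normal(size=(100, 2))
        x = np.column_stack([z[:, 0], z[:, 0]])
        with pytest.raises(ValueError, match="separate exposures"):
            smm_multivariable(z, x, rng.random(100))

    def test_fewer_instruments_than_exposures_errors(self, rng):
        with pytest.raises(ValueError):
            smm_multivariable(
                rng.normal(size=(50, 1)), rng.normal(size=(50, 2)), rng.random(50)
            )

    @pytest.mark.parametrize("seed", range(10))
    def test_just_identified_equals_tsls(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(40, 300)
        z = rng.normal(size=(n, 2))
        x = z @ rng.normal(size=(2, 2)) + rng.normal(size=(n, 2))
        y = x @ np.array([0.3, -0.1]) + rng.normal(size=n)
        est = smm_multivariable(z, x, y)
        oracle = tsls_oracle(z, x, y)
        np.testing.assert_allclose(est.psi, oracle, rtol=1e-10)

    def test_over_identified_equals_tsls(self, rng):
        n, m, k = 400, 5, 2
        z = rng.normal(size=(n, m))
        x = z @ rng.normal(size=(m, k)) * 0.4 + rng.normal(size=(n, k))
        y = x @ np.array([0.2, 0.1]) + rng.normal(size=n)
        est = smm_multivariable(z, x, y)
        np.testing.assert_allclose(est.psi, tsls_oracle(z, x, y), rtol=1e-8)

    def test_conditional_f_reported_per_exposure(self, rng):
        z = rng.normal(size=(1000, 2))
        x = z + 0.3 * rng.normal(size=(1000, 2))
        est = smm_multivariable(z, x, rng.random(1000))
        assert est.first_stage_F.shape == (2,)
        assert np.all(est.first_stage_F > 50)


class TestSandwich:
    def test_zero_residual_gives_zero_se(self, rng):
        z = rng.normal(size=100)
        x = z + rng.normal(size=100)
        psi = np.array([0.7])
        y = 0.7 * x  # no residual at psi
        se, lo, hi = sandwich_se(z, x, y, psi)
        assert se[0] == pytest.approx(0.0, abs=1e-14)
        assert lo[0] == hi[0] == pytest.approx(0.7)

    def test_row_duplication_scaling(self, rng):
        z = rng.normal(size=300)
        x = 0.6 * z + rng.normal(size=300)
        y = (rng.random(300) < 0.4 + 0.05 * x).astype(float)
        psi = smm_univariable(z, x, y).psi
        se1, *_ = sandwich_se(z, x, y, psi)
        z2, x2, y2 = np.tile(z, 2), np.tile(x, 2), np.tile(y, 2)
        se2, *_ = sandwich_se(z2, x2, y2, psi)
        assert se2[0] == pytest.approx(se1[0] / np.sqrt(2), rel=1e-10)


class TestBootstrap:
    @staticmethod
    def _data(rng, n=1500):
        z = rng.normal(size=n)
        x = 0.8 * z + rng.normal(size=n)
        y = (rng.random(n) < 0.4 + 0.06 * x).astype(float)
        return z, x, y

    @staticmethod
    def _wald(z, x, y):
        zc = z - z.mean()
        return np.array([zc @ y / (zc @ x)])

    def test_deterministic_given_seed(self, rng):
        data = self._data(rng)
        a = bootstrap_se(self._wald, data, n_boot=200, seed=9)
        b = bootstrap_se(self._wald, data, n_boot=200, seed=9)
        np.testing.assert_array_equal(a[0], b[0])

    def test_agrees_with_sandwich(self, rng):
        z, x, y = self._data(rng, n=3000)
        psi = self._wald(z, x, y)
        sand, *_ = sandwich_se(z, x, y, psi)
        boot, *_ = bootstrap_se(self._wald, (z, x, y), n_boot=2000, seed=1)
        assert boot[0] == pytest.approx(sand[0], rel=0.15)

    def test_degenerate_data_errors(self):
        z = np.ones(50)
        x = np.arange(50.0)
        y = np.zeros(50)

        def est(zb, xb, yb):
            zc = zb - zb.mean()
            d = zc @ xb
            if abs(d) < 1e-8:
                raise ValueError("degenerate")
            return np.array([zc @ yb / d])

        with pytest.raises(ValueError):
            bootstrap_se(est, (z, x, y), n_boot=100, seed=0)

    def test_minimum_replicates_enforced(self):
        with pytest.raises(ValueError):
            bootstrap_se(self._wald, (np.ones(3),) * 3, n_boot=10, seed=0)


class TestRegimes:
    def test_registry_fixes_assumption_text(self):
        for label, text in REGIME_REGISTRY.items():
            assert EstimandRegime(label).assumption_text == text

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            EstimandRegime("forever")

    def test_regime_is_metadata_not_formula(self, rng):
        z = rng.normal(size=200)
        x = z + rng.normal(size=200)
        y = rng.random(200)
        a = smm_univariable(z, x, y, regime="period")
        b = smm_univariable(z, x, y, regime="lifetime")
        assert a.psi[0] == b.psi[0]
        assert a.estimand_regime.label != b.estimand_regime.label


class TestCovariates:
    def test_residualization_matches_manual(self, rng):
        n = 500
        cov = rng.normal(size=(n, 2))
        z = rng.normal(size=n) + cov @ [0.5, -0.2]
        x = 0.7 * z + cov @ [0.3, 0.3] + rng.normal(size=n)
        y = 0.05 * x + cov @ [0.1, 0.0] + rng.normal(size=n)
        est = smm_univariable(z, x, y, covariates=cov)
        d = np.column_stack([np.ones(n), cov])

        def resid(v):
            return v - d @ np.linalg.lstsq(d, v, rcond=None)[0]

        manual = smm_univariable(resid(z), resid(x), resid(y))
        assert est.psi[0] == pytest.approx(manual.psi[0], rel=1e-12)
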