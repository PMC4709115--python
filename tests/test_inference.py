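import dataclasses

import numpy as np
import pytest

import mkdfe as M
from mkdfe.inference import _Transform, n_free_params
from mkdfe.validation import warm_start


class TestTransform:
    @pytest.mark.parametrize("family,variant", [
        ("neutral", "standard"), ("gamma", "standard"),
        ("gammaexpo", "minus_A"), ("scaledbeta", "standard"),
        ("displgamma", "minus_A"),
    ])
    def test_pack_unpack_round_trip(self, family, variant):
        tr = _Transform(family, 7, variant)
        dfe_kwargs = {"displgamma": {"displacement": 0.2}}.get(family, {})
        params = M.ModelParams(
            theta=0.013, r=np.array([1.0, 0.9, 1.1, 0.8, 1.2, 0.95, 1.05]),
            T=0.21, A=12.5 if variant == "standard" else 0.0,
            dfe=M.make_dfe(family, **dfe_kwargs))
        back = tr.unpack(tr.pack(params))
        assert back.theta == pytest.approx(params.theta, rel=1e-10)
        assert back.T == pytest.approx(params.T, rel=1e-10)
        assert np.allclose(back.r, params.r, rtol=1e-10)
        assert back.A == pytest.approx(params.A, rel=1e-6)
        for name, v in params.dfe.params().items():
            assert back.dfe.params()[name] == pytest.approx(v, rel=1e-6)

    def test_free_parameter_count(self):
        # 2 (theta, T) + (classes - 1) r's + DFE params + 1 for A
        assert n_free_params("gammaexpo", 7, "standard") == 2 + 6 + 4 + 1
        assert n_free_params("gammaexpo", 7, "minus_A") == 2 + 6 + 4
        assert n_free_params("neutral", 4, "standard") == 2 + 3 + 1 + 1


class TestFit:
    def test_neutral_parameter_recovery(self, neutral_dataset):
        scenario, ds = neutral_dataset
        fr = M.fit(ds, "neutral", restarts=2, seed=1)
        assert fr.converged
        assert fr.params_hat.dfe.f_neutral == pytest.approx(0.4, abs=0.02)
        assert fr.params_hat.theta == pytest.approx(0.02, rel=0.02)
        assert fr.params_hat.T == pytest.approx(0.08, rel=0.02)

    def test_refit_from_optimum_is_fixed_point(self, gamma_dataset, gamma_fit):
        _, ds = gamma_dataset
        tr = _Transform("gamma", 5, "standard")
        again = M.fit(ds, "gamma", restarts=1, seed=9,
                      x0=tr.pack(gamma_fit.params_hat))
        assert again.loglik == pytest.approx(gamma_fit.loglik, abs=1e-6)

    def test_synonymous_score_equation_at_optimum(self):
        # with no non-synonymous signal the Poisson MLE satisfies
        # theta * L_S * sum(r_i / i) = sum(P_S) exactly
        rng = np.random.default_rng(4)
        ps = rng.poisson([120, 60, 40, 30, 24], size=5).astype(float)
        ds = M.PolyDivDataset(
            label="syn_only",
            sfs_nonsyn=M.Spectrum(np.zeros(5), 6),
            sfs_syn=M.Spectrum(ps, 6),
            D_N=0.0, D_S=500.0, L_N=10_000.0, L_S=10_000.0)
        fr = M.fit(ds, "neutral", restarts=2, seed=2, ftol=1e-13)
        i = np.arange(1, 6)
        lhs = fr.params_hat.theta * ds.L_S * np.sum(fr.params_hat.r / i)
        assert lhs == pytest.approx(ps.sum(), rel=1e-4)

    def test_aic_identity(self, gamma_fit):
        assert gamma_fit.aic == pytest.approx(
            2 * gamma_fit.n_free - 2 * gamma_fit.loglik)

    def test_deterministic_given_seed(self, gamma_dataset):
        _, ds = gamma_dataset
        a = M.fit(ds, "gamma", restarts=2, seed=5)
        b = M.fit(ds, "gamma", restarts=2, seed=5)
        assert a.loglik == b.loglik
        assert a.params_hat.theta == b.params_hat.theta

    def test_minus_A_requires_positive_effect_family(self, gamma_dataset):
        _, ds = gamma_dataset
        with pytest.raises(ValueError, match="positive-effect"):
            M.fit_minus_A(ds, "gamma")

    def test_minus_A_never_beats_standard(self, gamma_dataset):
        _, ds = gamma_dataset
        mA = M.fit_minus_A(ds, "gammaexpo", restarts=2, seed=3)
        std = M.fit(ds, "gammaexpo", restarts=1, seed=3,
                    x0=warm_start(mA, "gammaexpo", "standard", 5))
        assert mA.loglik <= std.loglik + 1e-6
        assert std.n_free - mA.n_free == 1

    def test_scaling_invariance_of_alpha(self, gamma_dataset):
        _, ds = gamma_dataset
        scaled = M.PolyDivDataset(
            label="scaled",
            sfs_nonsyn=M.Spectrum(ds.sfs_nonsyn.counts * 10, 6),
            sfs_syn=M.Spectrum(ds.sfs_syn.counts * 10, 6),
            D_N=ds.D_N * 10, D_S=ds.D_S * 10,
            L_N=ds.L_N * 10, L_S=ds.L_S * 10,
            Ldiv_N=ds.Ldiv_N * 10, Ldiv_S=ds.Ldiv_S * 10)
        f1 = M.fit(ds, "gamma", restarts=2, seed=7)
        f2 = M.fit(scaled, "gamma", restarts=2, seed=7)
        a1 = M.adaptive_rates(ds, f1.params_hat).alpha
        a2 = M.adaptive_rates(scaled, f2.params_hat).alpha
        assert a2 == pytest.approx(a1, abs=0.02)
        # theta and T are per-site rates: unchanged; A is a count: x10
        assert f2.params_hat.theta == pytest.approx(f1.params_hat.theta, rel=0.05)
        assert f2.params_hat.T == pytest.approx(f1.params_hat.T, rel=0.05)


class TestLRT:
    def _fake_fit(self, family, variant, loglik, n_classes=5):
        nf = n_free_params(family, n_classes, variant)
        params = M.ModelParams(theta=0.01, r=np.ones(n_classes), T=0.1,
                               A=1.0 if variant == "standard" else 0.0,
                               dfe=M.make_dfe(family))
        return M.FitResult(params_hat=params, loglik=loglik,
                           aic=2 * nf - 2 * loglik, n_free=nf, converged=True,
                           n_restarts_used=1, variant=variant, family=family)

    def test_equal_logliks_give_unit_pvalue(self):
        st, df, p = M.lrt(self._fake_fit("gamma", "standard", -10.0),
                          self._fake_fit("gammaexpo", "standard", -10.0))
        assert st == 0.0 and p == 1.0

    def test_reference_chi_square_quantile(self):
        st, df, p = M.lrt(
            self._fake_fit("gammaexpo", "minus_A", -11.92),
            self._fake_fit("gammaexpo", "standard", -10.0))
        assert df == 1
        assert p == pytest.approx(0.05, abs=0.002)

    def test_gamma_vs_gammaexpo_df(self):
        _, df, _ = M.lrt(self._fake_fit("gamma", "standard", -10.0),
                         self._fake_fit("gammaexpo", "standard", -9.0))
        assert df == 2

    def test_non_nested_pair_rejected(self):
        with pytest.raises(ValueError, match="not nested"):
            M.lrt(self._fake_fit("scaledbeta", "standard", -10.0),
                  self._fake_fit("gammaexpo", "standard", -9.0))


class TestModelScan:
    def test_ranking_and_reproducibility(self, gamma_dataset):
        _, ds = gamma_dataset
        table1, fits1 = M.model_scan(ds, families=("neutral", "gamma"),
                                     restarts=1, seed=4)
        table2, _ = M.model_scan(ds, families=("neutral", "gamma"),
                                 restarts=1, seed=4)
        assert list(table1["family"]) == list(table2["family"])
        assert table1["AIC"].is_monotonic_increasing
        assert table1["delta_AIC"].iloc[0] == 0.0
        assert "gamma" in set(table1["family"])
        lrt_table = table1.attrs["lrt"]
        assert {"null", "alt", "p"} <= set(lrt_table.columns)


class TestProfileCI:
    def test_zero_drop_collapses_to_point_estimate(self, gamma_dataset, gamma_fit):
        _, ds = gamma_dataset
        lo, hi, clipped = M.profile_ci_alpha(ds, gamma_fit, drop=0.0)
        est = M.adaptive_rates(ds, gamma_fit.params_hat)
        assert lo == hi == pytest.approx(est.alpha, abs=1e-9)
        assert not clipped

    def test_interval_contains_ml_estimate(self, gamma_dataset, gamma_fit):
        _, ds = gamma_dataset
        lo, hi, _ = M.profile_ci_alpha(ds, gamma_fit, step=0.02)
        est = M.adaptive_rates(ds, gamma_fit.params_hat)
        assert lo <= est.alpha <= hi
        assert hi - lo < 0.5  # informative at these counts
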