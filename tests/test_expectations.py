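import numpy as np
import pytest
from scipy import optimize

from mkdfe import (
    DatasetShape,
    ModelParams,
    dfe_expectation,
    expected_data,
    fixation_factor,
    log_likelihood,
    make_dfe,
    sampling_prob,
    seg_factor,
    sojourn_density,
)
from mkdfe.expectations import seg_factor_vector
from mkdfe.simulate import SimScenario, sample_dataset
from mkdfe.spectra import fold


class TestSojournDensity:
    def test_neutral_limit_two_over_x(self):
        assert sojourn_density(0.0, 0.5) == pytest.approx(4.0)
        assert sojourn_density(0.0, 0.1) == pytest.approx(20.0)

    def test_high_precision_reference_values(self):
        # frozen from a 30-digit symbolic evaluation of the closed form
        assert sojourn_density(-2.0, 0.5) == pytest.approx(
            2.15153137095996096599072606543, rel=1e-12)
        assert sojourn_density(5.0, 0.1) == pytest.approx(
            22.1244288615375813435245541962, rel=1e-12)

    def test_frequency_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            sojourn_density(1.0, 0.0)
        with pytest.raises(ValueError):
            sojourn_density(1.0, 1.0)

    def test_extreme_selection_no_overflow(self):
        x = np.linspace(0.01, 0.99, 25)
        h_neg = sojourn_density(-5000.0, x)
        h_pos = sojourn_density(5000.0, x)
        assert np.all(np.isfinite(h_neg)) and np.all(h_neg >= 0)
        assert np.all(np.isfinite(h_pos)) and np.all(h_pos > 0)
        # strongly advantageous: sojourn ~ 2/(x(1-x))
        assert np.allclose(h_pos, 2 / (x * (1 - x)), rtol=1e-10)


class TestSamplingProb:
    def test_closed_form_cases(self):
        assert sampling_prob(1, 2, 0.5) == pytest.approx(0.5)
        assert sampling_prob(0, 8, 0.3) == pytest.approx(0.7 ** 8)

    def test_normalization_over_classes(self):
        i = np.arange(0, 9)
        assert np.sum(sampling_prob(i, 8, 0.37)) == pytest.approx(1.0)


class TestSegFactor:
    def test_neutral_closed_form(self):
        assert seg_factor(1e-10, 2, 8) == pytest.approx(1.0, abs=1e-6)
        assert seg_factor(1e-10, 5, 12) == pytest.approx(0.4, abs=1e-6)

    def test_quadrature_converged_at_default_nodes(self):
        for S in (-50.0, -5.0, -0.5, 0.5, 5.0, 50.0):
            coarse = seg_factor_vector(np.array([S]), 8, n_x=256)
            fine = seg_factor_vector(np.array([S]), 8, n_x=512)
            assert np.allclose(coarse, fine, rtol=1e-9)

    def test_asymptotic_branch_continuous(self):
        near = seg_factor_vector(np.array([-499.0]), 8)
        far = seg_factor_vector(np.array([-501.0]), 8)
        assert np.allclose(near, far, rtol=0.05)

    def test_class_out_of_range(self):
        with pytest.raises(ValueError):
            seg_factor(1.0, 8, 8)


class TestFixationFactor:
    def test_reference_points(self):
        assert fixation_factor(0.0) == 1.0
        assert fixation_factor(2.0) == pytest.approx(2 / (1 - np.exp(-2.0)))

    def test_antisymmetry_identity(self):
        S = np.linspace(-40.0, 40.0, 81)
        assert np.max(np.abs(
            fixation_factor(S) - fixation_factor(-S) - S)) < 1e-10

    def test_strong_selection_limits(self):
        assert fixation_factor(1000.0) == pytest.approx(1000.0)
        assert fixation_factor(-2000.0) == pytest.approx(0.0, abs=1e-300)


class TestExpectedData:
    shape = DatasetShape(8, False, 1000.0, 1000.0, 1000.0, 1000.0)

    def _neutral_params(self):
        return ModelParams(theta=0.01, r=np.ones(7), T=0.05, A=0.0,
                           dfe=make_dfe("neutral", f_neutral=1.0))

    def test_fully_neutral_closed_form(self):
        exp = expected_data(self._neutral_params(), self.shape)
        i = np.arange(1, 8)
        assert np.allclose(exp.exp_PS, 10.0 / i, rtol=1e-9)
        assert np.allclose(exp.exp_PN, 10.0 / i, rtol=1e-9)
        assert exp.exp_DS == pytest.approx(50.0)
        assert exp.exp_DN == pytest.approx(50.0, rel=1e-9)

    def test_neutral_sfs_proportional_LN_over_LS(self):
        shape = DatasetShape(8, False, 2500.0, 1000.0, 2500.0, 1000.0)
        exp = expected_data(self._neutral_params(), shape)
        assert np.allclose(exp.exp_PN / exp.exp_PS, 2.5, rtol=1e-9)

    def test_gamma_expectation_vs_riemann_oracle(self):
        # dense trapezoid integral of density * G over a light-tailed Gamma
        dfe = make_dfe("gamma", shape=1.0, mean_del=20.0)
        params = ModelParams(theta=0.01, r=np.ones(7), T=0.05, A=0.0, dfe=dfe)
        exp = expected_data(params, self.shape)
        S = -np.linspace(1e-6, 500.0, 200_001)
        G = seg_factor_vector(S, 8)
        dens = dfe.density(S)
        oracle = 0.5 * 0.01 * 1000.0 * np.trapezoid(
            dens[:, None] * G, x=-S, axis=0)
        assert np.allclose(exp.exp_PN, oracle, rtol=1e-4)

    def test_purifying_selection_reduces_pn_monotonically(self):
        ratios = []
        for mean_del in (10.0, 100.0, 1000.0):
            dfe = make_dfe("gamma", shape=0.4, mean_del=mean_del)
            params = ModelParams(theta=0.01, r=np.ones(7), T=0.05, A=0.0,
                                 dfe=dfe)
            exp = expected_data(params, self.shape)
            assert np.all(exp.exp_PN < exp.exp_PS)
            ratios.append(exp.exp_DN / exp.exp_DS)
        assert ratios[0] > ratios[1] > ratios[2]

    def test_dnds_increases_with_positive_mass(self):
        ratios = []
        for p_pos in (0.0, 0.01, 0.05):
            dfe = make_dfe("gammaexpo", shape=0.4, mean_del=1000.0,
                           p_pos=p_pos, mean_adv=4.0)
            params = ModelParams(theta=0.01, r=np.ones(7), T=0.05, A=0.0,
                                 dfe=dfe)
            exp = expected_data(params, self.shape)
            ratios.append(exp.exp_DN / exp.exp_DS)
        assert ratios[0] < ratios[1] < ratios[2]

    def test_folded_expectation_is_fold_of_unfolded(self):
        dfe = make_dfe("gamma", shape=0.4, mean_del=300.0)
        unfolded = expected_data(
            ModelParams(theta=0.01, r=np.ones(7), T=0.05, A=5.0, dfe=dfe),
            self.shape)
        folded = expected_data(
            ModelParams(theta=0.01, r=np.ones(4), T=0.05, A=5.0, dfe=dfe),
            DatasetShape(8, True, 1000.0, 1000.0, 1000.0, 1000.0))
        from mkdfe.spectra import Spectrum
        assert np.allclose(
            folded.exp_PN, fold(Spectrum(unfolded.exp_PN, 8)).counts,
            rtol=1e-12)
        assert np.allclose(
            folded.exp_PS, fold(Spectrum(unfolded.exp_PS, 8)).counts,
            rtol=1e-12)

    def test_r_vector_length_checked(self):
        with pytest.raises(ValueError, match="classes"):
            expected_data(
                ModelParams(theta=0.01, r=np.ones(5), T=0.05, A=0.0,
                            dfe=make_dfe("neutral")), self.shape)


class TestLogLikelihood:
    def _dataset(self):
        params = ModelParams(theta=0.01, r=np.ones(7), T=0.05, A=0.0,
                             dfe=make_dfe("neutral", f_neutral=1.0))
        scenario = SimScenario(params=params, n_chrom=8, L_N=100_000.0,
                               L_S=100_000.0, seed=3)
        return sample_dataset(scenario, 0), params

    def test_single_cell_terms(self):
        from mkdfe.expectations import _poisson_terms
        assert _poisson_terms(np.array([1.0]), np.array([1.0])) == pytest.approx(-1.0)
        assert _poisson_terms(np.array([0.0]), np.array([3.7])) == pytest.approx(-3.7)
        assert _poisson_terms(np.array([2.0]), np.array([0.0])) == -np.inf

    def test_theta_mle_matches_closed_form(self):
        # with everything else fixed neutral and r = 1, the synonymous-SFS
        # part of the likelihood is maximized at theta = sum(P_S)/(L_S sum 1/i)
        ds, params = self._dataset()
        i = np.arange(1, 8)
        closed = ds.sfs_syn.total() / (ds.L_S * np.sum(1.0 / i))

        def neg_syn_ll(theta):
            from mkdfe.expectations import _poisson_terms
            return -_poisson_terms(ds.sfs_syn.counts, theta * ds.L_S / i)

        res = optimize.minimize_scalar(
            neg_syn_ll, bounds=(closed / 10, closed * 10), method="bounded",
            options={"xatol": 1e-12})
        assert res.x == pytest.approx(closed, rel=1e-6)

    def test_likelihood_peaks_near_truth(self):
        ds, params = self._dataset()
        ll_true = log_likelihood(ds, params)
        import dataclasses
        worse = dataclasses.replace(params, theta=params.theta * 1.5)
        assert ll_true > log_likelihood(ds, worse)
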