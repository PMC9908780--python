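"""WLS fitting, fit statistics and uncertainty reporting."""

import numpy as np
import pytest

from fdgdose import (
    BiokineticModel,
    CompartmentalSystem,
    ObservationSeries,
    SampleDefinition,
    goodness_of_fit,
    information_criteria,
    weighted_residuals,
)


class TestWeightedResiduals:
    def test_data_based(self):
        assert weighted_residuals([1.1], [1.0], sds=[0.1])[0] == pytest.approx(1.0)

    def test_perfect_prediction(self):
        assert weighted_residuals([1.0], [1.0], sds=[0.1])[0] == 0.0

    def test_model_based_ten_percent(self):
        # sigma = 0.1 x 2.0 = 0.2
        assert weighted_residuals([2.2], [2.0])[0] == pytest.approx(1.0)

    def test_zero_sigma_points_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            r = weighted_residuals([0.5, 1.1], [0.0, 1.0])
        assert len(r) == 1


class TestGoodnessOfFit:
    def test_published_fit_statistic(self):
        """SSWR 212 on 194 dof: p = 0.18, the fit is adequate."""
        p, rejected = goodness_of_fit(212.0, 194 + 21, 21)
        assert round(p, 2) == 0.18
        assert not rejected

    def test_zero_sswr_gives_p_one(self):
        p, rejected = goodness_of_fit(0.0, 12, 2)
        assert p == 1.0 and not rejected

    def test_standard_chi2_quantile(self):
        # chi2 upper 5% point at 10 dof is 18.307 (standard table value)
        p, rejected = goodness_of_fit(18.307, 12, 2)
        assert p == pytest.approx(0.05, abs=5e-4)

    def test_monotone_decreasing_in_sswr(self):
        ps = [goodness_of_fit(s, 30, 10)[0] for s in (5.0, 20.0, 40.0)]
        assert ps[0] > ps[1] > ps[2]

    def test_dof_must_be_positive(self):
        with pytest.raises(ValueError):
            goodness_of_fit(10.0, 5, 5)


class TestInformationCriteria:
    def test_gaussian_wls_forms(self):
        aic, bic = information_criteria(100.0, 100, 2)
        assert aic == pytest.approx(4.0)
        assert bic == pytest.approx(2 * np.log(100))

    def test_extra_parameter_flips_ordering(self):
        aic2, _ = information_criteria(100.0, 100, 2)
        aic3, _ = information_criteria(100.0, 100, 3)
        assert aic3 == pytest.approx(6.0)
        assert aic2 < aic3

    def test_zero_sswr_sentinel(self):
        with pytest.warns(UserWarning, match="undefined"):
            aic, bic = information_criteria(0.0, 10, 1)
        assert aic == -np.inf and bic == -np.inf

    def test_parsimony_on_nested_structures(self):
        """Data generated from the smaller structure: on average over
        replicate datasets both criteria prefer it over a superset structure
        with a spurious extra pathway (a single replicate can favour the
        larger model when the spurious term soaks up > 2 SSWR units)."""
        truth = CompartmentalSystem(["A", "B", "C"], [("A", "B", 0.8)], "A")
        times = np.linspace(0.1, 4.0, 12)
        defs = [SampleDefinition("a", (("A", 1.0),)), SampleDefinition("b", (("B", 1.0),))]
        solved = truth.solve(times)
        big_sys = CompartmentalSystem(
            ["A", "B", "C"], [("A", "B", 0.8), ("B", "C", 0.1)], "A"
        )
        d_aic, d_bic = [], []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            obs = [
                ObservationSeries(
                    sid, times,
                    y := solved.activity(comp) * (1 + 0.05 * rng.standard_normal(len(times))),
                    sds=0.05 * solved.activity(comp),
                    variance_model="data-based",
                )
                for sid, comp in (("a", "A"), ("b", "B"))
            ]
            small = BiokineticModel(obs, truth, defs, [("A", "B")]).fit(n_starts=3, seed=0)
            big = BiokineticModel(obs, big_sys, defs, "all").fit(n_starts=3, seed=0)
            d_aic.append(big.aic - small.aic)
            d_bic.append(big.bic - small.bic)
        assert np.mean(d_aic) > 0
        assert np.mean(d_bic) > 0
        assert np.mean(np.array(d_bic) > 0) >= 0.75


class TestFit:
    def test_one_compartment_washout_closed_form(self):
        """y = e^(-kt) at three times determines k = 0.8 exactly."""
        sys_ = CompartmentalSystem(["A", "B"], [("A", "B", 0.5)], "A")
        times = np.array([0.5, 1.0, 2.0])
        obs = [ObservationSeries("a", times, np.exp(-0.8 * times))]
        model = BiokineticModel(obs, sys_, [SampleDefinition("a", (("A", 1.0),))], [("A", "B")])
        res = model.fit(n_starts=5, seed=1)
        assert res.params.iloc[0] == pytest.approx(0.8, rel=1e-6)
        assert res.converged

    def test_noise_free_exact_recovery(self, default_system):
        """Noise-free synthetic data: estimates hit the generating values to
        optimiser tolerance and SSWR ~ 0 (exact-recovery limit)."""
        from fdgdose.synthetic import SyntheticDesign, generate_tac_dataset

        design = SyntheticDesign(truth=default_system, seed=3, noise_fraction=0.0)
        obs = generate_tac_dataset(design)
        free = [("Blood 1", "Brain"), ("Brain", "Blood 1"), ("Kidneys", "UB contents")]
        truth_vals = [default_system.rate(s, d) for s, d in free]
        perturbed = default_system.with_rates(
            {e: v * 2.0 for e, v in zip(free, truth_vals)}
        )
        model = BiokineticModel(obs, perturbed, design.sample_definitions, free)
        res = model.fit(n_starts=1, start_values=np.array(truth_vals) * 2.0)
        assert res.params.to_numpy() == pytest.approx(truth_vals, rel=1e-4)
        assert res.sswr < 1e-8

    def test_recovery_within_reported_uncertainty(self, default_system):
        """10% noise, a handful of free parameters: estimates land within
        3 reported SDs of the generating values and the fit is not rejected."""
        from fdgdose.synthetic import SyntheticDesign, generate_tac_dataset

        design = SyntheticDesign(truth=default_system, seed=11, noise_fraction=0.10)
        obs = generate_tac_dataset(design)
        free = [("Blood 1", "Liver"), ("Liver", "Blood 1"), ("Blood 1", "Brain")]
        truth_vals = np.array([default_system.rate(s, d) for s, d in free])
        model = BiokineticModel(obs, default_system, design.sample_definitions, free)
        res = model.fit(n_starts=3, seed=11, start_values=truth_vals)
        assert np.all(np.abs(res.params.to_numpy() - truth_vals) <= 3 * res.bse.to_numpy())
        assert not res.rejected

    def test_seeded_fit_is_bit_identical(self, two_compartment):
        times = np.array([0.5, 1.0, 2.0, 3.0])
        y = np.exp(-1.0 * times)
        obs = [ObservationSeries("a", times, y)]
        defs = [SampleDefinition("a", (("A", 1.0),))]
        r1 = BiokineticModel(obs, two_compartment, defs, [("A", "B")]).fit(n_starts=4, seed=99)
        r2 = BiokineticModel(obs, two_compartment, defs, [("A", "B")]).fit(n_starts=4, seed=99)
        assert (r1.params == r2.params).all()
        assert r1.sswr == r2.sswr

    def test_best_start_wins(self, two_compartment):
        """Multi-start never reports a worse objective than any single start."""
        times = np.array([0.5, 1.0, 2.0])
        obs = [ObservationSeries("a", times, np.exp(-0.8 * times))]
        defs = [SampleDefinition("a", (("A", 1.0),))]
        model = BiokineticModel(obs, two_compartment, defs, [("A", "B")])
        multi = model.fit(n_starts=6, seed=5)
        single = model.fit(n_starts=1, seed=5)
        assert multi.sswr <= single.sswr + 1e-12

    def test_dof_guard(self, two_compartment):
        obs = [ObservationSeries("a", [1.0], [0.5])]
        with pytest.raises(ValueError, match="dof"):
            BiokineticModel(obs, two_compartment, [SampleDefinition("a", (("A", 1.0),))], "all")

    def test_unknown_free_edge(self, two_compartment):
        obs = [ObservationSeries("a", [0.5, 1.0], [0.6, 0.4])]
        with pytest.raises(KeyError):
            BiokineticModel(
                obs, two_compartment, [SampleDefinition("a", (("A", 1.0),))], [("B", "A")]
            )

    def test_collinear_parameters_raise_unidentifiability(self):
        """Two parallel pathways out of the observed compartment are perfectly
        collinear when only their sum is identified."""
        sys_ = CompartmentalSystem(["A", "B", "C"], [("A", "B", 0.4), ("A", "C", 0.4)], "A")
        times = np.array([0.5, 1.0, 2.0, 4.0])
        obs = [ObservationSeries("a", times, np.exp(-0.8 * times))]
        model = BiokineticModel(obs, sys_, [SampleDefinition("a", (("A", 1.0),))], "all")
        with pytest.raises(np.linalg.LinAlgError, match="unidentifiable"):
            model.fit(n_starts=2, seed=0)


class TestResults:
    @pytest.fixture(scope="class")
    def fitted(self, default_system):
        from fdgdose.synthetic import SyntheticDesign, generate_tac_dataset

        design = SyntheticDesign(truth=default_system, seed=21, noise_fraction=0.10)
        obs = generate_tac_dataset(design)
        free = [("Blood 1", "Pancreas"), ("Pancreas", "Blood 1")]
        start = np.array([default_system.rate(s, d) for s, d in free])
        model = BiokineticModel(obs, default_system, design.sample_definitions, free)
        return model.fit(n_starts=2, seed=21, start_values=start)

    def test_cv_definition(self, fitted):
        # CV% = 100 x sd / estimate, e.g. 201 +/- 20 -> 10.0%
        assert fitted.cv_percent.to_numpy() == pytest.approx(
            100 * fitted.bse.to_numpy() / np.abs(fitted.params.to_numpy())
        )
        assert 100 * 20 / 201 == pytest.approx(10.0, abs=0.05)

    def test_correlation_matrix_properties(self, fitted):
        corr = fitted.corr.to_numpy()
        assert np.allclose(corr, corr.T)
        assert np.allclose(np.diag(corr), 1.0)
        assert (np.abs(corr) <= 1 + 1e-9).all()

    def test_dof_and_counts(self, fitted):
        assert fitted.df_resid == fitted.nobs - fitted.n_params > 0

    def test_summary_contains_key_statistics(self, fitted):
        text = fitted.summary()
        for token in ("SSWR", "p-value", "AIC", "cv %"):
            assert token in text
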