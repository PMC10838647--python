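"""Tests of the likelihood, parameter masks and Nelder-Mead fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hpaxis import (
    HPAModel,
    HPAParameters,
    ObservedDataset,
    ParameterMask,
    PopulationSpec,
    default_params,
    generate_population,
    neg_log_likelihood,
    visual_start,
)


def _noise_free_data(n=4, seed=7, **spec_kw):
    spec = PopulationSpec(n=n, gtot_cv=0.0, noise_cv=0.0, gr_expr_cv=0.0,
                          seed=seed, **spec_kw)
    return generate_population(spec, default_params())


class TestNegLogLikelihood:
    def test_matches_brute_force_gaussian_assembly(self, fixture_data):
        """Independent likelihood assembly: predict, then sum Gaussian
        log-densities with scipy.stats.norm, profiling sigma at its MLE."""
        p = default_params()
        model = HPAModel(fixture_data)
        pred = model.predict(p)
        resid = fixture_data.values - pred
        s2 = np.mean(resid**2)
        want = -stats.norm.logpdf(resid, scale=np.sqrt(s2)).sum()
        assert model.nll(p) == pytest.approx(want, abs=1e-10)

    def test_fixed_sigma_hand_computed_three_observations(self):
        """Three-point toy profile with fixed sigma against the Gaussian sum
        written out by hand."""
        p = default_params()
        df = pd.DataFrame({
            "individual_id": ["a"] * 3,
            "sampling_class": ["baseline", "stress_induced", "post_acth"],
            "time_min": [1.0, 25.0, 100.0],
            "gc_value": [5.0, 13.0, 80.0],
        })
        data = ObservedDataset.from_frame(df)
        model = HPAModel(data)
        pred = model.predict(p)
        sigma = 2.5
        hand = sum(
            0.5 * np.log(2 * np.pi * sigma**2) + (o - f) ** 2 / (2 * sigma**2)
            for o, f in zip([5.0, 13.0, 80.0], pred)
        )
        assert model.nll(p, sigma=sigma) == pytest.approx(hand, abs=1e-10)

    def test_duplicating_observations_doubles_nll(self, fixture_data):
        p = default_params()
        single = neg_log_likelihood(p, fixture_data)
        doubled_frame = pd.concat([fixture_data.frame] * 2, ignore_index=True)
        doubled = neg_log_likelihood(p, ObservedDataset(doubled_frame))
        assert doubled == pytest.approx(2 * single, rel=1e-12)

    def test_row_permutation_invariance(self, fixture_data):
        p = default_params()
        shuffled = fixture_data.frame.sample(frac=1.0, random_state=5).reset_index(drop=True)
        assert neg_log_likelihood(p, ObservedDataset(shuffled)) == pytest.approx(
            neg_log_likelihood(p, fixture_data), rel=1e-12)

    def test_truth_beats_perturbations_on_noise_free_data(self):
        data, _ = _noise_free_data()
        truth = default_params()
        model = HPAModel(data)
        nll_truth = model.nll(truth)
        for factor, name in [(1.3, "k_O"), (0.7, "b_O"), (1.5, "G_tot"), (0.5, "b")]:
            perturbed = truth.replace(**{name: getattr(truth, name) * factor})
            assert model.nll(perturbed) > nll_truth

    def test_lognormal_error_model(self, fixture_data):
        p = default_params()
        model = HPAModel(fixture_data, error_model="lognormal")
        pred = model.predict(p)
        resid = np.log(fixture_data.values) - np.log(pred)
        s2 = np.mean(resid**2)
        want = 0.5 * resid.size * (np.log(2 * np.pi * s2) + 1)
        assert model.nll(p) == pytest.approx(want, abs=1e-10)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            ObservedDataset.from_frame(pd.DataFrame())


class TestParameterMask:
    def test_zero_free_parameters_rejected(self):
        with pytest.raises(ValueError):
            ParameterMask(free=())

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError):
            ParameterMask(free=("not_a_rate",))

    def test_transform_roundtrip(self):
        mask = ParameterMask(free=("k_O", "G_tot"), bounds={"G_tot": (1.0, 50.0)})
        p = default_params().replace(k_O=2.5, G_tot=12.0)
        q = mask.to_params(mask.to_opt(p))
        assert q.k_O == pytest.approx(2.5, rel=1e-12)
        assert q.G_tot == pytest.approx(12.0, rel=1e-12)

    def test_bounds_enforced_by_construction(self):
        mask = ParameterMask(free=("G_tot",), bounds={"G_tot": (1.0, 50.0)})
        for x in (-50.0, -3.0, 0.0, 3.0, 50.0):
            v = mask.to_params(np.array([x])).G_tot
            assert 1.0 <= v <= 50.0  # extreme optimizer steps saturate at the box

    def test_start_outside_bounds_rejected(self):
        with pytest.raises(ValueError):
            ParameterMask(free=("G_tot",), bounds={"G_tot": (10.0, 50.0)})


class TestVisualStart:
    def test_no_contrast_gives_no_stressor(self):
        df = pd.DataFrame({
            "individual_id": ["a"] * 4,
            "sampling_class": ["baseline", "stress_induced", "post_dex", "post_acth"],
            "time_min": [1.0, 25.0, 70.0, 100.0],
            "gc_value": [6.0, 6.0, 5.0, 6.0],
        })
        start = visual_start(ObservedDataset.from_frame(df))
        assert start.b == pytest.approx(0.0, abs=1e-5)

    def test_scale_equivariance_of_production_start(self):
        data, _ = _noise_free_data()
        scaled = data.frame.copy()
        scaled["gc_value"] *= 3.0
        s1 = visual_start(data)
        s2 = visual_start(ObservedDataset(scaled))
        assert s2.k_O == pytest.approx(3.0 * s1.k_O, rel=1e-9)
        assert s2.b == pytest.approx(s1.b, rel=1e-9)      # contrast is relative
        assert s2.b_O == pytest.approx(s1.b_O, rel=1e-9)  # decay rate is a ratio

    def test_missing_classes_fall_back_with_warning(self):
        df = pd.DataFrame({
            "individual_id": ["a"],
            "sampling_class": ["post_acth"],
            "time_min": [100.0],
            "gc_value": [50.0],
        })
        with pytest.warns(UserWarning):
            start = visual_start(ObservedDataset.from_frame(df))
        assert start.b == default_params().b


class TestFit:
    def test_start_at_truth_stays_at_truth_noise_free(self):
        data, _ = _noise_free_data()
        truth = default_params()
        model = HPAModel(data)
        res = model.fit(mask=ParameterMask(free=("k_O", "b_O"), start=truth), maxiter=400)
        assert res.params.k_O == pytest.approx(truth.k_O, rel=1e-3)
        assert res.params.b_O == pytest.approx(truth.b_O, rel=1e-3)
        assert res.rss < 1e-6

    def test_recovers_displaced_parameters_noise_free(self):
        data, _ = _noise_free_data(n=8)
        truth = default_params()
        start = truth.replace(k_O=truth.k_O * 1.7, G_tot=truth.G_tot * 0.5)
        model = HPAModel(data)
        res = model.fit(mask=ParameterMask(free=("k_O", "G_tot"), start=start), maxiter=800)
        assert res.params.k_O == pytest.approx(truth.k_O, rel=0.02)
        assert res.params.G_tot == pytest.approx(truth.G_tot, rel=0.02)

    def test_seeded_multistart_is_bit_reproducible(self, fixture_data):
        model = HPAModel(fixture_data)
        mask = ParameterMask(free=("k_O", "G_tot"), start=default_params())
        r1 = model.fit(mask=mask, n_starts=3, seed=11, maxiter=150)
        r2 = model.fit(mask=mask, n_starts=3, seed=11, maxiter=150)
        assert r1.params == r2.params
        assert r1.llf == r2.llf

    def test_overparameterized_mask_warns(self):
        data, _ = _noise_free_data(n=1)  # 4 observations
        model = HPAModel(data)
        with pytest.warns(UserWarning, match="unidentifiable"):
            model.fit(mask=ParameterMask.protocol(start=default_params()), maxiter=5)

    def test_summary_and_json_roundtrip(self, fixture_fit, tmp_path):
        text = fixture_fit.summary()
        assert "log-likelihood" in text and "G_tot" in text
        out = tmp_path / "fit.json"
        fixture_fit.to_json(out)
        import json

        d = json.loads(out.read_text())
        assert d["llf"] == pytest.approx(fixture_fit.llf)
        restored = HPAParameters.from_dict(d["params"])
        assert restored == fixture_fit.params

    def test_fitted_values_frame_alignment(self, fixture_fit):
        df = fixture_fit.fittedvalues_frame()
        assert len(df) == fixture_fit.n_obs
        np.testing.assert_allclose(df["gc_value"] - df["fitted"], df["resid"])

    def test_individual_gr_mode_recovers_heterogeneous_gr(self):
        """With shared kinetics fixed at truth, per-individual G_tot fits
        recover each individual's receptor abundance from noise-free data."""
        spec = PopulationSpec(n=3, gtot_cv=0.6, noise_cv=0.0, gr_expr_cv=0.0, seed=21)
        data, truth = generate_population(spec, default_params())
        model = HPAModel(data)
        est = model.fit_individual_gr(shared=default_params())
        merged = est.merge(truth, on="individual_id", suffixes=("_est", "_true"))
        rel_err = np.abs(merged["G_tot_est"] - merged["G_tot_true"]) / merged["G_tot_true"]
        assert np.max(rel_err) < 0.05
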