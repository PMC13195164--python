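"""Generators: survival curves, reactivation counts, scenes, standard curves."""

import numpy as np
import pandas as pd
import pytest

from uvcled import imaging as I
from uvcled import synthetic as S


class TestSurvivalCurve:
    def test_single_population_first_order_identity(self):
        params = S.InactivationModelParams(kf_sensitive=1.0, p=0.0, C0=1e8)
        curve = S.simulate_survival_curve(params, [0, 2, 4, 6], noise=False, n_replicates=1)
        series = curve.log_reductions()
        assert np.allclose(series.L, [0, 2, 4, 6], atol=1e-12)

    def test_plateau_at_minus_log10_p(self):
        # with a fully shielded subpopulation (rho=0), L saturates at -log10(p)
        params = S.InactivationModelParams(kf_sensitive=2.0, p=0.01, rho=0.0, C0=1e9)
        L_inf = -np.log10(params.p)
        C = S.survival_model(params, 50.0)
        assert np.log10(params.C0 / C) == pytest.approx(L_inf, abs=1e-6)

    def test_poisson_counts_unbiased(self):
        """Mean plated count over many draws matches the model expectation."""
        params = S.InactivationModelParams(kf_sensitive=1.0, p=0.0, C0=1e8)
        F = 6.0
        expected_conc = float(S.survival_model(params, F))
        rng = np.random.default_rng(42)
        plating = S.PlatingProtocol()
        draws = [
            S._observe_concentration(expected_conc, plating, rng)[0] for _ in range(200)
        ]
        se = np.std(draws, ddof=1) / np.sqrt(len(draws))
        assert abs(np.mean(draws) - expected_conc) < 3 * se

    def test_zero_counts_censored(self):
        params = S.InactivationModelParams(kf_sensitive=1.0, p=0.0, C0=1e8)
        # at F=14 the model predicts 1e-6 CFU/mL: always below detection
        curve = S.simulate_survival_curve(params, [0, 14], seed=0)
        assert all(o.censored for o in curve.observations if o.fluence == 14)

    def test_rejects_empty_or_unsorted_fluences(self):
        params = S.InactivationModelParams(kf_sensitive=1.0)
        with pytest.raises(ValueError):
            S.simulate_survival_curve(params, [])
        with pytest.raises(ValueError):
            S.simulate_survival_curve(params, [4, 2, 0])

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            S.InactivationModelParams(kf_sensitive=-1.0)
        with pytest.raises(ValueError):
            S.InactivationModelParams(kf_sensitive=1.0, p=1.0)
        with pytest.raises(ValueError):
            S.InactivationModelParams(kf_sensitive=1.0, rho=1.2)

    def test_same_seed_bitwise_identical(self):
        params = S.InactivationModelParams(kf_sensitive=1.2)
        a = S.simulate_survival_curve(params, [0, 2, 4], seed=5)
        b = S.simulate_survival_curve(params, [0, 2, 4], seed=5)
        c = S.simulate_survival_curve(params, [0, 2, 4], seed=6)
        assert a.observations == b.observations
        assert a.observations != c.observations


class TestReactivationGenerator:
    def test_zero_recovery_means_identical_concentrations(self):
        params = S.InactivationModelParams(kf_sensitive=0.5)
        obs, _ = S.simulate_reactivation_counts(params, 0.0, "dark", noise=False)
        concs = {o.concentration for o in obs}
        assert len(concs) == 1

    def test_half_log_recovery_arithmetic(self):
        # L(0 h) = 7.0 and 0.5 log recovery at 18 h -> L(18 h) = 6.5
        params = S.InactivationModelParams(kf_sensitive=0.5, p=0.0, C0=1e8)
        obs, C0 = S.simulate_reactivation_counts(params, 0.5, "dark", noise=False)
        L = {o.time_h: np.log10(C0 / o.concentration) for o in obs}
        assert L[0.0] == pytest.approx(7.0, abs=1e-9)
        assert L[18.0] == pytest.approx(6.5, abs=1e-9)

    def test_negative_recovery_rejected(self):
        params = S.InactivationModelParams(kf_sensitive=0.5)
        with pytest.raises(ValueError):
            S.simulate_reactivation_counts(params, -0.1, "dark")


class TestSceneRendering:
    def test_empty_scene(self):
        scene = S.render_scene(S.SceneSpec(n_cells=0, image_shape=(64, 64)))
        assert scene.truth_mask.max() == 0
        assert len(scene.truth_table) == 0

    def test_truth_mask_table_bijection_and_no_overlap(self, default_scene):
        labels = set(np.unique(default_scene.truth_mask)) - {0}
        assert labels == set(default_scene.truth_table["label"])
        # rejection sampling leaves a gap: no label touches another
        import scipy.ndimage as ndi

        for lab in list(labels)[:20]:
            grown = ndi.binary_dilation(default_scene.truth_mask == lab)
            neighbours = set(np.unique(default_scene.truth_mask[grown])) - {0, lab}
            assert not neighbours

    def test_cells_fully_inside_frame(self, default_scene):
        m = default_scene.truth_mask
        assert m[0].max() == 0 and m[-1].max() == 0
        assert m[:, 0].max() == 0 and m[:, -1].max() == 0

    def test_kappa_zero_noiseless_symmetric(self, small_noiseless_scene):
        scene = small_noiseless_scene
        recs = I.per_cell_stats(scene.to_stack(), scene.truth_label_mask())
        g1 = [r.channel_stats["dna"].skewness for r in recs]
        assert abs(np.mean(g1)) <= 0.1

    def test_condensation_raises_skewness_paired_seeds(self):
        means = {}
        for kappa in (0.0, 0.8):
            spec = S.SceneSpec(n_cells=150, kappa=kappa, seed=3, image_shape=(400, 400))
            scene = S.render_scene(spec)
            recs = I.per_cell_stats(scene.to_stack(), scene.truth_label_mask())
            means[kappa] = np.mean([r.channel_stats["dna"].skewness for r in recs])
        assert means[0.8] > means[0.0]

    def test_mean_skewness_nondecreasing_in_kappa(self):
        means = []
        for kappa in (0.0, 0.25, 0.5, 0.75, 1.0):
            spec = S.SceneSpec(n_cells=200, kappa=kappa, seed=7)
            scene = S.render_scene(spec)
            recs = I.per_cell_stats(scene.to_stack(), scene.truth_label_mask())
            means.append(np.mean([r.channel_stats["dna"].skewness for r in recs]))
        assert all(a <= b for a, b in zip(means, means[1:]))

    def test_pi_state_flips_stain_dominance(self):
        spec = S.SceneSpec(
            n_cells=60, pi_positive_prob=0.5, seed=9, image_shape=(300, 300),
            shot_noise=False, gaussian_noise_sd=0.0,
        )
        scene = S.render_scene(spec)
        recs = I.per_cell_stats(scene.to_stack(), scene.truth_label_mask())
        truth = dict(zip(scene.truth_table["label"], scene.truth_table["pi_state"]))
        for r in recs:
            pi, syto = r.channel_stats["pi"].mean, r.channel_stats["syto9"].mean
            assert (pi > syto) == bool(truth[r.label])

    def test_same_seed_bit_identical_scenes(self):
        a = S.render_scene(S.SceneSpec(n_cells=40, seed=2, image_shape=(200, 200)))
        b = S.render_scene(S.SceneSpec(n_cells=40, seed=2, image_shape=(200, 200)))
        for name in a.channels:
            assert np.array_equal(a.channels[name], b.channels[name])
        assert np.array_equal(a.truth_mask, b.truth_mask)

    def test_overcrowded_scene_raises(self):
        spec = S.SceneSpec(
            n_cells=2000, image_shape=(96, 96), max_attempts_per_cell=20
        )
        with pytest.raises(RuntimeError):
            S.render_scene(spec)


class TestStandardCurveGenerator:
    def test_linear_point(self):
        df = S.simulate_standard_curve(
            {"model": "linear", "intercept": 0.1, "slope": 0.002}, [100.0]
        )
        assert df["absorbance"].iloc[0] == pytest.approx(0.3)

    def test_4pl_strictly_increasing(self):
        df = S.simulate_standard_curve(
            {"model": "4pl", "a": 0.1, "d": 2.0, "c": 50.0, "b": 1.2},
            [3.125, 6.25, 12.5, 25, 50, 100, 200, 400],
        )
        assert (np.diff(df["absorbance"]) > 0).all()

    def test_non_monotone_model_rejected(self):
        with pytest.raises(ValueError):
            S.simulate_standard_curve(
                {"model": "linear", "intercept": 0.1, "slope": -1.0}, [1, 2]
            )
        with pytest.raises(ValueError):
            S.simulate_standard_curve(
                {"model": "4pl", "a": 2.0, "d": 0.1, "c": 50.0, "b": 1.2}, [1, 2, 4, 8]
            )
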