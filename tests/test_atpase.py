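"""Coupled-assay rate extraction, mixture deconvolution and Δ statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clampdyn.atpase import (
    ActivityRecord,
    ProgressCurve,
    UndefinedFoldError,
    analyze_plate,
    build_delta_matrix,
    deconvolve_mixture,
    delta_asymm,
    delta_symm,
    fold_stimulation,
    heterodimer_activity,
    mixture_composition,
    rate_from_curve,
    subtract_background,
)
from clampdyn import synthetic as syn


def _linear_curve(rate_um_min, conc_um, eps=6220.0, t_max=40.0, n=21, a0=3.4):
    t = np.linspace(0.0, t_max, n)
    a340 = a0 - eps * rate_um_min * conc_um * 1e-6 * t
    return ProgressCurve(time=t, a340=a340, well_id="W1")


class TestRateFromCurve:
    def test_exact_recovery_from_linear_decay(self):
        curve = _linear_curve(rate_um_min=0.5, conc_um=2.5)
        rate = rate_from_curve(curve, hsp90_conc=2.5)
        assert rate == pytest.approx(0.5, rel=1e-9)

    def test_flat_curve_gives_zero_rate(self):
        t = np.linspace(0.0, 40.0, 21)
        curve = ProgressCurve(time=t, a340=np.full(21, 3.4))
        assert rate_from_curve(curve, hsp90_conc=2.5) == pytest.approx(0.0)

    def test_rising_a340_warns(self):
        t = np.linspace(0.0, 40.0, 21)
        curve = ProgressCurve(time=t, a340=3.0 + 0.01 * t)
        with pytest.warns(UserWarning, match="increases"):
            rate_from_curve(curve, hsp90_conc=2.5)

    def test_window_restriction(self):
        curve = _linear_curve(rate_um_min=0.5, conc_um=2.5)
        rate = rate_from_curve(curve, hsp90_conc=2.5, window=(0.0, 20.0))
        assert rate == pytest.approx(0.5, rel=1e-9)

    def test_automatic_window_avoids_depletion_curvature(self):
        # linear early, saturating late (NADH exhausted): automatic window
        # selection must recover the initial slope
        t = np.linspace(0.0, 60.0, 61)
        eps = 6220.0
        a0 = 3.4
        a340 = a0 - eps * 0.5 * 2.5 * 1e-6 * t
        a340[t > 40] = 0.4 + 0.25 * np.exp(-(t[t > 40] - 40.0) / 5.0)
        curve = ProgressCurve(time=t, a340=a340)
        rate = rate_from_curve(curve, hsp90_conc=2.5)
        assert rate == pytest.approx(0.5, rel=0.05)

    def test_noisy_ensemble_unbiased(self):
        rng = np.random.default_rng(0)
        rates = []
        for _ in range(200):
            curve = _linear_curve(rate_um_min=0.5, conc_um=2.5)
            noisy = ProgressCurve(
                time=curve.time,
                a340=curve.a340 + rng.normal(0, 0.002, curve.time.size),
            )
            rates.append(rate_from_curve(noisy, hsp90_conc=2.5, window=(0, 40)))
        assert np.mean(rates) == pytest.approx(0.5, rel=0.02)

    def test_too_few_points_rejected(self):
        t = np.linspace(0.0, 3.0, 4)
        curve = ProgressCurve(time=t, a340=3.4 - 0.01 * t)
        with pytest.raises(ValueError):
            rate_from_curve(curve, hsp90_conc=2.5)


class TestBackgroundSubtraction:
    def test_mean_difference(self):
        net, sd = subtract_background([10.0, 10.0], [2.0, 2.0])
        assert net == 8.0 and sd == 0.0

    def test_equal_means_give_zero(self):
        net, _ = subtract_background([5.0], [5.0])
        assert net == 0.0

    def test_negative_net_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            net, _ = subtract_background([1.0], [2.0])
        assert net == 0.0

    def test_sd_combined_in_quadrature(self):
        s = [10.0, 12.0, 8.0, 10.0]
        b = [1.0, 3.0, 2.0, 2.0]
        net, sd = subtract_background(s, b)
        assert net == pytest.approx(8.0)
        assert sd == pytest.approx(
            np.hypot(np.std(s, ddof=1), np.std(b, ddof=1))
        )

    def test_unbiased_over_simulated_plates(self):
        rng = np.random.default_rng(3)
        nets = []
        for _ in range(200):
            nets.append(
                subtract_background(
                    10.0 + rng.normal(0, 0.5, 4), 2.0 + rng.normal(0, 0.5, 4)
                )[0]
            )
        assert np.mean(nets) == pytest.approx(8.0, abs=0.1)


class TestMixtureAlgebra:
    def test_equimolar_gives_1_2_1(self):
        assert mixture_composition(0.5) == pytest.approx((0.25, 0.5, 0.25))

    def test_pure_subunit(self):
        assert mixture_composition(1.0) == (1.0, 0.0, 0.0)

    def test_binomial_expansion(self):
        assert mixture_composition(0.3) == pytest.approx((0.09, 0.42, 0.49))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mixture_composition(1.2)

    def test_dead_plus_stimulated_mixture_deconvolution(self):
        # mixture at 1.6× WT, dead homodimer, 2.5× stimulated homodimer
        hetd = heterodimer_activity(1.6, 0.0, 2.5)
        assert hetd == pytest.approx(1.95)
        assert delta_asymm(hetd, 1.6) == pytest.approx(0.35)

    def test_uniform_activity_is_fixed_point(self):
        assert heterodimer_activity(1.0, 1.0, 1.0) == pytest.approx(1.0)

    @given(
        st.floats(0.0, 5.0), st.floats(0.0, 5.0), st.floats(0.0, 5.0)
    )
    @settings(max_examples=200, deadline=None)
    def test_composition_deconvolution_roundtrip(self, h1, het, h2):
        mix = 0.25 * h1 + 0.5 * het + 0.25 * h2
        assert heterodimer_activity(mix, h1, h2) == pytest.approx(
            het, rel=1e-12, abs=1e-12
        )

    def test_delta_symm_examples(self):
        assert delta_symm(2.5) == pytest.approx(1.5)
        assert delta_symm(0.0) == pytest.approx(-1.0)
        assert delta_symm(1.0) == 0.0

    def test_delta_asymm_zero_at_homodimer_average(self):
        # mixture equal to the homodimer average is the null case
        h1, h2 = 2.0, 0.5
        mix = 0.25 * h1 + 0.25 * h2 + 0.5 * ((h1 + h2) / 2.0)
        hetd = heterodimer_activity(mix, h1, h2)
        assert delta_asymm(hetd, mix) == pytest.approx(0.0, abs=1e-12)


class TestDeltaMatrix:
    def test_wt_alone_gives_zero_diagonal(self):
        rec = ActivityRecord("WT", 0.5, 0.01, 1.0, 4, "WT", "WT")
        m = build_delta_matrix([rec])
        assert m.labels == ["WT"]
        assert m.values[0, 0] == 0.0

    def test_two_variant_toy_set_matches_hand_computation(self):
        # WT at 1.0, variant V at 2.0, mixture measured at 1.4:
        # hetD = (1.4 - 0.25*1 - 0.25*2)/0.5 = 1.3; Δ_asymm = -0.1
        records = [
            ActivityRecord("WT", 0.5, 0.0, 1.0, 4, "WT", "WT"),
            ActivityRecord("V", 1.0, 0.0, 2.0, 4, "V", "V"),
            ActivityRecord("WT:V", 0.7, 0.0, 1.4, 4, "WT", "V"),
        ]
        m = build_delta_matrix(records)
        i, j = m.labels.index("V"), m.labels.index("WT")
        assert m.values[m.labels.index("WT"), m.labels.index("WT")] == 0.0
        assert m.values[i, i] == pytest.approx(1.0)
        lo, hi = max(i, j), min(i, j)
        assert m.values[lo, hi] == pytest.approx(-0.1)

    def test_missing_homodimer_reference_annotated(self):
        records = [
            ActivityRecord("WT", 0.5, 0.0, 1.0, 4, "WT", "WT"),
            ActivityRecord("WT:V", 0.7, 0.0, 1.4, 4, "WT", "V"),
        ]
        m = build_delta_matrix(records)
        assert any("missing homodimer" in v for v in m.annotations.values())
        i, j = m.labels.index("V"), m.labels.index("WT")
        assert np.isnan(m.values[max(i, j), min(i, j)])

    def test_upper_triangle_undefined(self):
        records = [
            ActivityRecord("WT", 0.5, 0.0, 1.0, 4, "WT", "WT"),
            ActivityRecord("V", 1.0, 0.0, 2.0, 4, "V", "V"),
            ActivityRecord("WT:V", 0.7, 0.0, 1.4, 4, "WT", "V"),
        ]
        m = build_delta_matrix(records)
        for i in range(len(m.labels)):
            for j in range(i + 1, len(m.labels)):
                assert np.isnan(m.values[i, j])


class TestDeconvolveMixture:
    def test_worked_example_with_error_propagation(self):
        mix = ActivityRecord("A:B", 0.8, 0.0, 1.6, 4, "A", "B",
                             fractional_wt_sd=0.1)
        h1 = ActivityRecord("A", 0.0, 0.0, 0.0, 4, "A", "A",
                            fractional_wt_sd=0.05)
        h2 = ActivityRecord("B", 1.25, 0.0, 2.5, 4, "B", "B",
                            fractional_wt_sd=0.05)
        res = deconvolve_mixture(mix, h1, h2)
        assert res.hetd == pytest.approx(1.95)
        assert res.delta_asymm == pytest.approx(0.35)
        # hetD = 2·mix − 0.5·h1 − 0.5·h2
        assert res.hetd_sd == pytest.approx(
            np.sqrt((2 * 0.1) ** 2 + 2 * (0.5 * 0.05) ** 2)
        )
        assert res.delta_asymm_sd == pytest.approx(
            np.sqrt(0.1**2 + 2 * 0.25 * 0.05**2)
        )


class TestFoldStimulation:
    def test_examples(self):
        assert fold_stimulation(20.0, 1.0) == 20.0
        assert fold_stimulation(3.0, 3.0) == 1.0

    def test_zero_basal_rate_undefined(self):
        with pytest.raises(UndefinedFoldError):
            fold_stimulation(5.0, 0.0)


class TestPlatePipeline:
    def test_zero_noise_plate_reproduces_generator_deltas(self):
        curves, wellmap, truth = syn.gen_plate(
            noise_sd=0.0,
            seed=0,
            subunit_activity={"WT": 0.25, "L18D": 0.625, "F6D/F8D": 0.0},
            heterodimer_activity_override={("F6D/F8D", "L18D"): 0.975},
            aha1_fold={"WT": 20.0, "L18D": 6.0},
        )
        records, matrix, folds = analyze_plate(curves, wellmap)
        idx = {lab: i for i, lab in enumerate(matrix.labels)}
        for variant, expected in truth["delta_symm"].items():
            i = idx[variant]
            assert matrix.values[i, i] == pytest.approx(expected, abs=1e-9)
        for pair, expected in truth["delta_asymm"].items():
            a, b = pair.split(":")
            i, j = sorted((idx[a], idx[b]), reverse=True)
            assert matrix.values[i, j] == pytest.approx(expected, abs=1e-9)
        assert folds["WT"] == pytest.approx(20.0, rel=1e-9)
        assert folds["L18D"] == pytest.approx(6.0, rel=1e-9)

    def test_dead_homodimer_has_no_fold_entry(self):
        curves, wellmap, _ = syn.gen_plate(
            noise_sd=0.0,
            seed=0,
            subunit_activity={"WT": 0.25, "DEAD": 0.0},
            aha1_fold={"WT": 20.0, "DEAD": 6.0},
        )
        _, _, folds = analyze_plate(curves, wellmap)
        assert "WT" in folds and "DEAD" not in folds

    def test_missing_wt_reference_raises(self):
        curves, wellmap, _ = syn.gen_plate(noise_sd=0.0, seed=0)
        with pytest.raises(ValueError, match="normalisation"):
            analyze_plate(curves, wellmap, wt_label="NOSUCH")

    def test_delta_scale_invariance(self):
        # doubling every absolute rate leaves the Δ matrix unchanged
        base = {"WT": 0.25, "L18D": 0.625}
        out = []
        for scale in (1.0, 2.0):
            acts = {k: v * scale for k, v in base.items()}
            curves, wellmap, _ = syn.gen_plate(
                noise_sd=0.0, seed=0, subunit_activity=acts
            )
            _, matrix, _ = analyze_plate(curves, wellmap)
            out.append(matrix.values.copy())
        np.testing.assert_allclose(out[0], out[1], atol=1e-10)

    def test_delta_sd_shrinks_with_replicates(self):
        sds = []
        for n_reps in (4, 16):
            curves, wellmap, _ = syn.gen_plate(
                noise_sd=0.003, seed=12, n_reps=n_reps,
                subunit_activity={"WT": 0.25, "L18D": 0.625},
            )
            _, matrix, _ = analyze_plate(curves, wellmap)
            i = matrix.labels.index("L18D")
            sds.append(matrix.sds[i, i])
        # SEM-based propagation: 4x replicates ~ halves the SD
        assert sds[1] < 0.75 * sds[0]
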