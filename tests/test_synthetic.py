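"""Synthetic-data generators: decay traces, studies, stacks, profiles, matrices."""

import numpy as np
import pandas as pd
import pytest

from myostates import synthetic
from myostates.mant_atp import fit_decay, normalize
from myostates.types import BeamGeometry, ConditionEffects, DecayTruth, StudyDesign


class TestSimulateDecay:
    def test_no_decaying_component_gives_constant_one(self, time_grid):
        truth = DecayTruth(0.0, 15.0, 0.0, 200.0)
        trace = synthetic.simulate_decay(truth, time_grid, 0.0, seed=0,
                                         baseline_intensity=1.0, background_level=0.0)
        assert np.allclose(trace.raw_fluor, 1.0)

    def test_value_at_time_zero_is_exactly_one(self, time_grid, reference_truth):
        trace = synthetic.simulate_decay(reference_truth, time_grid, 0.0, seed=0)
        norm = normalize(trace)
        assert norm.norm_fluor[0] == 1.0

    def test_long_time_limit_equals_plateau(self, reference_truth):
        grid = np.array([0.0, 1e7])
        trace = synthetic.simulate_decay(reference_truth, grid, 0.0, seed=0)
        norm = normalize(trace)
        # plateau = 1 - 0.25 - 0.50, evaluated by hand
        assert norm.norm_fluor[-1] == pytest.approx(0.25, abs=1e-9)

    def test_invalid_truth_names_violated_invariant(self, time_grid):
        with pytest.raises(ValueError, match="t1_s"):
            synthetic.simulate_decay(DecayTruth(0.2, -1.0, 0.3, 100.0), time_grid)
        with pytest.raises(ValueError, match="exceeds 1"):
            synthetic.simulate_decay(DecayTruth(0.7, 15.0, 0.6, 100.0), time_grid)

    def test_refit_of_noiseless_trace_recovers_truth(self, time_grid, reference_truth):
        # round trip: generator -> normalization -> fit, relative error < 1e-6
        trace = synthetic.simulate_decay(reference_truth, time_grid, 0.0, seed=0)
        fit = fit_decay(normalize(trace))
        est = np.array([fit.p1_pct / 100, fit.t1_s, fit.p2_pct / 100, fit.t2_s])
        truth = np.array([0.25, 15.0, 0.50, 200.0])
        assert np.all(np.abs(est - truth) / truth < 1e-6)


class TestSimulateStudy:
    def test_trace_count_within_design_bounds(self):
        design = StudyDesign(conditions=("SA", "IBA", "torpor"), seed=11)
        traces, truth = synthetic.simulate_study(design)
        n = truth.shape[0]
        assert 3 * 5 * 8 <= n <= 3 * 5 * 12
        assert traces["fiber_id"].nunique() == n

    def test_same_seed_gives_identical_tables(self):
        design = StudyDesign(conditions=("SA",), animals_per_condition=2,
                             fibers_per_animal=(3, 5), seed=7)
        t1, tr1 = synthetic.simulate_study(design)
        t2, tr2 = synthetic.simulate_study(design)
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(tr1, tr2)

    def test_zero_variance_effects_share_one_truth(self):
        design = StudyDesign(conditions=("SA",), animals_per_condition=2,
                             fibers_per_animal=(3, 3), seed=3)
        effects = ConditionEffects(animal_cv=0.0, fiber_cv=0.0,
                                   animal_amp_sd=0.0, fiber_amp_sd=0.0)
        _, truth = synthetic.simulate_study(design, effects)
        for col in ("p1_frac", "t1_s", "p2_frac", "t2_s"):
            assert truth[col].nunique() == 1

    def test_labels_cover_every_trace(self):
        design = StudyDesign(conditions=("SA", "torpor"), animals_per_condition=2,
                             fibers_per_animal=(2, 3), temperatures_C=(20.0, 8.0),
                             seed=1)
        traces, _ = synthetic.simulate_study(design)
        assert set(traces["condition"]) == {"SA", "torpor"}
        assert set(traces["temperature_C"]) == {20.0, 8.0}
        assert set(traces["fiber_type"]) <= {"I", "II"}

    def test_between_animal_variance_grows_with_animal_component(self):
        # empirical between-animal variance of fiber-mean T1, monotone over
        # three settings of the animal variance component
        design = StudyDesign(conditions=("SA",), animals_per_condition=5,
                             fibers_per_animal=(4, 4))
        spread = []
        for cv in (0.02, 0.10, 0.30):
            vars_ = []
            for rep in range(100):
                d = StudyDesign(**{**design.__dict__, "seed": rep})
                effects = ConditionEffects(animal_cv=cv, fiber_cv=0.05)
                _, truth = synthetic.simulate_study(d, effects)
                vars_.append(truth.groupby("animal_id")["t1_s"].mean().var())
            spread.append(np.mean(vars_))
        assert spread[0] < spread[1] < spread[2]


class TestImageStack:
    def test_shape_matches_grid_and_frame(self, time_grid, reference_truth):
        trace = synthetic.simulate_decay(reference_truth, time_grid, 0.0, seed=0)
        stack, _, _ = synthetic.simulate_image_stack(trace, frame_shape=(64, 64))
        assert stack.shape == (61, 64, 64)

    def test_background_pixels_match_background_level(self, time_grid, reference_truth):
        trace = synthetic.simulate_decay(
            reference_truth, time_grid, 0.0, seed=0,
            baseline_intensity=500.0, background_level=50.0,
        )
        stack, fm, bm = synthetic.simulate_image_stack(trace)
        assert np.allclose(stack[:, bm[0]].mean(axis=1), 50.0)

    def test_tiff_round_trip_preserves_stack_and_masks(
        self, tmp_path, time_grid, reference_truth
    ):
        from myostates.mant_atp import extract_roi_traces

        trace = synthetic.simulate_decay(reference_truth, time_grid, 0.0, seed=0)
        stack, fm, bm = synthetic.simulate_image_stack(trace, frame_shape=(32, 32))
        synthetic.write_image_stack(stack, fm, bm, tmp_path / "fiber1")
        stack2, fm2, bm2 = synthetic.read_image_stack(tmp_path / "fiber1")
        assert stack2.shape == stack.shape
        for a, b in zip(fm + bm, fm2 + bm2):
            assert np.array_equal(a, b)
        fiber, background = extract_roi_traces(stack2, fm2, bm2)
        # float32 storage: round trip within single precision
        assert np.allclose(fiber, trace.raw_fluor, rtol=1e-6)
        assert np.allclose(background, trace.background_fluor, rtol=1e-6)

    def test_overlapping_rois_rejected(self, time_grid, reference_truth):
        trace = synthetic.simulate_decay(reference_truth, time_grid, 0.0, seed=0)
        m = np.zeros((64, 64), bool)
        m[10:20, 10:20] = True
        with pytest.raises(ValueError, match="overlap"):
            synthetic.simulate_image_stack(trace, roi_geometry=([m, m], [~m]))


class TestDiffractionProfile:
    def test_single_peak_lands_at_bragg_radius(self):
        # hand-evaluated Bragg geometry: r = L * tan(2 asin(lambda/(2 d)))
        geom = BeamGeometry(wavelength_nm=0.10, camera_length_m=2.14)
        d = 7.20
        prof = synthetic.simulate_diffraction_profile(
            [(d, 100.0, 0.1)], geom, background=(0.0, 0.0, 1.0), noise_sd=0.0
        )
        expected_r = 2.14 * np.tan(2 * np.arcsin(0.10 / (2 * d))) * 1e3
        r_max = prof.radius_mm[np.argmax(prof.intensity)]
        assert r_max == pytest.approx(expected_r, abs=np.diff(prof.radius_mm)[0])

    def test_zero_peaks_equals_background(self):
        prof = synthetic.simulate_diffraction_profile([], background=(5.0, 50.0, 10.0))
        expected = 5.0 + 50.0 * np.exp(-prof.radius_mm / 10.0)
        assert np.allclose(prof.intensity, expected)

    def test_out_of_range_peak_named_in_error(self):
        with pytest.raises(ValueError, match="d=500"):
            synthetic.simulate_diffraction_profile([(500.0, 10.0, 0.1)],
                                                   r_range_mm=(2.0, 60.0))

    def test_intensity_ratio_by_construction(self):
        from myostates import xray

        prof = synthetic.simulate_diffraction_profile(
            [(14.34, 100.0, 0.15), (7.17, 50.0, 0.12)], noise_sd=0.0
        )
        ms = xray.measure_reflections(prof, {"M3": 14.3, "M6": 7.2})
        assert ms["M6"].intensity / ms["M3"].intensity == pytest.approx(0.5, rel=0.01)


class TestAbundanceMatrix:
    def test_zero_de_fraction_has_no_de_truth(self):
        _, _, truth = synthetic.simulate_abundance_matrix(200, de_fraction=0.0, seed=0)
        assert not truth["is_de"].any()

    def test_de_shift_matches_requested_fold_change(self):
        mat, grp, truth = synthetic.simulate_abundance_matrix(
            2000, {"SA": 20, "torpor": 20}, de_fraction=0.2, log2_fc=2.0,
            feature_sd=0.05, missingness="off", seed=1,
        )
        de = truth.index[truth["is_de"]]
        a = mat.loc[de, grp.index[grp == "SA"]].mean(axis=1)
        b = mat.loc[de, grp.index[grp == "torpor"]].mean(axis=1)
        observed = (b - a) * np.sign(truth.loc[de, "log2_fc"])
        assert observed.mean() == pytest.approx(2.0, abs=0.05)

    def test_missingness_off_gives_complete_matrix(self):
        mat, _, _ = synthetic.simulate_abundance_matrix(100, missingness="off", seed=0)
        assert not mat.isna().any().any()

    def test_missingness_is_left_censored(self):
        mat, _, _ = synthetic.simulate_abundance_matrix(
            3000, missing_rate=0.2, seed=2
        )
        complete, _, _ = synthetic.simulate_abundance_matrix(
            3000, missing_rate=0.2, missingness="off", seed=2
        )
        missing = mat.isna().to_numpy()
        assert missing.any()
        # missing cells sit at systematically lower underlying abundance
        assert complete.to_numpy()[missing].mean() < complete.to_numpy()[~missing].mean() - 1.0
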