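"""Virtual-patient generator: determinism, closed-loop recovery, cohort draws."""

import numpy as np
import pytest

from ctgrad import (
    CohortPopulation,
    MIGrade,
    PatientSpec,
    ValidationError,
    apply_mi_correction,
    generate_cohort,
    generate_patient,
    generate_training_triples,
    minimal_orifice_area,
    peak_systolic_flow,
    tpg_power_law_ml_per_s,
)


class TestPatientSpec:
    def test_infeasible_volumes_rejected(self):
        with pytest.raises(ValidationError):
            PatientSpec(edv=50.0, esv=80.0)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValidationError):
            PatientSpec(volume_noise_ml=-1.0)

    def test_analytic_peak_flow(self):
        spec = PatientSpec(edv=136.0, esv=57.0, systole_duration=0.42)
        assert spec.peak_flow_analytic == pytest.approx(np.pi * 79 / 0.84)


class TestGeneratePatient:
    def test_deterministic_given_seed(self):
        a = generate_patient(PatientSpec(seed=5, volume_noise_ml=1.0, tpg_disagreement_mmhg=10.0))
        b = generate_patient(PatientSpec(seed=5, volume_noise_ml=1.0, tpg_disagreement_mmhg=10.0))
        np.testing.assert_array_equal(a.volume_series.volumes, b.volume_series.volumes)
        np.testing.assert_array_equal(a.lv_waveform.pressures, b.lv_waveform.pressures)
        for ca, cb in zip(a.valve_geometry.contours, b.valve_geometry.contours):
            np.testing.assert_array_equal(ca, cb)
        assert a.echo_velocity_ms == b.echo_velocity_ms

    def test_dense_noiseless_sampling_recovers_spec(self):
        spec = PatientSpec(seed=2, n_frames=50)
        patient = generate_patient(spec)
        q = peak_systolic_flow(patient.volume_series)
        assert q == pytest.approx(spec.peak_flow_analytic, rel=0.02)
        ava = minimal_orifice_area(patient.valve_geometry).area_cm2
        assert ava == pytest.approx(spec.true_ava, rel=0.01)

    def test_zero_noise_closed_loop_matches_forward_model(self, noiseless_patient):
        """Measuring the generated data end to end reproduces the forward
        model at the ground-truth (Q, AVA) within discretisation error."""
        patient = noiseless_patient
        q = peak_systolic_flow(patient.volume_series)
        q = apply_mi_correction(q, patient.spec.mi_grade)
        ava = minimal_orifice_area(patient.valve_geometry).area_cm2
        tpg_ct = tpg_power_law_ml_per_s(q, ava)
        assert tpg_ct == pytest.approx(patient.truth.tpg_model_mmhg, rel=0.02)

    def test_mi_grade_reduces_target_flow(self):
        clean = generate_patient(PatientSpec(seed=1, mi_grade=MIGrade.NONE))
        mi = generate_patient(PatientSpec(seed=1, mi_grade=MIGrade.MODERATE))
        assert mi.truth.q_aortic_mls == pytest.approx(0.7 * clean.truth.q_aortic_mls)
        assert mi.truth.tpg_model_mmhg < clean.truth.tpg_model_mmhg

    def test_echo_velocity_consistent_with_target_gradient(self, noiseless_patient):
        truth = noiseless_patient.truth
        assert 4.0 * truth.echo_velocity_ms**2 == pytest.approx(
            truth.tpg_catheter_mmhg, rel=1e-9
        )


class TestGenerateCohort:
    def test_same_seed_identical_table(self):
        a = generate_cohort(10, seed=3)
        b = generate_cohort(10, seed=3)
        assert a.equals(b)

    def test_single_patient_file_set(self, tmp_path):
        table = generate_cohort(1, seed=0, out_dir=tmp_path)
        assert len(table) == 1
        stem = table["id"].iloc[0]
        for suffix in ("_volumes.csv", "_lv.csv", "_ao.csv", "_valve.json"):
            assert (tmp_path / f"{stem}{suffix}").exists()
        assert (tmp_path / "cohort.csv").exists()

    def test_cohort_mean_ava_matches_population(self):
        tables = [generate_cohort(84, seed=s) for s in (1, 2, 3)]
        mean_ava = np.mean([t["ava"].mean() for t in tables])
        se = 0.25 / np.sqrt(3 * 84)
        assert abs(mean_ava - 0.79) < 3 * se + 0.02  # +2% planimetry tolerance

    def test_cohort_columns_and_ranges(self):
        t = generate_cohort(30, seed=9)
        assert t["id"].is_unique
        assert (t["tpg_ct"] >= 0).all() and (t["tpg_catheter"] >= 0).all()
        assert t["n_frames"].between(11, 20).all()
        assert set(t["mi_grade"]).issubset({"none", "mild", "moderate"})

    def test_coarse_frames_bias_prediction_error_positive(self):
        """Few reconstruction phases under-sample the ejection slope, so the
        model underestimates the gradient (positive catheter-minus-model
        error); dense sampling removes the bias."""
        coarse_pop = CohortPopulation(n_frames_range=(6, 10), tpg_disagreement_mmhg=0.0)
        dense_pop = CohortPopulation(n_frames_range=(18, 22), tpg_disagreement_mmhg=0.0)
        errs_coarse, errs_dense = [], []
        for seed in (11, 12):
            tc = generate_cohort(30, seed=seed, population=coarse_pop)
            td = generate_cohort(30, seed=seed, population=dense_pop)
            errs_coarse.append((tc["tpg_catheter"] - tc["tpg_ct"]).mean())
            errs_dense.append((td["tpg_catheter"] - td["tpg_ct"]).mean())
        assert all(e > 0 for e in errs_coarse)
        assert all(abs(e) < 5.0 for e in errs_dense)
        assert np.mean(errs_coarse) > np.mean(errs_dense)

    def test_invalid_population_rejected(self):
        with pytest.raises(ValidationError):
            CohortPopulation(mi_probabilities=(0.5, 0.5, 0.5, 0.0))


class TestGenerateTrainingTriples:
    def test_zero_noise_lies_on_model_surface(self):
        from ctgrad import DEFAULT_COEFFICIENTS as c

        for t in generate_training_triples(20, noise_sigma=0.0, seed=4):
            assert t.tpg == pytest.approx(t.q**c.b * t.ava ** (-c.c) * c.a, rel=1e-12)

    def test_reproducible_given_seed(self):
        assert generate_training_triples(10, seed=8) == generate_training_triples(10, seed=8)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValidationError):
            generate_training_triples(10, noise_sigma=-0.1)

    def test_ranges_respected(self):
        for t in generate_training_triples(50, seed=2):
            assert 0.1 <= t.q <= 0.6
            assert 0.31 <= t.ava <= 1.77
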