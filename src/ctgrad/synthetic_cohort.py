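"""Virtual patients and surrogate calibration data.

Real inputs to the pressure-gradient pipeline are dynamic CT segmentations,
catheter pressure traces and Doppler velocities, none of which can be
bundled.  This module generates synthetic stand-ins with the statistical
structure the method assumes, so that every pipeline stage — volume-curve
differencing, orifice planimetry, peak averaging, calibration and the
agreement statistics — can be exercised end to end with known ground truth.

A virtual patient consists of

* an LV volume curve: cosine ejection from EDV to ESV over the systole
  duration, cosine refilling over the rest of the cycle, sampled at the
  CT frame count (the analytic peak emptying rate is
  pi * (EDV - ESV) / (2 * T_systole));
* a tri-leaflet valve orifice: three circular-arc leaflet edges meeting at
  commissures, stacked over several annulus-parallel slices, scaled so the
  minimal projected area equals the prescribed AVA, then rigidly rotated
  and translated in 3D;
* LV and aortic pressure traces over four beats whose peak pressures differ
  by a target catheter gradient (the model-implied gradient plus a
  configurable modality-disagreement noise);
* an echo peak velocity consistent with that target gradient through the
  simplified Bernoulli relation.

Cohort-level defaults mirror the validation population the model was tested
on: AVA lognormal with mean 0.79 and SD 0.25 cm^2 (range-clipped to
0.31-1.77), aortic flow normal 296 +/- 106 ml/s truncated positive,
mitral-insufficiency grades none/mild/moderate with frequencies 9/59/16
out of 84, 43/84 female, CT heart rate 71 +/- 20 bpm and catheter heart
rate 63 +/- 13 bpm, and 11-20 CT frames per beat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .errors import ValidationError
from .model_core import (
    DEFAULT_COEFFICIENTS,
    MIGrade,
    MI_REDUCTION_FRACTIONS,
    ModelCoefficients,
    apply_mi_correction,
    tpg_power_law_ml_per_s,
)
from .calibration import TrainingTriple
from .units import hr_to_period_s
from .valve_geometry import ValveGeometry, minimal_orifice_area
from .ventricular_flow import VolumeSeries, peak_systolic_flow
from .waveform import PressureWaveform, tpg_catheter

__all__ = [
    "PatientSpec",
    "GroundTruth",
    "PatientData",
    "CohortPopulation",
    "generate_patient",
    "generate_cohort",
    "generate_training_triples",
]

_WAVEFORM_HZ = 250.0
_N_BEATS = 4
_SYSTOLIC_FRACTION = 0.35  # fraction of the pressure beat spent in systole
_AO_SYSTOLIC_MMHG = 113.0
_AO_DIASTOLIC_MMHG = 70.0
_LV_DIASTOLIC_MMHG = 8.0


@dataclass(frozen=True)
class PatientSpec:
    """Ground-truth parameters of one virtual patient.

    Defaults describe a typical severe-stenosis patient: stroke volume
    79 ml at 58 % ejection fraction, systole length tuned so the analytic
    peak flow is ~296 ml/s, AVA 0.79 cm^2, 20 CT frames per beat.  All
    noise amplitudes default to zero so the spec doubles as an exact
    closed-loop fixture.
    """

    edv: float = 136.0  # ml
    esv: float = 57.0  # ml
    systole_duration: float = 0.42  # s
    n_frames: int = 20
    true_ava: float = 0.79  # cm^2
    mi_grade: MIGrade = MIGrade.NONE
    hr_ct: float = 71.0  # 1/min
    hr_catheter: float = 63.0  # 1/min
    sex: str = "female"
    volume_noise_ml: float = 0.0
    pressure_noise_mmhg: float = 0.0
    echo_velocity_noise_ms: float = 0.0
    tpg_disagreement_mmhg: float = 0.0  # SD of catheter-vs-model disagreement
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.edv > self.esv > 0):
            raise ValidationError(
                f"need edv > esv > 0, got edv={self.edv}, esv={self.esv}"
            )
        if self.n_frames < 4:
            raise ValidationError(f"n_frames must be >= 4, got {self.n_frames}")
        if not self.true_ava > 0:
            raise ValidationError(f"true_ava must be positive, got {self.true_ava}")
        if not (self.hr_ct > 0 and self.hr_catheter > 0):
            raise ValidationError("heart rates must be positive")
        cycle = hr_to_period_s(self.hr_ct)
        if not 0 < self.systole_duration < cycle:
            raise ValidationError(
                f"systole_duration must lie within the cardiac cycle ({cycle:.3f} s)"
            )
        for name in (
            "volume_noise_ml",
            "pressure_noise_mmhg",
            "echo_velocity_noise_ms",
            "tpg_disagreement_mmhg",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")

    @property
    def stroke_volume(self) -> float:
        return self.edv - self.esv

    @property
    def peak_flow_analytic(self) -> float:
        """Analytic peak emptying rate of the cosine volume curve, ml/s."""
        return math.pi * self.stroke_volume / (2.0 * self.systole_duration)


@dataclass(frozen=True)
class GroundTruth:
    """Exact quantities the measurement pipeline should recover."""

    q_lv_mls: float  # analytic peak LV emptying rate, before MI correction
    q_aortic_mls: float  # after MI correction
    ava_cm2: float
    tpg_model_mmhg: float  # forward model at (q_aortic, ava)
    tpg_catheter_mmhg: float  # model + modality disagreement, floored at 0
    echo_velocity_ms: float


@dataclass(frozen=True)
class PatientData:
    spec: PatientSpec
    volume_series: VolumeSeries
    valve_geometry: ValveGeometry
    lv_waveform: PressureWaveform
    ao_waveform: PressureWaveform
    echo_velocity_ms: float
    truth: GroundTruth


# ---------------------------------------------------------------------------
# volume curve


def _volume_curve(spec: PatientSpec, t: np.ndarray) -> np.ndarray:
    """Cosine-ejection / cosine-filling LV volume over one cycle."""
    cycle = hr_to_period_s(spec.hr_ct)
    ts = spec.systole_duration
    amp = spec.stroke_volume / 2.0
    v = np.empty_like(t)
    systole = t <= ts
    v[systole] = spec.esv + amp * (1.0 + np.cos(np.pi * t[systole] / ts))
    v[~systole] = spec.esv + amp * (1.0 - np.cos(np.pi * (t[~systole] - ts) / (cycle - ts)))
    return v


def _sample_volume_series(spec: PatientSpec, rng: np.random.Generator) -> VolumeSeries:
    cycle = hr_to_period_s(spec.hr_ct)
    # frames cover one cycle without duplicating the end-diastolic frame
    t = np.arange(spec.n_frames) * cycle / spec.n_frames
    v = _volume_curve(spec, t)
    if spec.volume_noise_ml > 0:
        v = v + rng.normal(0.0, spec.volume_noise_ml, size=v.shape)
        v = np.clip(v, 1.0, None)
    return VolumeSeries(times=t, volumes=v)


# ---------------------------------------------------------------------------
# valve orifice


def _arc_through(p1: np.ndarray, p2: np.ndarray, apex: np.ndarray, n: int) -> np.ndarray:
    """Sample the circular arc from p1 to p2 passing through apex (2D)."""
    # circumcircle of the three points
    ax, ay = p1
    bx, by = apex
    cx, cy = p2
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay) + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx) + (cx**2 + cy**2) * (bx - ax)) / d
    centre = np.array([ux, uy])
    r = np.linalg.norm(p1 - centre)
    th1 = math.atan2(ay - uy, ax - ux)
    thm = math.atan2(by - uy, bx - ux)
    th2 = math.atan2(cy - uy, cx - ux)

    # sweep from th1 to th2 in the direction that passes through thm
    def _unwrap(target: float, start: float, ccw: bool) -> float:
        delta = (target - start) % (2.0 * math.pi)
        return start + (delta if ccw else delta - 2.0 * math.pi)

    for ccw in (True, False):
        end = _unwrap(th2, th1, ccw)
        mid = _unwrap(thm, th1, ccw)
        if min(th1, end) <= mid <= max(th1, end):
            theta = np.linspace(th1, end, n)
            return centre + r * np.column_stack([np.cos(theta), np.sin(theta)])
    raise AssertionError("arc construction failed")  # pragma: no cover


def _tri_leaflet_outline(bulge: float, n_per_arc: int = 60) -> np.ndarray:
    """Closed 2D outline of a tri-leaflet orifice of unit commissure radius.

    Three commissures sit on the unit circle; each leaflet free edge is a
    circular arc between adjacent commissures bowing toward the centre by
    ``bulge`` times the half-chord.
    """
    angles = np.deg2rad([90.0, 210.0, 330.0])
    commissures = np.column_stack([np.cos(angles), np.sin(angles)])
    pieces = []
    for i in range(3):
        p1 = commissures[i]
        p2 = commissures[(i + 1) % 3]
        chord_mid = (p1 + p2) / 2.0
        inward = -chord_mid / np.linalg.norm(chord_mid)
        sagitta = bulge * np.linalg.norm(p2 - p1) / 2.0
        apex = chord_mid + sagitta * inward
        arc = _arc_through(p1, p2, apex, n_per_arc)
        pieces.append(arc[:-1])  # avoid duplicating commissure vertices
    return np.vstack(pieces)


def _rotation_matrix(rng: np.random.Generator) -> np.ndarray:
    """Uniformly random rotation (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _build_valve_geometry(spec: PatientSpec, rng: np.random.Generator) -> ValveGeometry:
    """Orifice contour stack whose minimal projected area equals true AVA."""
    # above ~0.26 the arc tangents at the commissures leave their 120-degree
    # sector and adjacent arcs cross, so the bulge stays safely below that
    bulge = float(rng.uniform(0.05, 0.22))
    outline = _tri_leaflet_outline(bulge)
    base_area_mm2 = Polygon(outline).area
    target_mm2 = spec.true_ava * 100.0
    # area scales with the square of a uniform scale factor, so the factor
    # that hits the target area exactly is a square root
    outline = outline * math.sqrt(target_mm2 / base_area_mm2)

    # stack of annulus-parallel slices; the orifice narrows to the target
    # area at one interior slice and widens on both sides of it
    n_slices = 5
    min_slice = 2
    slice_spacing_mm = 1.5
    contours = []
    for j in range(n_slices):
        widen = math.sqrt(1.0 + 0.15 * (j - min_slice) ** 2)
        ring = outline * widen
        z = np.full(ring.shape[0], j * slice_spacing_mm)
        contours.append(np.column_stack([ring, z]))

    rot = _rotation_matrix(rng)
    origin = rng.uniform(-50.0, 50.0, size=3)
    contours = [c @ rot.T + origin for c in contours]
    normal = rot @ np.array([0.0, 0.0, 1.0])
    return ValveGeometry(annulus_point=origin, annulus_normal=normal, contours=tuple(contours))


# ---------------------------------------------------------------------------
# pressure waveforms


def _pressure_trace(
    hr: float,
    systolic: float,
    diastolic: float,
    peak_jitter: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    period = hr_to_period_s(hr)
    t = np.arange(0.0, _N_BEATS * period, 1.0 / _WAVEFORM_HZ)
    phase = (t % period) / period
    beat = np.minimum((t // period).astype(int), _N_BEATS - 1)
    p = np.full_like(t, diastolic)
    in_sys = phase < _SYSTOLIC_FRACTION
    shape = np.sin(np.pi * phase[in_sys] / _SYSTOLIC_FRACTION) ** 2
    amp = systolic - diastolic + peak_jitter[beat[in_sys]]
    p[in_sys] = diastolic + amp * shape
    return t, p


def _build_waveforms(
    spec: PatientSpec, tpg_target: float, rng: np.random.Generator
) -> tuple[PressureWaveform, PressureWaveform]:
    jitter_lv = rng.normal(0.0, spec.pressure_noise_mmhg, _N_BEATS) if spec.pressure_noise_mmhg else np.zeros(_N_BEATS)
    jitter_ao = rng.normal(0.0, spec.pressure_noise_mmhg, _N_BEATS) if spec.pressure_noise_mmhg else np.zeros(_N_BEATS)
    lv_sys = _AO_SYSTOLIC_MMHG + tpg_target
    t_lv, p_lv = _pressure_trace(spec.hr_catheter, lv_sys, _LV_DIASTOLIC_MMHG, jitter_lv)
    t_ao, p_ao = _pressure_trace(spec.hr_catheter, _AO_SYSTOLIC_MMHG, _AO_DIASTOLIC_MMHG, jitter_ao)
    lv = PressureWaveform(times=t_lv, pressures=p_lv, site="left_ventricle")
    ao = PressureWaveform(times=t_ao, pressures=p_ao, site="ascending_aorta")
    return lv, ao


# ---------------------------------------------------------------------------
# patient and cohort generation


def generate_patient(
    spec: PatientSpec, coeffs: ModelCoefficients = DEFAULT_COEFFICIENTS
) -> PatientData:
    """Generate the full synthetic file set for one virtual patient.

    Deterministic given ``spec.seed``.  With all noise amplitudes zero, the
    measurement pipeline applied to the generated data recovers the ground
    truth up to the discretisation error of the frame sampling.
    """
    rng = np.random.default_rng(spec.seed)
    series = _sample_volume_series(spec, rng)
    geometry = _build_valve_geometry(spec, rng)

    q_lv = spec.peak_flow_analytic
    q_aortic = apply_mi_correction(q_lv, spec.mi_grade)
    tpg_model = tpg_power_law_ml_per_s(q_aortic, spec.true_ava, coeffs)

    disagreement = (
        rng.normal(0.0, spec.tpg_disagreement_mmhg) if spec.tpg_disagreement_mmhg else 0.0
    )
    tpg_cath = max(0.0, tpg_model + disagreement)
    lv, ao = _build_waveforms(spec, tpg_cath, rng)

    v_echo = math.sqrt(tpg_cath / 4.0)
    if spec.echo_velocity_noise_ms:
        v_echo = max(0.0, v_echo + rng.normal(0.0, spec.echo_velocity_noise_ms))

    truth = GroundTruth(
        q_lv_mls=q_lv,
        q_aortic_mls=q_aortic,
        ava_cm2=spec.true_ava,
        tpg_model_mmhg=tpg_model,
        tpg_catheter_mmhg=tpg_cath,
        echo_velocity_ms=v_echo,
    )
    return PatientData(
        spec=spec,
        volume_series=series,
        valve_geometry=geometry,
        lv_waveform=lv,
        ao_waveform=ao,
        echo_velocity_ms=v_echo,
        truth=truth,
    )


@dataclass(frozen=True)
class CohortPopulation:
    """Population distributions a cohort is drawn from.

    Defaults reproduce the validation cohort's descriptive statistics; see
    the module docstring.  ``n_frames_range`` is inclusive on both ends.
    """

    ava_mean: float = 0.79  # cm^2
    ava_sd: float = 0.25
    ava_range: tuple = (0.31, 1.77)
    q_mean: float = 296.0  # aortic (post-correction) peak flow, ml/s
    q_sd: float = 106.0
    q_range: tuple = (98.0, 584.0)
    sv_mean: float = 79.1  # ml
    sv_sd: float = 24.9
    sv_range: tuple = (25.9, 138.7)
    ef_mean: float = 58.0  # %
    ef_sd: float = 15.0
    ef_range: tuple = (19.0, 83.0)
    hr_ct_mean: float = 71.0
    hr_ct_sd: float = 20.0
    hr_ct_range: tuple = (37.0, 132.0)
    hr_cath_mean: float = 63.0
    hr_cath_sd: float = 13.0
    hr_cath_range: tuple = (39.0, 108.0)
    n_frames_range: tuple = (11, 20)
    mi_probabilities: tuple = (9 / 84, 59 / 84, 16 / 84, 0.0)  # none/mild/moderate/severe
    female_fraction: float = 43 / 84
    # parametric model-based segmentation yields smooth volume curves, so
    # frame-to-frame jitter is small; large white noise would artificially
    # inflate the maximum finite-difference slope
    volume_noise_ml: float = 0.5
    pressure_noise_mmhg: float = 2.0
    echo_velocity_noise_ms: float = 0.1
    tpg_disagreement_mmhg: float = 15.0

    def __post_init__(self) -> None:
        if abs(sum(self.mi_probabilities) - 1.0) > 1e-9:
            raise ValidationError("mi_probabilities must sum to 1")
        for name in ("ava_sd", "q_sd", "sv_sd", "ef_sd", "hr_ct_sd", "hr_cath_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        lo, hi = self.n_frames_range
        if not (4 <= lo <= hi):
            raise ValidationError("n_frames_range must satisfy 4 <= lo <= hi")


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


_MI_ORDER = (MIGrade.NONE, MIGrade.MILD, MIGrade.MODERATE, MIGrade.SEVERE)


def _draw_spec(
    pop: CohortPopulation, rng: np.random.Generator, patient_seed: int
) -> PatientSpec:
    mu, sigma = _lognormal_params(pop.ava_mean, pop.ava_sd)
    ava = float(np.clip(rng.lognormal(mu, sigma), *pop.ava_range))

    q_aortic = float(np.clip(rng.normal(pop.q_mean, pop.q_sd), *pop.q_range))
    mi = _MI_ORDER[rng.choice(4, p=pop.mi_probabilities)]
    q_lv = q_aortic / (1.0 - MI_REDUCTION_FRACTIONS[mi])

    sv = float(np.clip(rng.normal(pop.sv_mean, pop.sv_sd), *pop.sv_range))
    ef = float(np.clip(rng.normal(pop.ef_mean, pop.ef_sd), *pop.ef_range))
    edv = sv / (ef / 100.0)
    esv = edv - sv

    hr_ct = float(np.clip(rng.normal(pop.hr_ct_mean, pop.hr_ct_sd), *pop.hr_ct_range))
    hr_cath = float(np.clip(rng.normal(pop.hr_cath_mean, pop.hr_cath_sd), *pop.hr_cath_range))

    # systole length that makes the analytic peak emptying rate equal q_lv;
    # when that would exceed 60 % of the cycle, shorten the stroke volume
    # instead so the drawn flow rate is preserved
    ts = math.pi * sv / (2.0 * q_lv)
    ts_cap = 0.6 * hr_to_period_s(hr_ct)
    if ts > ts_cap:
        ts = ts_cap
        sv = 2.0 * q_lv * ts / math.pi
        edv = sv / (ef / 100.0)
        esv = edv - sv

    n_frames = int(rng.integers(pop.n_frames_range[0], pop.n_frames_range[1] + 1))
    sex = "female" if rng.random() < pop.female_fraction else "male"

    return PatientSpec(
        edv=edv,
        esv=esv,
        systole_duration=ts,
        n_frames=n_frames,
        true_ava=ava,
        mi_grade=mi,
        hr_ct=hr_ct,
        hr_catheter=hr_cath,
        sex=sex,
        volume_noise_ml=pop.volume_noise_ml,
        pressure_noise_mmhg=pop.pressure_noise_mmhg,
        echo_velocity_noise_ms=pop.echo_velocity_noise_ms,
        tpg_disagreement_mmhg=pop.tpg_disagreement_mmhg,
        seed=patient_seed,
    )


def generate_cohort(
    n: int,
    seed: int,
    population: Optional[CohortPopulation] = None,
    coeffs: ModelCoefficients = DEFAULT_COEFFICIENTS,
    out_dir: Optional[Path] = None,
) -> pd.DataFrame:
    """Generate ``n`` virtual patients and run the measurement pipeline on each.

    Returns the cohort table with one row per patient: measured flow and
    valve area, the three gradient estimates (power-law model from measured
    inputs, catheter peaks, Bernoulli echo), heart rates, MI grade, sex,
    frame count and a low-flow low-gradient flag (severe-by-area orifice,
    < 1 cm^2, with a sub-threshold catheter gradient and flow below the
    cohort's low-flow cut of 210 ml/s).  Patients draw independent random
    streams spawned from the cohort seed, so the table is reproducible and
    insensitive to patient order.  With ``out_dir`` set, per-patient CSV/JSON
    files and the cohort CSV are written there.
    """
    if n < 1:
        raise ValidationError(f"cohort size must be >= 1, got {n}")
    pop = population or CohortPopulation()
    root = np.random.SeedSequence(seed)
    draw_rng = np.random.default_rng(root.spawn(1)[0])
    patient_seeds = [int(s.generate_state(1)[0] % 2**31) for s in root.spawn(n + 1)[1:]]

    rows = []
    patients = []
    for i in range(n):
        spec = _draw_spec(pop, draw_rng, patient_seeds[i])
        patient = generate_patient(spec, coeffs)
        patients.append(patient)

        q_meas = peak_systolic_flow(patient.volume_series)
        q_corrected = apply_mi_correction(q_meas, spec.mi_grade)
        ava_meas = minimal_orifice_area(patient.valve_geometry).area_cm2
        tpg_ct = tpg_power_law_ml_per_s(q_corrected, ava_meas, coeffs)
        tpg_cath = max(
            0.0,
            tpg_catheter(
                patient.lv_waveform, patient.ao_waveform, expected_hr=spec.hr_catheter
            ),
        )
        tpg_echo = 4.0 * patient.echo_velocity_ms**2
        lflg = bool(ava_meas < 1.0 and q_corrected < 210.0 and tpg_cath < 64.0)

        rows.append(
            {
                "id": f"vp{i:03d}",
                "tpg_ct": tpg_ct,
                "tpg_catheter": tpg_cath,
                "tpg_echo": tpg_echo,
                "hr_ct": spec.hr_ct,
                "hr_catheter": spec.hr_catheter,
                "mi_grade": spec.mi_grade.value,
                "sex": spec.sex,
                "n_frames": spec.n_frames,
                "low_flow_low_gradient": lflg,
                "q": q_corrected,
                "ava": ava_meas,
            }
        )

    table = pd.DataFrame(rows)
    if out_dir is not None:
        from . import io  # local import: io depends on the measurement types

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for row, patient in zip(rows, patients):
            stem = out / row["id"]
            io.write_volume_series(patient.volume_series, f"{stem}_volumes.csv")
            io.write_waveform(patient.lv_waveform, f"{stem}_lv.csv")
            io.write_waveform(patient.ao_waveform, f"{stem}_ao.csv")
            io.write_geometry(patient.valve_geometry, f"{stem}_valve.json")
        io.write_cohort(table, out / "cohort.csv")
    return table


def generate_training_triples(
    n: int,
    coeffs: ModelCoefficients = DEFAULT_COEFFICIENTS,
    noise_sigma: float = 0.0,
    seed: int = 0,
    q_range: tuple = (0.1, 0.6),
    ava_range: tuple = (0.31, 1.77),
) -> list[TrainingTriple]:
    """Surrogate calibration triples in place of high-fidelity simulations.

    (Q, AVA) pairs are drawn log-uniformly within the stated ranges (l/s and
    cm^2) and the gradient is the forward model times a multiplicative
    lognormal factor exp(N(0, noise_sigma)); ``noise_sigma=0`` puts the
    triples exactly on the model surface.
    """
    if n < 4:
        raise ValidationError(f"need n >= 4 triples, got {n}")
    if noise_sigma < 0:
        raise ValidationError(f"noise_sigma must be non-negative, got {noise_sigma}")
    rng = np.random.default_rng(seed)
    q = np.exp(rng.uniform(math.log(q_range[0]), math.log(q_range[1]), n))
    ava = np.exp(rng.uniform(math.log(ava_range[0]), math.log(ava_range[1]), n))
    tpg = coeffs.a * q**coeffs.b * ava ** (-coeffs.c)
    if noise_sigma > 0:
        tpg = tpg * np.exp(rng.normal(0.0, noise_sigma, n))
    return [TrainingTriple(q=float(qi), ava=float(ai), tpg=float(ti)) for qi, ai, ti in zip(q, ava, tpg)]
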