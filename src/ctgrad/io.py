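"""File formats and the per-patient pipeline.

All tabular files are comma-delimited UTF-8 CSV with a mandatory header of
unit-suffixed column names (``time_s``, ``volume_ml``, ``pressure_mmhg``),
so a file in the wrong unit fails loudly instead of producing a silent
1000-fold error.  Valve geometry travels as JSON
``{"annulus_point": [...], "annulus_normal": [...], "contours": [[[x,y,z],...], ...]}``
in mm.  Parse errors name the offending column and data row.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from .errors import CtgradError, ParseError, ValidationError
from .model_core import (
    DEFAULT_COEFFICIENTS,
    MI_REDUCTION_FRACTIONS,
    MIGrade,
    ModelCoefficients,
    SEVERITY_THRESHOLD_MMHG,
    apply_mi_correction,
    grade_severity,
    tpg_bernoulli,
    tpg_power_law_ml_per_s,
)
from .valve_geometry import ValveGeometry, minimal_orifice_area
from .ventricular_flow import VolumeSeries, peak_systolic_flow
from .waveform import PressureWaveform, cycle_peaks, tpg_catheter

__all__ = [
    "RunConfig",
    "read_volume_series",
    "write_volume_series",
    "read_waveform",
    "write_waveform",
    "read_geometry",
    "write_geometry",
    "read_cohort",
    "write_cohort",
    "run_pipeline",
]

PathLike = Union[str, Path]

REPORT_SCHEMA = "ctgrad-report/1"

COHORT_COLUMNS = [
    "id",
    "tpg_ct",
    "tpg_catheter",
    "tpg_echo",
    "hr_ct",
    "hr_catheter",
    "mi_grade",
    "sex",
    "n_frames",
    "low_flow_low_gradient",
    "q",
    "ava",
]


@dataclass(frozen=True)
class RunConfig:
    """Run-wide configuration for the per-patient pipeline."""

    coefficients: ModelCoefficients = DEFAULT_COEFFICIENTS
    mi_reductions: Mapping[MIGrade, float] = field(
        default_factory=lambda: dict(MI_REDUCTION_FRACTIONS)
    )
    severity_threshold: float = SEVERITY_THRESHOLD_MMHG
    bsa_formula: str = "du_bois"
    alpha: float = 0.05
    output_precision: int = 1  # decimals at the reporting layer only

    def __post_init__(self) -> None:
        if not self.severity_threshold > 0:
            raise ValidationError("severity threshold must be positive")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")

    @classmethod
    def from_file(cls, path: PathLike) -> "RunConfig":
        """Load configuration from a JSON or YAML file.

        Recognised keys: ``coefficients`` (inline ``{a,b,c}`` mapping or a
        path to a coefficient JSON), ``mi_reductions`` (grade -> fraction),
        ``severity_threshold``, ``bsa_formula``, ``alpha``,
        ``output_precision``.
        """
        p = Path(path)
        text = p.read_text()
        if p.suffix in (".yaml", ".yml"):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        if not isinstance(raw, dict):
            raise ParseError(f"{p}: config must be a mapping")
        kwargs: dict = {}
        if "coefficients" in raw:
            c = raw["coefficients"]
            if isinstance(c, str):
                coeff_path = Path(c)
                if not coeff_path.is_absolute():
                    coeff_path = p.parent / coeff_path
                if not coeff_path.exists():
                    raise ValidationError(f"coefficient file not found: {coeff_path}")
                kwargs["coefficients"] = ModelCoefficients.from_json(coeff_path)
            else:
                kwargs["coefficients"] = ModelCoefficients.from_dict(c)
        if "mi_reductions" in raw:
            kwargs["mi_reductions"] = {
                MIGrade.parse(k): float(v) for k, v in raw["mi_reductions"].items()
            }
        for key in ("severity_threshold", "bsa_formula", "alpha", "output_precision"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


def _read_csv(path: PathLike, required: list[str]) -> pd.DataFrame:
    p = Path(path)
    try:
        df = pd.read_csv(p)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise ParseError(f"{p}: cannot parse CSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(
            f"{p}: missing required column(s) {missing}; found {list(df.columns)}. "
            "Column names carry unit suffixes (e.g. volume_ml) — check units."
        )
    return df


def _first_bad_row(mask: "pd.Series") -> int:
    """1-based data-file line of the first True entry (header is line 1)."""
    return int(mask.idxmax()) + 2


# ---------------------------------------------------------------------------
# volume series


def read_volume_series(path: PathLike) -> VolumeSeries:
    df = _read_csv(path, ["time_s", "volume_ml"])
    bad = ~np.isfinite(df["volume_ml"]) | (df["volume_ml"] <= 0)
    if bad.any():
        raise ParseError(
            f"{path}: non-positive or missing volume_ml at line {_first_bad_row(bad)}"
        )
    try:
        return VolumeSeries(times=df["time_s"].to_numpy(), volumes=df["volume_ml"].to_numpy())
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_volume_series(series: VolumeSeries, path: PathLike) -> None:
    pd.DataFrame({"time_s": series.times, "volume_ml": series.volumes}).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# pressure waveforms


def read_waveform(path: PathLike, site: str) -> PressureWaveform:
    df = _read_csv(path, ["time_s", "pressure_mmhg"])
    bad = ~np.isfinite(df["pressure_mmhg"])
    if bad.any():
        raise ParseError(
            f"{path}: missing or non-finite pressure_mmhg at line {_first_bad_row(bad)}"
        )
    try:
        return PressureWaveform(
            times=df["time_s"].to_numpy(),
            pressures=df["pressure_mmhg"].to_numpy(),
            site=site,
        )
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_waveform(wave: PressureWaveform, path: PathLike) -> None:
    pd.DataFrame({"time_s": wave.times, "pressure_mmhg": wave.pressures}).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# valve geometry


def read_geometry(path: PathLike) -> ValveGeometry:
    p = Path(path)
    try:
        raw = json.loads(p.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{p}: invalid JSON ({exc})") from exc
    for key in ("annulus_point", "annulus_normal", "contours"):
        if key not in raw:
            raise ParseError(f"{p}: geometry JSON missing key {key!r}")
    try:
        return ValveGeometry(
            annulus_point=np.asarray(raw["annulus_point"], dtype=float),
            annulus_normal=np.asarray(raw["annulus_normal"], dtype=float),
            contours=tuple(np.asarray(c, dtype=float) for c in raw["contours"]),
        )
    except (ValidationError, ValueError) as exc:
        raise ParseError(f"{p}: {exc}") from exc


def write_geometry(geom: ValveGeometry, path: PathLike) -> None:
    payload = {
        "annulus_point": geom.annulus_point.tolist(),
        "annulus_normal": geom.annulus_normal.tolist(),
        "contours": [c.tolist() for c in geom.contours],
    }
    Path(path).write_text(json.dumps(payload))


# ---------------------------------------------------------------------------
# cohort table


def read_cohort(path: PathLike) -> pd.DataFrame:
    """Cohort table: one row per patient, missing values as empty cells."""
    df = _read_csv(path, ["id", "tpg_ct", "tpg_catheter"])
    dup = df["id"].duplicated()
    if dup.any():
        raise ValidationError(
            f"{path}: duplicate patient id {df['id'][dup].iloc[0]!r} "
            f"at line {_first_bad_row(dup)}"
        )
    for col in ("tpg_ct", "tpg_catheter", "tpg_echo", "q", "ava"):
        if col in df.columns:
            bad = df[col].notna() & (df[col] < 0)
            if bad.any():
                raise ValidationError(
                    f"{path}: negative {col} at line {_first_bad_row(bad)}"
                )
    if "mi_grade" in df.columns:
        df["mi_grade"] = [
            MIGrade.parse(g).value if isinstance(g, str) else g for g in df["mi_grade"]
        ]
    return df


def write_cohort(table: pd.DataFrame, path: PathLike) -> None:
    table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# per-patient pipeline


def run_pipeline(
    volumes_path: PathLike,
    geometry_path: PathLike,
    lv_path: Optional[PathLike] = None,
    ao_path: Optional[PathLike] = None,
    echo_velocity_ms: Optional[float] = None,
    mi_grade: Union[str, MIGrade] = MIGrade.NONE,
    expected_hr: Optional[float] = None,
    config: Optional[RunConfig] = None,
    patient_id: str = "patient",
) -> dict:
    """Run the full estimation chain for one patient and return the record.

    Computes flow from the volume curve, applies the MI correction, measures
    the planimetric AVA, evaluates the power-law gradient, and — when the
    corresponding inputs are present — the catheter and echo gradients with
    their severity grades.  Missing echo or catheter inputs yield ``None``
    fields, not failures; any stage error is re-raised with the patient id
    and stage attached.
    """
    cfg = config or RunConfig()

    def _stage(name: str, fn):
        try:
            return fn()
        except CtgradError as exc:
            raise type(exc)(f"[{patient_id}] stage {name!r}: {exc}") from exc

    series = _stage("volumes", lambda: read_volume_series(volumes_path))
    q_raw = _stage("peak_flow", lambda: peak_systolic_flow(series))
    grade = MIGrade.parse(mi_grade)
    q_corrected = apply_mi_correction(q_raw, grade, cfg.mi_reductions)

    geom = _stage("geometry", lambda: read_geometry(geometry_path))
    orifice = _stage("ava", lambda: minimal_orifice_area(geom))

    tpg_ct = tpg_power_law_ml_per_s(q_corrected, orifice.area_cm2, cfg.coefficients)
    record = {
        "schema": REPORT_SCHEMA,
        "id": patient_id,
        "q_raw_mls": q_raw,
        "mi_grade": grade.value,
        "q_mls": q_corrected,
        "ava_cm2": orifice.area_cm2,
        "ava_slice_index": orifice.slice_index,
        "tpg_ct_mmhg": tpg_ct,
        "grade_ct": grade_severity(tpg_ct, cfg.severity_threshold).label,
        "tpg_catheter_mmhg": None,
        "grade_catheter": None,
        "lv_peaks_mmhg": None,
        "ao_peaks_mmhg": None,
        "tpg_echo_mmhg": None,
        "grade_echo": None,
    }

    if lv_path is not None and ao_path is not None:
        lv = _stage("lv_waveform", lambda: read_waveform(lv_path, "left_ventricle"))
        ao = _stage("ao_waveform", lambda: read_waveform(ao_path, "ascending_aorta"))
        record["lv_peaks_mmhg"] = [float(v) for v in _stage("lv_peaks", lambda: cycle_peaks(lv, expected_hr))]
        record["ao_peaks_mmhg"] = [float(v) for v in _stage("ao_peaks", lambda: cycle_peaks(ao, expected_hr))]
        tpg_cath = _stage("tpg_catheter", lambda: tpg_catheter(lv, ao, expected_hr))
        record["tpg_catheter_mmhg"] = tpg_cath
        if tpg_cath >= 0:
            record["grade_catheter"] = grade_severity(tpg_cath, cfg.severity_threshold).label

    if echo_velocity_ms is not None:
        tpg_echo = tpg_bernoulli(echo_velocity_ms)
        record["tpg_echo_mmhg"] = tpg_echo
        record["grade_echo"] = grade_severity(tpg_echo, cfg.severity_threshold).label

    return record
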