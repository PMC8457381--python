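"""Centralised unit conversions.

Canonical units at I/O boundaries: seconds, millilitres, ml/s for flow,
mm for geometry coordinates, cm^2 for valve areas, mmHg for pressures,
m/s for echo velocities.  The power-law pressure model takes flow in l/s,
so every ml/s -> l/s conversion goes through this module; no other module
is allowed to multiply or divide by 1000 on its own.
"""

ML_PER_L = 1000.0
MM2_PER_CM2 = 100.0
S_PER_MIN = 60.0


def ml_per_s_to_l_per_s(q_mls: float) -> float:
    return q_mls / ML_PER_L


def l_per_s_to_ml_per_s(q_ls: float) -> float:
    return q_ls * ML_PER_L


def mm2_to_cm2(area_mm2: float) -> float:
    return area_mm2 / MM2_PER_CM2


def ml_to_l(v_ml: float) -> float:
    return v_ml / ML_PER_L


def hr_to_period_s(hr_per_min: float) -> float:
    """Cardiac cycle length in seconds for a heart rate in beats/min."""
    return S_PER_MIN / hr_per_min
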