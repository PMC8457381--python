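"""Catheter-based gradient from LV and ascending-aorta pressure traces.

During catheterization the ascending aorta and the left ventricle are
measured sequentially (not simultaneously), each over at least three
consecutive cardiac cycles.  The peak-systolic pressure of each site is the
average of the per-cycle peak values, and the catheter gradient is the
difference of those two averages.  No beat alignment between the two traces
is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import find_peaks

from .errors import AnalysisError, ValidationError
from .units import hr_to_period_s

__all__ = ["PressureWaveform", "cycle_peaks", "tpg_catheter", "SITES"]

SITES = ("left_ventricle", "ascending_aorta")


@dataclass(frozen=True)
class PressureWaveform:
    """Multi-cycle pressure trace (mmHg) at times (s) for one site."""

    times: np.ndarray
    pressures: np.ndarray
    site: str

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.pressures, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "pressures", p)
        if t.ndim != 1 or p.ndim != 1 or t.size != p.size:
            raise ValidationError("times and pressures must be 1-D arrays of equal length")
        if t.size < 3:
            raise ValidationError("a pressure waveform needs at least 3 samples")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("times must be strictly increasing")
        if not np.all(np.isfinite(p)):
            raise ValidationError("pressures must be finite")
        if self.site not in SITES:
            raise ValidationError(
                f"unknown site {self.site!r}; expected one of {SITES}"
            )


def cycle_peaks(
    wave: PressureWaveform, expected_hr: Optional[float] = None
) -> np.ndarray:
    """Per-cycle peak pressures (mmHg), one per detected cardiac cycle.

    Cycles are segmented as local maxima separated by at least half the
    expected beat period (0.5 * 60/HR seconds); without a heart rate the
    separation defaults to 0.3 s, which covers rates up to ~120 bpm.  For a
    plateau peak the first sample of the plateau is taken.  Fewer than three
    detected cycles is an :class:`AnalysisError` naming the count found.
    """
    if expected_hr is not None and not expected_hr > 0:
        raise ValidationError(f"expected heart rate must be positive, got {expected_hr}")
    min_sep_s = 0.5 * hr_to_period_s(expected_hr) if expected_hr else 0.3
    dt = float(np.median(np.diff(wave.times)))
    distance = max(1, int(round(min_sep_s / dt)))
    p = wave.pressures
    span = float(np.ptp(p))
    if span == 0:
        raise AnalysisError("flat pressure trace: 0 cardiac cycles detected (>= 3 required)")
    # small prominence floor rejects sampling ripple without losing real beats
    idx, props = find_peaks(
        p, distance=distance, prominence=0.05 * span, plateau_size=(1, None)
    )
    peak_idx = props["left_edges"]  # first sample of a plateau
    if peak_idx.size < 3:
        raise AnalysisError(
            f"only {peak_idx.size} cardiac cycles detected (>= 3 required)"
        )
    return p[peak_idx].astype(float)


def tpg_catheter(
    lv: PressureWaveform,
    ao: PressureWaveform,
    expected_hr: Optional[float] = None,
) -> float:
    """Catheter gradient (mmHg): mean LV peak pressure minus mean aortic peak pressure.

    A negative result is physiologically suspicious for the sequential
    acquisition protocol and is flagged with a warning, not an error.
    """
    if lv.site != "left_ventricle":
        raise ValidationError(f"first argument must be a left_ventricle trace, got {lv.site!r}")
    if ao.site != "ascending_aorta":
        raise ValidationError(f"second argument must be an ascending_aorta trace, got {ao.site!r}")
    lv_peaks = cycle_peaks(lv, expected_hr)
    ao_peaks = cycle_peaks(ao, expected_hr)
    tpg = float(np.mean(lv_peaks) - np.mean(ao_peaks))
    if tpg < 0:
        warnings.warn(
            f"negative catheter gradient ({tpg:.1f} mmHg): LV peaks below aortic peaks",
            stacklevel=2,
        )
    return tpg
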