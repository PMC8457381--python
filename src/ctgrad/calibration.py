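"""Nonlinear least-squares calibration of the power-law coefficients.

The three coefficients of TPG = a * Q**b * AVA**(-c) are fitted to training
triples (Q in l/s, AVA in cm^2, TPG in mmHg) by unweighted nonlinear least
squares in linear mmHg space — the space in which prediction errors and
standard errors of estimate are reported.  Because the model is log-linear,
an ordinary least-squares fit of log(TPG) on log(Q) and log(AVA) supplies
the starting point; on noiseless data that initialiser is already the exact
optimum and the nonlinear refinement must not move away from it.  Positivity
of all three coefficients is enforced by optimising their logarithms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError, ValidationError
from .model_core import ModelCoefficients

__all__ = ["TrainingTriple", "FitResult", "CrossValidation", "fit_power_law", "cross_validate"]

_MIN_TRIPLES = 4


@dataclass(frozen=True)
class TrainingTriple:
    """One calibration sample: flow (l/s), valve area (cm^2), gradient (mmHg)."""

    q: float
    ava: float
    tpg: float

    def __post_init__(self) -> None:
        if not (self.q > 0 and self.ava > 0 and self.tpg > 0):
            raise ValidationError(
                f"training triple must be strictly positive, got {self!r}"
            )


@dataclass(frozen=True)
class FitResult:
    coeffs: ModelCoefficients
    residual_rms: float  # mmHg, sqrt(mean squared residual)
    n_triples: int
    converged: bool


@dataclass(frozen=True)
class CrossValidation:
    fold_rms: tuple  # held-out RMS per fold, mmHg
    mean_rms: float
    sd_rms: float
    n_folds: int


def _arrays(triples: Sequence[TrainingTriple]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    q = np.array([t.q for t in triples], dtype=float)
    ava = np.array([t.ava for t in triples], dtype=float)
    tpg = np.array([t.tpg for t in triples], dtype=float)
    return q, ava, tpg


def fit_power_law(triples: Sequence[TrainingTriple]) -> FitResult:
    """Fit (a, b, c) minimising sum (tpg_i - a q_i^b ava_i^-c)^2.

    Requires at least 4 triples and variation in both Q and AVA; a
    degenerate design raises :class:`FitError`.  Non-convergence is
    reported through ``converged=False``, never as a silently wrong answer.
    """
    if len(triples) < _MIN_TRIPLES:
        raise FitError(
            f"power-law fit needs >= {_MIN_TRIPLES} triples, got {len(triples)}"
        )
    q, ava, tpg = _arrays(triples)
    if np.ptp(q) == 0 or np.ptp(ava) == 0:
        raise FitError("degenerate design: no variation in Q or AVA")

    # log-space OLS initialiser: log tpg = log a + b log q - c log ava
    design = np.column_stack([np.ones_like(q), np.log(q), np.log(ava)])
    beta, *_ = np.linalg.lstsq(design, np.log(tpg), rcond=None)
    log_a0, b0, c0 = beta[0], beta[1], -beta[2]
    b0 = max(b0, 1e-6)
    c0 = max(c0, 1e-6)

    def residuals(theta: np.ndarray) -> np.ndarray:
        a, b, c = np.exp(theta)
        return tpg - a * q**b * ava ** (-c)

    x0 = np.array([log_a0, np.log(b0), np.log(c0)])
    sol = least_squares(
        residuals, x0, method="lm", xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=500 * 3
    )
    a, b, c = np.exp(sol.x)
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    return FitResult(
        coeffs=ModelCoefficients(a=float(a), b=float(b), c=float(c)),
        residual_rms=rms,
        n_triples=len(triples),
        converged=bool(sol.status > 0),
    )


def cross_validate(
    triples: Sequence[TrainingTriple], folds: int, seed: int
) -> CrossValidation:
    """K-fold cross-validation of the power-law fit; deterministic given seed.

    Reports the held-out root-mean-square prediction error per fold and its
    mean/SD across folds.  ``folds=n`` gives leave-one-out.
    """
    n = len(triples)
    if folds < 2:
        raise ValidationError(f"folds must be >= 2, got {folds}")
    if folds > n:
        raise ValidationError(f"folds ({folds}) may not exceed n_triples ({n})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_rms = []
    for k in range(folds):
        test_idx = set(order[k::folds].tolist())
        train = [triples[i] for i in range(n) if i not in test_idx]
        test = [triples[i] for i in sorted(test_idx)]
        fit = fit_power_law(train)
        c = fit.coeffs
        res = [t.tpg - c.a * t.q**c.b * t.ava ** (-c.c) for t in test]
        fold_rms.append(float(np.sqrt(np.mean(np.square(res)))))
    fold_rms_arr = np.array(fold_rms)
    return CrossValidation(
        fold_rms=tuple(fold_rms),
        mean_rms=float(fold_rms_arr.mean()),
        sd_rms=float(fold_rms_arr.std(ddof=1)) if folds > 1 else 0.0,
        n_folds=folds,
    )
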