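"""Derivation of all free model parameters from clinical anchors.

The anchors are quantities a clinician or the literature can supply: the
active stem-cell pool, target blood counts, first-guess blood lifetimes,
the megakaryocyte burst size, the cell-cycle ceiling ``r_max``, the
stem-cell division rate at target (``r_S``, about once a year), the
output rate into the blood (``r_blood``), the size of the last common
progenitor pool (CFU-GEMM, ~60000 cells) and the stem-cell rate under
full depletion (``r_S'``) that sets the feedback gain.

From these the sensitivity offset ``b`` follows in closed form, while the
slopes ``a_x``, stage counts ``K_x`` and commitment probabilities ``q_x``
are mutually dependent and are resolved by a fixed-point iteration that
converges in a handful of passes. Stage counts are then rounded to
integers and the blood death rates re-solved so the steady-state blood
counts land exactly on their targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
import math

import numpy as np

from . import kinetics
from .model_core import (
    COMMITTED_LINEAGES,
    GrowthFactors,
    Lineage,
    ModelParameters,
    ValidationError,
    ZERO_CONCENTRATIONS,
    validate,
)


class ConvergenceError(RuntimeError):
    """The calibration fixed point failed to converge."""


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


@dataclass(frozen=True)
class ClinicalAnchors:
    """Clinically anchored inputs of the calibration (defaults: healthy adult).

    Targets assume 5 L of blood: 5.0e6 erythrocytes/µL, 4000
    granulocytes/µL and 250000 platelets/µL (hence N_T = 1.25e12).
    """

    N_S: int = 400
    N_E: float = 2.5e13
    N_G: float = 2.0e10
    N_T: float = 1.25e12
    r_E: float = 1.0 / 110.0  # initial guesses, re-solved after rounding K_x
    r_G: float = 1.0 / 2.0
    r_T: float = 1.0 / 10.0
    m_E: int = 1
    m_G: int = 1
    m_T: int = 50
    r_max: float = 5.0
    r_S: float = 1.0 / 365.0
    r_blood: float = 4.0
    N_C_target: float = 6.0e4
    r_S_prime: float = 1.0

    def __post_init__(self) -> None:
        for name in ("N_S", "N_E", "N_G", "N_T", "r_E", "r_G", "r_T",
                     "m_E", "m_G", "m_T", "r_max", "r_S", "r_blood",
                     "N_C_target", "r_S_prime"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"anchor {name} must be positive")
        if self.r_S >= self.r_max:
            raise ValidationError("r_S must be below r_max")
        if self.r_blood >= self.r_max:
            raise ValidationError("r_blood must be below r_max")

    def N(self, x: Lineage) -> float:
        return getattr(self, f"N_{x.value}")

    def r_guess(self, x: Lineage) -> float:
        return getattr(self, f"r_{x.value}")

    def m(self, x: Lineage) -> int:
        return getattr(self, f"m_{x.value}")


def stem_offset(r_S: float, r_max: float) -> tuple:
    """Occupancy at the stem stage and the sensitivity offset b.

    The stem rate at target satisfies ``r_S = r_max*(1 - (1-p_stem)^3)``
    (three identical receptors, equal occupancies at c = 0), so
    ``p_stem = 1 - (1 - r_S/r_max)^(1/3)`` and ``b = logit(p_stem)``.
    """
    if not 0 < r_S < r_max:
        raise ValidationError("need 0 < r_S < r_max")
    p_stem = 1.0 - (1.0 - r_S / r_max) ** (1.0 / 3.0)
    return p_stem, _logit(p_stem)


def slope(K_C: int, K_x: float, b: float, r_blood: float, r_max: float) -> float:
    """Sensitivity slope a_x from the known rate at the last marrow stage.

    The previous-to-last stage divides at ``r_blood``, i.e. its occupancy
    is ``r_blood/r_max`` at global stage ``K_C + K_x - 1``.
    """
    denom = K_C + K_x - 1
    if denom == 0:
        raise ZeroDivisionError("K_C + K_x must exceed 1")
    return (_logit(r_blood / r_max) - b) / denom


def stage_count(N_x: float, r_x: float, N_S: float, r_S: float,
                K_C: int, q_x: float, m_x: float) -> float:
    """Real-valued stage count K_x from the steady-state blood constraint.

    Inverts ``N_x = N_S*(r_S/r_x)*2^(K_C+K_x-1)*q_x*m_x`` for K_x.
    """
    if not 0.0 < q_x < 1.0:
        raise ValidationError("q_x must lie in (0, 1)")
    return (1.0 - K_C + math.log2(N_x * r_x / (N_S * r_S))
            - math.log2(q_x) - math.log2(m_x))


def feedback_gain(r_S_prime: float, r_max: float, b: float) -> float:
    """Feedback gain delta from the stem rate under full depletion.

    When a lineage is fully depleted every ``c_x = delta``; requiring the
    stem rate to become ``r_S'`` there gives
    ``delta = logit(1 - (1 - r_S'/r_max)^(1/3)) - b``.
    """
    p_prime, logit_p = stem_offset(r_S_prime, r_max)
    return logit_p - b


@dataclass(frozen=True)
class FitReport:
    """Diagnostics of one calibration run."""

    iterations: int
    K_real: dict  # lineage symbol -> converged real-valued stage count
    a: dict
    q: dict
    N_C: float  # expected last-common-progenitor count at c = 0
    params: ModelParameters


def _commitment_at_zero(a: dict, b: float, K_C: int) -> dict:
    """q_x at c = 0 for trial slopes, via the kinetics commitment rule."""
    p = {x: 1.0 / (1.0 + math.exp(-(a[x] * K_C + b))) for x in COMMITTED_LINEAGES}
    q_raw = {}
    for x in COMMITTED_LINEAGES:
        y, z = [w for w in COMMITTED_LINEAGES if w is not x]
        q_raw[x] = p[x] * ((1 - p[y]) * (1 - p[z])
                           + 0.5 * p[y] * (1 - p[z])
                           + 0.5 * (1 - p[y]) * p[z]
                           + p[y] * p[z] / 3.0)
    total = sum(q_raw.values())
    return {x: q_raw[x] / total for x in COMMITTED_LINEAGES}


def fit(anchors: ClinicalAnchors = ClinicalAnchors(), K_C: int = 14, *,
        gamma: float = 0.0, dt: float | None = None,
        max_iter: int = 100, tol: float = 1e-10,
        full_report: bool = False):
    """Calibrate all free parameters for a given number of common stages.

    Fixed-point scheme: starting from symmetric commitment ``q_x = 1/3``,
    alternate (i) stage counts from the blood constraint, (ii) slopes from
    the blood-output rate, (iii) commitment probabilities at c = 0, until
    the stage counts move by less than *tol*. The converged real-valued
    counts are rounded half-up to integers, slopes and commitment
    recomputed, and the blood death rates re-solved so the steady-state
    constraint holds exactly.
    """
    p_stem, b = stem_offset(anchors.r_S, anchors.r_max)

    q = {x: 1.0 / 3.0 for x in COMMITTED_LINEAGES}
    K_prev = None
    a = {}
    for iteration in range(1, max_iter + 1):
        K = {
            x: stage_count(anchors.N(x), anchors.r_guess(x), anchors.N_S,
                           anchors.r_S, K_C, q[x], anchors.m(x))
            for x in COMMITTED_LINEAGES
        }
        a = {x: slope(K_C, K[x], b, anchors.r_blood, anchors.r_max)
             for x in COMMITTED_LINEAGES}
        q = _commitment_at_zero(a, b, K_C)
        if K_prev is not None and max(
            abs(K[x] - K_prev[x]) for x in COMMITTED_LINEAGES
        ) < tol:
            K_prev = K
            break
        K_prev = K
    else:
        raise ConvergenceError(f"stage counts did not settle in {max_iter} iterations")

    K_real = dict(K_prev)
    K_int = {x: int(math.floor(K_real[x] + 0.5)) for x in COMMITTED_LINEAGES}
    a = {x: slope(K_C, K_int[x], b, anchors.r_blood, anchors.r_max)
         for x in COMMITTED_LINEAGES}
    q = _commitment_at_zero(a, b, K_C)

    # Re-solve the blood constraint for the death rates with integer stages.
    r_adj = {
        x: anchors.N_S * anchors.r_S * 2.0 ** (K_C + K_int[x] - 1)
        * q[x] * anchors.m(x) / anchors.N(x)
        for x in COMMITTED_LINEAGES
    }

    delta = feedback_gain(anchors.r_S_prime, anchors.r_max, b)
    params = validate(ModelParameters(
        N_S=anchors.N_S,
        N_E=anchors.N_E, N_G=anchors.N_G, N_T=anchors.N_T,
        r_E=r_adj[Lineage.E], r_G=r_adj[Lineage.G], r_T=r_adj[Lineage.T],
        m_E=anchors.m_E, m_G=anchors.m_G, m_T=anchors.m_T,
        r_max=anchors.r_max, b=b,
        a_E=a[Lineage.E], a_G=a[Lineage.G], a_T=a[Lineage.T],
        K_C=K_C,
        K_E=K_int[Lineage.E], K_G=K_int[Lineage.G], K_T=K_int[Lineage.T],
        delta=delta, gamma=gamma,
        dt=dt if dt is not None else 1.0 / anchors.r_max / 5.0,
    ))
    if not full_report:
        return params
    r_C = float(kinetics.common_precursor_rate(K_C, ZERO_CONCENTRATIONS, params))
    N_C = anchors.N_S * (anchors.r_S / r_C) * 2.0 ** (K_C - 1)
    return FitReport(
        iterations=iteration,
        K_real={x.value: K_real[x] for x in COMMITTED_LINEAGES},
        a={x.value: a[x] for x in COMMITTED_LINEAGES},
        q={x.value: q[x] for x in COMMITTED_LINEAGES},
        N_C=N_C,
        params=params,
    )


def last_common_pool(params: ModelParameters) -> float:
    """Expected count of the last common progenitor stage at c = 0."""
    r_S = float(kinetics.common_precursor_rate(0, ZERO_CONCENTRATIONS, params))
    r_C = float(kinetics.common_precursor_rate(params.K_C, ZERO_CONCENTRATIONS, params))
    return params.N_S * (r_S / r_C) * 2.0 ** (params.K_C - 1)


def choose_K_C(anchors: ClinicalAnchors = ClinicalAnchors(),
               K_C_range: range = range(5, 26)) -> int:
    """Pick the common-stage count whose CFU-GEMM pool is closest to target.

    Runs the full fit for each candidate and minimizes
    ``|N_C - N_C_target|``; ties break toward the smaller (more
    parsimonious) K_C.
    """
    candidates = sorted(K_C_range)
    if not candidates:
        raise ValidationError("empty K_C range")
    best, best_err = None, math.inf
    for K_C in candidates:
        params = fit(anchors, K_C)
        err = abs(last_common_pool(params) - anchors.N_C_target)
        if err < best_err:
            best, best_err = K_C, err
    return best


@lru_cache(maxsize=None)
def _default_parameters_cached(gamma: float, dt: float | None) -> ModelParameters:
    return fit(ClinicalAnchors(), K_C=14, gamma=gamma, dt=dt)


def default_parameters(*, gamma: float = 0.0, dt: float | None = None) -> ModelParameters:
    """The calibrated healthy-adult parameter set (K_C = 14 anchors)."""
    return _default_parameters_cached(gamma, dt)
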