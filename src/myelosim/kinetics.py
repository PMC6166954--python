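"""Deterministic rate laws of the model.

Receptor occupancy is a logistic function of a linear stage sensitivity
``s_{x,j} = a_x*j + b`` shifted by the growth-factor log-concentration.
Common precursors divide if any of their three receptors is occupied;
committed precursors respond only to their own factor; the blood stage
turns over at a constant death rate. Lineage commitment at the last common
stage weighs simultaneous occupancies symmetrically (1, 1/2, 1/3 for one,
two, three bound factors). The feedback map is linear in the relative
deviation of each blood count from its target.
"""

from __future__ import annotations

import numpy as np

from .model_core import (
    COMMITTED_LINEAGES,
    GrowthFactors,
    Lineage,
    ModelParameters,
    StageRangeError,
    ValidationError,
)


def _check_global_stage(x: Lineage, j, params: ModelParameters) -> None:
    hi = params.K_C + params.K(x)
    j = np.asarray(j)
    if (j < 0).any() or (j >= hi).any():
        raise StageRangeError(
            f"global stage {j} outside 0..{hi - 1} for lineage {x.value}"
        )


def binding_probability(x: Lineage, j, c: GrowthFactors, params: ModelParameters):
    """Occupancy probability of the *x*-receptor at global stage *j*.

    ``1 / (1 + exp(-(a_x*j + b + c_x)))``; vectorized over *j*.
    """
    if x is Lineage.C:
        raise ValidationError("binding_probability is defined for committed lineages")
    _check_global_stage(x, j, params)
    s = params.a(x) * np.asarray(j, dtype=float) + params.b + c.of(x)
    return 1.0 / (1.0 + np.exp(-s))


def common_precursor_rate(k, c: GrowthFactors, params: ModelParameters):
    """Division rate (1/day) of common-precursor stage(s) ``k in 0..K_C``.

    A cell divides iff at least one of the three receptors is occupied:
    ``r_max * (1 - prod_x (1 - p_{x,k}))``.
    """
    k = np.asarray(k)
    if (k < 0).any() or (k > params.K_C).any():
        raise StageRangeError(f"common stage {k} outside 0..{params.K_C}")
    none_bound = np.ones_like(np.asarray(k, dtype=float))
    for x in COMMITTED_LINEAGES:
        none_bound = none_bound * (1.0 - binding_probability(x, k, c, params))
    return params.r_max * (1.0 - none_bound)


def committed_rate(x: Lineage, k: int, c: GrowthFactors, params: ModelParameters) -> float:
    """Division rate (1/day) of committed stage ``k in 1..K_x`` of lineage *x*.

    Marrow stages divide at ``r_max * p_{x, K_C+k}``; the blood stage
    (``k = K_x``) turns over at the constant death rate ``r_x``.
    """
    K_x = params.K(x)
    if not 1 <= k <= K_x:
        raise StageRangeError(f"{x.value} stage {k} outside 1..{K_x}")
    if k == K_x:
        return params.r_blood_death(x)
    return float(params.r_max * binding_probability(x, params.K_C + k, c, params))


def committed_rates(x: Lineage, c: GrowthFactors, params: ModelParameters) -> np.ndarray:
    """Vector of rates for stages 1..K_x of lineage *x* (last = death rate)."""
    K_x = params.K(x)
    rates = np.empty(K_x, dtype=float)
    if K_x > 1:
        j = params.K_C + np.arange(1, K_x)
        rates[:-1] = params.r_max * binding_probability(x, j, c, params)
    rates[-1] = params.r_blood_death(x)
    return rates


def common_rates(c: GrowthFactors, params: ModelParameters) -> np.ndarray:
    """Vector of rates for common stages 0..K_C."""
    return common_precursor_rate(np.arange(params.K_C + 1), c, params)


def division_rate(x: Lineage, k: int, c: GrowthFactors, params: ModelParameters) -> float:
    """Stage rate for any lineage: dispatches to common or committed law."""
    if x is Lineage.C:
        return float(common_precursor_rate(k, c, params))
    return committed_rate(x, k, c, params)


def commitment_probabilities(c: GrowthFactors, params: ModelParameters) -> np.ndarray:
    """Probabilities (q_E, q_G, q_T) of entering each lineage.

    Evaluated from the occupancies at the last common stage (global stage
    K_C): a cell with only factor x bound enters lineage x; with one
    competitor bound as well, with probability 1/2; with all three bound,
    1/3. The three weights are normalized to sum to one.
    """
    p = {
        x: float(binding_probability(x, params.K_C, c, params))
        for x in COMMITTED_LINEAGES
    }
    q_raw = {}
    for x in COMMITTED_LINEAGES:
        y, z = [w for w in COMMITTED_LINEAGES if w is not x]
        px, py, pz = p[x], p[y], p[z]
        q_raw[x] = px * (
            (1 - py) * (1 - pz)
            + 0.5 * py * (1 - pz)
            + 0.5 * (1 - py) * pz
            + py * pz / 3.0
        )
    total = sum(q_raw.values())
    if total <= 0.0:
        raise ValidationError(
            "all commitment weights vanished (all binding probabilities 0)"
        )
    return np.array([q_raw[x] / total for x in COMMITTED_LINEAGES])


def feedback_concentrations(blood_counts: dict, params: ModelParameters) -> GrowthFactors:
    """Growth-factor log-concentrations from the current blood counts.

    ``c_x = delta * (N_x - count_x) / N_x``: zero at target, ``delta``
    when the lineage is fully depleted, negative above target.
    """
    vals = {}
    for x in COMMITTED_LINEAGES:
        n = blood_counts[x]
        if n < 0:
            raise ValidationError(f"negative blood count for {x.value}")
        target = params.N(x)
        vals[f"c_{x.value}"] = params.delta * (target - n) / target
    return GrowthFactors(**vals)
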