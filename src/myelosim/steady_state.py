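"""Conditional steady-state expectations at fixed growth-factor levels.

With the concentrations ``c`` pinned, expected inflow equals expected
outflow in every compartment, so the whole expectation profile follows
from the stem-cell outflow ``E[M_C0] = N_S * r_C0(c) * dt``: outflows
double at every symmetric-division stage, committed lineages pick up the
commitment probability ``q_x(c)`` and the blood stage the burst factor
``m_x``. Counts follow from the binomial identity ``E[M] = E[N]*r*dt``.
These are conditional expectations only — the feedback-closed stationary
distribution is not analyzed here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetics import committed_rates, common_rates, commitment_probabilities
from .model_core import (
    COMMITTED_LINEAGES,
    GrowthFactors,
    Lineage,
    ModelParameters,
    ZERO_CONCENTRATIONS,
)


@dataclass(frozen=True)
class SteadyStateProfile:
    """Expected per-step outflow and expected count for every compartment.

    ``outflow_*`` entries are per time step (multiply by ``1/dt`` for a
    daily flux). Indexing mirrors :class:`~myelosim.model_core.SystemState`.
    """

    c: GrowthFactors
    outflow_common: np.ndarray  # stages 0..K_C
    outflow_committed: dict  # lineage -> stages 1..K_x
    count_common: np.ndarray  # stages 0..K_C
    count_committed: dict  # lineage -> stages 1..K_x


def _profile(params: ModelParameters, c: GrowthFactors) -> SteadyStateProfile:
    r_common = common_rates(c, params)
    q = commitment_probabilities(c, params)
    K_C = params.K_C

    m_stem = params.N_S * r_common[0] * params.dt
    # E[M_{C,k}]: asymmetric stem division feeds stage 1 without doubling,
    # every later stage doubles, so k=0 -> m_stem, k>=1 -> m_stem * 2^(k-1).
    out_common = np.empty(K_C + 1)
    out_common[0] = m_stem
    out_common[1:] = m_stem * 2.0 ** (np.arange(1, K_C + 1) - 1)

    out_committed, cnt_committed = {}, {}
    for qi, x in zip(q, COMMITTED_LINEAGES):
        K_x = params.K(x)
        k = np.arange(1, K_x + 1)
        out = m_stem * 2.0 ** (K_C + k - 1) * qi
        out[-1] *= params.m(x)
        rates = committed_rates(x, c, params)
        out_committed[x] = out
        cnt_committed[x] = out / (rates * params.dt)

    cnt_common = out_common / (r_common * params.dt)
    return SteadyStateProfile(
        c=c,
        outflow_common=out_common,
        outflow_committed=out_committed,
        count_common=cnt_common,
        count_committed=cnt_committed,
    )


def expected_outflows(params: ModelParameters, c: GrowthFactors = ZERO_CONCENTRATIONS):
    """Expected per-step outflow ``E[M | c]`` for every compartment."""
    p = _profile(params, c)
    return p.outflow_common, p.outflow_committed


def expected_counts(params: ModelParameters, c: GrowthFactors = ZERO_CONCENTRATIONS):
    """Expected count ``E[N | c]`` for every compartment."""
    p = _profile(params, c)
    return p.count_common, p.count_committed


def profile(params: ModelParameters, c: GrowthFactors = ZERO_CONCENTRATIONS) -> SteadyStateProfile:
    """Full expectation profile (outflows and counts) at fixed *c*."""
    return _profile(params, c)


def marrow_total(params: ModelParameters, c: GrowthFactors = ZERO_CONCENTRATIONS) -> float:
    """Expected total marrow cell count (every compartment except blood)."""
    p = _profile(params, c)
    total = float(p.count_common.sum())
    for x in COMMITTED_LINEAGES:
        total += float(p.count_committed[x][:-1].sum())
    return total


def profile_table(params: ModelParameters, c: GrowthFactors = ZERO_CONCENTRATIONS) -> pd.DataFrame:
    """Per-stage table: lineage, local/global stage, rate, daily outflow, count."""
    p = _profile(params, c)
    r_common = common_rates(c, params)
    rows = []
    for k in range(params.K_C + 1):
        rows.append(
            (Lineage.C.value, k, k, r_common[k],
             p.outflow_common[k] / params.dt, p.count_common[k])
        )
    for x in COMMITTED_LINEAGES:
        rates = committed_rates(x, c, params)
        for k in range(1, params.K(x) + 1):
            rows.append(
                (x.value, k, params.K_C + k, rates[k - 1],
                 p.outflow_committed[x][k - 1] / params.dt,
                 p.count_committed[x][k - 1])
            )
    return pd.DataFrame(
        rows,
        columns=["lineage", "stage", "global_stage", "rate_per_day",
                 "E_outflow_per_day", "E_count"],
    )
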