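"""Stochastic time stepping of the full compartment system.

Each synchronous step of duration ``dt``:

1. growth-factor concentrations are computed from the pre-step blood counts;
2. every compartment's outflow is drawn Binomial(N, r*dt) — or
   beta-binomial with a mean-preserving Beta-distributed success
   probability when the noise scaling ``gamma`` is positive;
3. the outflow of the last common stage is split multinomially over the
   three lineages with the commitment probabilities;
4. the difference equations are applied: the stem pool is replenished by
   asymmetric division, the first common stage gains the stem outflow
   without doubling, every later stage gains twice its upstream outflow,
   and the blood stage additionally picks up the burst factor ``m_x``.

All draws use the pre-step counts; a single :class:`numpy.random.Generator`
determines the full trajectory.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import kinetics, steady_state
from .model_core import (
    COMMITTED_LINEAGES,
    GrowthFactors,
    ModelParameters,
    SystemState,
    TimeSeriesRecord,
    ValidationError,
)


def _sample_outflows(n: np.ndarray, rates: np.ndarray, dt: float,
                     gamma: float, rng: np.random.Generator) -> np.ndarray:
    """Vectorized (beta-)binomial outflow draw for an array of compartments."""
    alpha = np.asarray(rates, dtype=float) * dt
    if np.any(alpha < 0) or np.any(alpha > 1.0 + 1e-12):
        raise ValidationError("rate*dt must lie in [0, 1]")
    alpha = np.clip(alpha, 0.0, 1.0)
    n = np.asarray(n, dtype=np.int64)
    if gamma > 0.0:
        p = np.empty_like(alpha)
        interior = (alpha > 0.0) & (alpha < 1.0)
        p[~interior] = alpha[~interior]  # degenerate Beta: point mass
        if interior.any():
            a = alpha[interior] / gamma
            b = (1.0 - alpha[interior]) / gamma
            p[interior] = rng.beta(a, b)
    else:
        p = alpha
    return rng.binomial(n, p)


def sample_outflow(n: int, rate: float, dt: float, gamma: float,
                   rng: np.random.Generator) -> int:
    """Number of cells leaving a compartment of *n* cells in one step.

    Mean is ``n*rate*dt`` for any ``gamma >= 0``; overdispersion grows
    with ``gamma`` (the per-step division probability is Beta-distributed
    with mean ``rate*dt``).
    """
    return int(_sample_outflows(np.array([n]), np.array([rate]), dt, gamma, rng)[0])


def _draw_step(state: SystemState, params: ModelParameters,
               rng: np.random.Generator,
               pin_c: GrowthFactors | None = None):
    """Sample concentrations, all outflows and the commitment split."""
    if pin_c is None:
        c = kinetics.feedback_concentrations(state.blood_counts(), params)
    else:
        c = pin_c
    m_common = _sample_outflows(
        state.common, kinetics.common_rates(c, params),
        params.dt, params.gamma, rng,
    )
    m_committed = {
        x: _sample_outflows(
            state.committed[x], kinetics.committed_rates(x, c, params),
            params.dt, params.gamma, rng,
        )
        for x in COMMITTED_LINEAGES
    }
    q = kinetics.commitment_probabilities(c, params)
    split = rng.multinomial(m_common[-1], q)
    return c, m_common, m_committed, dict(zip(COMMITTED_LINEAGES, split))


def _apply_step(state: SystemState, params: ModelParameters,
                m_common: np.ndarray, m_committed: dict,
                split: dict) -> SystemState:
    """Apply the synchronous difference equations to pre-step counts."""
    new = state.copy()
    # Stem compartment: asymmetric division keeps it at N_S (no change).
    # Stage 1 gains the undoubled stem outflow; later stages double.
    new.common[1:] -= m_common[1:]
    new.common[1] += m_common[0]
    if params.K_C >= 2:
        new.common[2:] += 2 * m_common[1:-1]
    for x in COMMITTED_LINEAGES:
        arr = new.committed[x]
        m = m_committed[x]
        arr -= m
        arr[0] += 2 * split[x]
        if params.K(x) >= 2:
            arr[1:-1] += 2 * m[:-2]
            arr[-1] += 2 * m[-2] * params.m(x)
    new.t = state.t + params.dt
    return new


def step(state: SystemState, params: ModelParameters,
         rng: np.random.Generator,
         pin_c: GrowthFactors | None = None) -> SystemState:
    """One stochastic update of duration ``dt``.

    ``pin_c`` freezes the growth-factor concentrations (open-loop run for
    conditional steady-state checks); by default the feedback closes the
    loop from the pre-step blood counts.
    """
    _, m_common, m_committed, split = _draw_step(state, params, rng, pin_c)
    return _apply_step(state, params, m_common, m_committed, split)


def initial_steady_state(params: ModelParameters) -> SystemState:
    """State at the rounded conditional steady-state expectations (c = 0).

    Blood stages land exactly on the integer targets by construction of
    the calibrated death rates.
    """
    cnt_common, cnt_committed = steady_state.expected_counts(params)
    state = SystemState.empty(params)
    state.common[:] = np.rint(cnt_common).astype(np.int64)
    state.common[0] = params.N_S
    for x in COMMITTED_LINEAGES:
        state.committed[x][:] = np.rint(cnt_committed[x]).astype(np.int64)
        # the calibrated death rates make E[blood] = N_x exactly; pin the
        # integer target rather than keep float round-off
        state.committed[x][-1] = int(round(params.N(x)))
    return state


def simulate(initial: SystemState, params: ModelParameters, duration: float,
             rng: np.random.Generator, record_every: float | None = None,
             record_compartments: bool = False,
             pin_c: GrowthFactors | None = None) -> TimeSeriesRecord:
    """Run ``ceil(duration/dt)`` steps, recording series at a fixed cadence.

    Always records the three blood counts and the total marrow count; with
    ``record_compartments`` every compartment is recorded as
    ``<lineage><stage>``. Bit-reproducible for a given generator state.
    """
    if duration <= 0:
        raise ValidationError("duration must be positive")
    dt = params.dt
    if record_every is None:
        record_every = dt
    if record_every < dt:
        raise ValidationError("record_every must be at least dt")
    stride = max(1, int(round(record_every / dt)))
    n_steps = math.ceil(duration / dt - 1e-9)

    rows = []

    def snapshot(s: SystemState):
        blood = s.blood_counts()
        row = [s.t, blood[COMMITTED_LINEAGES[0]], blood[COMMITTED_LINEAGES[1]],
               blood[COMMITTED_LINEAGES[2]], s.marrow_total()]
        if record_compartments:
            row.extend(int(v) for v in s.common)
            for x in COMMITTED_LINEAGES:
                row.extend(int(v) for v in s.committed[x])
        rows.append(row)

    state = initial.copy()
    snapshot(state)
    for i in range(1, n_steps + 1):
        state = step(state, params, rng, pin_c)
        if i % stride == 0 or i == n_steps:
            snapshot(state)

    columns = ["time_days", "E_blood", "G_blood", "T_blood", "marrow_total"]
    if record_compartments:
        columns += [f"C{k}" for k in range(params.K_C + 1)]
        for x in COMMITTED_LINEAGES:
            columns += [f"{x.value}{k}" for k in range(1, params.K(x) + 1)]
    return TimeSeriesRecord(pd.DataFrame(rows, columns=columns))
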