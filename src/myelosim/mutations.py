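"""Leukemogenesis extension: replicative capacity, mutations, marrow overflow.

Every non-stem cell can divide a fixed number of times (the Hayflick
limit, default 60). For normal cells the divisions used are determined by
the stage, so only mutant cohorts carry an explicit remaining-capacity
index. Two mutations are modeled: a *differentiation block* (both
daughters remain at the parent's stage, burning one unit of capacity per
division) and *unlimited replication* (capacity is never decremented).
Their combination doubles in place indefinitely — the engine of acute
leukemia in this model. The bone marrow has a hard capacity; excess cells
(normal and mutant alike) are pushed out uniformly at random and recorded
as circulating blasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Flag, auto
import math

import numpy as np
import pandas as pd

from . import engine, kinetics, steady_state
from .model_core import (
    COMMITTED_LINEAGES,
    GrowthFactors,
    Lineage,
    ModelParameters,
    SystemState,
    TimeSeriesRecord,
    ValidationError,
    ZERO_CONCENTRATIONS,
)


class MutationType(Flag):
    """Pathway hits a mutant cohort carries."""

    BLOCK = auto()
    IMMORTAL = auto()


@dataclass(frozen=True)
class MutationEvent:
    """Appearance of mutant founder cells at a marrow stage."""

    time_days: float
    lineage: Lineage
    stage: int
    flags: MutationType
    count: int = 1

    def check(self, params: ModelParameters) -> None:
        if not self.flags:
            raise ValidationError("mutation event must carry at least one flag")
        if self.count < 1:
            raise ValidationError("mutation event count must be >= 1")
        x = self.lineage
        if x is Lineage.C:
            if not 1 <= self.stage <= params.K_C:
                raise ValidationError(
                    f"common mutation stage {self.stage} outside 1..{params.K_C}"
                )
        else:
            if not 1 <= self.stage <= params.K(x) - 1:
                raise ValidationError(
                    f"{x.value} mutation stage {self.stage} is not a marrow stage"
                )


@dataclass(frozen=True)
class MutationConfig:
    """Hayflick limit, marrow capacity and the scheduled mutation events."""

    hayflick_limit: int = 60
    marrow_capacity_per_uL: float = 30000.0
    events: tuple = ()

    def check(self, params: ModelParameters) -> None:
        if self.hayflick_limit <= params.K_C + params.K_E:
            raise ValidationError(
                "hayflick_limit must exceed K_C + K_E or no mature "
                "erythrocytes can be produced"
            )
        if self.marrow_capacity_per_uL <= 0:
            raise ValidationError("marrow capacity must be positive")
        for ev in self.events:
            ev.check(params)

    def capacity_cells(self, params: ModelParameters) -> int:
        return int(round(self.marrow_capacity_per_uL * params.blood_volume_uL))


class MutantCohortState:
    """Mutant counts indexed by (lineage, stage, flags) and remaining capacity.

    ``cohorts[(lineage, stage, flags)]`` is an int64 vector over remaining
    capacity 0..R. Committed blood stages appear only transiently for
    immortal clones that differentiate all the way out; they are excluded
    from marrow occupancy.
    """

    def __init__(self, hayflick_limit: int):
        self.R = int(hayflick_limit)
        self.cohorts: dict = {}

    def copy(self) -> "MutantCohortState":
        new = MutantCohortState(self.R)
        new.cohorts = {k: v.copy() for k, v in self.cohorts.items()}
        return new

    def _vec(self, key) -> np.ndarray:
        if key not in self.cohorts:
            self.cohorts[key] = np.zeros(self.R + 1, dtype=np.int64)
        return self.cohorts[key]

    def add(self, lineage: Lineage, stage: int, flags: MutationType,
            capacity: int, count: int) -> None:
        if not 0 <= capacity <= self.R:
            raise ValidationError(f"capacity {capacity} outside 0..{self.R}")
        self._vec((lineage, stage, flags))[capacity] += count

    def seed_event(self, ev: MutationEvent, params: ModelParameters) -> None:
        """Add founders with the capacity implied by their stage."""
        j = ev.stage if ev.lineage is Lineage.C else params.K_C + ev.stage
        self.add(ev.lineage, ev.stage, ev.flags, self.R - j, ev.count)

    def _is_marrow(self, key, params: ModelParameters) -> bool:
        x, k, _ = key
        return x is Lineage.C or k < params.K(x)

    def total(self) -> int:
        return int(sum(v.sum() for v in self.cohorts.values()))

    def marrow_total(self, params: ModelParameters) -> int:
        return int(sum(v.sum() for k, v in self.cohorts.items()
                       if self._is_marrow(k, params)))

    def prune(self) -> None:
        self.cohorts = {k: v for k, v in self.cohorts.items() if v.any()}


def _stage_rate(x: Lineage, k: int, c: GrowthFactors,
                params: ModelParameters) -> float:
    return kinetics.division_rate(x, k, c, params)


def _remove_uniform(pools: list, excess: int, rng: np.random.Generator) -> list:
    """Multivariate hypergeometric removal of *excess* cells across *pools*.

    Sequential conditional draws; each marginal is an exact hypergeometric
    when within numpy's count limit and its binomial approximation (with
    feasibility clipping, hence exactly mass-conserving) otherwise.
    """
    total = int(sum(pools))
    if excess > total:
        raise ValidationError("cannot remove more cells than present")
    removed = []
    rest = total
    left = int(excess)
    for n_i in pools:
        n_i = int(n_i)
        rest -= n_i
        if left == 0 or n_i == 0:
            removed.append(0)
            continue
        lo = max(0, left - rest)
        hi = min(n_i, left)
        if n_i < 10**9 and rest < 10**9 and left <= n_i + rest:
            x = int(rng.hypergeometric(n_i, rest, left))
        else:
            x = int(rng.binomial(left, n_i / (n_i + rest)))
        x = min(max(x, lo), hi)
        removed.append(x)
        left -= x
    return removed


def step_with_mutants(state: SystemState, mutants: MutantCohortState,
                      config: MutationConfig, params: ModelParameters,
                      rng: np.random.Generator):
    """One step of the extended system; returns (state, mutants, blast_outflow).

    Normal cells follow the base engine exactly (same draws in the same
    order, so with no mutants present the trajectory is identical to
    :func:`myelosim.engine.step` for the same generator). Mutant cohorts
    divide at the rate of normal cells at their stage and under the same
    overdispersion; their daughters move according to the cohort's flags.
    After the update, marrow occupancy above the capacity limit is pushed
    out uniformly at random and reported as circulating blasts.
    """
    c, m_common, m_committed, split = engine._draw_step(state, params, rng)
    new_state = engine._apply_step(state, params, m_common, m_committed, split)

    new_mut = mutants.copy()
    q = None
    for key in sorted(mutants.cohorts,
                      key=lambda k: (k[0].value, k[1], k[2].value)):
        x, k, flags = key
        vec = mutants.cohorts[key]
        if not vec.any():
            continue
        is_blood = x is not Lineage.C and k == params.K(x)
        rate = _stage_rate(x, k, c, params)
        m = engine._sample_outflows(
            vec, np.full(vec.shape, rate), params.dt, params.gamma, rng
        )
        dst = new_mut._vec(key)
        if is_blood:
            dst -= m  # blood-stage mutants just die out
            continue
        if flags & MutationType.BLOCK and flags & MutationType.IMMORTAL:
            dst += m  # -m leave, +2m daughters at same stage and capacity
            continue
        if flags & MutationType.BLOCK:
            dst -= m  # capacity-0 cells vanish on attempted division
            dst[:-1] += 2 * m[1:]  # daughters: same stage, capacity - 1
            continue
        # IMMORTAL only: daughters advance one stage, capacity untouched.
        dst -= m
        if x is Lineage.C:
            if k < params.K_C:
                new_mut._vec((Lineage.C, k + 1, flags))[:] += 2 * m
            else:
                if q is None:
                    q = kinetics.commitment_probabilities(c, params)
                for rho in np.nonzero(m)[0]:
                    parts = rng.multinomial(int(m[rho]), q)
                    for y, n_y in zip(COMMITTED_LINEAGES, parts):
                        if n_y:
                            new_mut._vec((y, 1, flags))[rho] += 2 * n_y
        else:
            mult = params.m(x) if k == params.K(x) - 1 else 1
            new_mut._vec((x, k + 1, flags))[:] += 2 * m * mult

    # Marrow capacity: push out excess cells uniformly at random.
    blast_outflow = 0
    capacity = config.capacity_cells(params)
    occupancy = new_state.marrow_total() + new_mut.marrow_total(params)
    if occupancy > capacity:
        excess = occupancy - capacity
        # Normal and mutant cells alike are pushed out, stem pool included:
        # a marrow fully taken over by blasts stops hematopoiesis for good.
        pools, writers = [], []
        pools.append(new_state.common)
        writers.append(("common", None))
        for x in COMMITTED_LINEAGES:
            pools.append(new_state.committed[x][:-1])
            writers.append(("committed", x))
        mut_keys = [k for k in sorted(new_mut.cohorts,
                                      key=lambda k: (k[0].value, k[1], k[2].value))
                    if new_mut._is_marrow(k, params)]
        for k in mut_keys:
            pools.append(new_mut.cohorts[k])
            writers.append(("mutant", k))
        flat = np.concatenate([np.asarray(p, dtype=np.int64) for p in pools])
        removed = np.array(_remove_uniform(list(flat), excess, rng), dtype=np.int64)
        offset = 0
        for p, (kind, ref) in zip(pools, writers):
            n = len(p)
            r = removed[offset:offset + n]
            offset += n
            if kind == "common":
                new_state.common -= r
            elif kind == "committed":
                new_state.committed[ref][:-1] -= r
            else:
                new_mut.cohorts[ref] -= r
        blast_outflow = int(excess)

    new_mut.prune()
    return new_state, new_mut, blast_outflow


def simulate_with_mutants(params: ModelParameters, config: MutationConfig,
                          duration: float, rng: np.random.Generator,
                          initial: SystemState | None = None,
                          record_every: float | None = None,
                          stop_on_extinction: bool = False) -> TimeSeriesRecord:
    """Drive the extended stepper, injecting events at their times.

    Records blood counts, normal marrow total, mutant total and per-step
    blast outflow. With ``stop_on_extinction`` the run ends early once
    every scheduled event has fired and no mutant cells remain.
    """
    config.check(params)
    if initial is None:
        initial = engine.initial_steady_state(params)
    dt = params.dt
    if record_every is None:
        record_every = dt
    if record_every < dt:
        raise ValidationError("record_every must be at least dt")
    stride = max(1, int(round(record_every / dt)))
    n_steps = math.ceil(duration / dt - 1e-9)

    state = initial.copy()
    mutants = MutantCohortState(config.hayflick_limit)
    pending = sorted(config.events, key=lambda e: e.time_days)

    rows = []

    def snapshot(s, mut, blasts):
        blood = s.blood_counts()
        rows.append([
            s.t, blood[Lineage.E], blood[Lineage.G], blood[Lineage.T],
            s.marrow_total(), mut.total(), blasts,
        ])

    # Events scheduled at or before t = 0 fire before the first step.
    while pending and pending[0].time_days <= state.t + 1e-12:
        mutants.seed_event(pending.pop(0), params)
    snapshot(state, mutants, 0)

    for i in range(1, n_steps + 1):
        state, mutants, blasts = step_with_mutants(
            state, mutants, config, params, rng
        )
        while pending and pending[0].time_days <= state.t + 1e-12:
            mutants.seed_event(pending.pop(0), params)
        if i % stride == 0 or i == n_steps:
            snapshot(state, mutants, blasts)
        if stop_on_extinction and not pending and mutants.total() == 0:
            if rows[-1][0] != state.t:
                snapshot(state, mutants, blasts)
            break

    return TimeSeriesRecord(pd.DataFrame(
        rows,
        columns=["time_days", "E_blood", "G_blood", "T_blood",
                 "marrow_total", "mutant_total", "blast_outflow"],
    ))


# ---------------------------------------------------------------------------
# Analytic diagnosis / breakdown timeline (limited capacity ignored)
# ---------------------------------------------------------------------------

def rate_at_global_stage(j: int, params: ModelParameters,
                         lineage: Lineage | None = None) -> float:
    """The c = 0 division rate at global stage *j*.

    Stages ``j <= K_C`` are common precursors; beyond that a committed
    *lineage* must be named since the three branches differ.
    """
    if j <= params.K_C:
        return float(kinetics.common_precursor_rate(j, ZERO_CONCENTRATIONS, params))
    if lineage is None or lineage is Lineage.C:
        raise ValidationError("a committed lineage is required for j > K_C")
    return kinetics.committed_rate(
        lineage, j - params.K_C, ZERO_CONCENTRATIONS, params
    )


def expected_mutant_growth(j: int, t: float, params: ModelParameters,
                           lineage: Lineage | None = None) -> float:
    """Expected multiplier exp(r_j * t) of a block+immortal clone at stage j."""
    return math.exp(rate_at_global_stage(j, params, lineage) * t)


def time_to_diagnosis(j: int, params: ModelParameters,
                      lineage: Lineage | None = None,
                      founders: int = 1) -> float:
    """Years until a block+immortal clone at stage j reaches half the
    steady-state marrow cell total (the diagnosis threshold)."""
    r = rate_at_global_stage(j, params, lineage)
    threshold = 0.5 * steady_state.marrow_total(params)
    return math.log(threshold / founders) / r / 365.0


def time_diagnosis_to_breakdown(j: int, params: ModelParameters,
                                lineage: Lineage | None = None) -> float:
    """Years from diagnosis (half the marrow) to breakdown (twice the
    marrow): ln(4)/r_j, independent of the founder count."""
    r = rate_at_global_stage(j, params, lineage)
    return math.log(4.0) / r / 365.0
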