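"""Pre-packaged experiment setups.

Covers the canonical simulations of the model: closed-loop steady state,
recovery after a stem-cell transplant, and the four single-/double-
mutation experiments (immortal-only clone, block-only clone, early
differentiation block, late block+immortal clone).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import engine, mutations
from .model_core import (
    COMMITTED_LINEAGES,
    Lineage,
    ModelParameters,
    SystemState,
    TimeSeriesRecord,
    ValidationError,
)
from .mutations import MutationConfig, MutationEvent, MutationType

RECIPES = ("steady_state", "transplant", "custom")


@dataclass(frozen=True)
class ScenarioSpec:
    """A named, fully reproducible experiment setup."""

    name: str
    recipe: str = "steady_state"  # initial-state recipe
    duration_days: float = 365.0
    dt: float | None = None  # None -> parameter default
    gamma: float | None = None
    mutation_config: MutationConfig | None = None
    record_every: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.recipe not in RECIPES:
            raise ValidationError(
                f"unknown recipe {self.recipe!r}; expected one of {RECIPES}"
            )
        if self.duration_days <= 0:
            raise ValidationError("duration_days must be positive")


def transplant_initial_state(params: ModelParameters) -> SystemState:
    """Marrow emptied by myeloablative conditioning, stem pool re-engrafted.

    Erythrocytes and thrombocytes sit at their targets (transfused to
    stabilize the patient); granulocytes, which cannot be transfused and
    have a short half-life, start at zero.
    """
    state = SystemState.empty(params)
    state.committed[Lineage.E][-1] = int(params.N_E)
    state.committed[Lineage.T][-1] = int(params.N_T)
    # granulocyte blood stage stays 0
    return state


def _initial_state(spec: ScenarioSpec, params: ModelParameters,
                   custom_initial: SystemState | None) -> SystemState:
    if spec.recipe == "steady_state":
        return engine.initial_steady_state(params)
    if spec.recipe == "transplant":
        return transplant_initial_state(params)
    if custom_initial is None:
        raise ValidationError("custom recipe requires an explicit initial state")
    return custom_initial


def run_scenario(spec: ScenarioSpec, params: ModelParameters,
                 custom_initial: SystemState | None = None,
                 **sim_kwargs) -> TimeSeriesRecord:
    """Build the initial state, dispatch to the right stepper, return the record."""
    overrides = {}
    if spec.dt is not None:
        overrides["dt"] = spec.dt
    if spec.gamma is not None:
        overrides["gamma"] = spec.gamma
    if overrides:
        params = params.with_overrides(**overrides)
    rng = np.random.default_rng(spec.seed)
    initial = _initial_state(spec, params, custom_initial)
    record_every = sim_kwargs.pop("record_every", spec.record_every)
    if spec.mutation_config is not None:
        return mutations.simulate_with_mutants(
            params, spec.mutation_config, spec.duration_days, rng,
            initial=initial, record_every=record_every, **sim_kwargs,
        )
    return engine.simulate(
        initial, params, spec.duration_days, rng,
        record_every=record_every, **sim_kwargs,
    )


# -- canonical setups -------------------------------------------------------

def steady_state_scenario(duration_days: float = 365.0, gamma: float = 0.0,
                          seed: int = 0) -> ScenarioSpec:
    """Closed-loop run from the rounded steady-state profile."""
    return ScenarioSpec(name="steady", recipe="steady_state",
                        duration_days=duration_days, gamma=gamma, seed=seed)


def transplant_scenario(duration_days: float = 90.0, gamma: float = 0.0,
                        seed: int = 0) -> ScenarioSpec:
    """Stem-cell transplant recovery."""
    return ScenarioSpec(name="transplant", recipe="transplant",
                        duration_days=duration_days, gamma=gamma, seed=seed)


def immortal_only_scenario(duration_days: float = 365.0, seed: int = 0,
                           stage: int = 10) -> ScenarioSpec:
    """Single unlimited-replication mutation in the granulocyte lineage."""
    cfg = MutationConfig(events=(
        MutationEvent(0.0, Lineage.G, stage, MutationType.IMMORTAL),
    ))
    return ScenarioSpec(name="immortal_only", recipe="steady_state",
                        duration_days=duration_days, mutation_config=cfg,
                        seed=seed)


def block_only_scenario(duration_days: float = 365.0, seed: int = 0,
                        stage: int = 10) -> ScenarioSpec:
    """Single differentiation block in the granulocyte lineage."""
    cfg = MutationConfig(events=(
        MutationEvent(0.0, Lineage.G, stage, MutationType.BLOCK),
    ))
    return ScenarioSpec(name="block_only", recipe="steady_state",
                        duration_days=duration_days, mutation_config=cfg,
                        seed=seed)


def early_block_scenario(duration_days: float = 4000.0, seed: int = 0,
                         stage: int = 8, dt: float = 0.2) -> ScenarioSpec:
    """Differentiation block at an early common-precursor stage.

    Early clones have most of their replicative capacity left, grow past
    the marrow capacity and shut hematopoiesis down; a multi-year run with
    the coarser multi-year time step.
    """
    cfg = MutationConfig(events=(
        MutationEvent(0.0, Lineage.C, stage, MutationType.BLOCK),
    ))
    return ScenarioSpec(name="early_block", recipe="steady_state",
                        duration_days=duration_days, dt=dt,
                        mutation_config=cfg, seed=seed)


def late_double_mutation_scenario(duration_days: float = 400.0, seed: int = 0,
                                  stage: int = 10) -> ScenarioSpec:
    """Block + unlimited replication late in the granulocyte lineage."""
    cfg = MutationConfig(events=(
        MutationEvent(0.0, Lineage.G, stage,
                      MutationType.BLOCK | MutationType.IMMORTAL),
    ))
    return ScenarioSpec(name="late_double", recipe="steady_state",
                        duration_days=duration_days, mutation_config=cfg,
                        seed=seed)
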