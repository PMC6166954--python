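"""Shared domain types: lineages, parameters, system state, trajectories.

Stage indexing convention
-------------------------
Common precursors use local stages ``k = 0..K_C`` where stage 0 is the stem
cell compartment. Each committed lineage ``x in {E, G, T}`` uses local stages
``k = 1..K_x`` where ``k = K_x`` is the blood stream. The *global* stage index
used by the growth-factor sensitivities is ``j = k`` for common stages and
``j = K_C + k`` for committed stages, so the first committed compartment has
``j = K_C + 1``. All simulation counts are absolute cell numbers; per-µL
values are derived by dividing by ``blood_volume_uL``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from enum import Enum
import json
import math

import numpy as np
import pandas as pd


class Lineage(str, Enum):
    """Cell lineage symbol: C (common precursors), E, G, T (committed)."""

    C = "C"
    E = "E"
    G = "G"
    T = "T"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: The three committed myeloid lineages (erythrocyte, granulocyte, thrombocyte).
COMMITTED_LINEAGES = (Lineage.E, Lineage.G, Lineage.T)


class ValidationError(ValueError):
    """A model parameter or configuration violates an invariant."""


class StageRangeError(IndexError):
    """A stage index lies outside the compartment chain."""


@dataclass(frozen=True)
class GrowthFactors:
    """Log-concentrations of the three effective growth factors.

    ``c_x = 0`` means the corresponding blood count sits exactly at its
    target; positive values speed up division at every sensitive stage.
    """

    c_E: float = 0.0
    c_G: float = 0.0
    c_T: float = 0.0

    def __post_init__(self) -> None:
        for name in ("c_E", "c_G", "c_T"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValidationError(f"{name} must be finite, got {v!r}")

    def of(self, x: Lineage) -> float:
        """Concentration for committed lineage *x*."""
        return getattr(self, f"c_{x.value}")

    def as_array(self) -> np.ndarray:
        return np.array([self.c_E, self.c_G, self.c_T], dtype=float)


#: All growth factors at target (the conditional steady-state operating point).
ZERO_CONCENTRATIONS = GrowthFactors(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class ModelParameters:
    """All physiological and model constants.

    Units: rates in 1/day, times in days, counts absolute. ``b`` and the
    slopes ``a_x`` live on the log-odds scale of receptor occupancy;
    ``delta`` is the feedback gain in log-concentration units; ``gamma``
    scales the beta-binomial overdispersion (0 recovers plain binomial).
    """

    N_S: int
    N_E: float
    N_G: float
    N_T: float
    r_E: float
    r_G: float
    r_T: float
    m_E: int
    m_G: int
    m_T: int
    r_max: float
    b: float
    a_E: float
    a_G: float
    a_T: float
    K_C: int
    K_E: int
    K_G: int
    K_T: int
    delta: float
    gamma: float = 0.0
    dt: float = 0.04
    blood_volume_uL: float = 5.0e6

    # -- per-lineage accessors -------------------------------------------
    def N(self, x: Lineage) -> float:
        """Target blood count of committed lineage *x*."""
        return getattr(self, f"N_{x.value}")

    def r_blood_death(self, x: Lineage) -> float:
        """Blood-stream death rate of lineage *x* (1/day)."""
        return getattr(self, f"r_{x.value}")

    def m(self, x: Lineage) -> int:
        """Burst multiplicity (platelets per megakaryocyte nuclear unit)."""
        return getattr(self, f"m_{x.value}")

    def a(self, x: Lineage) -> float:
        """Sensitivity slope of lineage *x* (log-odds per stage)."""
        return getattr(self, f"a_{x.value}")

    def K(self, x: Lineage) -> int:
        """Number of stages of lineage *x* (committed: includes blood)."""
        return getattr(self, f"K_{x.value}")

    def global_stage(self, x: Lineage, k: int) -> int:
        """Global sensitivity index j for local stage *k* of lineage *x*."""
        if x is Lineage.C:
            if not 0 <= k <= self.K_C:
                raise StageRangeError(f"common stage {k} outside 0..{self.K_C}")
            return k
        if not 1 <= k <= self.K(x):
            raise StageRangeError(f"{x.value} stage {k} outside 1..{self.K(x)}")
        return self.K_C + k

    def local_stage(self, x: Lineage, j: int) -> int:
        """Inverse of :meth:`global_stage` for lineage *x*."""
        k = j if x is Lineage.C else j - self.K_C
        self.global_stage(x, k)  # range check
        return k

    # -- serialization ----------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, source) -> "ModelParameters":
        if hasattr(source, "read"):
            data = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                data = json.loads(text)
            else:
                with open(text) as fh:
                    data = json.load(fh)
        unknown = set(data) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise ValidationError(f"unknown parameter keys: {sorted(unknown)}")
        return validate(cls(**data))

    def with_overrides(self, **kw) -> "ModelParameters":
        return validate(replace(self, **kw))


def validate(params: ModelParameters) -> ModelParameters:
    """Check every parameter invariant; return the parameters unchanged.

    Raises :class:`ValidationError` naming the offending field.
    """
    p = params
    positives = {
        "N_S": p.N_S, "N_E": p.N_E, "N_G": p.N_G, "N_T": p.N_T,
        "r_E": p.r_E, "r_G": p.r_G, "r_T": p.r_T,
        "m_E": p.m_E, "m_G": p.m_G, "m_T": p.m_T,
        "r_max": p.r_max, "dt": p.dt, "blood_volume_uL": p.blood_volume_uL,
        "a_E": p.a_E, "a_G": p.a_G, "a_T": p.a_T,
    }
    for name, v in positives.items():
        if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
            raise ValidationError(f"{name} must be strictly positive, got {v!r}")
    for name in ("K_C", "K_E", "K_G", "K_T"):
        v = getattr(p, name)
        if not (isinstance(v, (int, np.integer)) and not isinstance(v, bool) and v >= 1):
            raise ValidationError(f"{name} must be a positive integer, got {v!r}")
    for name in ("b", "delta"):
        if not math.isfinite(getattr(p, name)):
            raise ValidationError(f"{name} must be finite")
    if p.gamma < 0 or not math.isfinite(p.gamma):
        raise ValidationError(f"gamma must be >= 0, got {p.gamma!r}")
    if p.r_max * p.dt > 1.0 + 1e-12:
        raise ValidationError(
            f"r_max*dt = {p.r_max * p.dt:g} > 1: per-step division "
            "probabilities would exceed 1"
        )
    for x in COMMITTED_LINEAGES:
        if p.r_blood_death(x) > p.r_max:
            raise ValidationError(f"r_{x.value} exceeds r_max")
    return params


@dataclass
class SystemState:
    """Integer cell counts of every compartment plus the simulation clock.

    ``common[k]`` holds stage k of the common precursors (``common[0]`` is
    the stem compartment and stays at ``N_S``); ``committed[x][k-1]`` holds
    stage k of lineage x, the last entry being the blood stream.
    """

    t: float
    common: np.ndarray
    committed: dict

    @classmethod
    def empty(cls, params: ModelParameters, t: float = 0.0) -> "SystemState":
        """All marrow compartments zero except the stem pool; blood zero."""
        common = np.zeros(params.K_C + 1, dtype=np.int64)
        common[0] = params.N_S
        committed = {
            x: np.zeros(params.K(x), dtype=np.int64) for x in COMMITTED_LINEAGES
        }
        return cls(t=t, common=common, committed=committed)

    def copy(self) -> "SystemState":
        return SystemState(
            t=self.t,
            common=self.common.copy(),
            committed={x: a.copy() for x, a in self.committed.items()},
        )

    def count(self, x: Lineage, k: int) -> int:
        if x is Lineage.C:
            return int(self.common[k])
        return int(self.committed[x][k - 1])

    def blood_counts(self) -> dict:
        """Mature counts in the blood stream, keyed by committed lineage."""
        return {x: int(self.committed[x][-1]) for x in COMMITTED_LINEAGES}

    def marrow_total(self) -> int:
        """Total cells outside the blood stream (stem pool included)."""
        total = int(self.common.sum())
        for x in COMMITTED_LINEAGES:
            total += int(self.committed[x][:-1].sum())
        return total

    def check(self, params: ModelParameters) -> None:
        if int(self.common[0]) != params.N_S:
            raise ValidationError("stem compartment count drifted from N_S")
        if (self.common < 0).any() or any(
            (a < 0).any() for a in self.committed.values()
        ):
            raise ValidationError("negative compartment count")


@dataclass
class TimeSeriesRecord:
    """Recorded trajectories keyed by column name, one row per time point.

    Always contains ``time_days``, the three blood counts (``E_blood``,
    ``G_blood``, ``T_blood``) and ``marrow_total``; mutation runs add
    ``mutant_total`` and ``blast_outflow``. ``per_microliter`` derives
    count columns divided by blood volume, suffixed ``_per_uL``.
    """

    frame: pd.DataFrame

    @property
    def time(self) -> np.ndarray:
        return self.frame["time_days"].to_numpy()

    def __len__(self) -> int:
        return len(self.frame)

    def series(self, name: str) -> np.ndarray:
        return self.frame[name].to_numpy()

    def per_microliter(self, blood_volume_uL: float) -> "TimeSeriesRecord":
        out = self.frame[["time_days"]].copy()
        for col in self.frame.columns:
            if col == "time_days":
                continue
            out[f"{col}_per_uL"] = self.frame[col] / blood_volume_uL
        return TimeSeriesRecord(out)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TimeSeriesRecord":
        return cls(pd.read_csv(path))
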