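"""Run configuration parsing and time-series serialization.

A run config is one flat YAML mapping. Recognized keys are the clinical
anchors (prefixed ``anchors.``-free, i.e. given directly by anchor field
name), calibrated-parameter overrides (by parameter field name), and the
run controls below. Unknown keys are rejected. Defaults reproduce the
calibrated healthy-adult model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields, replace
import hashlib
import json
import logging

import yaml

from .calibration import ClinicalAnchors, fit
from .model_core import (
    Lineage,
    ModelParameters,
    TimeSeriesRecord,
    ValidationError,
)
from .mutations import MutationConfig, MutationEvent, MutationType
from .scenarios import RECIPES, ScenarioSpec

log = logging.getLogger("myelosim")

_ANCHOR_KEYS = {f.name for f in dc_fields(ClinicalAnchors)}
_PARAM_KEYS = {f.name for f in dc_fields(ModelParameters)}
_RUN_KEYS = {
    "K_C", "scenario", "duration_days", "dt", "gamma", "seed",
    "record_every", "hayflick_limit", "marrow_capacity_per_uL",
    "mutation_events", "out", "per_microliter", "log_level",
}
_FLAG_NAMES = {"block": MutationType.BLOCK, "immortal": MutationType.IMMORTAL}


@dataclass
class RunConfig:
    """Validated configuration of one simulation run."""

    anchors: ClinicalAnchors
    param_overrides: dict
    spec: ScenarioSpec
    K_C: int = 14
    out: str | None = None
    per_microliter: bool = False
    log_level: str = "INFO"

    def parameters(self) -> ModelParameters:
        params = fit(self.anchors, K_C=self.K_C)
        if self.param_overrides:
            params = params.with_overrides(**self.param_overrides)
        return params


def _parse_events(raw) -> tuple:
    events = []
    if not isinstance(raw, list):
        raise ValidationError("mutation_events must be a list")
    for i, entry in enumerate(raw):
        if not isinstance(entry, dict):
            raise ValidationError(f"mutation_events[{i}] must be a mapping")
        unknown = set(entry) - {"time_days", "lineage", "stage", "flags", "count"}
        if unknown:
            raise ValidationError(
                f"unknown keys in mutation_events[{i}]: {sorted(unknown)}"
            )
        try:
            lineage = Lineage(entry["lineage"])
        except (KeyError, ValueError) as exc:
            raise ValidationError(
                f"mutation_events[{i}]: lineage must be one of C/E/G/T"
            ) from exc
        flags = MutationType(0)
        for name in entry.get("flags", []):
            if name not in _FLAG_NAMES:
                raise ValidationError(
                    f"mutation_events[{i}]: unknown flag {name!r}"
                )
            flags |= _FLAG_NAMES[name]
        events.append(MutationEvent(
            time_days=float(entry.get("time_days", 0.0)),
            lineage=lineage,
            stage=int(entry["stage"]),
            flags=flags,
            count=int(entry.get("count", 1)),
        ))
    return tuple(events)


def load_config(path) -> RunConfig:
    """Parse and validate a flat YAML run config, filling defaults."""
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except FileNotFoundError as exc:
        raise ValidationError(f"config file not found: {path}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValidationError("config must be a flat key-value mapping")

    unknown = set(raw) - _ANCHOR_KEYS - _PARAM_KEYS - _RUN_KEYS
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")

    def _num(key, value):
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise ValidationError(f"config key {key!r} must be a number")
        return value

    for key in ("dt", "gamma", "record_every", "duration_days", "seed", "K_C"):
        if key in raw:
            _num(key, raw[key])

    anchor_kwargs = {}
    for key in _ANCHOR_KEYS & set(raw):
        anchor_kwargs[key] = _num(key, raw[key])
    anchors = ClinicalAnchors(**anchor_kwargs)

    overrides = {}
    for key in (_PARAM_KEYS - _ANCHOR_KEYS - {"K_C", "dt", "gamma"}) & set(raw):
        overrides[key] = _num(key, raw[key])

    recipe = raw.get("scenario", "steady_state")
    mutation_config = None
    if "mutation_events" in raw or recipe == "leukemia":
        mutation_config = MutationConfig(
            hayflick_limit=int(raw.get("hayflick_limit", 60)),
            marrow_capacity_per_uL=float(raw.get("marrow_capacity_per_uL", 30000.0)),
            events=_parse_events(raw.get("mutation_events", [])),
        )
        if recipe == "leukemia":
            recipe = "steady_state"
    spec = ScenarioSpec(
        name=str(recipe),
        recipe=recipe,
        duration_days=float(raw.get("duration_days", 365.0)),
        dt=raw.get("dt"),
        gamma=raw.get("gamma"),
        mutation_config=mutation_config,
        record_every=raw.get("record_every"),
        seed=int(raw.get("seed", 0)),
    )
    return RunConfig(
        anchors=anchors,
        param_overrides=overrides,
        spec=spec,
        K_C=int(raw.get("K_C", 14)),
        out=raw.get("out"),
        per_microliter=bool(raw.get("per_microliter", False)),
        log_level=str(raw.get("log_level", "INFO")),
    )


def write_timeseries(record: TimeSeriesRecord, path) -> None:
    """Write a recorded trajectory as CSV (header mandatory)."""
    if len(record) == 0:
        raise ValidationError("refusing to write an empty record")
    record.to_csv(path)


def read_timeseries(path) -> TimeSeriesRecord:
    return TimeSeriesRecord.from_csv(path)


def parameter_hash(params: ModelParameters) -> str:
    """Short provenance hash of a parameter set."""
    return hashlib.sha256(params.to_json().encode()).hexdigest()[:12]


def log_provenance(params: ModelParameters, seed: int) -> None:
    log.info(
        "run provenance: seed=%d dt=%g gamma=%g params=%s",
        seed, params.dt, params.gamma, parameter_hash(params),
    )
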