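"""Declarative model configuration: schema, YAML IO, packaged models.

A model config is a versioned YAML mapping with a ``kind`` discriminator:

``complex_i``
    the packaged 17-state cycle, defined entirely by its thermodynamic
    ``parameters`` section (see :class:`ComplexIParamsConfig`);

``single_site``
    the three-state single-buried-site membrane proton transfer;

``custom``
    explicit ``states`` (label, dg0, cumulative charge moves) and
    ``transitions`` (barrier may be ``null`` = unknown) — the format the
    random-model generator emits.

Validation is strict: unknown keys are rejected, and a missing required
field raises a :class:`ConfigError` naming both the field and the
physical quantity it encodes.  Defaults that were applied are logged at
INFO level.  Three model files ship with the package:
``complex_i_ubiquinone``, ``complex_i_menaquinone`` and
``single_site_fig_passive``.
"""

from __future__ import annotations

import hashlib
import logging
from importlib import resources
from pathlib import Path
from typing import Any, Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from .constants import get_spec
from .pump import (
    ComplexIParams,
    PumpModel,
    PumpState,
    Transition,
    build_complex_i_model,
    build_single_site_model,
)
from .random_models import RandomPumpSpec
from .random_models import generate_random_pump as _generate_dict
from .thermo import ChargeMove

__all__ = [
    "ConfigError",
    "ModelConfig",
    "load_model",
    "loads_model",
    "dump_model",
    "build_model",
    "generate_random_pump",
    "packaged_model_path",
    "list_packaged_models",
]

logger = logging.getLogger("pcetpump")

#: Human descriptions of the physical quantity behind each config field,
#: used to make validation errors self-explanatory.
_FIELD_MEANING = {
    "donor_em_mv": "electron-donor midpoint potential Em (mV vs NHE; NADH couple)",
    "acceptor_em_mv": "electron-acceptor midpoint potential Em (mV vs NHE; quinone couple)",
    "n_electrons": "number of electrons transferred per cycle",
    "uptake_pka": "pKa of the proton-uptake site after quinone reduction",
    "release_pka": "pKa of the terminal/middle proton-relay residues",
    "q_motion_fraction": "fraction of the redox drop released by quinol motion",
    "relay_step_dg": "free energy of each lateral relay proton transfer (kcal/mol)",
    "ph_n": "N-side bulk pH",
    "ph_p": "P-side bulk pH",
    "pKa": "pKa of the single buried proton-loading site",
    "step_time_s": "assumed uptake/release timescale (s)",
}


class ConfigError(ValueError):
    """A model configuration failed schema validation."""


class ComplexIParamsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    donor_em_mv: float = -320.0
    acceptor_em_mv: float
    n_electrons: int = 2
    ph_n: float = 7.0
    ph_p: float = 7.0
    uptake_pka: float = 10.0
    release_pka: float = 9.0
    q_motion_fraction: float = 0.6
    relay_step_dg: float = -1.0
    q_reduction_barrier: float = 13.0
    q_motion_barrier: float = 4.0
    ion_pair_barrier: float = 4.0
    relay_barrier: float = 10.0
    water_barrier: float = 10.0
    buried_fraction: float = 0.5
    unknown_barrier_ceiling: float = 14.0
    exchange_barrier: float = 14.0
    final_step_dg: Optional[float] = None


class SingleSiteParamsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    pKa: float
    pH_N: float = 7.0
    pH_P: float = 7.0
    step_time_s: float = 1e-6
    buried_fraction: float = 0.5


class StateConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    label: str
    dg0: float
    #: cumulative charge moves completed by this state: [[charge, fraction], ...]
    moves: list[tuple[float, float]] = []


class TransitionConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    source: str
    target: str
    barrier: Optional[float] = None
    mechanism: str = ""


class ModelConfig(BaseModel):
    """Validated, schema-versioned model definition."""

    model_config = ConfigDict(extra="forbid")

    schema_version: Literal[1] = 1
    name: str
    kind: Literal["complex_i", "single_site", "custom"]
    constants_mode: Literal["exact", "rounded"] = "exact"
    parameters: ComplexIParamsConfig | SingleSiteParamsConfig | None = None
    states: Optional[list[StateConfig]] = None
    transitions: Optional[list[TransitionConfig]] = None
    unknown_barrier_ceiling: float = 14.0
    exchange_barrier: float = 14.0

    @model_validator(mode="before")
    @classmethod
    def _coerce_parameters(cls, data: Any) -> Any:
        if isinstance(data, dict) and isinstance(data.get("parameters"), dict):
            kind = data.get("kind")
            if kind == "complex_i":
                data["parameters"] = ComplexIParamsConfig(**data["parameters"])
            elif kind == "single_site":
                data["parameters"] = SingleSiteParamsConfig(**data["parameters"])
        return data

    @model_validator(mode="after")
    def _check_sections(self) -> "ModelConfig":
        if self.kind in ("complex_i", "single_site"):
            if self.parameters is None:
                raise ValueError(f"kind {self.kind!r} requires a parameters section")
            if self.states or self.transitions:
                raise ValueError(
                    f"kind {self.kind!r} builds its own states; "
                    "explicit states/transitions are only valid for kind 'custom'"
                )
            expected = (
                ComplexIParamsConfig if self.kind == "complex_i"
                else SingleSiteParamsConfig
            )
            if not isinstance(self.parameters, expected):
                raise ValueError(f"parameters section does not match kind {self.kind!r}")
        else:
            if not self.states or not self.transitions:
                raise ValueError("kind 'custom' requires states and transitions")
        return self

    def sha256(self) -> str:
        """Hash of the canonical serialized config (provenance)."""
        return hashlib.sha256(dump_model(self).encode()).hexdigest()


def _rewrap(exc: ValidationError, source: str) -> ConfigError:
    parts = []
    for err in exc.errors():
        loc = ".".join(str(x) for x in err["loc"])
        fieldname = str(err["loc"][-1]) if err["loc"] else ""
        meaning = _FIELD_MEANING.get(fieldname)
        msg = f"{loc}: {err['msg']}"
        if meaning:
            msg += f" [{meaning}]"
        parts.append(msg)
    return ConfigError(f"invalid model config {source}: " + "; ".join(parts))


def loads_model(text: str, source: str = "<string>") -> ModelConfig:
    """Parse and validate a YAML model config from a string."""
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError(f"{source}: model config must be a mapping")
    try:
        cfg = ModelConfig(**raw)
    except ValidationError as exc:
        raise _rewrap(exc, source) from None
    if isinstance(cfg.parameters, BaseModel):
        defaulted = [
            f for f in type(cfg.parameters).model_fields
            if f not in cfg.parameters.model_fields_set
        ]
        if defaulted:
            logger.info(
                "%s: defaults applied for %s", cfg.name, ", ".join(sorted(defaulted))
            )
    return cfg


def load_model(path: str | Path) -> ModelConfig:
    """Load and validate a model config from a YAML file; packaged model
    names (e.g. ``"complex_i_ubiquinone"``) are accepted as well."""
    p = Path(path)
    if not p.exists():
        candidate = packaged_model_path(str(path))
        if candidate is not None:
            p = candidate
        else:
            raise FileNotFoundError(
                f"no such model file or packaged model: {path}"
            )
    return loads_model(p.read_text(), source=str(p))


def dump_model(config: ModelConfig, path: str | Path | None = None) -> str:
    """Serialize a config to canonical YAML; round-trips with
    :func:`load_model`."""
    payload = config.model_dump(exclude_none=True)
    text = yaml.safe_dump(payload, sort_keys=True, default_flow_style=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def build_model(config: ModelConfig) -> PumpModel:
    """Instantiate the :class:`~pcetpump.pump.PumpModel` a config
    describes."""
    spec = get_spec(config.constants_mode)
    if config.kind == "complex_i":
        pc = config.parameters
        params = ComplexIParams(**pc.model_dump())
        model = build_complex_i_model(params, spec)
    elif config.kind == "single_site":
        pc = config.parameters
        model = build_single_site_model(
            pKa=pc.pKa, pH_N=pc.pH_N, pH_P=pc.pH_P,
            step_time=pc.step_time_s, buried_fraction=pc.buried_fraction,
            spec=spec,
        )
    else:
        states = tuple(
            PumpState(
                s.label, s.dg0,
                tuple(ChargeMove(c, f) for c, f in s.moves),
            )
            for s in config.states
        )
        transitions = tuple(
            Transition(t.source, t.target, t.barrier, t.mechanism)
            for t in config.transitions
        )
        model = PumpModel(
            states=states,
            transitions=transitions,
            spec=spec,
            unknown_barrier_ceiling=config.unknown_barrier_ceiling,
            exchange_barrier=config.exchange_barrier,
            provenance={"model": config.name, "constants_mode": spec.mode},
        )
    model.provenance["config_name"] = config.name
    model.provenance["config_sha256"] = config.sha256()
    return model


def generate_random_pump(spec: RandomPumpSpec) -> ModelConfig:
    """Generate a synthetic closed-cycle pump config (deterministic per
    seed); see :mod:`pcetpump.random_models` for the construction."""
    raw = _generate_dict(spec)
    return loads_model(yaml.safe_dump(raw), source=f"<random seed={spec.seed}>")


def list_packaged_models() -> list[str]:
    """Names of the model files that ship with the package."""
    pkg = resources.files("pcetpump") / "data"
    return sorted(
        p.name.removesuffix(".yaml")
        for p in pkg.iterdir()
        if p.name.endswith(".yaml")
    )


def packaged_model_path(name: str) -> Path | None:
    """Filesystem path of a packaged model, or None if no such model."""
    fname = name if name.endswith(".yaml") else name + ".yaml"
    ref = resources.files("pcetpump") / "data" / fname
    try:
        with resources.as_file(ref) as p:
            return Path(p) if p.exists() else None
    except FileNotFoundError:
        return None
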