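"""Run configuration: one YAML file describing subject, controller, ventilator,
protocol and logging options, validated before any run.

Defaults reproduce the pilot settings: 7.5 mL/kg volume guarantee, PEEP
5.0 hPa, etCO2 target 7.0 kPa, SpO2 minimum 97%, ORI band 0.0-0.4,
40 s control interval, 0.8 s inspiratory time.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Union

import yaml

from . import subject as subj
from .controller import ControllerConfig
from .core import VentilatorSettings
from .errors import ConfigError
from .protocol import Protocol, default_ventilator, load_protocol


@dataclass
class RunConfig:
    subject: subj.SubjectParams = field(default_factory=subj.SubjectParams)
    controller: ControllerConfig = field(default_factory=ControllerConfig)
    ventilator: Optional[VentilatorSettings] = None
    protocol: Union[str, Protocol] = "default"
    seed: int = 0
    dt: float = 1.0

    def resolved_ventilator(self) -> VentilatorSettings:
        return self.ventilator or default_ventilator(self.subject)

    def resolved_protocol(self) -> Protocol:
        if isinstance(self.protocol, Protocol):
            return self.protocol
        return load_protocol(self.protocol)

    def snapshot(self) -> dict:
        """Serializable snapshot sufficient to reproduce the run."""
        proto = self.resolved_protocol()
        return {
            "seed": self.seed,
            "dt": self.dt,
            "subject": dataclasses.asdict(self.subject),
            "controller": dataclasses.asdict(self.controller),
            "ventilator": dataclasses.asdict(self.resolved_ventilator()),
            "protocol": {
                "name": proto.name,
                "steps": [dataclasses.asdict(s) for s in proto.steps],
            },
        }


def _build(cls, section: dict, name: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    for key in section:
        if key not in fields:
            raise ConfigError(f"unknown field '{name}.{key}'")
    try:
        return cls(**section)
    except TypeError as exc:
        raise ConfigError(f"invalid section '{name}': {exc}") from exc


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    Raises :class:`ConfigError` naming the offending field on any problem.
    """
    try:
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
    except FileNotFoundError as exc:
        raise ConfigError(f"config file not found: {path}") from exc
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed YAML in {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError(f"config file {path} must be a mapping of sections")

    known = {"subject", "controller", "ventilator", "protocol", "seed", "dt", "logging"}
    for key in doc:
        if key not in known:
            raise ConfigError(f"unknown config section '{key}'")

    subject_sec = dict(doc.get("subject", {}))
    if "noise_sd" in subject_sec:
        subject_sec["noise_sd"] = _build(
            subj.NoiseLevels, dict(subject_sec["noise_sd"]), "subject.noise_sd"
        )
    params = _build(subj.SubjectParams, subject_sec, "subject")
    cfg = _build(ControllerConfig, dict(doc.get("controller", {})), "controller")
    vent = None
    if "ventilator" in doc:
        vent = _build(VentilatorSettings, dict(doc["ventilator"]), "ventilator")
    protocol = doc.get("protocol", "default")
    seed = doc.get("seed", 0)
    dt = doc.get("dt", 1.0)
    if not isinstance(seed, int):
        raise ConfigError(f"'seed' must be an integer, got {seed!r}")
    if not isinstance(dt, (int, float)) or dt <= 0:
        raise ConfigError(f"'dt' must be a positive number, got {dt!r}")
    return RunConfig(
        subject=params, controller=cfg, ventilator=vent,
        protocol=protocol, seed=seed, dt=float(dt),
    )
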