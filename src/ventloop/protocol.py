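"""Automated experiment protocol: the IAP staircase with CT breath holds.

The pre-programmed experiment steps the insufflation pressure through
0, 5, 8, 10, 12, 14, 16, 18, 20, 16, 10, 5, 0 hPa.  Each step holds its
pressure for a 3-minute stabilization window, after which a CT scan is taken
during an expiratory and an inspiratory breath hold.  Holds default to 5 s
(one helical acquisition of a 21.5 kg animal) followed by a 35 s gap for
scanner preparation; both are configurable.  During every hold ventilation
pauses, the end-tidal channel is flagged invalid and controller actuation is
frozen; control cycles resume at the next interval boundary.

``run_protocol`` closes the loop between the virtual subject, the controller
and the insufflator, labels every log record with the active step, and
supports a manual-override hook mirroring the platform's operator override.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence

import yaml

from . import subject as subj
from .bus import RunLog, record
from .controller import ControllerConfig, condition_measurements, control_cycle
from .core import (
    InsufflatorSettings,
    VentilatorSettings,
    VitalSample,
    tidal_volume_setting,
)
from .errors import ConfigError, SimulationError

__version__ = "0.1.0"

HOLD_PHASES = ("expiratory", "inspiratory")

#: The staircase pressure sequence, hPa.
STAIRCASE_IAPS = (0, 5, 8, 10, 12, 14, 16, 18, 20, 16, 10, 5, 0)


@dataclass(frozen=True)
class BreathHoldSpec:
    """One respiratory pause for CT scanning."""

    phase: str  # expiratory | inspiratory
    duration: float = 5.0  # s

    def __post_init__(self) -> None:
        if self.phase not in HOLD_PHASES:
            raise ConfigError(f"hold phase must be one of {HOLD_PHASES}, got {self.phase!r}")
        if self.duration <= 0:
            raise ConfigError(f"hold duration must be positive, got {self.duration}")


@dataclass(frozen=True)
class ProtocolStep:
    """One staircase stage: IAP target, stabilization timer, then breath holds.

    The holds occur after the stabilization window and extend the step; each
    hold is followed by ``post_hold_gap`` seconds of resumed ventilation for
    scanner preparation / recovery before the next hold or step.
    """

    iap: float  # hPa
    stabilization: float = 180.0  # s
    holds: Sequence[BreathHoldSpec] = ()
    label: str = ""
    post_hold_gap: float = 35.0  # s after each hold

    def __post_init__(self) -> None:
        if self.stabilization < 0:
            raise ConfigError(f"stabilization must be >= 0, got {self.stabilization}")
        if self.post_hold_gap < 0:
            raise ConfigError(f"post_hold_gap must be >= 0, got {self.post_hold_gap}")

    @property
    def duration(self) -> float:
        return self.stabilization + sum(h.duration + self.post_hold_gap for h in self.holds)


@dataclass(frozen=True)
class Protocol:
    steps: Sequence[ProtocolStep]
    name: str = "protocol"

    def __post_init__(self) -> None:
        if not self.steps:
            raise ConfigError("a protocol needs at least one step")

    @property
    def duration(self) -> float:
        return sum(s.duration for s in self.steps)


def default_protocol(
    stabilization: float = 180.0,
    hold_duration: float = 5.0,
    post_hold_gap: float = 35.0,
) -> Protocol:
    """The 13-step IAP staircase with paired CT breath holds per plateau."""
    steps = []
    for i, iap in enumerate(STAIRCASE_IAPS):
        steps.append(
            ProtocolStep(
                iap=float(iap),
                stabilization=stabilization,
                holds=(
                    BreathHoldSpec("expiratory", hold_duration),
                    BreathHoldSpec("inspiratory", hold_duration),
                ),
                label=f"step{i:02d}_iap{iap:g}",
                post_hold_gap=post_hold_gap,
            )
        )
    return Protocol(steps=tuple(steps), name="iap_staircase")


def load_protocol(source) -> Protocol:
    """Load a protocol from a YAML file, or the built-in staircase.

    ``source`` may be the keyword ``"default"`` or a path to a YAML document:

    .. code-block:: yaml

        name: my_protocol
        steps:
          - {iap: 0, stabilization: 180, holds: [{phase: expiratory, duration: 5}]}
    """
    if source == "default":
        return default_protocol()
    with open(source, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "steps" not in doc:
        raise ConfigError(f"protocol file {source} must define a 'steps' list")
    steps = []
    for i, raw in enumerate(doc["steps"]):
        if "iap" not in raw:
            raise ConfigError(f"protocol step {i} is missing field 'iap'")
        holds = tuple(
            BreathHoldSpec(h["phase"], float(h.get("duration", 5.0)))
            for h in raw.get("holds", [])
        )
        steps.append(
            ProtocolStep(
                iap=float(raw["iap"]),
                stabilization=float(raw.get("stabilization", 180.0)),
                holds=holds,
                label=raw.get("label", f"step{i:02d}_iap{raw['iap']:g}"),
                post_hold_gap=float(raw.get("post_hold_gap", 35.0)),
            )
        )
    return Protocol(steps=tuple(steps), name=doc.get("name", "protocol"))


def default_ventilator(params: subj.SubjectParams) -> VentilatorSettings:
    """Initial ventilator settings of the pilot protocol: 7.5 mL/kg volume
    guarantee, PEEP 5 hPa, Ti 0.8 s, RR 20 bpm, FiO2 25%."""
    return VentilatorSettings(
        tidal_volume=tidal_volume_setting(params.weight, 7.5, 10.0),
        respiratory_rate=20.0,
        peep=5.0,
        fio2=25.0,
        inspiratory_time=0.8,
    )


@dataclass(frozen=True)
class _HoldWindow:
    start: float
    end: float
    phase: str


def _schedule(protocol: Protocol):
    """Absolute timeline: (step start, step, hold windows) per step."""
    t = 0.0
    out = []
    for step in protocol.steps:
        holds = []
        h0 = t + step.stabilization
        for h in step.holds:
            holds.append(_HoldWindow(h0, h0 + h.duration, h.phase))
            h0 += h.duration + step.post_hold_gap
        out.append((t, step, holds))
        t += step.duration
    return out


def breath_hold(
    state: subj.SubjectState,
    params: subj.SubjectParams,
    vent: VentilatorSettings,
    insuff: InsufflatorSettings,
    phase: str,
    duration: float,
    dt: float = 1.0,
) -> subj.SubjectState:
    """Advance the subject through one breath hold.

    Ventilation is zero throughout; the held lung volume (end-expiratory at
    PEEP, or end-inspiratory at PEEP + Vt) differs per phase but the gas
    kinetics of the minimal model are identical for both.
    """
    if phase not in HOLD_PHASES:
        raise ConfigError(f"hold phase must be one of {HOLD_PHASES}, got {phase!r}")
    if duration <= 0:
        raise ConfigError(f"hold duration must be positive, got {duration}")
    t = 0.0
    while t < duration - 1e-9:
        step = min(dt, duration - t)
        state = subj.advance(state, params, vent, insuff, step, breath_hold=True)
        t += step
    return state


OverrideHook = Callable[[float, VentilatorSettings], Optional[VentilatorSettings]]


def run_protocol(
    protocol: Protocol,
    params: Optional[subj.SubjectParams] = None,
    cfg: Optional[ControllerConfig] = None,
    vent: Optional[VentilatorSettings] = None,
    seed: int = 0,
    dt: float = 1.0,
    override: Optional[OverrideHook] = None,
    header_extra: Optional[dict] = None,
) -> RunLog:
    """Simulate the full protocol timeline against the virtual subject.

    At each step the insufflator setpoint is commanded and the subject is
    advanced tick by tick; the controller executes at every multiple of
    ``cfg.interval`` outside breath holds; every record carries the step
    label.  The optional ``override`` hook may inject manual settings at any
    tick; applied overrides are flagged in the log.  With noise disabled the
    run is bit-reproducible for a fixed seed.
    """
    params = params or subj.SubjectParams()
    cfg = cfg or ControllerConfig()
    settings = vent or default_ventilator(params)
    if dt <= 0:
        raise SimulationError(f"dt must be positive, got {dt}")

    max_iap = max(s.iap for s in protocol.steps)
    rng = subj.SignalRngs(seed) if params.noise_sd.any_enabled else None
    insuff = InsufflatorSettings(iap_setpoint=protocol.steps[0].iap,
                                 max_iap=max(20.0, max_iap))
    state = subj.initial_state(params, settings,
                               InsufflatorSettings(iap_setpoint=0.0))
    schedule = _schedule(protocol)
    total = protocol.duration

    header = {
        "ventloop_version": __version__,
        "seed": seed,
        "dt_s": dt,
        "protocol": protocol.name,
        "n_steps": len(protocol.steps),
        "subject": _asdict(params),
        "controller": dataclasses.asdict(cfg),
        "ventilator_initial": dataclasses.asdict(settings),
    }
    header.update(header_extra or {})
    log = RunLog(header)

    def locate(t: float):
        for t0, step, holds in schedule:
            if t0 <= t < t0 + step.duration or (step is schedule[-1][1] and t >= t0):
                for hw in holds:
                    if hw.start <= t < hw.end:
                        return step, hw
                return step, None
        return schedule[-1][1], None

    samples: List[VitalSample] = []
    n_ticks = int(round(total / dt))
    for k in range(n_ticks + 1):
        t = k * dt
        step, hold = locate(t)
        insuff = dataclasses.replace(insuff, iap_setpoint=step.iap)
        hold_now = hold is not None
        obs_state = dataclasses.replace(state, breath_hold_active=hold_now)
        sample = subj.observe(obs_state, params, settings, rng,
                              hold_phase=hold.phase if hold_now else None)
        samples.append(sample)

        command = False
        override_flag = False
        if k > 0 and _is_cycle(t, cfg.interval, dt) and not hold_now:
            inp = condition_measurements(samples, t, cfg, breath_hold=False)
            new = control_cycle(inp, settings, cfg)
            command = new != settings
            settings = new
        if override is not None:
            injected = override(t, settings)
            if injected is not None and injected != settings:
                settings = injected
                override_flag = True

        record(
            log, t, step.label, sample, settings, insuff,
            phase=hold.phase if hold_now else "run",
            breath_hold=hold_now,
            iap_actual=state.iap_actual,
            paco2=state.paco2,
            pao2=state.pao2,
            command=command,
            override=override_flag,
        )

        if k < n_ticks:
            _, hold_mid = locate(t + dt / 2.0)
            try:
                state = subj.advance(state, params, settings, insuff, dt,
                                     breath_hold=hold_mid is not None)
            except SimulationError as exc:
                raise SimulationError(f"[{step.label}] {exc}") from exc
    return log


def run_closed_loop(
    iap: float,
    duration: float,
    params: Optional[subj.SubjectParams] = None,
    cfg: Optional[ControllerConfig] = None,
    vent: Optional[VentilatorSettings] = None,
    seed: int = 0,
    dt: float = 1.0,
) -> RunLog:
    """Free-running closed loop at constant IAP, no breath holds."""
    step = ProtocolStep(iap=float(iap), stabilization=float(duration), holds=(),
                        label=f"const_iap{iap:g}")
    proto = Protocol(steps=(step,), name=f"constant_iap{iap:g}")
    return run_protocol(proto, params, cfg, vent, seed=seed, dt=dt)


def _is_cycle(t: float, interval: float, dt: float) -> bool:
    r = t % interval
    tol = min(dt, interval) * 1e-6
    return r < tol or interval - r < tol


def _asdict(params: subj.SubjectParams) -> dict:
    d = dataclasses.asdict(params)
    return d
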