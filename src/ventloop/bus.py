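"""Mock-device layer: time-synchronized run logging and log replay.

The hardware platform couples an insufflator, a ventilator and a patient
monitor over serial lines and records all streams against a single clock.
The desk stand-in is a :class:`RunLog`: one wide CSV row per simulation tick
on a single monotone clock, every row labelled with the active protocol step,
plus a JSON header carrying the full configuration snapshot so a run
directory is self-describing.

``replay`` streams a recorded (or hand-written) log back through the
controller without the simulator, reproducing the command sequence of the
live run bit-for-bit.
"""

from __future__ import annotations

import io
import json
import re
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence

import pandas as pd

from .controller import ControllerConfig, condition_measurements, control_cycle
from .core import InsufflatorSettings, VentilatorSettings, VitalSample
from .errors import LoggingError, SchemaError

#: Fixed column order, for diffability.
COLUMNS = [
    "time_s",
    "step_label",
    "phase",
    "breath_hold",
    "valid",
    "etco2_valid",
    "etco2_kpa",
    "spo2_pct",
    "ori",
    "pip_hpa",
    "paco2_kpa",
    "pao2_mmhg",
    "iap_hpa",
    "iap_set_hpa",
    "rr_bpm",
    "fio2_pct",
    "vt_ml",
    "peep_hpa",
    "ti_s",
    "command",
    "override",
]

_HEADER_MAGIC = "# ventloop-runlog v1"


@dataclass(frozen=True)
class DeviceEndpoint:
    """One device on the bus: name, role and command-to-effect latency."""

    name: str
    role: str  # ventilator | insufflator | monitor
    latency: float = 0.0  # s
    last_seen: Optional[float] = None

    def __post_init__(self) -> None:
        if self.role not in ("ventilator", "insufflator", "monitor"):
            raise LoggingError(f"unknown device role {self.role!r}")
        if self.latency < 0:
            raise LoggingError(f"latency must be >= 0, got {self.latency}")


def default_bus() -> List[DeviceEndpoint]:
    """The platform's primary device topology."""
    return [
        DeviceEndpoint("ventilator", "ventilator"),
        DeviceEndpoint("insufflator", "insufflator"),
        DeviceEndpoint("patient_monitor", "monitor"),
    ]


def validate_bus(endpoints: Sequence[DeviceEndpoint]) -> None:
    names = [e.name for e in endpoints]
    if len(set(names)) != len(names):
        raise LoggingError(f"device names must be unique on a bus, got {names}")


class RunLog:
    """Time-synchronized multi-stream record of one run.

    The header (configuration snapshot, seed, defaults) is written once; each
    record is one row on a single monotone clock carrying all signals, the
    active settings, the step label and command/override flags.
    """

    def __init__(self, header: Optional[dict] = None) -> None:
        self.header: dict = dict(header or {})
        self.records: List[dict] = []

    def __len__(self) -> int:
        return len(self.records)

    @property
    def last_timestamp(self) -> Optional[float]:
        return self.records[-1]["time_s"] if self.records else None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=COLUMNS)

    def write_csv(self, path) -> None:
        frame = self.to_frame()
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write(_HEADER_MAGIC + "\n")
            fh.write("# header: " + json.dumps(self.header, sort_keys=True) + "\n")
            frame.to_csv(fh, index=False, lineterminator="\n")

    @classmethod
    def read_csv(cls, path) -> "RunLog":
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
        header: dict = {}
        body_lines = []
        for line in text.splitlines():
            if line.startswith("# header:"):
                header = json.loads(line[len("# header:"):])
            elif line.startswith("#"):
                continue
            else:
                body_lines.append(line)
        # round_trip parsing keeps write->read->write bit-identical
        frame = pd.read_csv(io.StringIO("\n".join(body_lines)), float_precision="round_trip")
        missing = [c for c in COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"run-log CSV is missing column(s): {', '.join(missing)}")
        log = cls(header)
        log.records = frame.to_dict("records")
        return log


def record(
    log: RunLog,
    timestamp: float,
    step_label: str,
    sample: VitalSample,
    settings: VentilatorSettings,
    insufflator: InsufflatorSettings,
    *,
    phase: str = "run",
    breath_hold: bool = False,
    iap_actual: Optional[float] = None,
    paco2: Optional[float] = None,
    pao2: Optional[float] = None,
    command: bool = False,
    override: bool = False,
) -> RunLog:
    """Append one row; the clock must never run backwards."""
    last = log.last_timestamp
    if last is not None and timestamp < last:
        raise LoggingError(
            f"clock regression: timestamp {timestamp} s after {last} s"
        )
    log.records.append(
        {
            "time_s": timestamp,
            "step_label": step_label,
            "phase": phase,
            "breath_hold": int(breath_hold),
            "valid": int(sample.valid),
            "etco2_valid": int(sample.etco2_valid),
            "etco2_kpa": sample.etco2,
            "spo2_pct": sample.spo2,
            "ori": sample.ori,
            "pip_hpa": sample.pip,
            "paco2_kpa": paco2 if paco2 is not None else float("nan"),
            "pao2_mmhg": pao2 if pao2 is not None else float("nan"),
            "iap_hpa": iap_actual if iap_actual is not None else float("nan"),
            "iap_set_hpa": insufflator.iap_setpoint,
            "rr_bpm": settings.respiratory_rate,
            "fio2_pct": settings.fio2,
            "vt_ml": settings.tidal_volume,
            "peep_hpa": settings.peep,
            "ti_s": settings.inspiratory_time,
            "command": int(command),
            "override": int(override),
        }
    )
    return log


def log_filename(protocol_name: str, step_label: str, start_stamp: str) -> str:
    """Automated file name derived from protocol, step label and start stamp."""
    parts = [protocol_name, step_label, start_stamp]
    safe = [re.sub(r"[^A-Za-z0-9._-]+", "-", str(p)).strip("-") for p in parts if p]
    return "_".join(safe) + ".csv"


def _samples_from_frame(frame: pd.DataFrame) -> List[VitalSample]:
    samples = []
    for row in frame.itertuples(index=False):
        samples.append(
            VitalSample(
                timestamp=float(row.time_s),
                etco2=float(row.etco2_kpa),
                spo2=float(row.spo2_pct),
                ori=float(row.ori),
                pip=float(row.pip_hpa),
                valid=bool(row.valid),
                etco2_valid=bool(row.etco2_valid),
            )
        )
    return samples


def replay(
    csv_path,
    cfg: ControllerConfig,
    initial_settings: Optional[VentilatorSettings] = None,
) -> List[tuple]:
    """Stream a recorded log through the controller; return the command trace.

    The trace holds one entry per executed control cycle:
    ``(time, rr, fio2, changed)``.  Initial settings default to the ones in
    the log's first row.  A live run and a replay of its own log produce
    identical traces.
    """
    log = RunLog.read_csv(csv_path)
    frame = log.to_frame()
    if frame.empty:
        return []
    samples = _samples_from_frame(frame)
    hold_by_time = dict(zip(frame["time_s"], frame["breath_hold"].astype(bool)))
    if initial_settings is None:
        first = frame.iloc[0]
        initial_settings = VentilatorSettings(
            tidal_volume=float(first["vt_ml"]),
            respiratory_rate=float(first["rr_bpm"]),
            peep=float(first["peep_hpa"]),
            fio2=float(first["fio2_pct"]),
            inspiratory_time=float(first["ti_s"]),
        )
    settings = initial_settings
    t_end = float(frame["time_s"].iloc[-1])
    trace = []
    n_cycles = int(t_end / cfg.interval + 1e-9)
    window: List[VitalSample] = []
    si = 0
    for k in range(1, n_cycles + 1):
        t = k * cfg.interval
        while si < len(samples) and samples[si].timestamp <= t + 1e-9:
            window.append(samples[si])
            si += 1
        hold = hold_by_time.get(t, False)
        inp = condition_measurements(window, t, cfg, breath_hold=bool(hold))
        new = control_cycle(inp, settings, cfg)
        trace.append((t, new.respiratory_rate, new.fio2, new != settings))
        settings = new
    return trace
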