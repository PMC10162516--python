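"""Closed-loop ventilation controller.

CO2 and O2 are regulated by two independent incremental branches executed at
a fixed interval (default 40 s):

* CO2 branch: the respiratory rate moves one step (default 1 bpm) toward the
  etCO2 target (default 7.0 kPa, permissive hypercapnia) whenever the
  conditioned etCO2 leaves the deadband, clamped to the hardware range
  (4-37 bpm) with an active safety floor (10 bpm).  Tidal volume, PEEP and
  inspiratory time are never touched.
* O2 branch: FiO2 is raised one step (default 1%) to build a hyperoxic
  buffer while SpO2 sits in the 97-98% band with ORI inside 0.0-0.4, or
  whenever SpO2 falls below the 97% safety minimum; FiO2 is lowered one step
  when ORI exceeds 0.4.  With SpO2 above the band and ORI in range FiO2 is
  held: the buffer is already adequate.

Measurements are conditioned before use: only valid samples from the most
recent averaging window (default 5 s) are averaged per channel, and actuation
is halted entirely during breath holds or when the window is stale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .core import VentilatorSettings, VitalSample
from .errors import ConfigError

# Physiologic plausibility limits for the validity check.
_ETCO2_RANGE = (0.0, 20.0)  # kPa
_SPO2_RANGE = (50.0, 100.0)  # %
_ORI_RANGE = (0.0, 1.0)


@dataclass(frozen=True)
class ControllerConfig:
    """Targets, bands, step sizes, limits and timing of the control algorithm."""

    etco2_target: float = 7.0  # kPa
    etco2_deadband: float = 0.2  # kPa, +/- around the target
    rr_step: float = 1.0  # bpm per cycle
    rr_min_hw: float = 4.0  # bpm, ventilator hardware minimum
    rr_max_hw: float = 37.0  # bpm, ventilator hardware maximum
    rr_min_safety: float = 10.0  # bpm, active lower limit
    fio2_step: float = 1.0  # % per cycle
    spo2_band_lo: float = 97.0  # %
    spo2_band_hi: float = 98.0  # %
    spo2_min: float = 97.0  # %, minimum allowed saturation
    ori_lo: float = 0.0
    ori_hi: float = 0.4
    interval: float = 40.0  # s between controller executions
    avg_window: float = 5.0  # s of data averaged per execution

    def __post_init__(self) -> None:
        if not self.rr_min_hw <= self.rr_min_safety < self.rr_max_hw:
            raise ConfigError(
                "require rr_min_hw <= rr_min_safety < rr_max_hw, got "
                f"{self.rr_min_hw}, {self.rr_min_safety}, {self.rr_max_hw}"
            )
        if self.spo2_band_lo > self.spo2_band_hi:
            raise ConfigError("spo2_band_lo must not exceed spo2_band_hi")
        if self.ori_lo >= self.ori_hi:
            raise ConfigError("ori_lo must be below ori_hi")
        if self.interval <= 0:
            raise ConfigError(f"interval must be positive, got {self.interval}")
        if self.avg_window <= 0:
            raise ConfigError(f"avg_window must be positive, got {self.avg_window}")
        for name in ("etco2_deadband", "rr_step", "fio2_step"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")

    @property
    def rr_floor(self) -> float:
        return max(self.rr_min_hw, self.rr_min_safety)


@dataclass(frozen=True)
class ControllerInput:
    """Conditioned measurements fed to one controller execution."""

    etco2_avg: float
    spo2_avg: float
    ori_avg: float
    breath_hold: bool = False
    stale: bool = False


def _sample_ok(s: VitalSample) -> bool:
    return (
        s.valid
        and _SPO2_RANGE[0] <= s.spo2 <= _SPO2_RANGE[1]
        and _ORI_RANGE[0] <= s.ori <= _ORI_RANGE[1]
    )


def _etco2_ok(s: VitalSample) -> bool:
    return _sample_ok(s) and s.etco2_valid and _ETCO2_RANGE[0] <= s.etco2 <= _ETCO2_RANGE[1]


def condition_measurements(
    samples: Sequence[VitalSample],
    now: float,
    cfg: ControllerConfig,
    breath_hold: bool = False,
) -> ControllerInput:
    """Average valid samples in the window (now - avg_window, now] per channel.

    Staleness is signalled, never raised: a stale input freezes actuation
    downstream.  The etCO2 channel additionally excludes samples flagged
    invalid during breath holds.
    """
    window = [s for s in samples if now - cfg.avg_window < s.timestamp <= now]
    et_vals = [s.etco2 for s in window if _etco2_ok(s)]
    sp_vals = [s.spo2 for s in window if _sample_ok(s)]
    ori_vals = [s.ori for s in window if _sample_ok(s)]
    stale = not et_vals or not sp_vals or not ori_vals
    mean = lambda xs: sum(xs) / len(xs) if xs else float("nan")
    return ControllerInput(
        etco2_avg=mean(et_vals),
        spo2_avg=mean(sp_vals),
        ori_avg=mean(ori_vals),
        breath_hold=breath_hold,
        stale=stale,
    )


def co2_branch(inp: ControllerInput, current_rr: float, cfg: ControllerConfig) -> float:
    """Next respiratory rate: one step toward the etCO2 target, clamped."""
    rr = current_rr
    if inp.etco2_avg > cfg.etco2_target + cfg.etco2_deadband:
        rr = current_rr + cfg.rr_step
    elif inp.etco2_avg < cfg.etco2_target - cfg.etco2_deadband:
        rr = current_rr - cfg.rr_step
    return min(cfg.rr_max_hw, max(cfg.rr_floor, rr))


def o2_branch(inp: ControllerInput, current_fio2: float, cfg: ControllerConfig) -> float:
    """Next FiO2: one step up to build the O2 buffer, one step down on high ORI.

    Hypoxia protection dominates: SpO2 below the safety minimum always raises
    FiO2, even with a contradictory high ORI reading.
    """
    fio2 = current_fio2
    in_spo2_band = cfg.spo2_band_lo <= inp.spo2_avg <= cfg.spo2_band_hi
    in_ori_band = cfg.ori_lo <= inp.ori_avg <= cfg.ori_hi
    if (in_spo2_band and in_ori_band) or inp.spo2_avg < cfg.spo2_min:
        fio2 = current_fio2 + cfg.fio2_step
    elif inp.ori_avg > cfg.ori_hi:
        fio2 = current_fio2 - cfg.fio2_step
    return min(100.0, max(21.0, fio2))


def control_cycle(
    inp: ControllerInput, settings: VentilatorSettings, cfg: ControllerConfig
) -> VentilatorSettings:
    """One controller execution: both branches applied independently.

    Actuation is halted during breath holds and on stale measurements; tidal
    volume, PEEP and inspiratory time pass through untouched always.
    """
    if inp.breath_hold or inp.stale:
        return settings
    rr = co2_branch(inp, settings.respiratory_rate, cfg)
    fio2 = o2_branch(inp, settings.fio2, cfg)
    return settings.with_rate(rr).with_fio2(fio2)
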