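"""Shared domain types, unit conversions and derived-settings arithmetic.

All pressures are stored internally in hPa.  Ventilation practice labels the
same numbers in cmH2O (1 hPa = 1.019716 cmH2O, close enough that clinical
devices use them interchangeably); :func:`paper_style_cmh2o` reproduces that
1:1 labelling convention, while :func:`convert_pressure` applies the exact
physical factors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

from .errors import ConfigError

# Exact conversion factors, unit -> hPa per unit.
MMHG_PER_HPA = 0.750062
CMH2O_PER_HPA = 1.019716

_TO_HPA = {
    "hPa": 1.0,
    "mmHg": 1.0 / MMHG_PER_HPA,
    "cmH2O": 1.0 / CMH2O_PER_HPA,
}

PRESSURE_UNITS = tuple(_TO_HPA)


@dataclass(frozen=True)
class Pressure:
    """A pressure value with an explicit unit (hPa, cmH2O or mmHg)."""

    value: float
    unit: str = "hPa"

    def __post_init__(self) -> None:
        if self.unit not in _TO_HPA:
            raise ConfigError(
                f"unknown pressure unit {self.unit!r}; expected one of {PRESSURE_UNITS}"
            )
        if not math.isfinite(self.value):
            raise ConfigError(f"pressure value must be finite, got {self.value!r}")

    def to(self, target_unit: str) -> "Pressure":
        return convert_pressure(self, target_unit)


def convert_pressure(p: Pressure, target_unit: str) -> Pressure:
    """Convert ``p`` to ``target_unit`` using exact physical factors.

    The value is never rounded here; round only at display time
    (e.g. 5 hPa -> 3.7503... mmHg, displayed as 3.75 mmHg).
    """
    if target_unit not in _TO_HPA:
        raise ConfigError(
            f"unknown pressure unit {target_unit!r}; expected one of {PRESSURE_UNITS}"
        )
    hpa = p.value * _TO_HPA[p.unit]
    return Pressure(hpa / _TO_HPA[target_unit], target_unit)


def paper_style_cmh2o(value_hpa: float) -> float:
    """Return the cmH2O label used on ventilator panels for a pressure in hPa.

    Clinical convention treats hPa and cmH2O as the same scale (a 5.0 hPa PEEP
    is labelled "5 cmH2O"); this is a labelling convention, not a conversion.
    """
    return value_hpa


def tidal_volume_setting(weight: float, per_kg_target: float, resolution: float = 10.0) -> float:
    """Tidal volume a volume-guarantee ventilator is set to deliver, in mL.

    ``weight * per_kg_target`` quantized to the nearest multiple of
    ``resolution`` with ties broken toward the lower volume
    (21.5 kg x 7.5 mL/kg -> 161.25 -> 160 mL on a 10 mL grid).
    """
    if weight <= 0:
        raise ConfigError(f"weight must be positive, got {weight}")
    if per_kg_target <= 0:
        raise ConfigError(f"per_kg_target must be positive, got {per_kg_target}")
    if resolution <= 0:
        raise ConfigError(f"resolution must be positive, got {resolution}")
    steps = math.ceil(weight * per_kg_target / resolution - 0.5)
    return float(steps * resolution)


@dataclass(frozen=True)
class VentilatorSettings:
    """Actuator command for the mechanical ventilator.

    Tidal volume, PEEP and inspiratory time are protocol constants; only the
    respiratory rate and FiO2 are touched by the closed-loop controller.
    """

    tidal_volume: float  # mL
    respiratory_rate: float  # breaths/min
    peep: float = 5.0  # hPa
    fio2: float = 25.0  # %
    inspiratory_time: float = 0.8  # s
    volume_guarantee: bool = True

    def __post_init__(self) -> None:
        if self.tidal_volume <= 0:
            raise ConfigError(f"tidal_volume must be positive, got {self.tidal_volume}")
        if self.respiratory_rate <= 0:
            raise ConfigError(
                f"respiratory_rate must be positive, got {self.respiratory_rate}"
            )
        if not 21.0 <= self.fio2 <= 100.0:
            raise ConfigError(f"fio2 must be within 21-100%, got {self.fio2}")
        if self.inspiratory_time <= 0:
            raise ConfigError(
                f"inspiratory_time must be positive, got {self.inspiratory_time}"
            )

    def with_rate(self, rr: float) -> "VentilatorSettings":
        return replace(self, respiratory_rate=rr)

    def with_fio2(self, fio2: float) -> "VentilatorSettings":
        return replace(self, fio2=fio2)


@dataclass(frozen=True)
class InsufflatorSettings:
    """Insufflator command: intra-abdominal pressure setpoint."""

    iap_setpoint: float = 0.0  # hPa
    enabled: bool = True
    max_iap: float = 20.0  # hPa, configured hardware maximum

    def __post_init__(self) -> None:
        if not 0.0 <= self.iap_setpoint <= self.max_iap:
            raise ConfigError(
                f"iap_setpoint must be within 0-{self.max_iap} hPa, got {self.iap_setpoint}"
            )


@dataclass(frozen=True)
class VitalSample:
    """One timestamped multi-signal observation of the subject.

    ``valid`` flags the sample as a whole (sensor fault); ``etco2_valid``
    additionally drops the end-tidal channel during breath holds, when no
    expired gas reaches the airway-opening sensor.
    """

    timestamp: float  # s since run start
    etco2: float  # kPa
    spo2: float  # %
    ori: float  # index, 0-1
    pip: float  # hPa
    map_art: Optional[float] = None  # mmHg
    cvp: Optional[float] = None  # mmHg
    heart_rate: Optional[float] = None  # bpm
    valid: bool = True
    etco2_valid: bool = True
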