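"""Lumped-parameter physiological model of a ventilated, insufflated pig.

The model closes the control loop in place of the animal.  It keeps two
states, arterial PaCO2 and PaO2:

* CO2: the body behaves as a single well-mixed store with effective stiffness
  ``k_store`` (kPa of PaCO2 per mL of stored CO2).  CO2 enters at
  ``vco2_met + k_perit * IAP`` (metabolic production plus peritoneal uptake of
  insufflated gas, both mL/min) and leaves with alveolar ventilation at
  ``VA * PaCO2 / P_ALV`` -- alveolar gas carries CO2 at fraction
  PaCO2 / (Pb - PH2O).  At steady state the expired CO2 rate therefore equals
  the total load, which is what makes expired CO2 volume a readout of
  peritoneal uptake once etCO2 is held constant.
* O2: PaO2 relaxes first-order toward a shunt-reduced alveolar target set by
  FiO2 (alveolar gas equation); during apnea it decays slowly toward the
  mixed-venous level, emulating depletion of the lung O2 store.

Respiratory mechanics are static: the respiratory-system compliance falls
with IAP as ``crs0 / (1 + k_crs * IAP)``, so at fixed tidal volume and PEEP
the peak inspiratory pressure rises directly with IAP.

Both ODEs are linear with piecewise-constant coefficients over one tick, so
``advance`` applies the closed-form exponential update: the fixed-step scheme
is exact for the in-tick dynamics and time-step halving only re-samples the
trajectory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .core import InsufflatorSettings, VentilatorSettings, VitalSample
from .errors import ConfigError, SimulationError

#: Alveolar dilution pressure Pb - PH2O at body conditions, kPa.
P_ALV_KPA = 95.0
MMHG_PER_KPA = 7.50062
#: Water-vapour-corrected barometric pressure, mmHg (alveolar gas equation).
P_ALV_MMHG = 713.0


@dataclass(frozen=True)
class NoiseLevels:
    """Per-channel Gaussian measurement noise (standard deviations)."""

    etco2: float = 0.0  # kPa
    spo2: float = 0.0  # %
    ori: float = 0.0  # index
    pip: float = 0.0  # hPa

    def __post_init__(self) -> None:
        for name in ("etco2", "spo2", "ori", "pip"):
            if getattr(self, name) < 0:
                raise ConfigError(f"noise sd {name} must be >= 0")

    @property
    def any_enabled(self) -> bool:
        return any(getattr(self, n) > 0 for n in ("etco2", "spo2", "ori", "pip"))


@dataclass(frozen=True)
class SubjectParams:
    """Constants of the virtual subject.

    Defaults describe a healthy 21.5 kg juvenile pig under deep anesthesia and
    muscle relaxation; they are calibrated so that an IAP step from 0 to
    20 hPa at fixed ventilation raises steady-state etCO2 by about 1 kPa and
    so that post-apnea CO2 transients clear within a 3-minute stabilization
    window under the default controller.
    """

    weight: float = 21.5  # kg
    vco2_met: float = 101.0  # mL/min STPD metabolic CO2 production
    vd: float = 95.0  # mL series dead space, anatomical + apparatus
    k_store: float = 0.012  # kPa/mL, inverse whole-body CO2 capacitance
    k_perit: float = 0.70  # mL/min/hPa peritoneal CO2 uptake per unit IAP
    crs0: float = 21.5  # mL/hPa respiratory-system compliance at IAP 0
    k_crs: float = 0.08  # 1/hPa compliance attenuation per unit IAP
    shunt: float = 0.05  # venous admixture fraction
    pao2_ori_lo: float = 100.0  # mmHg, ORI = 0 endpoint
    pao2_ori_hi: float = 200.0  # mmHg, ORI = 1 endpoint
    et_gradient: float = 0.5  # kPa PaCO2 - etCO2 offset
    resp_quotient: float = 0.8  # respiratory exchange ratio
    tau_o2: float = 30.0  # s, PaO2 equilibration time constant
    tau_o2_apnea: float = 240.0  # s, lung O2 store depletion during apnea
    pv_o2: float = 40.0  # mmHg mixed-venous O2 tension
    iap_rate: float = 5.0  # hPa/s insufflator actuation slew rate
    noise_sd: NoiseLevels = field(default_factory=NoiseLevels)

    def __post_init__(self) -> None:
        positive = (
            "weight", "vco2_met", "vd", "k_store", "k_perit", "crs0", "k_crs",
            "pao2_ori_lo", "pao2_ori_hi", "et_gradient", "resp_quotient",
            "tau_o2", "tau_o2_apnea", "pv_o2", "iap_rate",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"SubjectParams.{name} must be positive")
        if not 0.0 <= self.shunt < 1.0:
            raise ConfigError(f"shunt must be in [0, 1), got {self.shunt}")
        if self.pao2_ori_lo >= self.pao2_ori_hi:
            raise ConfigError("pao2_ori_lo must be below pao2_ori_hi")


@dataclass(frozen=True)
class SubjectState:
    """Physiological state of the virtual subject at one instant."""

    paco2: float  # kPa
    pao2: float  # mmHg
    time: float = 0.0  # s
    iap_actual: float = 0.0  # hPa
    breath_hold_active: bool = False

    def __post_init__(self) -> None:
        if self.paco2 <= 0 or self.pao2 <= 0:
            raise SimulationError(
                f"non-physical state: paco2={self.paco2}, pao2={self.pao2}"
            )


def severinghaus_spo2(pao2_mmhg: float) -> float:
    """Hemoglobin O2 saturation (%) from PaO2 via the Severinghaus curve."""
    p = max(pao2_mmhg, 1e-6)
    return 100.0 / (1.0 + 23400.0 / (p ** 3 + 150.0 * p))


def alveolar_ventilation(
    vent: VentilatorSettings, params: SubjectParams, breath_hold: bool = False
) -> float:
    """Alveolar ventilation RR x (Vt - Vd) in mL/min; zero during a breath hold."""
    if vent.tidal_volume <= params.vd:
        raise SimulationError(
            f"tidal volume {vent.tidal_volume} mL does not exceed dead space "
            f"{params.vd} mL: total dead-space ventilation"
        )
    if breath_hold:
        return 0.0
    return vent.respiratory_rate * (vent.tidal_volume - params.vd)


def co2_load(iap: float, params: SubjectParams) -> float:
    """Total CO2 load (mL/min): metabolic production + peritoneal uptake."""
    if iap < 0:
        raise SimulationError(f"IAP must be >= 0, got {iap}")
    return params.vco2_met + params.k_perit * iap


def equilibrium_paco2(load: float, va: float) -> float:
    """Closed-form PaCO2 fixed point load / (g * VA) with g = 1 / P_ALV."""
    return load * P_ALV_KPA / va


def alveolar_po2_target(
    fio2: float, paco2_kpa: float, params: SubjectParams
) -> float:
    """Shunt-reduced alveolar O2 target (mmHg) from the alveolar gas equation."""
    pao2_alv = fio2 / 100.0 * P_ALV_MMHG - paco2_kpa * MMHG_PER_KPA / params.resp_quotient
    return max((1.0 - params.shunt) * pao2_alv, params.pv_o2)


def pip_pressure(vent: VentilatorSettings, params: SubjectParams, iap: float) -> float:
    """Peak inspiratory pressure (hPa) at the current compliance: PEEP + Vt/Crs."""
    return vent.peep + vent.tidal_volume * (1.0 + params.k_crs * iap) / params.crs0


def advance(
    state: SubjectState,
    params: SubjectParams,
    vent: VentilatorSettings,
    insuff: InsufflatorSettings,
    dt: float,
    breath_hold: bool = False,
) -> SubjectState:
    """Advance the subject by ``dt`` seconds under constant settings.

    The per-tick update is the exact solution of the linear gas-kinetic ODEs;
    the IAP actuator ramps toward its setpoint at the insufflator slew rate.
    """
    if dt <= 0:
        raise SimulationError(f"dt must be positive, got {dt}")
    setpoint = insuff.iap_setpoint if insuff.enabled else 0.0
    iap = state.iap_actual
    if iap < setpoint:
        iap = min(setpoint, iap + params.iap_rate * dt)
    elif iap > setpoint:
        iap = max(setpoint, iap - params.iap_rate * dt)

    load = co2_load(iap, params)
    dt_min = dt / 60.0
    if breath_hold:
        paco2 = state.paco2 + params.k_store * load * dt_min
        pao2 = params.pv_o2 + (state.pao2 - params.pv_o2) * math.exp(
            -dt / params.tau_o2_apnea
        )
    else:
        va = alveolar_ventilation(vent, params)
        eq = equilibrium_paco2(load, va)
        lam = params.k_store * va / P_ALV_KPA  # 1/min
        paco2 = eq + (state.paco2 - eq) * math.exp(-lam * dt_min)
        tgt = alveolar_po2_target(vent.fio2, paco2, params)
        pao2 = tgt + (state.pao2 - tgt) * math.exp(-dt / params.tau_o2)

    if not (math.isfinite(paco2) and math.isfinite(pao2)):
        raise SimulationError(
            f"non-finite state at t={state.time + dt:.1f}s: "
            f"paco2={paco2}, pao2={pao2} (load={load}, rr={vent.respiratory_rate})"
        )
    return SubjectState(
        paco2=paco2,
        pao2=pao2,
        time=state.time + dt,
        iap_actual=iap,
        breath_hold_active=breath_hold,
    )


class SignalRngs:
    """Independent per-channel noise streams spawned from one global seed.

    Each monitored channel draws from its own substream, so enabling or
    disabling noise on one channel never perturbs the samples of another.
    """

    CHANNELS = ("etco2", "spo2", "ori", "pip")

    def __init__(self, seed: int) -> None:
        children = np.random.SeedSequence(seed).spawn(len(self.CHANNELS))
        self.streams = {
            name: np.random.default_rng(child)
            for name, child in zip(self.CHANNELS, children)
        }

    def draw(self, channel: str, sd: float) -> float:
        if sd <= 0:
            return 0.0
        return float(self.streams[channel].normal(0.0, sd))


def observe(
    state: SubjectState,
    params: SubjectParams,
    vent: VentilatorSettings,
    rng: Optional["SignalRngs"] = None,
    hold_phase: Optional[str] = None,
) -> VitalSample:
    """Produce one monitor sample from the current state.

    During a breath hold the end-tidal channel is flagged invalid (no expired
    gas reaches the sensor) and the airway pressure shows the held level:
    PEEP for an expiratory hold, the inspiratory plateau for an inspiratory
    hold.
    """
    etco2 = max(0.0, state.paco2 - params.et_gradient)
    spo2 = severinghaus_spo2(state.pao2)
    span = params.pao2_ori_hi - params.pao2_ori_lo
    ori = min(1.0, max(0.0, (state.pao2 - params.pao2_ori_lo) / span))
    if state.breath_hold_active and hold_phase == "expiratory":
        pip = vent.peep
    else:
        pip = pip_pressure(vent, params, state.iap_actual)
    if rng is not None and params.noise_sd.any_enabled:
        sd = params.noise_sd
        etco2 = max(0.0, etco2 + rng.draw("etco2", sd.etco2))
        spo2 = min(100.0, max(0.0, spo2 + rng.draw("spo2", sd.spo2)))
        ori = min(1.0, max(0.0, ori + rng.draw("ori", sd.ori)))
        pip = pip + rng.draw("pip", sd.pip)
    return VitalSample(
        timestamp=state.time,
        etco2=etco2,
        spo2=spo2,
        ori=ori,
        pip=pip,
        valid=True,
        etco2_valid=not state.breath_hold_active,
    )


def initial_state(
    params: SubjectParams,
    vent: VentilatorSettings,
    insuff: InsufflatorSettings = InsufflatorSettings(iap_setpoint=0.0),
) -> SubjectState:
    """Resting steady state consistent with the initial settings."""
    setpoint = insuff.iap_setpoint if insuff.enabled else 0.0
    va = alveolar_ventilation(vent, params)
    paco2 = equilibrium_paco2(co2_load(setpoint, params), va)
    pao2 = alveolar_po2_target(vent.fio2, paco2, params)
    return SubjectState(paco2=paco2, pao2=pao2, time=0.0, iap_actual=setpoint)
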