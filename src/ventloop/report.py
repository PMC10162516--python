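"""Post-run analysis: per-step settling metrics and time-series figures.

All summaries are pure functions of the run log, so recomputing them from a
saved CSV reproduces them exactly.  The figure set mirrors the platform's
standard four-panel layout: insufflation pressure, CO2 control, O2 control
and airway pressures, with breath holds shaded grey.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .bus import RunLog
from .core import MMHG_PER_HPA
from .errors import VentloopError

DEFAULT_TARGET = 7.0  # kPa
DEFAULT_BAND = 0.3  # kPa, settling tolerance around the target


@dataclass(frozen=True)
class StepSummary:
    """Settling and interaction metrics for one staircase step."""

    step_label: str
    iap: float  # hPa
    settling_time: Optional[float]  # s; None if never settled
    settled: bool
    etco2_at_hold: float  # kPa, last valid etCO2 before the first hold
    pip_at_hold: float  # hPa
    rr_at_hold: float  # bpm
    fio2_at_hold: float  # %


def _step_slice(frame: pd.DataFrame, step_label: str) -> pd.DataFrame:
    sel = frame[frame["step_label"] == step_label]
    if sel.empty:
        raise VentloopError(f"unknown step label {step_label!r}")
    return sel


def _hold_onset(step_frame: pd.DataFrame) -> float:
    """Time of the first breath hold in the step, or the step end."""
    holds = step_frame[step_frame["breath_hold"] == 1]
    if holds.empty:
        return float(step_frame["time_s"].iloc[-1])
    return float(holds["time_s"].iloc[0])


def settling_time(
    log: RunLog,
    step_label: str,
    target: float = DEFAULT_TARGET,
    band: float = DEFAULT_BAND,
) -> Optional[float]:
    """Seconds from the step's IAP command until etCO2 enters and remains
    within ``target +/- band`` up to the hold onset; None if it never does."""
    frame = log.to_frame()
    sel = _step_slice(frame, step_label)
    t0 = float(sel["time_s"].iloc[0])
    onset = _hold_onset(sel)
    pre = sel[(sel["time_s"] < onset) & (sel["valid"] == 1) & (sel["etco2_valid"] == 1)]
    if pre.empty:
        return None
    inside = (pre["etco2_kpa"] - target).abs().to_numpy() <= band
    # last index where the trace is outside the band
    outside = np.flatnonzero(~inside)
    if len(outside) == 0:
        return 0.0
    if outside[-1] == len(inside) - 1:
        return None
    return float(pre["time_s"].to_numpy()[outside[-1] + 1] - t0)


def step_summaries(
    log: RunLog, target: float = DEFAULT_TARGET, band: float = DEFAULT_BAND
) -> pd.DataFrame:
    """One :class:`StepSummary` row per protocol step, in timeline order."""
    frame = log.to_frame()
    if frame.empty:
        raise VentloopError("empty run log")
    rows = []
    for label in frame["step_label"].unique():
        sel = _step_slice(frame, label)
        onset = _hold_onset(sel)
        pre = sel[sel["time_s"] < onset]
        at = pre.iloc[-1] if not pre.empty else sel.iloc[0]
        st = settling_time(log, label, target, band)
        rows.append(
            StepSummary(
                step_label=str(label),
                iap=float(sel["iap_set_hpa"].iloc[-1]),
                settling_time=st,
                settled=st is not None,
                etco2_at_hold=float(at["etco2_kpa"]),
                pip_at_hold=float(at["pip_hpa"]),
                rr_at_hold=float(at["rr_bpm"]),
                fio2_at_hold=float(at["fio2_pct"]),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def pip_vs_iap(log: RunLog) -> pd.DataFrame:
    """Table of (iap, pip_at_hold), one row per plateau: the direct
    pressure-interaction outcome at fixed Vt and PEEP."""
    summ = step_summaries(log)
    return summ[["step_label", "iap", "pip_at_hold"]].reset_index(drop=True)


def _shade_holds(ax, frame: pd.DataFrame) -> None:
    hold = frame["breath_hold"].to_numpy().astype(bool)
    t = frame["time_s"].to_numpy()
    if not hold.any():
        return
    edges = np.flatnonzero(np.diff(hold.astype(int)) != 0) + 1
    bounds = np.concatenate([[0], edges, [len(hold)]])
    for a, b in zip(bounds[:-1], bounds[1:]):
        if hold[a]:
            ax.axvspan(t[a] / 60.0, t[b - 1] / 60.0, color="0.85", zorder=0)


def render_timeseries(log: RunLog, out_dir, fmt: str = "png") -> List[str]:
    """Write the four standard panels; returns the file paths.

    Panels: (A) IAP setting and actual; (B) etCO2 with the closed-loop RR;
    (C) SpO2, ORI and FiO2; (D) airway pressures on dual cmH2O / mmHg axes.
    Breath holds are shaded grey in every panel.
    """
    import os

    frame = log.to_frame()
    if frame.empty:
        raise VentloopError("empty run log: nothing to render")
    os.makedirs(out_dir, exist_ok=True)
    tmin = frame["time_s"].to_numpy() / 60.0
    paths = []

    def _save(fig, name):
        path = os.path.join(out_dir, f"{name}.{fmt}")
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)

    # A: insufflation pressure
    fig, ax = plt.subplots(figsize=(9, 3))
    _shade_holds(ax, frame)
    ax.step(tmin, frame["iap_set_hpa"], where="post", color="0.4", label="IAP setting")
    ax.plot(tmin, frame["iap_hpa"], color="tab:blue", lw=1, label="IAP actual")
    ax.set_xlabel("time (min)"); ax.set_ylabel("IAP (hPa)")
    ax.legend(loc="upper right", fontsize=8)
    ax.set_title("A  Intra-abdominal insufflation pressure")
    _save(fig, "panel_A_iap")

    # B: CO2 measurement and control
    fig, ax = plt.subplots(figsize=(9, 3))
    _shade_holds(ax, frame)
    valid = frame[(frame["valid"] == 1) & (frame["etco2_valid"] == 1)]
    ax.plot(valid["time_s"] / 60.0, valid["etco2_kpa"], color="tab:green", lw=1,
            label="etCO2 (kPa)")
    ax.set_xlabel("time (min)"); ax.set_ylabel("etCO2 (kPa)")
    ax2 = ax.twinx()
    ax2.step(tmin, frame["rr_bpm"], where="post", color="tab:blue", lw=1,
             label="RR (bpm)")
    ax2.set_ylabel("RR (bpm)")
    ax.set_title("B  CO2 measurement and closed-loop respiratory rate")
    _save(fig, "panel_B_co2")

    # C: O2 measurement and control
    fig, ax = plt.subplots(figsize=(9, 3))
    _shade_holds(ax, frame)
    ax.plot(tmin, frame["spo2_pct"], color="tab:blue", lw=1, label="SpO2 (%)")
    ax.step(tmin, frame["fio2_pct"], where="post", color="k", lw=1, label="FiO2 (%)")
    ax.set_xlabel("time (min)"); ax.set_ylabel("SpO2 / FiO2 (%)")
    ax.legend(loc="upper left", fontsize=8)
    ax2 = ax.twinx()
    ax2.plot(tmin, frame["ori"], color="tab:green", lw=1, label="ORI")
    ax2.set_ylabel("ORI"); ax2.set_ylim(0, 1)
    ax.set_title("C  O2 measurement and closed-loop FiO2")
    _save(fig, "panel_C_o2")

    # D: airway pressures, dual axes (cmH2O label convention left, mmHg right)
    fig, ax = plt.subplots(figsize=(9, 3))
    _shade_holds(ax, frame)
    ax.plot(tmin, frame["pip_hpa"], color="tab:blue", lw=1, label="PIP")
    ax.plot(tmin, frame["peep_hpa"], color="tab:blue", lw=1, ls="--", label="PEEP")
    ax.step(tmin, frame["iap_set_hpa"], where="post", color="0.6", lw=1, label="IAP")
    ax.set_xlabel("time (min)"); ax.set_ylabel("pressure (cmH2O)")
    ax.legend(loc="upper left", fontsize=8)
    ax2 = ax.secondary_yaxis(
        "right", functions=(lambda h: h * MMHG_PER_HPA, lambda m: m / MMHG_PER_HPA)
    )
    ax2.set_ylabel("pressure (mmHg)")
    ax.set_title("D  Airway pressures during insufflation")
    _save(fig, "panel_D_pressures")
    return paths
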