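# Methods

This note documents the models, parameters and design choices behind
`ventloop`: what the virtual subject does and does not emulate, how the
controller and protocol are specified, and which numerical conventions the
implementation uses.

## The virtual subject

The subject is the smallest model that closes the control loop and
reproduces, qualitatively and at the right magnitudes, every interaction the
platform is built to measure: IAP raises the CO₂ load and stiffens the
respiratory system; ventilation clears CO₂; apnea accumulates it; FiO₂ sets
the oxygen buffer. It keeps two states, arterial PaCO₂ (kPa) and PaO₂
(mmHg).

### CO₂ kinetics

The whole body is one well-mixed CO₂ store with effective stiffness
`k_store` (kPa of PaCO₂ per mL of stored CO₂ gas):

    dPaCO₂/dt = k_store · (V̇CO₂ − V̇A · PaCO₂ / P_alv),   P_alv = 95 kPa

- `V̇CO₂ = vco2_met + k_perit · IAP` — metabolic production plus peritoneal
  uptake of insufflated CO₂, both mL/min STPD. Uptake is linear in IAP: the
  simplest monotone relation, sufficient for staircase experiments.
- `V̇A = RR · (Vt − Vd)` — alveolar ventilation; zero during breath holds.
  `Vd` lumps anatomical and apparatus dead space in series.
- `P_alv = Pb − PH₂O ≈ 95 kPa` converts PaCO₂ into the alveolar CO₂
  fraction, so elimination is `V̇A · PaCO₂ / P_alv` mL/min and the steady
  state obeys the mass balance `expired CO₂ rate = V̇CO₂` exactly. This is
  the property that lets a constant-etCO₂ experiment read peritoneal uptake
  from expired CO₂ volume.

The closed-form fixed point is `PaCO₂* = V̇CO₂ · P_alv / V̇A`. Monitored
etCO₂ is `PaCO₂ − et_gradient` (default 0.5 kPa, a fixed
arterial-to-end-tidal gradient; floored at zero).

A single store cannot reproduce both the large, slow tissue CO₂ capacitance
and the fast blood/lung compartment of real physiology; `k_store` is an
*effective* stiffness chosen for the time scales that matter here (minutes,
see Calibration). Intra-breath dynamics, multi-compartment stores and
ventilation-perfusion heterogeneity are out of scope.

### O₂ kinetics

PaO₂ relaxes first-order (τ = `tau_o2`, default 30 s) toward a shunt-reduced
alveolar target from the alveolar gas equation:

    PaO₂_target = (1 − shunt) · (FiO₂/100 · 713 − PaCO₂[mmHg] / R)

with `R = 0.8` and `shunt = 0.05`. During apnea PaO₂ decays toward the
mixed-venous tension `pv_o2 = 40 mmHg` with the much slower
`tau_o2_apnea = 240 s`, emulating depletion of the lung O₂ store at the held
lung volume; a 5 s hold therefore costs only a few mmHg, which is exactly
the situation the pre-hold hyperoxic buffer is meant to absorb.

SpO₂ is the Severinghaus saturation
`100 / (1 + 23400 / (p³ + 150 p))`. ORI is a clamped linear map of PaO₂
between `pao2_ori_lo = 100` and `pao2_ori_hi = 200 mmHg` — the simplest
monotone surrogate for an index of the hyperoxic buffer above full
hemoglobin saturation.

### Mechanics and actuation

Respiratory-system compliance falls with insufflation,
`Crs(IAP) = crs0 / (1 + k_crs · IAP)`, so at fixed tidal volume and PEEP

    PIP = PEEP + Vt · (1 + k_crs · IAP) / crs0

rises linearly with IAP and carries no hysteresis: up-leg and down-leg
plateaus at equal IAP give identical PIP. During an expiratory hold the
airway-pressure channel shows PEEP; during an inspiratory hold the
inspiratory plateau. The insufflator ramps the actual IAP toward its
setpoint at a finite slew rate (`iap_rate = 5 hPa/s`) rather than stepping —
insufflators are flow-limited.

### Default parameters (21.5 kg pig, deep anesthesia and relaxation)

| parameter | default | unit | meaning |
|---|---|---|---|
| weight | 21.5 | kg | pilot subject weight |
| vco2_met | 101 | mL/min | metabolic CO₂ production (≈4.7 mL/kg/min) |
| vd | 95 | mL | series dead space incl. apparatus (≈4.4 mL/kg) |
| k_store | 0.012 | kPa/mL | effective CO₂ store stiffness |
| k_perit | 0.70 | mL/min/hPa | peritoneal uptake per unit IAP |
| crs0 | 21.5 | mL/hPa | compliance at IAP 0 (≈1 mL/hPa/kg) |
| k_crs | 0.08 | 1/hPa | compliance attenuation per unit IAP |
| shunt | 0.05 | – | venous admixture |
| et_gradient | 0.5 | kPa | PaCO₂ − etCO₂ |
| pao2_ori_lo/hi | 100 / 200 | mmHg | ORI mapping endpoints |
| tau_o2 / tau_o2_apnea | 30 / 240 | s | PaO₂ time constants |
| iap_rate | 5 | hPa/s | insufflator slew rate |

### Calibration

The defaults were fixed, before any acceptance measurement, to satisfy the
study conditions the platform defines, jointly:

1. an IAP step 0 → 20 hPa at *fixed* ventilation raises steady-state etCO₂
   by ≈1 kPa (sets `k_perit` against `vco2_met`);
2. at every staircase plateau at least one integer RR in range puts the
   etCO₂ equilibrium inside the controller deadband, with the IAP-10
   plateau closest to the 7.0 kPa target (sets `vd`, i.e. the per-bpm
   equilibrium spacing `≈ PaCO₂/RR`, and the operating RR ≈ 20 bpm);
3. post-hold CO₂ transients clear within the 3-minute stabilization window
   under the ±1 bpm / 40 s controller (sets `k_store`; see the hold-duration
   note below).

Condition 3 is a real constraint of the single-store model: the apnea
accumulation rate (`k_store · V̇CO₂`) and the recovery rate
(`k_store · V̇A · ΔPaCO₂ / P_alv`) scale with the same `k_store`, and their
ratio `V̇A · ΔPaCO₂ / (P_alv · V̇CO₂)` is ≈ 0.05 per 0.3 kPa of excess. Long
apneas therefore inject more CO₂ than an incremental controller can clear in
three minutes, for *any* `k_store`.

## The controller

Two independent branches run every `interval = 40 s` on conditioned inputs;
conditioning averages the most recent `avg_window = 5 s` of samples per
channel, keeping only samples that are flagged valid and physiologically
plausible (etCO₂ 0–20 kPa, SpO₂ 50–100 %, ORI 0–1); end-tidal samples taken
during breath holds are flagged invalid at the source. If a channel has no
valid sample in the window the input is stale and the cycle does nothing.
Actuation is halted during breath holds and resumes at the next interval
boundary.

- CO₂: ±`rr_step` = 1 bpm toward `etco2_target` = 7.0 kPa outside the
  deadband, clamped to [max(4, 10), 37] bpm. The deadband (±0.2 kPa) is a
  design choice — a pure target would limit-cycle the RR; it is configurable
  and reported in every log header.
- O₂: +1 % FiO₂ if (SpO₂ in 97–98 % and ORI in 0.0–0.4) or SpO₂ < 97 %;
  −1 % if ORI > 0.4; otherwise hold; clamped to 21–100 %. Two corner cases
  are resolved explicitly: SpO₂ below minimum with ORI high → *increase*
  (hypoxia protection dominates), and SpO₂ above 98 % with ORI in band →
  *hold* (the buffer-building rule is conditioned on the 97–98 % band).

These branch definitions are also encoded, independently from the
implementation, as a 27-cell decision table in the test suite and checked
cell-for-cell.

## The protocol engine

The default protocol is the 13-step IAP staircase
0, 5, 8, 10, 12, 14, 16, 18, 20, 16, 10, 5, 0 hPa. Each step: command the
setpoint, hold for 180 s of stabilization, then one expiratory and one
inspiratory breath hold for CT scanning. Steps are timed from stabilization
start and the holds extend the step beyond 180 s. Stabilization timers are
fixed — the engine does not wait for convergence.

Hold duration defaults to 5 s — one helical CT acquisition of a 21.5 kg
animal — followed by a 35 s gap after each hold for scanner preparation and
recovery before the next hold or IAP step. Longer holds are configurable,
but note the single-store constraint above: at 20 s per hold the injected
CO₂ exceeds what the incremental controller can clear within the next
stabilization window, and the settling guarantee is lost by model
construction, not by controller defect.

A manual-override hook `(time, settings) -> settings | None` can inject
operator commands at any tick; applied overrides are flagged in the log.

## Logging, replay, determinism

One wide CSV row per integration tick on a single monotone clock (clock
regressions raise), each row labelled with the active protocol step; the
full configuration snapshot, seed and version are written once as a JSON
header line, so a run directory reproduces itself. Reading uses round-trip
float parsing, making write → read → write bit-identical. `replay` streams a
recorded log back through `condition_measurements`/`control_cycle` at the
configured interval and reproduces the live command sequence exactly; it
carries no hidden state, so record and replay are independently restartable.

Sensor noise is off by default; when enabled, each channel draws from its
own substream spawned from the single run seed, so enabling one channel
never perturbs another, and runs are bit-reproducible per seed.

## Numerical choices

- Both state equations are linear with piecewise-constant coefficients over
  a tick, so `advance` applies the closed-form exponential update. The
  default tick is `dt = 1 s` (configurable); halving `dt` only re-samples
  the trajectory (differences enter via the 1–2 s IAP ramp and are
  < 0.1 %).
- The subject starts at the resting steady state consistent with the
  initial settings (RR 20 bpm, FiO₂ 25 %, IAP 0).
- Ventilator quantization: tidal volume on a 10 mL grid with ties toward
  the lower volume (21.5 kg × 7.5 mL/kg = 161.25 → 160 mL); RR 1 bpm;
  FiO₂ 1 %.
- Pressures are stored in hPa. Exact conversions (1 hPa = 0.750062 mmHg =
  1.019716 cmH₂O) are applied unrounded and rounded only for display; the
  clinical 1:1 hPa↔cmH₂O labelling is available as an explicit display
  convention.
- Settling time of a step is the first instant after the IAP command from
  which etCO₂ stays within target ± band (default ±0.3 kPa) until the hold
  onset; an empty or never-contained trace reports not-settled rather than
  a number.

## What passing tests do and do not show

The virtual subject is a deliberately minimal plant: deterministic by
default, memoryless mechanics, single CO₂ store, no hemodynamic feedback
(blood pressures, heart rate and cardiac output are not modeled), no
measurement dropouts beyond the validity flags. Green tests therefore show
that the controller and protocol logic are correct and that the closed loop
meets its settling and band specifications *on this plant* — they do not
certify performance on an animal, where slower multi-compartment CO₂
dynamics, drifting metabolism and sensor artefacts apply. The problem sizes
used throughout (a ~56-minute staircase at 1 s ticks, 20-minute constant-IAP
runs) are the package's native scale; all suites run in seconds.

## Known limitations

- One store, one time constant per gas: apnea spikes and washout share
  `k_store`, which bounds usable hold durations (see Calibration).
- ORI is a linear PaO₂ surrogate; real ORI depends on perfusion and
  calibration and saturates differently between devices.
- The etCO₂–PaCO₂ gradient is constant; in reality it widens with dead-space
  fraction and low cardiac output.
- The controller interval must be a multiple of the tick for replay
  equivalence to be exact.
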