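# ventloop

An in-silico testbed for studying the interaction between surgical CO₂
insufflation and mechanical ventilation under closed-loop control.

In laparoscopy the abdomen is insufflated with pressurized CO₂ to create
workspace. The intra-abdominal pressure (IAP) pushes on the diaphragm,
lowering respiratory-system compliance, while CO₂ absorbed from the
peritoneum adds to the metabolic CO₂ load. Animal platforms that study this
interaction fix the confounders — tidal volume, PEEP, inspiratory time and
blood gases — by closed-loop control of the remaining ventilator parameters,
so that peak inspiratory pressure (PIP) and abdominal volume become direct
outcome parameters of the applied IAP. `ventloop` reproduces that platform
at the desk: a lumped-parameter virtual porcine subject stands in for the
animal, the incremental ventilation controller and the automated IAP
staircase protocol run against it, and every run produces a
time-synchronized log, per-step settling metrics and the standard four-panel
figures. It is intended for controller development, protocol design and
teaching, without animals or hardware.

## Model and controller

Virtual subject (two states, exact per-tick exponential updates):

- CO₂ kinetics — a single well-mixed store with stiffness `k_store` (kPa/mL):
  `dPaCO₂/dt = k_store · (V̇CO₂ − V̇A · PaCO₂ / (Pb − PH₂O))`,
  where the load `V̇CO₂ = V̇CO₂,met + k_perit · IAP` (metabolic production
  plus peritoneal uptake) and `V̇A = RR · (Vt − Vd)` is alveolar ventilation
  (zero during breath holds). At steady state the expired CO₂ rate equals
  the load, so expired CO₂ reads out peritoneal uptake once etCO₂ is held
  constant. Monitored etCO₂ is PaCO₂ minus a fixed gradient.
- O₂ kinetics — PaO₂ relaxes first-order toward a shunt-reduced alveolar
  target from the alveolar gas equation,
  `PAO₂ = FiO₂·(Pb − PH₂O) − PaCO₂/R`; SpO₂ follows the Severinghaus
  saturation curve and the oxygen reserve index (ORI) is a clamped linear
  map of PaO₂ between 100 and 200 mmHg. During apnea PaO₂ decays slowly
  toward the mixed-venous level.
- Mechanics — compliance falls with insufflation,
  `Crs(IAP) = Crs0 / (1 + k_crs · IAP)`, so at fixed Vt and PEEP,
  `PIP = PEEP + Vt / Crs(IAP)` rises directly with IAP.

Controller (executed every 40 s on 5-s averages of valid samples, frozen
during breath holds):

- CO₂ branch — RR moves ±1 bpm toward the 7.0 kPa etCO₂ target (permissive
  hypercapnia) outside a ±0.2 kPa deadband, clamped to the 4–37 bpm
  hardware range with a 10 bpm safety floor.
- O₂ branch — FiO₂ moves +1 % while SpO₂ is in the 97–98 % band with ORI in
  0.0–0.4 (building a hyperoxic buffer for the breath holds) or whenever
  SpO₂ < 97 %, and −1 % when ORI > 0.4. Tidal volume (volume guarantee,
  7.5 mL/kg), PEEP (5.0 hPa) and inspiratory time (0.8 s) are never touched.

The default protocol steps IAP through
0, 5, 8, 10, 12, 14, 16, 18, 20, 16, 10, 5, 0 hPa with 3 minutes of
stabilization per step followed by an expiratory and an inspiratory CT
breath hold.

## Worked example

```
$ ventloop run-protocol --seed 1 --out demo
protocol 'iap_staircase': 13 steps, 56.3 simulated minutes, seed 1
wrote demo/log.csv (3381 records)

$ ventloop report demo/log.csv --out demo/report
13 steps -> demo/report/step_summary.csv
{"steps": 13, "all_settled": true, "max_settling_time_s": 0.0, "settling_band_kpa": 0.3}
wrote demo/report/panel_A_iap.png
...
```

The run completes in well under a minute. `all_settled: true` with
`max_settling_time_s: 0.0` says that on the default subject the loop kept
etCO₂ inside the ±0.3 kPa band around 7.0 kPa throughout every 3-minute
stabilization window — the platform's headline behavior. The first rows of
the step summary:

```
step_label,iap,settling_time,settled,etco2_at_hold,pip_at_hold,rr_at_hold,fio2_at_hold
step00_iap0,0.0,0.0,True,6.88,12.44,20.0,26.0
step01_iap5,5.0,0.0,True,7.09,15.42,20.0,26.0
step02_iap8,8.0,0.0,True,7.01,17.20,22.0,26.0
step08_iap20,20.0,0.0,True,7.00,24.35,23.0,26.0
```

(values shown to 2 decimals). Reading across a row: at the IAP-20 plateau
the controller holds etCO₂ at 7.00 kPa by raising RR from 20 to 23 bpm,
while PIP has climbed from 12.4 to 24.3 hPa at fixed Vt and PEEP — the
direct compliance effect of the pneumoperitoneum that the platform is built
to measure. Up-leg and down-leg plateaus at equal IAP give identical PIP
(the default mechanics are memoryless). `ventloop replay demo/log.csv`
streams the recorded vitals back through the controller and reproduces the
command sequence exactly.

The run log is a plain CSV with a `# header:` JSON line holding the full
configuration snapshot, then one row per tick with columns
`time_s, step_label, phase, breath_hold, valid, etco2_valid, etco2_kpa,
spo2_pct, ori, pip_hpa, paco2_kpa, pao2_mmhg, iap_hpa, iap_set_hpa, rr_bpm,
fio2_pct, vt_ml, peep_hpa, ti_s, command, override`.

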