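# hemostress

Noninvasive cardiovascular hemodynamics for the stress echocardiography lab.

Exercise and pharmacological stress echo usually focuses on wall-motion
abnormalities and ejection fraction. Yet the same session already measures
everything needed — left-ventricular end-diastolic and end-systolic volumes
(3D or biplane 2D echo), heart rate, cuff blood pressures and a handful of
Doppler velocities — to characterize the whole circulation quantitatively:
cardiac output and systemic vascular resistance, ventricular and arterial
elastance and their coupling, pulmonary pressures and resistances, and
diastolic function under stress. Doing those ~30 calculations per stage by
hand is slow and error-prone; `hemostress` is the calculation engine that
does them all, flags out-of-range physiology, and reports rest→peak changes.
It is aimed at echocardiographers, physiology trainees and researchers who
want the full derived panel from a single set of bedside measurements.

## The model

For each stage (rest, optional intermediate steps, peak):

- **Systemic / ventricular–arterial.** BSA = √(kg·cm/3600); SV = EDV − ESV;
  CO = HR·SV; MAP = (SBP − DBP)/3 + DBP; end-systolic pressure
  ESP = 0.9·SBP (the reliable cuff surrogate of LV end-systolic pressure);
  ventricular elastance index *E*es*I* = ESP/(ESV/BSA); arterial elastance
  index *E*a*I* = ESP/(SV/BSA); ventricular–arterial coupling
  VAC = *E*es/*E*a = SV/ESV (the pressure cancels, so coupling is
  blood-pressure independent); SVR = 80·(MAP − 5)/CO; arterial compliance
  C = SV/PP.
- **Pulmonary.** Right atrial pressure from IVC diameter/collapse
  (3, 8 or 15 mmHg); simplified Bernoulli gradients 4·v²;
  SPAP = 4·TRV² + RAP; PADP = 4·PR-EDV² + RAP;
  mPAP = SPAP/3 + 2·PADP/3 and, independently, 4·PR-peak² + RAP (the two
  estimates are cross-checked); PAPP = SPAP − PADP;
  PVR = 80·(mPAP − PCWP)/CO or, noninvasively, 10·TRV/TVI(RVOT) in Wood
  units; pulmonary capacitance PVC = SV/PAPP.
- **Diastology.** Septal E/e′ with its filling-pressure classes (< 8 normal,
  > 15 elevated); PCWP ≈ 1.24·(E/e′) + 1.9 mmHg; diastolic mean filling
  rate = SVI/diastolic time × 1000 (≈ triples with exercise in normals);
  rule-based RV diastolic grading from tricuspid Doppler.
- **Across stages.** Absolute and percent rest→peak changes; the
  force–frequency relation (SP/ESV index vs heart rate) classified as
  up-sloping, biphasic or flat/negative with its critical heart rate; the
  stroke-volume response decomposed into end-diastolic (Frank–Starling) and
  end-systolic (contractility) contributions; exercise SPAP limits
  (43 mmHg, up to 60 mmHg in athletes or age > 55).

## Worked example

Generate a synthetic healthy training case and compute its sheet:

```sh
hemostress fixture --profile normal --seed 1 --out case.json
hemostress calc --input case.json --format text
```

Selected rows of the output:

```
parameter                            algorithm           rest   peak   unit         pct_change
LV Elastance index (EesI)            ESP/(ESV/BSA)       4.46   14.32  mmHg/mL/m2   221.4
Arterial Elastance index (EaI)       ESP/(SV/BSA)        2.30   3.25   mmHg/mL/m2   41.3
Ventricular-Arterial Coupling (VAC)  SV/ESV              1.94   4.41   ratio        127.6
Systemic Vascular Resistance (SVR)   80*(MAP-5)/CO       1115   596    dyne*s*cm-5  -46.6
Diastolic Mean Filling Rate          (SVI/diastolic time)*1000  98.5  297.1  mL/m2/s  201.6
```

Reading: ventricular elastance rises ~3× more than arterial load, so
coupling climbs from 1.94 to 4.41 — the healthy exercise mismatch that
maximizes cardiac performance; the periphery vasodilates (SVR −47%) and
diastolic filling rate triples. The sheet ends with consistency notes, e.g.

```
- mean PAP estimates agree: standard 11.0 vs Doppler 11.1 mmHg (|Δ| = 0.1, tolerance 5)
- force-frequency relation: up_sloping, critical heart rate 158 bpm
```

The `dcm` profile shows the opposite pattern: peak ventricular elastance
index below half the arterial elastance index, coupling stuck near 0.4,
and only a modest SVR decrease. `hemostress plot` writes the per-parameter
heart-rate trend panels.

Case files are plain JSON or CSV (one row per stage); see
`hemostress.measurements.load_case` for the schema.

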