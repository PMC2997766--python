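# Methods

## Scope and model

`hemostress` computes the complete noninvasive hemodynamic panel from one
stage of stress-echo measurements and compares stages. All quantities are
closed-form functions of the raw measurements; there is no fitting or
iteration anywhere in the engine. The science rests on four surrogates:

1. **ESP ≈ 0.9·SBP.** The single-beat end-systolic pressure estimate from
   the cuff systolic pressure. It is the default pressure in both elastance
   indices; raw SBP can be selected instead (`EngineConfig.ees_pressure =
   "sbp"`), which is also the pressure used — always — in the
   force–frequency SP/ESV-index curve.
2. **Simplified Bernoulli, ΔP = 4·v².** Converts regurgitant-jet velocities
   (m/s) to pressure gradients (mmHg); adding the IVC-derived right atrial
   pressure yields SPAP, PADP and the Doppler mean PAP.
3. **E/e′ → PCWP.** The linear regression PCWP = 1.24·(E/e′) + 1.9 mmHg on
   the septal ratio. This estimate also feeds the invasive-form PVR when no
   measured wedge pressure exists; the report marks that row "PCWP
   estimated from E/e′".
4. **Cardiological diastole.** Diastolic time is the second-to-first heart
   sound interval (from M-mode or a precordial force sensor). It slightly
   overestimates true filling time, but the bias is systematic across
   stages, so rest→peak filling-rate ratios are barely affected.

## Conventions that were genuinely open

- **Elastance indexing.** Two readings circulate: divide the volume by BSA
  (pressure over volume *index*) or divide the whole elastance by BSA. Only
  the former reproduces the published normal averages (*E*es*I* 4.5 → 14.5,
  *E*a*I* 2.3 → 3.2 mmHg/mL/m² rest → peak), so it is the default;
  `EngineConfig.elastance_indexing = "per_bsa"` selects the other reading.
  VAC is always SV/ESV, which is identical under either convention.
- **BSA formula.** Both the Mosteller square-root form and the power form
  (kg^0.5378 · cm^0.3964) are implemented; Mosteller is the default used by
  the panel.
- **Doppler mean PAP.** The estimator is 4·(peak early PR velocity)² with
  the right atrial pressure added by default
  (`EngineConfig.mpap_doppler_add_rap`); the report's algorithm column
  names the form in use. The two mean-PAP estimates are compared per stage
  and a note is raised when they differ by more than
  `EngineConfig.mpap_tolerance` (default 5 mmHg — a design choice, not a
  published cutoff).
- **RAP lookup boundaries.** The IVC table leaves diameter exactly 2.1 cm
  and collapse exactly 50% unassigned; the closed rule used here puts
  diameter ≤ 2.1 cm on the small branch and collapse ≥ 0.5 on the
  collapsing branch, making the lookup total with range {3, 8, 15} mmHg.
  Indeterminate-pattern applications are logged at info level.
- **Force–frequency taxonomy.** Up-sloping requires the peak SP/ESV index
  to strictly exceed every earlier stage; at-or-below baseline is
  flat/negative; the remaining case (above baseline but not above some
  intermediate) is labeled *biphasic*, with the critical heart rate at the
  interior maximum (earliest stage on ties). With only two stages the rule
  degrades to a strict two-point comparison.
- **E/e′ bands.** 8 ≤ E/e′ ≤ 15 is reported *indeterminate*: only the two
  outer classes are defined. At the lower boundary the PCWP estimate is
  11.82 mmHg < 12, so a "normal" ratio can never trigger the elevated-PCWP
  flag (checked by test).
- **RV diastolic grading.** E/A boundaries 0.8 and 2.1 belong to the middle
  band; E/E′ must exceed 6 strictly; when the auxiliary datum for the
  matched band is missing (e.g. E/A 0.8–2.1 with E/E′ ≤ 6 and no hepatic
  data) the grade is *indeterminate*, never normal. Late diastolic
  antegrade pulmonary flow grades restrictive on its own.

## Units and numeric choices

- Measurement units are fixed per field (mitral velocities cm/s, TR/PR
  jets m/s, volumes mL, pressures mmHg, times ms). The loader converts
  nothing except IVC collapse, where a value > 1 is read as percent.
  The TR gradient is always derived (4·v²) and never accepted as an input.
- Cycle length = 60000/HR rounded half-away-from-zero to integer ms. Two
  published table entries (666 ms at 90 bpm, 463 ms at 130 bpm) differ from
  the rounding rule by 1 ms and are treated as typos.
- Resistance conversions use exact integer ratios (1 Wood = 80 dyn·s·cm⁻⁵ =
  8 MPa·s/m³, hence dyn ↔ MPa is a factor of 10 — the prose "divide by 8"
  for that conversion is inconsistent with its own printed ranges and is
  not followed). A conversion is a single multiplication by an integer
  ratio: exact for `int`/`Fraction` inputs, correctly rounded for floats.
- All derived values are kept at full precision; only report rendering
  rounds (pressures 0–1 dp, elastances/ratios 2 dp, percent changes 1 dp).
  Percent changes are computed on unrounded values.
- Degenerate inputs: division-style formulas raise `ValueError` on
  non-positive denominators; inside `derive_panel` these become
  per-parameter "not computable" entries with the reason named, so one bad
  or missing measurement never blocks the rest of the panel. A percent
  change with a zero rest value and a stroke-volume decomposition with
  ΔSV = 0 return a not-computable marker rather than raising.
- Normal-range bands (SV 60–100 mL, CO 4–6 L/min, CI 2.5–3.6, MAP 70–100,
  SVR 900–1300 and PVR 100–200 dyn·s·cm⁻⁵, exercise SPAP 43/60 mmHg,
  Doppler PVR 1.5/3/8 Wood) produce warnings only; the engine never refuses
  out-of-range physiology.

## Synthetic fixtures: what they emulate and what they do not

`make_fixture(profile, seed)` builds two-stage (rest/peak) cases backwards:
target elastance indices are drawn around the published averages — normal
4.5 → 14.5 vs 2.3 → 3.2 mmHg/mL/m²; DCM ~1.4 → ~1.95 vs ~3.5 → ~4.3, i.e.
ventricular elastance stuck below half the arterial — with small seeded
uniform jitter (±2–5%), then ESV and SV are solved from ESP·BSA/index and
the Doppler velocities are solved so the two mean-PAP estimates agree.
Diastolic times are solved from a target rest D/S ratio and a target
rest→peak filling-rate ratio (≈3 normal, ≈1.6 DCM). Because construction
is algebraic, the qualitative contracts (coupling rises and peak
*E*es*I* ≥ 2·*E*a*I* in normals; coupling < 1 and peak
*E*es*I* < 0.5·*E*a*I* in DCM; marked vs modest SVR fall) hold for every
seed, which the tests verify over 50 consecutive seeds per profile.

The fixtures emulate central tendencies, not real data: no measurement
noise beyond the target jitter, no respiratory variation, no E/A fusion at
high heart rate (fusion above ~100–120 bpm makes real exercise E/e′ often
uninterpretable — a documented limitation, not a computation), no missing
fields, and only two stages. A passing contract suite therefore shows the
engine reproduces the intended physiology classes, not that it has been
validated against patients. One consequence of elastance-targeted
construction: the normal peak EDV falls slightly instead of rising, so the
stroke-volume decomposition attributes the whole SV change (and more) to
ESV reduction; the decomposition still sums to 100% by construction.

## Problem sizes

Every computation is closed-form on scalar inputs, so the full suite —
including 10⁴-draw identity checks and 2 × 50 seeded fixture contracts —
runs in a few seconds on one CPU; the acceptance script runs one seeded
end-to-end case plus three right-atrial-pressure lookups in well under a
second.

## Known limitations

- No echo-image or Doppler-trace processing: volumes, velocities and times
  are inputs.
- The 0.9·SBP surrogate strictly applies to central pressures; brachial
  readings carry pulse-wave amplification error.
- SPAP equals RVSP only without RV outflow obstruction; the engine does not
  model outflow gradients.
- The Doppler PVR surrogate is unreliable above 8 Wood units (flagged) and
  is no substitute for catheterization when PVR guides therapy.
- The invasive-form PVR uses the E/e′-derived wedge estimate; in left-heart
  failure the estimated wedge can approach or exceed the estimated mean PAP,
  in which case the row is reported not computable rather than negative.
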