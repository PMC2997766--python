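"""Cross-stage orchestration: per-stage panels, rest→peak comparison,
force-frequency classification and consistency checks.

``derive_panel`` runs every applicable calculation for one stage and
records, for each parameter of the derived set, either a value or a
"not computable" reason naming the missing input.  ``compare_stages``
pairs the rest and peak panels into absolute and percent changes, runs the
force-frequency classification over all stages, decomposes the stroke-volume
response into its end-diastolic (Frank-Starling) and end-systolic
(contractility) contributions, and collects internal-consistency notes
(two mean-PAP estimators, exercise pulmonary-pressure limits).

The force-frequency relation (Bowditch treppe) uses the cuff systolic
pressure over end-systolic volume index as the contractility measure at
each heart rate; its maximum over the stages defines the critical heart
rate (optimum stimulation frequency).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from . import diastology as dia
from . import pulmonary_hemodynamics as pul
from . import systemic_hemodynamics as sys_h
from .measurements import CaseSeries, StageRecord, SubjectProfile

log = logging.getLogger("hemostress")


@dataclass(frozen=True)
class EngineConfig:
    """Calculation conventions for the whole engine.

    bsa_method: "mosteller" (default) or "power".
    ees_pressure: pressure fed to the ventricular elastance index — "esp"
        (0.9*SBP end-systolic estimate, default) or "sbp" (raw cuff
        systolic pressure).
    elastance_indexing: "volume_index" (pressure over volume/BSA, default)
        or "per_bsa" (raw elastance divided by BSA).
    mpap_doppler_add_rap: include right atrial pressure in the Doppler
        mean-PAP estimate (default True, the explicit prose form).
    mpap_tolerance: mmHg difference between the two mean-PAP estimates
        above which a consistency warning is raised.
    athlete: treat the subject as a well-trained athlete for the exercise
        SPAP limits (subjects older than 55 are treated this way
        automatically).
    """

    bsa_method: str = "mosteller"
    ees_pressure: str = "esp"
    elastance_indexing: str = "volume_index"
    mpap_doppler_add_rap: bool = True
    mpap_tolerance: float = 5.0
    athlete: bool = False


@dataclass(frozen=True)
class ReferenceRanges:
    """Printed normal bands used for warning flags (never hard limits)."""

    bands: dict[str, tuple[float, float, str]] = field(
        default_factory=lambda: {
            "bsa": (1.5, 3.5, "m²"),
            "sv": (60.0, 100.0, "mL"),
            "co": (4.0, 6.0, "L/min"),
            "ci": (2.5, 3.6, "L/min/m²"),
            "map": (70.0, 100.0, "mmHg"),
            "svr": (900.0, 1300.0, "dyne·s·cm⁻⁵"),
            "pvr_invasive": (100.0, 200.0, "dyne·s·cm⁻⁵"),
        }
    )
    #: peak-exercise SPAP upper limit for general subjects (mmHg)
    exercise_spap_limit: float = 43.0
    #: upper limit that may still be physiologic in athletes/>55 y (mmHg)
    exercise_spap_athlete_limit: float = 60.0


REFERENCE_RANGES = ReferenceRanges()

#: canonical parameter order of the derived panel (algorithm-sheet order,
#: then supporting estimates)
PANEL_PARAMETERS: tuple[str, ...] = (
    "bsa",
    "sv",
    "svi",
    "co",
    "ci",
    "map",
    "pp",
    "esp",
    "ees_index",
    "ea_index",
    "vac",
    "svr",
    "compliance",
    "e_over_eprime",
    "mean_filling_rate",
    "ds_ratio",
    "spap",
    "padp",
    "mpap_standard",
    "mpap_doppler",
    "papp",
    "pvr_invasive",
    "pvr_wood",
    "pvc",
    # supporting values
    "cycle_length",
    "rap",
    "tr_gradient",
    "e_over_eprime_avg",
    "pcwp_est",
)


@dataclass
class DerivedPanel:
    """All derived parameters for one stage.

    Every panel parameter appears either in ``values`` or in
    ``not_computable`` (mapping name -> reason).  ``flags`` carries
    normal-range and classification warnings per parameter.
    """

    stage_label: str
    heart_rate: Optional[float] = None
    values: dict[str, float] = field(default_factory=dict)
    flags: dict[str, list[str]] = field(default_factory=dict)
    not_computable: dict[str, str] = field(default_factory=dict)

    def get(self, name: str) -> Optional[float]:
        return self.values.get(name)

    def flag(self, name: str, message: str) -> None:
        self.flags.setdefault(name, []).append(message)


@dataclass(frozen=True)
class ForceFrequencyResult:
    shape: str  # up_sloping | biphasic | flat_or_negative
    critical_heart_rate: float  # bpm
    sp_esvi_by_stage: tuple[tuple[float, float], ...]  # (hr, SP/ESVi)


@dataclass(frozen=True)
class ConsistencyNote:
    subject: str
    difference: float
    consistent: bool
    message: str


@dataclass
class StressComparison:
    """Paired rest/peak panels with changes and cross-stage classifications."""

    rest: DerivedPanel
    peak: DerivedPanel
    panels: tuple[DerivedPanel, ...]
    deltas: dict[str, float]
    pct_changes: dict[str, Optional[float]]
    ffr: Optional[ForceFrequencyResult]
    sv_decomposition: Optional[tuple[float, float]]
    consistency_notes: list[ConsistencyNote]


# ---------------------------------------------------------------------------
# elementary cross-stage operations


def cycle_length(heart_rate: float) -> int:
    """Total cardiac cycle duration in ms: 60000/HR, rounded to integer.

    Rounding is half-away-from-zero (75 bpm -> 800 ms, 90 bpm -> 667 ms).
    """
    if heart_rate <= 0:
        raise ValueError(f"heart rate must be > 0 bpm (got {heart_rate})")
    return int(math.floor(60000.0 / heart_rate + 0.5))


def percent_change(rest_value: float, peak_value: float) -> Optional[float]:
    """100·(peak − rest)/rest; ``None`` (not computable) when rest is 0."""
    if rest_value == 0:
        return None
    return 100.0 * (peak_value - rest_value) / rest_value


def force_frequency(
    series: Sequence[tuple[float, float]],
) -> ForceFrequencyResult:
    """Classify the force-frequency relation over ordered stress stages.

    ``series`` is the stage-ordered list of (heart rate, SP/ESV index).
    Shapes: ``up_sloping`` when the final (peak) value strictly exceeds
    every earlier value; ``flat_or_negative`` when the final value is at or
    below the baseline value; ``biphasic`` otherwise (above baseline but at
    or below some intermediate value, implying an interior optimum).  The
    critical heart rate is the heart rate at the series maximum, earliest
    stage on ties.
    """
    if len(series) < 2:
        raise ValueError("force-frequency classification needs >= 2 stages")
    values = [v for _, v in series]
    final, baseline = values[-1], values[0]
    if all(final > v for v in values[:-1]):
        shape = "up_sloping"
    elif final <= baseline:
        shape = "flat_or_negative"
    else:
        shape = "biphasic"
    best = 0
    for i, v in enumerate(values):
        if v > values[best]:
            best = i
    if best != len(values) - 1:
        log.info(
            "force-frequency: interior maximum at stage %d (HR %.0f bpm)",
            best,
            series[best][0],
        )
    return ForceFrequencyResult(
        shape=shape,
        critical_heart_rate=series[best][0],
        sp_esvi_by_stage=tuple((float(h), float(v)) for h, v in series),
    )


def sv_decomposition(
    rest: tuple[float, float], peak: tuple[float, float]
) -> Optional[tuple[float, float]]:
    """Split the stroke-volume change into EDV and ESV contributions (%).

    rest/peak are (EDV, ESV) pairs.  With ΔSV = SV_peak − SV_rest, the
    end-diastolic (Frank-Starling) contribution is 100·ΔEDV/ΔSV and the
    end-systolic (contractility) contribution 100·(−ΔESV)/ΔSV; they sum to
    100 whenever defined.  Returns ``None`` when ΔSV = 0.
    """
    edv_r, esv_r = rest
    edv_p, esv_p = peak
    dsv = (edv_p - esv_p) - (edv_r - esv_r)
    if dsv == 0:
        return None
    return 100.0 * (edv_p - edv_r) / dsv, 100.0 * (esv_r - esv_p) / dsv


def exercise_spap_flag(
    peak_spap: float,
    athlete_or_over55: bool = False,
    ranges: ReferenceRanges = REFERENCE_RANGES,
) -> str:
    """Classify the peak-exercise systolic pulmonary artery pressure.

    Normal is < 43 mmHg during exercise.  In well-trained athletes or
    subjects older than 55 years, values up to 55-60 mmHg may still be
    physiologic, so the flag escalates only above 60 mmHg for them.
    """
    if peak_spap < 0:
        raise ValueError(f"SPAP must be >= 0 mmHg (got {peak_spap})")
    if peak_spap < ranges.exercise_spap_limit:
        return "normal"
    if athlete_or_over55 and peak_spap <= ranges.exercise_spap_athlete_limit:
        return "may_be_physiologic"
    return "abnormal"


def mpap_consistency(
    mpap_standard: float, mpap_doppler: float, tolerance: float = 5.0
) -> ConsistencyNote:
    """Compare the two mean-PAP estimators; warn when they disagree."""
    diff = abs(mpap_standard - mpap_doppler)
    consistent = diff <= tolerance
    message = (
        f"mean PAP estimates {'agree' if consistent else 'disagree'}: "
        f"standard {mpap_standard:.1f} vs Doppler {mpap_doppler:.1f} mmHg "
        f"(|Δ| = {diff:.1f}, tolerance {tolerance:g})"
    )
    return ConsistencyNote("mpap", diff, consistent, message)


# ---------------------------------------------------------------------------
# per-stage panel derivation


def derive_panel(
    stage: StageRecord,
    subject: SubjectProfile,
    config: Optional[EngineConfig] = None,
    ranges: ReferenceRanges = REFERENCE_RANGES,
) -> DerivedPanel:
    """Compute every applicable derived parameter for one stage.

    Parameters whose inputs are missing or unusable land in
    ``not_computable`` with the missing field (or failure reason) named;
    the rest of the panel is unaffected.
    """
    cfg = config or EngineConfig()
    panel = DerivedPanel(stage_label=stage.stage_label, heart_rate=stage.heart_rate)
    v = panel.values
    nc = panel.not_computable

    def run(name: str, fn, *args, requires: str = ""):
        try:
            return fn(*args)
        except ValueError as exc:
            nc[name] = str(exc)
            log.info("%s/%s not computable: %s", stage.stage_label, name, exc)
            return None

    def missing(name: str, *fields: str) -> None:
        nc[name] = "missing " + ", ".join(fields)
        log.info("%s/%s not computable: %s", stage.stage_label, name, nc[name])

    # systemic panel -------------------------------------------------------
    cl = run("cycle_length", cycle_length, stage.heart_rate)
    if cl is not None:
        v["cycle_length"] = float(cl)
    bsa = run("bsa", sys_h.body_surface_area, subject.weight, subject.height, cfg.bsa_method)
    if bsa is not None:
        v["bsa"] = bsa

    sv = svi = None
    if bsa is not None:
        out = run("sv", sys_h.stroke_volume, stage.edv, stage.esv, bsa)
        if out is not None:
            sv, svi = out
            v["sv"], v["svi"] = sv, svi
    else:
        nc["sv"] = "BSA not computable"
    if "sv" in nc:
        nc.setdefault("svi", nc["sv"])

    co = ci = None
    if sv is not None and bsa is not None:
        out = run("co", sys_h.cardiac_output, stage.heart_rate, sv, bsa)
        if out is not None:
            co, ci = out
            v["co"], v["ci"] = co, ci
    else:
        nc["co"] = "stroke volume not computable"
    if "co" in nc:
        nc.setdefault("ci", nc["co"])

    map_ = run("map", sys_h.mean_arterial_pressure, stage.sbp, stage.dbp)
    if map_ is not None:
        v["map"] = map_
    pp = run("pp", sys_h.pulse_pressure, stage.sbp, stage.dbp)
    if pp is not None:
        v["pp"] = pp
    esp = run("esp", sys_h.end_systolic_pressure, stage.sbp)
    if esp is not None:
        v["esp"] = esp

    ees_pressure = esp if cfg.ees_pressure == "esp" else stage.sbp
    if ees_pressure is not None and bsa is not None:
        ees = run(
            "ees_index",
            sys_h.lv_elastance_index,
            ees_pressure,
            stage.esv,
            bsa,
            cfg.elastance_indexing,
        )
        if ees is not None:
            v["ees_index"] = ees
    else:
        nc["ees_index"] = "ESP or BSA not computable"
    if esp is not None and sv is not None and bsa is not None:
        ea = run(
            "ea_index",
            sys_h.arterial_elastance_index,
            esp,
            sv,
            bsa,
            cfg.elastance_indexing,
        )
        if ea is not None:
            v["ea_index"] = ea
    else:
        nc["ea_index"] = "ESP, SV or BSA not computable"

    if sv is not None:
        vac = run("vac", sys_h.ventricular_arterial_coupling, sv, stage.esv)
        if vac is not None:
            v["vac"] = vac
    else:
        nc["vac"] = "stroke volume not computable"

    if map_ is not None and co is not None:
        svr = run("svr", sys_h.systemic_vascular_resistance, map_, co)
        if svr is not None:
            v["svr"] = svr
    else:
        nc["svr"] = "MAP or CO not computable"
    if sv is not None and pp is not None:
        compliance = run("compliance", sys_h.systemic_arterial_compliance, sv, pp)
        if compliance is not None:
            v["compliance"] = compliance
    else:
        nc["compliance"] = "SV or PP not computable"

    # diastolic panel ------------------------------------------------------
    septal_ratio = None
    if stage.mitral_e is not None and (
        stage.mitral_eprime_septal is not None or stage.mitral_eprime_lateral is not None
    ):
        out = run(
            "e_over_eprime",
            dia.e_over_eprime_panel,
            stage.mitral_e,
            stage.mitral_eprime_septal,
            stage.mitral_eprime_lateral,
        )
        if out is not None:
            septal_ratio, averaged = out
            if septal_ratio is not None:
                v["e_over_eprime"] = septal_ratio
                panel.flag(
                    "e_over_eprime",
                    f"LV filling pressure {dia.classify_filling_pressure(septal_ratio)}",
                )
            else:
                missing("e_over_eprime", "mitral_eprime_septal")
            if averaged is not None:
                v["e_over_eprime_avg"] = averaged
            else:
                missing("e_over_eprime_avg", "mitral_eprime_septal", "mitral_eprime_lateral")
    else:
        missing("e_over_eprime", "mitral_e", "mitral_eprime_septal")
        missing("e_over_eprime_avg", "mitral_e", "mitral_eprime_septal", "mitral_eprime_lateral")

    if septal_ratio is not None:
        pcwp = run("pcwp_est", dia.estimate_pcwp, septal_ratio)
        if pcwp is not None:
            v["pcwp_est"] = pcwp
            if pcwp > dia.PCWP_ELEVATED_LIMIT:
                panel.flag("pcwp_est", f"estimated PCWP > {dia.PCWP_ELEVATED_LIMIT:g} mmHg (elevated)")
    else:
        nc.setdefault("pcwp_est", "septal E/e' not computable")

    if svi is not None and stage.diastolic_time is not None:
        mfr = run("mean_filling_rate", dia.diastolic_mean_filling_rate, svi, stage.diastolic_time)
        if mfr is not None:
            v["mean_filling_rate"] = mfr
    elif stage.diastolic_time is None:
        missing("mean_filling_rate", "diastolic_time")
    else:
        nc["mean_filling_rate"] = "stroke volume index not computable"

    if stage.ds_ratio is not None:
        flagged = run("ds_ratio", dia.ds_ratio_flag, stage.ds_ratio)
        if "ds_ratio" not in nc:
            v["ds_ratio"] = stage.ds_ratio
            if flagged:
                panel.flag(
                    "ds_ratio", "diastolic/systolic ratio <= 1: reversal may compromise filling"
                )
    else:
        missing("ds_ratio", "ds_ratio")

    # pulmonary panel ------------------------------------------------------
    rap = None
    if stage.ivc_diameter is not None and stage.ivc_collapse is not None:
        est = run("rap", pul.right_atrial_pressure, stage.ivc_diameter, stage.ivc_collapse)
        if est is not None:
            rap = est.rap
            v["rap"] = est.rap
            panel.flag("rap", f"{est.label} ({est.low:g}-{est.high:g} mmHg)")
    else:
        missing("rap", "ivc_diameter", "ivc_collapse")

    if stage.tr_velocity is not None:
        trg = run("tr_gradient", pul.bernoulli_gradient, stage.tr_velocity)
        if trg is not None:
            v["tr_gradient"] = trg
    else:
        missing("tr_gradient", "tr_velocity")

    spap = None
    if stage.tr_velocity is not None and rap is not None:
        spap = run("spap", pul.rv_systolic_pressure, stage.tr_velocity, rap)
        if spap is not None:
            v["spap"] = spap
            if spap > pul.RVSP_EVALUATION_CUTOFF:
                panel.flag(
                    "spap",
                    f"RV systolic pressure > {pul.RVSP_EVALUATION_CUTOFF:g} mmHg: "
                    "further evaluation recommended",
                )
    elif stage.tr_velocity is None:
        missing("spap", "tr_velocity")
    else:
        nc["spap"] = "right atrial pressure not computable"

    padp = None
    if stage.pr_end_diastolic_velocity is not None and rap is not None:
        padp = run("padp", pul.pa_diastolic_pressure, stage.pr_end_diastolic_velocity, rap)
        if padp is not None:
            v["padp"] = padp
            ed_gradient = pul.bernoulli_gradient(stage.pr_end_diastolic_velocity)
            if ed_gradient > pul.PR_ED_GRADIENT_CUTOFF:
                panel.flag(
                    "padp",
                    f"PR end-diastolic gradient {ed_gradient:.1f} mmHg > "
                    f"{pul.PR_ED_GRADIENT_CUTOFF:g} mmHg",
                )
    elif stage.pr_end_diastolic_velocity is None:
        missing("padp", "pr_end_diastolic_velocity")
    else:
        nc["padp"] = "right atrial pressure not computable"

    if spap is not None and padp is not None:
        out = run("mpap_standard", pul.mean_pa_pressure, spap, padp)
        if out is not None and out[0] is not None:
            v["mpap_standard"] = out[0]
    else:
        nc["mpap_standard"] = "SPAP or PADP not computable"
    if stage.pr_peak_velocity is not None and rap is not None:
        out = run(
            "mpap_doppler",
            pul.mean_pa_pressure,
            None,
            None,
            stage.pr_peak_velocity,
            rap,
            cfg.mpap_doppler_add_rap,
        )
        if out is not None and out[1] is not None:
            v["mpap_doppler"] = out[1]
    elif stage.pr_peak_velocity is None:
        missing("mpap_doppler", "pr_peak_velocity")
    else:
        nc["mpap_doppler"] = "right atrial pressure not computable"

    papp = None
    if stage.tr_velocity is not None and stage.pr_end_diastolic_velocity is not None:
        papp = run(
            "papp", pul.pa_pulse_pressure, stage.tr_velocity, stage.pr_end_diastolic_velocity
        )
        if papp is not None:
            v["papp"] = papp
    else:
        missing("papp", "tr_velocity", "pr_end_diastolic_velocity")

    if "mpap_standard" in v and "pcwp_est" in v and co is not None:
        pvr = run("pvr_invasive", pul.pvr_invasive, v["mpap_standard"], v["pcwp_est"], co)
        if pvr is not None:
            v["pvr_invasive"] = pvr
            panel.flag("pvr_invasive", "PCWP estimated from E/e'")
    else:
        nc["pvr_invasive"] = "mean PAP, PCWP estimate or CO not computable"

    if stage.tr_velocity is not None and stage.rvot_tvi is not None:
        out = run("pvr_wood", pul.pvr_doppler, stage.tr_velocity, stage.rvot_tvi)
        if out is not None:
            v["pvr_wood"] = out.wood
            panel.flag("pvr_wood", out.severity)
            if not out.reliable:
                panel.flag(
                    "pvr_wood",
                    f"> {pul.PVR_DOPPLER_RELIABLE_LIMIT:g} Wood units: estimate not reliable",
                )
    else:
        missing("pvr_wood", "tr_velocity", "rvot_tvi")

    if sv is not None and papp is not None:
        pvc = run("pvc", pul.pulmonary_vascular_capacitance, sv, papp)
        if pvc is not None:
            v["pvc"] = pvc
    else:
        nc["pvc"] = "SV or PA pulse pressure not computable"

    # normal-range warning flags ------------------------------------------
    for name, (low, high, unit) in ranges.bands.items():
        val = v.get(name)
        if val is not None and not (low <= val <= high):
            panel.flag(name, f"outside normal range {low:g}-{high:g} {unit}")

    # totality: every panel parameter accounted for
    for name in PANEL_PARAMETERS:
        if name not in v and name not in nc:
            nc[name] = "not computed"
    return panel


# ---------------------------------------------------------------------------
# case-level comparison


def compare_stages(
    case: CaseSeries,
    config: Optional[EngineConfig] = None,
    ranges: ReferenceRanges = REFERENCE_RANGES,
) -> StressComparison:
    """Derive all stage panels and build the rest→peak comparison."""
    cfg = config or EngineConfig()
    if len(case.stages) < 2:
        raise ValueError("a stress comparison needs at least rest and peak stages")
    panels = tuple(derive_panel(s, case.subject, cfg, ranges) for s in case.stages)
    rest, peak = panels[0], panels[-1]

    deltas: dict[str, float] = {}
    pct: dict[str, Optional[float]] = {}
    for name in PANEL_PARAMETERS:
        r, p = rest.get(name), peak.get(name)
        if r is None or p is None:
            continue
        deltas[name] = p - r
        pct[name] = percent_change(r, p)

    ffr = None
    ffr_series = [
        (s.heart_rate, sys_h.lv_elastance_index(s.sbp, s.esv, panel.values["bsa"]))
        for s, panel in zip(case.stages, panels)
        if s.esv > 0 and s.sbp > 0 and "bsa" in panel.values
    ]
    if len(ffr_series) >= 2:
        ffr = force_frequency(ffr_series)

    decomposition = None
    if case.rest.edv > case.rest.esv > 0 and case.peak.edv > case.peak.esv > 0:
        decomposition = sv_decomposition(
            (case.rest.edv, case.rest.esv), (case.peak.edv, case.peak.esv)
        )

    notes: list[ConsistencyNote] = []
    for panel in panels:
        std, dop = panel.get("mpap_standard"), panel.get("mpap_doppler")
        if std is not None and dop is not None:
            note = mpap_consistency(std, dop, cfg.mpap_tolerance)
            notes.append(
                ConsistencyNote(
                    f"mpap[{panel.stage_label}]", note.difference, note.consistent, note.message
                )
            )
    peak_spap = peak.get("spap")
    if peak_spap is not None:
        athlete = cfg.athlete or (
            case.subject.age is not None and case.subject.age > 55
        )
        klass = exercise_spap_flag(peak_spap, athlete, ranges)
        notes.append(
            ConsistencyNote(
                "exercise_spap",
                peak_spap,
                klass == "normal",
                f"peak-exercise SPAP {peak_spap:.1f} mmHg: {klass}",
            )
        )

    return StressComparison(
        rest=rest,
        peak=peak,
        panels=panels,
        deltas=deltas,
        pct_changes=pct,
        ffr=ffr,
        sv_decomposition=decomposition,
        consistency_notes=notes,
    )
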