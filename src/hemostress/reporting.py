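"""Results-sheet rendering, trend plots and synthetic training fixtures.

The "calculated results" sheet mirrors the algorithm-set layout: one row
per derived parameter with the calculation algorithm, rest and peak values,
units, percent rest→peak change and any warning flags.  Rendering is
deterministic (byte-identical for identical inputs); values not computable
from the available measurements are printed ``n/c`` with the missing input
named.

The fixture generator builds complete synthetic training cases for a
``normal`` and a ``dcm`` (dilated cardiomyopathy) profile.  Cases are
constructed backwards: target derived values are drawn from the published
normal/pathological averages (ventricular elastance index 4.5 → 14.5 and
arterial elastance index 2.3 → 3.2 mmHg/mL/m² from rest to peak in
normals; ventricular-arterial coupling stuck at ~0.4-0.5 in DCM) with a
small seeded jitter, then raw measurements are solved algebraically, so
the qualitative rest→peak patterns hold by construction for every seed.
"""

from __future__ import annotations

import csv
import io
import json
import logging
import math
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .measurements import CaseSeries, StageRecord, SubjectProfile
from .stress_analysis import EngineConfig, PANEL_PARAMETERS, StressComparison
from .systemic_hemodynamics import body_surface_area

log = logging.getLogger("hemostress")

#: (key, label, algorithm text, unit, decimals) in sheet order
ROW_SPECS: tuple[tuple[str, str, str, str, int], ...] = (
    ("bsa", "Body Surface Area (BSA)", "sqrt(kg*cm/3600)", "m2", 2),
    ("sv", "Stroke Volume (SV)", "EDV - ESV", "mL", 1),
    ("svi", "Stroke Volume index (SVI)", "SV/BSA", "mL/m2", 1),
    ("co", "Cardiac Output (CO)", "HR * SV / 1000", "L/min", 2),
    ("ci", "Cardiac Index (CI)", "CO/BSA", "L/min/m2", 2),
    ("map", "Mean Arterial Pressure (MAP)", "(SBP-DBP)/3 + DBP", "mmHg", 1),
    ("pp", "Pulse Pressure (PP)", "SBP - DBP", "mmHg", 1),
    ("esp", "End Systolic Pressure (ESP)", "0.9 * SBP", "mmHg", 1),
    ("ees_index", "LV Elastance index (EesI)", "ESP/(ESV/BSA)", "mmHg/mL/m2", 2),
    ("ea_index", "Arterial Elastance index (EaI)", "ESP/(SV/BSA)", "mmHg/mL/m2", 2),
    ("vac", "Ventricular-Arterial Coupling (VAC)", "SV/ESV", "ratio", 2),
    ("svr", "Systemic Vascular Resistance (SVR)", "80*(MAP-5)/CO", "dyne*s*cm-5", 0),
    ("compliance", "Systemic Arterial Compliance (C)", "SV/PP", "mL/mmHg", 2),
    ("e_over_eprime", "Mitral E/e' (septal)", "E / e' septal", "ratio", 2),
    (
        "mean_filling_rate",
        "Diastolic Mean Filling Rate",
        "(SVI/diastolic time)*1000",
        "mL/m2/s",
        1,
    ),
    ("ds_ratio", "Diastolic/Systolic time ratio", "measured", "ratio", 2),
    ("spap", "PA Systolic Pressure (SPAP)", "4*TRV^2 + RAP", "mmHg", 1),
    ("padp", "PA Diastolic Pressure (PADP)", "4*PREDV^2 + RAP", "mmHg", 1),
    ("mpap_standard", "Mean PA Pressure (standard)", "SPAP/3 + 2*PADP/3", "mmHg", 1),
    ("mpap_doppler", "Mean PA Pressure (Doppler)", "4*PRpeak^2 + RAP", "mmHg", 1),
    ("papp", "PA Pulse Pressure (PAPP)", "4*TRV^2 - 4*PREDV^2", "mmHg", 1),
    (
        "pvr_invasive",
        "Pulmonary Vascular Resistance (PVR)",
        "80*(MPAP-PCWP)/CO",
        "dyne*s*cm-5",
        0,
    ),
    (
        "pvr_wood",
        "Pulmonary Vascular Resistance (Doppler)",
        "10*TRV/TVI(RVOT)",
        "Wood units",
        2,
    ),
    ("pvc", "Pulmonary Vascular Capacitance (PVC)", "SV/PAPP", "mL/mmHg", 2),
    ("cycle_length", "Cardiac cycle length", "60000/HR", "ms", 0),
    ("rap", "Right Atrial Pressure (RAP)", "IVC diameter & collapse lookup", "mmHg", 0),
    ("tr_gradient", "TR peak gradient", "4*TRV^2", "mmHg", 1),
    ("e_over_eprime_avg", "Mitral E/e' (averaged)", "E / mean(e' septal, lateral)", "ratio", 2),
    ("pcwp_est", "PCWP estimate", "1.24*(E/e') + 1.9", "mmHg", 1),
)

assert tuple(k for k, *_ in ROW_SPECS) == PANEL_PARAMETERS


def _fmt(value: Optional[float], decimals: int) -> str:
    if value is None:
        return ""
    return f"{value:.{decimals}f}"


def build_rows(
    comparison: StressComparison, config: Optional[EngineConfig] = None
) -> list[dict[str, str]]:
    """Assemble the report rows (strings, already rounded for display)."""
    cfg = config or EngineConfig()
    rows = []
    for key, label, algorithm, unit, decimals in ROW_SPECS:
        if key == "mpap_doppler" and not cfg.mpap_doppler_add_rap:
            algorithm = "4*PRpeak^2"
        cells = {}
        for which, panel in (("rest", comparison.rest), ("peak", comparison.peak)):
            val = panel.get(key)
            if val is not None:
                cells[which] = _fmt(val, decimals)
            else:
                reason = panel.not_computable.get(key, "not computed")
                cells[which] = f"n/c ({reason})"
        pct = comparison.pct_changes.get(key)
        if key in comparison.deltas:
            pct_cell = _fmt(pct, 1) if pct is not None else "n/c (rest value is 0)"
        else:
            pct_cell = "n/c"
        flags = []
        for which, panel in (("rest", comparison.rest), ("peak", comparison.peak)):
            for f in panel.flags.get(key, []):
                flags.append(f"{which}: {f}")
        rows.append(
            {
                "parameter": label,
                "algorithm": algorithm,
                "rest": cells["rest"],
                "peak": cells["peak"],
                "unit": unit,
                "pct_change": pct_cell,
                "flags": "; ".join(flags),
            }
        )
    return rows


def render_report(
    comparison: StressComparison,
    format: str = "text",
    config: Optional[EngineConfig] = None,
) -> str:
    """Render the calculated-results sheet as ``csv``, ``json`` or ``text``.

    Output is deterministic: identical comparisons render byte-identically.
    """
    rows = build_rows(comparison, config)
    notes = [n.message for n in comparison.consistency_notes]
    if comparison.ffr is not None:
        notes.append(
            f"force-frequency relation: {comparison.ffr.shape}, critical heart rate "
            f"{comparison.ffr.critical_heart_rate:.0f} bpm"
        )
    if comparison.sv_decomposition is not None:
        edv_c, esv_c = comparison.sv_decomposition
        notes.append(
            f"stroke-volume change decomposition: EDV contribution {edv_c:.1f}%, "
            f"ESV contribution {esv_c:.1f}%"
        )

    if format == "csv":
        buf = io.StringIO()
        writer = csv.DictWriter(
            buf,
            fieldnames=["parameter", "algorithm", "rest", "peak", "unit", "pct_change", "flags"],
            lineterminator="\n",
        )
        writer.writeheader()
        writer.writerows(rows)
        return buf.getvalue()
    if format == "json":
        return json.dumps({"rows": rows, "notes": notes}, indent=2) + "\n"
    if format == "text":
        widths = {
            col: max(
                len(col), *(len(r[col]) for r in rows)
            )
            for col in ("parameter", "algorithm", "rest", "peak", "unit", "pct_change")
        }
        lines = []
        header = "  ".join(col.ljust(widths[col]) for col in widths) + "  flags"
        lines.append(header)
        lines.append("-" * len(header))
        for r in rows:
            lines.append(
                "  ".join(r[col].ljust(widths[col]) for col in widths) + "  " + r["flags"]
            )
        if notes:
            lines.append("")
            lines.append("Notes:")
            lines.extend(f"  - {n}" for n in notes)
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown report format: {format!r}")


def plot_trends(comparison: StressComparison, outdir: str | Path) -> list[Path]:
    """Write one trend plot per parameter (heart rate on x, value on y).

    Parameters present in fewer than two stage panels are omitted (logged).
    The force-frequency curve gets a dedicated panel with the critical
    heart rate marked.  Returns the written file paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    panels = comparison.panels
    for key, label, _algo, unit, _dp in ROW_SPECS:
        points = [
            (p.heart_rate, p.values[key])
            for p in panels
            if p.heart_rate is not None and key in p.values
        ]
        if len(points) < 2:
            log.info("plot_trends: '%s' present in %d stage(s), panel omitted", key, len(points))
            continue
        xs, ys = zip(*points)
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.plot(xs, ys, marker="o")
        ax.set_xlabel("heart rate (bpm)")
        ax.set_ylabel(f"{label} ({unit})")
        ax.set_title(label, fontsize=9)
        fig.tight_layout()
        path = outdir / f"{key}.png"
        fig.savefig(path)
        plt.close(fig)
        written.append(path)
    if comparison.ffr is not None:
        xs = [hr for hr, _ in comparison.ffr.sp_esvi_by_stage]
        ys = [v for _, v in comparison.ffr.sp_esvi_by_stage]
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.plot(xs, ys, marker="o")
        ax.axvline(comparison.ffr.critical_heart_rate, linestyle="--", color="gray")
        ax.set_xlabel("heart rate (bpm)")
        ax.set_ylabel("SP/ESV index (mmHg/mL/m2)")
        ax.set_title(
            f"force-frequency: {comparison.ffr.shape} "
            f"(critical HR {comparison.ffr.critical_heart_rate:.0f} bpm)",
            fontsize=8,
        )
        fig.tight_layout()
        path = outdir / "force_frequency.png"
        fig.savefig(path)
        plt.close(fig)
        written.append(path)
    return written


# ---------------------------------------------------------------------------
# synthetic training fixtures


def _jitter(rng: np.random.Generator, value: float, frac: float) -> float:
    return float(value * (1.0 + frac * rng.uniform(-1.0, 1.0)))


def _solve_stage(
    rng: np.random.Generator,
    label: str,
    bsa: float,
    hr: float,
    sbp: float,
    dbp: float,
    ees_index: float,
    ea_index: float,
    trv: float,
    pr_edv: float,
    rvot_tvi: float,
    ivc_diameter: float,
    ivc_collapse: float,
    rap: float,
    mitral_e: float,
    eprime_septal: float,
    eprime_lateral: float,
    diastolic_time: float,
) -> StageRecord:
    """Solve raw volumes from target elastance indices and assemble a stage."""
    esp = 0.9 * sbp
    esv = esp * bsa / ees_index
    sv = esp * bsa / ea_index
    edv = esv + sv
    # peak early PR velocity chosen so the Doppler mean-PAP estimate matches
    # the standard formula (internal consistency holds by construction)
    spap = 4.0 * trv**2 + rap
    padp = 4.0 * pr_edv**2 + rap
    mpap = spap / 3.0 + 2.0 * padp / 3.0
    pr_peak = math.sqrt(max(mpap - rap, 0.0) / 4.0)
    cl = 60000.0 / hr
    ds_ratio = diastolic_time / (cl - diastolic_time)
    return StageRecord(
        stage_label=label,
        heart_rate=round(hr),
        sbp=round(sbp),
        dbp=round(dbp),
        edv=round(edv, 1),
        esv=round(esv, 1),
        mitral_e=round(mitral_e, 1),
        mitral_eprime_septal=round(eprime_septal, 1),
        mitral_eprime_lateral=round(eprime_lateral, 1),
        diastolic_time=round(diastolic_time),
        ds_ratio=round(ds_ratio, 2),
        tr_velocity=round(trv, 2),
        ivc_diameter=round(ivc_diameter, 1),
        ivc_collapse=round(ivc_collapse, 2),
        pr_end_diastolic_velocity=round(pr_edv, 2),
        pr_peak_velocity=round(pr_peak, 2),
        rvot_tvi=round(rvot_tvi, 1),
    )


def make_fixture(profile: str, seed: int) -> CaseSeries:
    """Build a seeded, reproducible synthetic training case.

    ``normal``: healthy exercise response — ventricular elastance index
    rising ~4.5 → ~14.5 mmHg/mL/m² against arterial elastance ~2.3 → ~3.2,
    so coupling rises ~1.9 → ~4.5; systemic resistance drops markedly; the
    diastolic mean filling rate roughly triples.

    ``dcm``: dilated cardiomyopathy — blunted contractile reserve with the
    ventricular elastance index stuck below half the arterial elastance
    index, coupling < 1 throughout, a modest resistance decrease, elevated
    E/e' and pulmonary pressures.

    The same (profile, seed) pair always yields an identical case.
    """
    rng = np.random.default_rng(seed)
    j = lambda value, frac: _jitter(rng, value, frac)  # noqa: E731

    if profile == "normal":
        subject = SubjectProfile(
            height=round(j(170, 0.03)), weight=round(j(72, 0.05), 1), age=round(j(45, 0.1))
        )
        bsa = body_surface_area(subject.weight, subject.height)
        rest_hr, peak_hr = j(70, 0.05), j(160, 0.04)
        rest = dict(
            label="rest",
            bsa=bsa,
            hr=rest_hr,
            sbp=j(120, 0.03),
            dbp=j(80, 0.03),
            ees_index=j(4.5, 0.03),
            ea_index=j(2.3, 0.03),
            trv=j(2.3, 0.03),
            pr_edv=j(0.7, 0.05),
            rvot_tvi=j(18, 0.05),
            ivc_diameter=j(1.8, 0.05),
            ivc_collapse=j(0.6, 0.05),
            rap=3.0,
            mitral_e=j(70, 0.05),
            eprime_septal=j(12, 0.05),
            eprime_lateral=j(14, 0.05),
        )
        peak = dict(
            label="peak",
            bsa=bsa,
            hr=peak_hr,
            sbp=j(180, 0.03),
            dbp=j(85, 0.03),
            ees_index=j(14.5, 0.03),
            ea_index=j(3.2, 0.03),
            trv=j(2.8, 0.02),
            pr_edv=j(0.95, 0.05),
            rvot_tvi=j(24, 0.05),
            ivc_diameter=j(1.8, 0.05),
            ivc_collapse=j(0.6, 0.05),
            rap=3.0,
            mitral_e=j(110, 0.05),
            eprime_septal=j(16, 0.05),
            eprime_lateral=j(18, 0.05),
        )
        rest_ds, filling_ratio = j(1.3, 0.05), j(3.0, 0.05)
    elif profile == "dcm":
        subject = SubjectProfile(
            height=round(j(172, 0.02)), weight=round(j(82, 0.05), 1), age=round(j(52, 0.05))
        )
        bsa = body_surface_area(subject.weight, subject.height)
        rest_hr, peak_hr = j(75, 0.05), j(120, 0.05)
        rest = dict(
            label="rest",
            bsa=bsa,
            hr=rest_hr,
            sbp=j(110, 0.03),
            dbp=j(70, 0.03),
            ees_index=j(1.4, 0.03),
            ea_index=j(3.5, 0.03),
            trv=j(3.05, 0.03),
            pr_edv=j(1.25, 0.04),
            rvot_tvi=j(14, 0.04),
            ivc_diameter=j(2.4, 0.03),
            ivc_collapse=j(0.55, 0.04),
            rap=8.0,
            mitral_e=j(82, 0.04),
            eprime_septal=j(5.2, 0.03),
            eprime_lateral=j(6.4, 0.04),
        )
        peak = dict(
            label="peak",
            bsa=bsa,
            hr=peak_hr,
            sbp=j(125, 0.03),
            dbp=j(75, 0.03),
            ees_index=j(1.95, 0.03),
            ea_index=j(4.3, 0.03),
            trv=j(3.3, 0.03),
            pr_edv=j(1.5, 0.04),
            rvot_tvi=j(15, 0.04),
            ivc_diameter=j(2.4, 0.03),
            ivc_collapse=j(0.55, 0.04),
            rap=8.0,
            mitral_e=j(100, 0.04),
            eprime_septal=j(5.3, 0.03),
            eprime_lateral=j(6.5, 0.04),
        )
        rest_ds, filling_ratio = j(1.05, 0.04), j(1.6, 0.05)
    else:
        raise ValueError(f"unknown fixture profile: {profile!r} (expected 'normal' or 'dcm')")

    # diastolic times: rest from the target D/S ratio, peak from the target
    # rest->peak filling-rate ratio
    rest_cl = 60000.0 / rest_hr
    rest_dt = rest_cl * rest_ds / (1.0 + rest_ds)
    rest_svi = (0.9 * rest["sbp"]) / rest["ea_index"]
    rest_rate = rest_svi / rest_dt * 1000.0
    peak_svi = (0.9 * peak["sbp"]) / peak["ea_index"]
    peak_dt = peak_svi / (filling_ratio * rest_rate) * 1000.0

    stages = (
        _solve_stage(rng, diastolic_time=rest_dt, **{k: v for k, v in rest.items()}),
        _solve_stage(rng, diastolic_time=peak_dt, **{k: v for k, v in peak.items()}),
    )
    return CaseSeries(subject=subject, stages=stages)
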