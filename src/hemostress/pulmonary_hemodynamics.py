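"""Right-heart and pulmonary circulation calculations.

Pulmonary pressures are derived from regurgitant-jet velocities with the
simplified Bernoulli equation (gradient = 4·v², v in m/s, gradient in mmHg)
plus an estimate of right atrial pressure from inferior vena cava diameter
and respiratory collapse.  Pulmonary vascular resistance is provided both in
its invasive form 80·(mPAP − PCWP)/CO (dyne·s·cm⁻⁵) and as the Doppler
surrogate 10·TRV/TVI_RVOT (Wood units); pulmonary vascular capacitance is
stroke volume over pulmonary pulse pressure.

Resistance unit conversions use exact integer ratios (1 Wood unit =
80 dyne·s·cm⁻⁵ = 8 MPa·s/m³), so round trips are exact whenever the input
supports exact arithmetic (``int``, ``fractions.Fraction``) and correctly
rounded for floats.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

log = logging.getLogger("hemostress")

#: Doppler PVR above this many Wood units is considered unreliable
PVR_DOPPLER_RELIABLE_LIMIT = 8.0
#: invasively normal PVR is below this (Wood units)
PVR_WOOD_NORMAL_LIMIT = 1.5
#: significant pulmonary hypertension threshold (Wood units)
PVR_WOOD_SIGNIFICANT_LIMIT = 3.0
#: RV systolic pressure above this (mmHg) warrants further evaluation
RVSP_EVALUATION_CUTOFF = 40.0
#: normal PR end-diastolic gradient is below this (mmHg)
PR_ED_GRADIENT_CUTOFF = 5.0


@dataclass(frozen=True)
class RAPEstimate:
    """Right atrial pressure point estimate with its lookup range."""

    rap: float  # mmHg
    low: float  # mmHg
    high: float  # mmHg
    label: str  # normal | intermediate | high


@dataclass(frozen=True)
class DopplerPVR:
    """Doppler pulmonary vascular resistance with reliability/severity."""

    wood: float
    reliable: bool
    severity: str  # normal | intermediate | significant_ph


def right_atrial_pressure(ivc_diameter: float, collapse: float) -> RAPEstimate:
    """Estimate right atrial pressure from IVC diameter and sniff collapse.

    A small IVC (<= 2.1 cm) that collapses >= 50% suggests a normal RAP of
    3 mmHg (range 0-5); a dilated IVC (> 2.1 cm) with < 50% collapse
    suggests a high RAP of 15 mmHg (range 10-20); every other combination
    is indeterminate and assigned the intermediate 8 mmHg (range 5-10).

    The lookup leaves diameter exactly 2.1 cm on the small-diameter branch
    and collapse exactly 50% on the collapsing branch, so every input pair
    maps to exactly one of {3, 8, 15}.
    """
    if ivc_diameter <= 0:
        raise ValueError(f"IVC diameter must be > 0 cm (got {ivc_diameter})")
    if not (0.0 <= collapse <= 1.0):
        raise ValueError(f"IVC collapse must be a fraction in [0, 1] (got {collapse})")
    small, collapsing = ivc_diameter <= 2.1, collapse >= 0.5
    if small and collapsing:
        return RAPEstimate(3.0, 0.0, 5.0, "normal")
    if not small and not collapsing:
        return RAPEstimate(15.0, 10.0, 20.0, "high")
    log.info(
        "RAP lookup: indeterminate IVC pattern (diameter %.2f cm, collapse %.0f%%) "
        "-> intermediate 8 mmHg",
        ivc_diameter,
        100 * collapse,
    )
    return RAPEstimate(8.0, 5.0, 10.0, "intermediate")


def bernoulli_gradient(velocity: float) -> float:
    """Simplified Bernoulli pressure gradient 4·v² (v in m/s, result mmHg)."""
    if velocity < 0:
        raise ValueError(f"jet velocity must be >= 0 m/s (got {velocity})")
    return 4.0 * velocity * velocity


def rv_systolic_pressure(tr_velocity: float, rap: float) -> float:
    """RVSP = 4·TRV² + RAP (mmHg).

    Equals systolic pulmonary artery pressure in the absence of a gradient
    across the pulmonary valve or RV outflow tract.  Values > 40 mmHg in
    dyspneic patients warrant further evaluation.
    """
    if rap < 0:
        raise ValueError(f"RAP must be >= 0 mmHg (got {rap})")
    return bernoulli_gradient(tr_velocity) + rap


def pa_diastolic_pressure(pr_end_diastolic_velocity: float, rap: float) -> float:
    """PADP = 4·(PR end-diastolic velocity)² + RAP (mmHg)."""
    if rap < 0:
        raise ValueError(f"RAP must be >= 0 mmHg (got {rap})")
    return bernoulli_gradient(pr_end_diastolic_velocity) + rap


def mean_pa_pressure(
    spap: Optional[float] = None,
    padp: Optional[float] = None,
    pr_peak_velocity: Optional[float] = None,
    rap: float = 0.0,
    add_rap: bool = True,
) -> tuple[Optional[float], Optional[float]]:
    """Mean pulmonary artery pressure, standard and Doppler estimates.

    Standard formula: mPAP = SPAP/3 + 2·PADP/3 (needs both pressures).
    Doppler method: mPAP = 4·(peak early PR velocity)² (+ RAP when
    ``add_rap``; the explicit prose form of the estimator includes RAP).
    Both are returned so the internal consistency of the data can be
    challenged; either is ``None`` when its inputs are absent.
    """
    standard = None
    if spap is not None and padp is not None:
        if spap < padp:
            raise ValueError(f"SPAP ({spap}) must be >= PADP ({padp})")
        standard = spap / 3.0 + 2.0 * padp / 3.0
    doppler = None
    if pr_peak_velocity is not None:
        doppler = bernoulli_gradient(pr_peak_velocity) + (rap if add_rap else 0.0)
    return standard, doppler


def pa_pulse_pressure(tr_velocity: float, pr_end_diastolic_velocity: float) -> float:
    """PAPP = 4·TRV² − 4·(PR end-diastolic velocity)² (mmHg).

    Identical to SPAP − PADP for any common RAP (the RAP terms cancel).
    A negative result means the two jets are mutually inconsistent.
    """
    papp = bernoulli_gradient(tr_velocity) - bernoulli_gradient(pr_end_diastolic_velocity)
    if papp < 0:
        raise ValueError(
            "inconsistent velocities: PR end-diastolic gradient exceeds TR gradient "
            f"(TRV {tr_velocity} m/s, PR-EDV {pr_end_diastolic_velocity} m/s)"
        )
    return papp


def pvr_invasive(mpap: float, pcwp: float, co: float) -> float:
    """PVR = 80·(mPAP − PCWP)/CO in dyne·s·cm⁻⁵.  Normal 100-200."""
    if co <= 0:
        raise ValueError(f"cardiac output must be > 0 L/min (got {co})")
    if mpap < pcwp:
        raise ValueError(f"mPAP ({mpap}) must be >= PCWP ({pcwp})")
    return 80.0 * (mpap - pcwp) / co


def pvr_doppler(tr_velocity: float, rvot_tvi: float) -> DopplerPVR:
    """Doppler PVR = 10·TRV/TVI_RVOT in Wood units.

    TRV in m/s, RVOT time-velocity integral in cm.  Not reliable above
    8 Wood units.  Severity: < 1.5 Wood normal, > 3 Wood significant
    pulmonary hypertension, intermediate otherwise.
    """
    if rvot_tvi <= 0:
        raise ValueError(f"RVOT TVI must be > 0 cm (got {rvot_tvi})")
    if tr_velocity < 0:
        raise ValueError(f"TR velocity must be >= 0 m/s (got {tr_velocity})")
    wood = 10.0 * tr_velocity / rvot_tvi
    reliable = wood <= PVR_DOPPLER_RELIABLE_LIMIT
    if wood < PVR_WOOD_NORMAL_LIMIT:
        severity = "normal"
    elif wood > PVR_WOOD_SIGNIFICANT_LIMIT:
        severity = "significant_ph"
    else:
        severity = "intermediate"
    return DopplerPVR(wood=wood, reliable=reliable, severity=severity)


def pulmonary_vascular_capacitance(sv: float, papp: float) -> float:
    """PVC = SV/PAPP, mL/mmHg — right-ventricular load/prognosis measure."""
    if papp <= 0:
        raise ValueError(f"PA pulse pressure must be > 0 mmHg (got {papp})")
    return sv / papp


# exact integer ratios to the Wood-unit pivot: unit = wood * factor
_TO_WOOD: dict[str, tuple[int, int]] = {
    "wood": (1, 1),
    "dyn": (1, 80),  # 1 dyn·s·cm⁻⁵ = 1/80 Wood
    "mpa": (1, 8),  # 1 MPa·s/m³ = 1/8 Wood
}


def convert_resistance(value, from_unit: str, to_unit: str):
    """Convert a vascular resistance between dyn·s·cm⁻⁵, Wood and MPa·s/m³.

    1 Wood unit = 80 dyne·s·cm⁻⁵ = 8 MPa·s/m³ (so dyn ↔ MPa is a factor of
    10).  The conversion is a single multiplication by an exact integer
    ratio: exact for ``int``/``Fraction`` inputs, correctly rounded for
    floats.
    """
    try:
        fn, fd = _TO_WOOD[from_unit]
        tn, td = _TO_WOOD[to_unit]
    except KeyError as exc:
        raise ValueError(
            f"unknown resistance unit {exc.args[0]!r}; expected 'dyn', 'wood' or 'mpa'"
        ) from None
    if isinstance(value, (int, float)) and value < 0:
        raise ValueError(f"resistance must be >= 0 (got {value})")
    # value[from] -> wood: * fn/fd ; wood -> value[to]: * td/tn
    return value * (fn * td) / (fd * tn)
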