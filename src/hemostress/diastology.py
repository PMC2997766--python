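"""Diastolic function metrics and classifications, left and right heart.

Left side: the mitral E/e' ratio (early inflow over early annular tissue
velocity) as a filling-pressure surrogate — septal E/e' < 8 implies normal
LV filling pressures, > 15 implies elevated; the regression estimate
PCWP = 1.24·(E/e') + 1.9 mmHg; and the diastolic mean filling rate,
stroke-volume index over cardiological diastolic time, which rises about
threefold from rest to peak in normals and far less in patients.

Right side: a rule-based grading of RV diastolic function from the
transtricuspid E/A ratio with auxiliary tissue-Doppler, deceleration-time,
hepatic-vein and pulmonary-artery flow criteria.
"""

from __future__ import annotations

import logging
from typing import Optional

log = logging.getLogger("hemostress")

#: septal E/e' below this implies normal LV filling pressures
E_EPRIME_NORMAL_LIMIT = 8.0
#: septal E/e' above this implies elevated LV filling pressures
E_EPRIME_ELEVATED_LIMIT = 15.0
#: mean PCWP above this (mmHg) is considered elevated
PCWP_ELEVATED_LIMIT = 12.0


def e_over_eprime(mitral_e: float, eprime: float) -> float:
    """Mitral E/e' ratio (both velocities in cm/s; result dimensionless)."""
    if eprime <= 0:
        raise ValueError(f"e' must be > 0 cm/s (got {eprime})")
    if mitral_e < 0:
        raise ValueError(f"mitral E must be >= 0 cm/s (got {mitral_e})")
    return mitral_e / eprime


def e_over_eprime_panel(
    mitral_e: float,
    eprime_septal: Optional[float] = None,
    eprime_lateral: Optional[float] = None,
) -> tuple[Optional[float], Optional[float]]:
    """(septal E/e', averaged E/e') from whichever annular velocities exist.

    The averaged ratio uses the mean of septal and lateral e' and is only
    defined when both are present; classification always uses the septal
    ratio.
    """
    septal = e_over_eprime(mitral_e, eprime_septal) if eprime_septal else None
    averaged = None
    if eprime_septal and eprime_lateral:
        averaged = e_over_eprime(mitral_e, (eprime_septal + eprime_lateral) / 2.0)
    return septal, averaged


def classify_filling_pressure(septal_ratio: float) -> str:
    """LV filling-pressure class from the septal E/e' ratio.

    < 8 -> ``normal``; > 15 -> ``elevated``; the 8-15 band is
    ``indeterminate`` (no outer class applies).
    """
    if septal_ratio < E_EPRIME_NORMAL_LIMIT:
        return "normal"
    if septal_ratio > E_EPRIME_ELEVATED_LIMIT:
        return "elevated"
    return "indeterminate"


def estimate_pcwp(e_over_eprime_ratio: float) -> float:
    """Pulmonary capillary wedge pressure estimate: 1.24·(E/e') + 1.9 mmHg.

    Values above 12 mmHg are considered elevated filling pressure.
    """
    if e_over_eprime_ratio < 0:
        raise ValueError(f"E/e' must be >= 0 (got {e_over_eprime_ratio})")
    return 1.24 * e_over_eprime_ratio + 1.9


def diastolic_mean_filling_rate(svi: float, diastolic_time: float) -> float:
    """Diastolic mean filling rate = (SVI / diastolic time [ms]) * 1000.

    SVI in mL/m², cardiological diastolic time in ms; result in mL/m²/s.
    Mitral filling volume is taken as equivalent to the stroke-volume
    index; the cardiological diastolic time (second to first heart sound)
    slightly overestimates the true filling time, an approximation that is
    systematic across stages.
    """
    if diastolic_time <= 0:
        raise ValueError(f"diastolic time must be > 0 ms (got {diastolic_time})")
    if svi <= 0:
        raise ValueError(f"stroke volume index must be > 0 mL/m² (got {svi})")
    return svi / diastolic_time * 1000.0


def ds_ratio_flag(ds_ratio: float) -> bool:
    """True when the diastolic/systolic time ratio is abnormal (<= 1).

    Normal diastole outlasts systole (ratio > 1); reversal may compromise
    cardiac filling and coronary perfusion time.
    """
    if ds_ratio <= 0:
        raise ValueError(f"D/S time ratio must be > 0 (got {ds_ratio})")
    return ds_ratio <= 1.0


def rv_diastolic_grade(
    tricuspid_e_a: float,
    tricuspid_e_eprime: Optional[float] = None,
    decel_time: Optional[float] = None,
    hepatic_diastolic_predominance: Optional[bool] = None,
    pa_late_antegrade_flow: Optional[bool] = None,
) -> str:
    """Grade RV diastolic function from transtricuspid Doppler criteria.

    Decision rule, applied in order on the tricuspid E/A ratio:

    * E/A < 0.8 -> ``impaired_relaxation``;
    * 0.8 <= E/A <= 2.1 with tricuspid E/E' > 6 or diastolic flow
      predominance in the hepatic veins -> ``pseudonormal``;
    * E/A > 2.1 with deceleration time < 120 ms -> ``restrictive``.

    Late diastolic antegrade flow in the pulmonary artery by itself also
    grades ``restrictive``.  When the auxiliary datum needed by the matched
    E/A band is absent (or present but non-diagnostic with the alternative
    criteria unknown), the grade is ``indeterminate`` rather than normal.
    """
    if tricuspid_e_a <= 0:
        raise ValueError(f"tricuspid E/A must be > 0 (got {tricuspid_e_a})")
    if tricuspid_e_a < 0.8:
        return "impaired_relaxation"
    if tricuspid_e_a <= 2.1:
        if (tricuspid_e_eprime is not None and tricuspid_e_eprime > 6.0) or (
            hepatic_diastolic_predominance is True
        ):
            return "pseudonormal"
        if pa_late_antegrade_flow is True:
            return "restrictive"
        return "indeterminate"
    # E/A > 2.1
    if decel_time is not None and decel_time < 120.0:
        return "restrictive"
    if pa_late_antegrade_flow is True:
        return "restrictive"
    return "indeterminate"
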