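"""Left-heart and systemic arterial calculations.

The core of noninvasive stress hemodynamics: from cuff pressures and
echo-measured ventricular volumes, derive stroke volume and cardiac output,
mean arterial and end-systolic pressures, ventricular and arterial elastance
indices, ventricular-arterial coupling, systemic vascular resistance and
total arterial compliance.

End-systolic pressure is approximated as 0.9 x systolic cuff pressure, the
most reliable noninvasive surrogate of LV end-systolic pressure.  Elastances
are indexed by dividing the volume term by body surface area (pressure over
volume *index*); this is the convention that reproduces the published
normal averages (ventricular elastance index 4.5 -> 14.5 mmHg/mL/m2 and
arterial elastance index 2.3 -> 3.2 mmHg/mL/m2 from rest to peak exercise).
The alternative reading — dividing the whole elastance by BSA — is exposed
through the ``indexing`` argument.

Ventricular-arterial coupling is computed as SV/ESV: the pressure terms in
E_es/E_a cancel, so coupling is independent of blood-pressure measurement.
"""

from __future__ import annotations

import math

#: ratio of end-systolic pressure to systolic cuff pressure
ESP_OVER_SBP = 0.9


def body_surface_area(weight: float, height: float, method: str = "mosteller") -> float:
    """Body surface area in m² from weight (kg) and height (cm).

    ``mosteller``: sqrt(weight * height / 3600) — the default.
    ``power``: the power-product form weight^0.5378 * height^0.3964.
    """
    if weight <= 0 or height <= 0:
        raise ValueError(f"weight and height must be > 0 (got {weight} kg, {height} cm)")
    if method == "mosteller":
        return math.sqrt(weight * height / 3600.0)
    if method == "power":
        return weight**0.5378 * height**0.3964
    raise ValueError(f"unknown BSA method: {method!r}")


def stroke_volume(edv: float, esv: float, bsa: float) -> tuple[float, float]:
    """Stroke volume (mL) and stroke volume index (mL/m²).

    SV = EDV - ESV; SVI = SV/BSA.  Normal SV is 60-100 mL/beat.
    """
    if esv <= 0 or edv <= esv:
        raise ValueError(f"volumes must satisfy EDV > ESV > 0 (got {edv}, {esv})")
    if bsa <= 0:
        raise ValueError(f"BSA must be > 0 (got {bsa})")
    sv = edv - esv
    return sv, sv / bsa


def cardiac_output(heart_rate: float, sv: float, bsa: float) -> tuple[float, float]:
    """Cardiac output (L/min) and cardiac index (L/min/m²).

    CO = HR * SV / 1000; CI = CO/BSA.  Normal CO ~4-6 L/min,
    CI ~2.5-3.6 L/min/m².
    """
    if heart_rate <= 0 or sv <= 0 or bsa <= 0:
        raise ValueError("heart rate, stroke volume and BSA must be > 0")
    co = heart_rate * sv / 1000.0
    return co, co / bsa


def mean_arterial_pressure(sbp: float, dbp: float) -> float:
    """MAP = (SBP - DBP)/3 + DBP, mmHg.  Normal 70-100 mmHg."""
    if sbp <= dbp:
        raise ValueError(f"SBP must exceed DBP (got {sbp}/{dbp})")
    return (sbp - dbp) / 3.0 + dbp


def pulse_pressure(sbp: float, dbp: float) -> float:
    """PP = SBP - DBP, mmHg."""
    if sbp <= dbp:
        raise ValueError(f"SBP must exceed DBP (got {sbp}/{dbp})")
    return sbp - dbp


def end_systolic_pressure(sbp: float) -> float:
    """LV end-systolic pressure surrogate: 0.9 * SBP, mmHg."""
    if sbp <= 0:
        raise ValueError(f"SBP must be > 0 (got {sbp})")
    return ESP_OVER_SBP * sbp


def lv_elastance_index(
    pressure: float, esv: float, bsa: float, indexing: str = "volume_index"
) -> float:
    """Ventricular (end-systolic) elastance index, mmHg/mL/m².

    Default ``volume_index`` convention: pressure / (ESV/BSA) — end-systolic
    pressure over end-systolic volume index.  ``per_bsa`` divides the raw
    elastance by BSA instead: (pressure/ESV)/BSA.  The pressure argument is
    normally the 0.9*SBP end-systolic estimate; raw SBP may be passed for
    the cuff-pressure contractility index used in force-frequency analysis.
    """
    if esv <= 0 or bsa <= 0:
        raise ValueError("ESV and BSA must be > 0")
    if indexing == "volume_index":
        return pressure / (esv / bsa)
    if indexing == "per_bsa":
        return (pressure / esv) / bsa
    raise ValueError(f"unknown elastance indexing: {indexing!r}")


def arterial_elastance_index(
    esp: float, sv: float, bsa: float, indexing: str = "volume_index"
) -> float:
    """Effective arterial elastance index, mmHg/mL/m².

    ESP over stroke-volume index (default), same indexing conventions as
    :func:`lv_elastance_index`.
    """
    if sv <= 0 or bsa <= 0:
        raise ValueError("SV and BSA must be > 0")
    if indexing == "volume_index":
        return esp / (sv / bsa)
    if indexing == "per_bsa":
        return (esp / sv) / bsa
    raise ValueError(f"unknown elastance indexing: {indexing!r}")


def ventricular_arterial_coupling(sv: float, esv: float) -> float:
    """Ventricular-arterial coupling = SV/ESV (dimensionless).

    Algebraically equal to E_es/E_a for any common pressure, hence
    independent of the blood-pressure measurement.  Published averages:
    ~1.9 at rest and ~4.5 at peak exercise in normals; ~0.4-0.5 in
    dilated cardiomyopathy.
    """
    if esv <= 0:
        raise ValueError(f"ESV must be > 0 (got {esv})")
    return sv / esv


def systemic_vascular_resistance(map_: float, co: float) -> float:
    """SVR = 80*(MAP - 5)/CO in dyne·s·cm⁻⁵.

    The constant 5 mmHg approximates right atrial pressure.  Normal
    900-1300 dyne·s·cm⁻⁵.
    """
    if co <= 0:
        raise ValueError(f"cardiac output must be > 0 (got {co})")
    return 80.0 * (map_ - 5.0) / co


def systemic_arterial_compliance(sv: float, pp: float) -> float:
    """Total systemic arterial compliance = SV/PP, mL/mmHg."""
    if pp <= 0:
        raise ValueError(f"pulse pressure must be > 0 (got {pp})")
    return sv / pp
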