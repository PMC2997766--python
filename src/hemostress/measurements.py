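"""Case data model, validation and file I/O for rest/stress hemodynamic cases.

A training case is a subject (age, height, weight) plus an ordered series of
stages — rest first, peak last, optional intermediate steps — each carrying
the raw measurement set of a stress-echo session: heart rate and cuff blood
pressures, left-ventricular end-diastolic and end-systolic volumes, mitral
inflow and annular tissue-Doppler velocities, cardiological diastolic time,
diastolic/systolic time ratio, and the right-heart Doppler set (tricuspid
regurgitation velocity, inferior vena cava diameter and respiratory collapse,
pulmonary regurgitation velocities, RVOT time-velocity integral).

Units are fixed per field exactly as they are acquired at the bedside:
cm/s for mitral velocities, m/s for tricuspid/pulmonary regurgitant jets,
mL for volumes, mmHg for pressures, ms for times, cm for IVC diameter and
RVOT TVI.  The only canonicalization the loader performs is on the IVC
respiratory collapse, which is stored as a fraction in [0, 1]: a value > 1
is interpreted as a percentage and divided by 100.

Validation is report-only and pure: an "error" issue blocks computation of
the dependent derived parameters only, never the whole case.
"""

from __future__ import annotations

import csv
import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

log = logging.getLogger("hemostress")

MANDATORY_STAGE_FIELDS = ("stage_label", "heart_rate", "sbp", "dbp", "edv", "esv")

OPTIONAL_STAGE_FIELDS = (
    "mitral_e",
    "mitral_eprime_septal",
    "mitral_eprime_lateral",
    "diastolic_time",
    "ds_ratio",
    "tr_velocity",
    "ivc_diameter",
    "ivc_collapse",
    "pr_end_diastolic_velocity",
    "pr_peak_velocity",
    "rvot_tvi",
)

STAGE_FIELDS = MANDATORY_STAGE_FIELDS + OPTIONAL_STAGE_FIELDS

SUBJECT_FIELDS = ("age", "height", "weight")


class CaseFileError(ValueError):
    """Malformed case file (unparsable content, unknown or missing fields)."""


class SchemaError(CaseFileError):
    """A mandatory field is absent or structurally wrong."""


@dataclass(frozen=True)
class SubjectProfile:
    """Biometrics of the subject under study.

    height in cm, weight in kg, age in years (optional).
    """

    height: float
    weight: float
    age: Optional[float] = None


@dataclass(frozen=True)
class StageRecord:
    """One stage's raw measurements.

    ``stage_label`` is ``"rest"``, ``"peak"`` or an intermediate label
    (e.g. ``"intermediate1"``).  Optional Doppler/sensor fields that were
    not acquired stay ``None``; they are never imputed and simply disable
    the derived parameters that depend on them.
    """

    stage_label: str
    heart_rate: float  # bpm
    sbp: float  # mmHg
    dbp: float  # mmHg
    edv: float  # mL
    esv: float  # mL
    mitral_e: Optional[float] = None  # cm/s
    mitral_eprime_septal: Optional[float] = None  # cm/s
    mitral_eprime_lateral: Optional[float] = None  # cm/s
    diastolic_time: Optional[float] = None  # ms, cardiological diastole
    ds_ratio: Optional[float] = None  # diastolic/systolic time ratio
    tr_velocity: Optional[float] = None  # m/s
    ivc_diameter: Optional[float] = None  # cm
    ivc_collapse: Optional[float] = None  # fraction 0-1
    pr_end_diastolic_velocity: Optional[float] = None  # m/s
    pr_peak_velocity: Optional[float] = None  # m/s
    rvot_tvi: Optional[float] = None  # cm


@dataclass(frozen=True)
class CaseSeries:
    """A subject plus its ordered stage series (first = rest, last = peak)."""

    subject: SubjectProfile
    stages: tuple[StageRecord, ...]

    @property
    def rest(self) -> StageRecord:
        return self.stages[0]

    @property
    def peak(self) -> StageRecord:
        return self.stages[-1]


@dataclass(frozen=True)
class Issue:
    field: str
    severity: str  # "error" | "warning"
    message: str


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_case`; report-only, never raises."""

    issues: list[Issue] = field(default_factory=list)

    def errors(self) -> list[Issue]:
        return [i for i in self.issues if i.severity == "error"]

    def warnings(self) -> list[Issue]:
        return [i for i in self.issues if i.severity == "warning"]

    @property
    def ok(self) -> bool:
        return not self.errors()


# ---------------------------------------------------------------------------
# canonicalization helpers


def _canonical_collapse(value: Optional[float]) -> Optional[float]:
    """IVC collapse is stored as a fraction; values > 1 are read as percent."""
    if value is None:
        return None
    if value > 1.0:
        return value / 100.0
    return value


def _to_number(raw: object, name: str, where: str) -> Optional[float]:
    if raw is None or raw == "":
        return None
    if isinstance(raw, bool):
        raise CaseFileError(f"{where}: field '{name}' must be numeric, got {raw!r}")
    try:
        return float(raw)
    except (TypeError, ValueError) as exc:
        raise CaseFileError(
            f"{where}: field '{name}' must be numeric, got {raw!r}"
        ) from exc


def _build_stage(raw: dict, where: str) -> StageRecord:
    unknown = set(raw) - set(STAGE_FIELDS)
    if unknown:
        raise CaseFileError(f"{where}: unknown field(s) {sorted(unknown)}")
    missing = [f for f in MANDATORY_STAGE_FIELDS if f != "stage_label" and raw.get(f) in (None, "")]
    if missing:
        raise SchemaError(f"{where}: missing mandatory field(s) {missing}")
    label = raw.get("stage_label")
    if not label:
        raise SchemaError(f"{where}: missing mandatory field(s) ['stage_label']")
    kwargs: dict[str, object] = {"stage_label": str(label)}
    for name in STAGE_FIELDS[1:]:
        kwargs[name] = _to_number(raw.get(name), name, where)
    kwargs["ivc_collapse"] = _canonical_collapse(kwargs["ivc_collapse"])  # type: ignore[arg-type]
    return StageRecord(**kwargs)  # type: ignore[arg-type]


def _build_subject(raw: dict, where: str) -> SubjectProfile:
    unknown = set(raw) - set(SUBJECT_FIELDS)
    if unknown:
        raise CaseFileError(f"{where}: unknown subject field(s) {sorted(unknown)}")
    missing = [f for f in ("height", "weight") if raw.get(f) in (None, "")]
    if missing:
        raise SchemaError(f"{where}: missing mandatory subject field(s) {missing}")
    return SubjectProfile(
        height=_to_number(raw["height"], "height", where),  # type: ignore[arg-type]
        weight=_to_number(raw["weight"], "weight", where),  # type: ignore[arg-type]
        age=_to_number(raw.get("age"), "age", where),
    )


# ---------------------------------------------------------------------------
# I/O


def load_case(path: str | Path, format: Optional[str] = None) -> CaseSeries:
    """Load a training case from a JSON or CSV file.

    JSON schema: ``{"subject": {"age", "height", "weight"},
    "stages": [{"stage_label": "rest", ...}, ...]}`` with stage field names
    exactly as in :class:`StageRecord`.

    CSV dialect: one row per stage, header row of field names; the subject
    columns (``age``, ``height``, ``weight``) are repeated on every row and
    must agree.  UTF-8, comma separator, ``.`` decimal.

    Unknown fields are rejected; missing optional fields stay absent.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower() or "json"
    text = path.read_text(encoding="utf-8")
    if format == "json":
        return _case_from_json(text, str(path))
    if format == "csv":
        return _case_from_csv(text, str(path))
    raise CaseFileError(f"unsupported case-file format: {format!r}")


def _case_from_json(text: str, where: str) -> CaseSeries:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise CaseFileError(f"{where}: invalid JSON at line {exc.lineno}: {exc.msg}") from exc
    if not isinstance(doc, dict) or set(doc) - {"subject", "stages"}:
        raise CaseFileError(f"{where}: top level must be {{'subject', 'stages'}}")
    if "subject" not in doc or "stages" not in doc:
        raise SchemaError(f"{where}: top level must contain 'subject' and 'stages'")
    subject = _build_subject(doc["subject"], f"{where}:subject")
    stages = tuple(
        _build_stage(s, f"{where}:stages[{i}]") for i, s in enumerate(doc["stages"])
    )
    return CaseSeries(subject=subject, stages=stages)


def _case_from_csv(text: str, where: str) -> CaseSeries:
    reader = csv.DictReader(io.StringIO(text))
    if reader.fieldnames is None:
        raise CaseFileError(f"{where}: empty CSV")
    allowed = set(STAGE_FIELDS) | set(SUBJECT_FIELDS)
    unknown = set(reader.fieldnames) - allowed
    if unknown:
        raise CaseFileError(f"{where}: unknown CSV column(s) {sorted(unknown)}")
    stages: list[StageRecord] = []
    subject: Optional[SubjectProfile] = None
    for lineno, row in enumerate(reader, start=2):
        stage_raw = {k: v for k, v in row.items() if k in STAGE_FIELDS and v not in (None, "")}
        subj_raw = {k: v for k, v in row.items() if k in SUBJECT_FIELDS and v not in (None, "")}
        here = f"{where}:line {lineno}"
        row_subject = _build_subject(subj_raw, here)
        if subject is None:
            subject = row_subject
        elif row_subject != subject:
            raise CaseFileError(f"{here}: subject columns differ between rows")
        stages.append(_build_stage(stage_raw, here))
    if subject is None:
        raise SchemaError(f"{where}: CSV contains no stage rows")
    return CaseSeries(subject=subject, stages=tuple(stages))


def save_case(case: CaseSeries, path: str | Path, format: Optional[str] = None) -> Path:
    """Write a case back to disk; ``load_case(save_case(c)) == c``."""
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower() or "json"
    if format == "json":
        doc = {
            "subject": _compact(
                {f: getattr(case.subject, f) for f in SUBJECT_FIELDS}
            ),
            "stages": [
                _compact({f: getattr(s, f) for f in STAGE_FIELDS}) for s in case.stages
            ],
        }
        path.write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")
    elif format == "csv":
        cols = list(SUBJECT_FIELDS) + list(STAGE_FIELDS)
        buf = io.StringIO()
        writer = csv.DictWriter(buf, fieldnames=cols, lineterminator="\n")
        writer.writeheader()
        for s in case.stages:
            row = {f: getattr(case.subject, f) for f in SUBJECT_FIELDS}
            row.update({f: getattr(s, f) for f in STAGE_FIELDS})
            writer.writerow({k: ("" if v is None else v) for k, v in row.items()})
        path.write_text(buf.getvalue(), encoding="utf-8")
    else:
        raise CaseFileError(f"unsupported case-file format: {format!r}")
    return path


def _compact(d: dict) -> dict:
    return {k: v for k, v in d.items() if v is not None}


# ---------------------------------------------------------------------------
# validation

#: TR velocity above which pulmonary-pressure follow-up is advised (m/s);
#: normal rest values are < 2.8-2.9 m/s.
TR_VELOCITY_NORMAL_CUTOFF = 2.9


def validate_case(case: CaseSeries) -> ValidationReport:
    """Check physiologic and structural plausibility; report-only.

    Errors mark measurements that cannot feed a formula (non-positive heart
    rate, DBP >= SBP, ESV >= EDV, negative velocities, collapse outside
    [0, 1]); warnings mark out-of-range but usable physiology (TR velocity
    above the normal cutoff, diastolic/systolic ratio below 1, peak heart
    rate not above rest).
    """
    report = ValidationReport()
    add = report.issues.append
    subj = case.subject
    if subj.height <= 0:
        add(Issue("height", "error", f"height must be > 0 cm (got {subj.height})"))
    if subj.weight <= 0:
        add(Issue("weight", "error", f"weight must be > 0 kg (got {subj.weight})"))
    if subj.age is not None and subj.age < 0:
        add(Issue("age", "error", f"age must be >= 0 years (got {subj.age})"))
    if len(case.stages) < 2:
        add(Issue("stages", "error", "a case needs at least a rest and a peak stage"))
    for s in case.stages:
        where = s.stage_label
        if s.heart_rate <= 0:
            add(Issue(f"{where}.heart_rate", "error", "heart rate must be > 0 bpm"))
        if s.dbp <= 0 or s.sbp <= s.dbp:
            add(
                Issue(
                    f"{where}.sbp/dbp",
                    "error",
                    f"pressures must satisfy SBP > DBP > 0 (got {s.sbp}/{s.dbp})",
                )
            )
        if s.esv <= 0 or s.edv <= s.esv:
            add(
                Issue(
                    f"{where}.edv/esv",
                    "error",
                    f"volumes must satisfy EDV > ESV > 0 (got EDV {s.edv}, ESV {s.esv}); "
                    "stroke volume not computable",
                )
            )
        for name in (
            "mitral_e",
            "mitral_eprime_septal",
            "mitral_eprime_lateral",
            "tr_velocity",
            "pr_end_diastolic_velocity",
            "pr_peak_velocity",
        ):
            v = getattr(s, name)
            if v is not None and v < 0:
                add(Issue(f"{where}.{name}", "error", "velocities must be >= 0"))
        if s.ivc_collapse is not None and not (0.0 <= s.ivc_collapse <= 1.0):
            add(
                Issue(
                    f"{where}.ivc_collapse",
                    "error",
                    f"IVC collapse must be a fraction in [0, 1] (got {s.ivc_collapse})",
                )
            )
        if s.tr_velocity is not None and s.tr_velocity > TR_VELOCITY_NORMAL_CUTOFF:
            add(
                Issue(
                    f"{where}.tr_velocity",
                    "warning",
                    f"TR velocity {s.tr_velocity} m/s above normal cutoff "
                    f"({TR_VELOCITY_NORMAL_CUTOFF} m/s)",
                )
            )
        if s.ds_ratio is not None and s.ds_ratio < 1.0:
            add(
                Issue(
                    f"{where}.ds_ratio",
                    "warning",
                    f"diastolic/systolic time ratio {s.ds_ratio} below 1; "
                    "reversal may compromise cardiac filling",
                )
            )
    if len(case.stages) >= 2 and case.peak.heart_rate <= case.rest.heart_rate:
        add(
            Issue(
                "peak.heart_rate",
                "warning",
                f"peak heart rate ({case.peak.heart_rate}) not above rest "
                f"({case.rest.heart_rate}); check stage ordering",
            )
        )
    return report
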