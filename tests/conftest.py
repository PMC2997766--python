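import hypothesis
import pytest

from hemostress import CaseSeries, StageRecord, SubjectProfile

hypothesis.settings.register_profile(
    "suite", derandomize=True, max_examples=200, deadline=None
)
hypothesis.settings.load_profile("suite")


@pytest.fixture
def subject():
    return SubjectProfile(height=175.0, weight=70.0, age=45.0)


@pytest.fixture
def full_stage():
    """A complete rest-stage record (every optional field acquired)."""
    return StageRecord(
        stage_label="rest",
        heart_rate=70.0,
        sbp=120.0,
        dbp=80.0,
        edv=120.0,
        esv=50.0,
        mitral_e=70.0,
        mitral_eprime_septal=12.0,
        mitral_eprime_lateral=14.0,
        diastolic_time=480.0,
        ds_ratio=1.3,
        tr_velocity=2.3,
        ivc_diameter=1.8,
        ivc_collapse=0.6,
        pr_end_diastolic_velocity=0.7,
        pr_peak_velocity=1.4,
        rvot_tvi=18.0,
    )


@pytest.fixture
def minimal_case(subject):
    """Two-stage case with mandatory fields only."""
    rest = StageRecord(stage_label="rest", heart_rate=70, sbp=120, dbp=80, edv=120, esv=50)
    peak = StageRecord(stage_label="peak", heart_rate=150, sbp=170, dbp=85, edv=125, esv=35)
    return CaseSeries(subject=subject, stages=(rest, peak))
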