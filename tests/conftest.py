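from datetime import datetime, timezone

import pytest

from ncdkit.model import DINMetadata, PatientRecord, Period, new_document
from ncdkit.synth import GeneratorParams, generate_session
from ncdkit.terminology import din_required_elements


@pytest.fixture
def period():
    return Period(
        start=datetime(2024, 1, 1, tzinfo=timezone.utc),
        end=datetime(2024, 1, 31, tzinfo=timezone.utc),
    )


@pytest.fixture
def level1_din():
    return DINMetadata(
        declared_level=1,
        elements=tuple((name, f"value-{name}") for name in din_required_elements(1)),
    )


@pytest.fixture
def patient():
    return PatientRecord(resource_id="pat-1", pseudonym="pseudonym-1")


@pytest.fixture
def minimal_doc(patient, period, level1_din):
    return new_document(
        subject=patient,
        period=period,
        export_date=datetime(2024, 2, 1, tzinfo=timezone.utc),
        din=level1_din,
    )


@pytest.fixture
def g8_doc():
    return generate_session("G8", GeneratorParams(seed=1, n_entries=5))
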