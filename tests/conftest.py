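import numpy as np
import pytest

from targetfish.activity import ActivityRecord, FilterCriteria
from targetfish.similarity import FP_LENGTH, Fingerprint


def make_fp(on_indices) -> Fingerprint:
    bits = np.zeros(FP_LENGTH, dtype=np.uint8)
    bits[list(on_indices)] = 1
    return Fingerprint(bits)


def make_record(**overrides) -> ActivityRecord:
    """A fully qualifying measurement unless a field is overridden."""
    base = dict(
        molecule_id="M1",
        target_id="T1",
        target_type="SINGLE PROTEIN",
        activity_type="IC50",
        relation="=",
        value=500.0,
        units="nM",
        assay_type="B",
        confidence=9,
    )
    base.update(overrides)
    return ActivityRecord(**base)


@pytest.fixture
def criteria_10um() -> FilterCriteria:
    return FilterCriteria(threshold_nM=10_000.0, min_ligands=1)


@pytest.fixture
def criteria_1um() -> FilterCriteria:
    return FilterCriteria(threshold_nM=1_000.0, min_ligands=1)


@pytest.fixture
def toy_six_rows() -> list[ActivityRecord]:
    """Six measurements, each probing one filter dimension.

    Row 1 qualifies at any threshold >= 500 nM; row 3 only at 10 uM;
    rows 2 and 4-6 each fail exactly one categorical filter.
    """
    return [
        make_record(molecule_id="M1", target_id="T1",
                    activity_type="IC50", relation="=", value=500.0),
        make_record(molecule_id="M2", target_id="T2",
                    activity_type="IC50", relation=">", value=500.0),
        make_record(molecule_id="M3", target_id="T3",
                    activity_type="Ki", relation="=", value=5000.0),
        make_record(molecule_id="M4", target_id="T4",
                    activity_type="Inhibition", value=500.0),
        make_record(molecule_id="M5", target_id="T5",
                    confidence=8, value=500.0),
        make_record(molecule_id="M6", target_id="T6",
                    units="ug.mL-1", value=500.0),
    ]


def random_fingerprints(rng: np.random.Generator, n: int, prefix: str = "M",
                        on_rate: float = 0.3) -> dict[str, Fingerprint]:
    return {
        f"{prefix}{i:03d}": Fingerprint(
            (rng.random(FP_LENGTH) < on_rate).astype(np.uint8)
        )
        for i in range(n)
    }
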