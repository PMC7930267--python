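import numpy as np
import pandas as pd
import pytest

from metnorm.io_formats import ProbeRecord, SampleCounts
from metnorm.simulate import SimulationConfig, generate_cohort


def fractions_from_counts(counts: dict, total: int) -> dict:
    return {k: v / total for k, v in counts.items()}


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A scaled-down cohort for fast unit tests (same structure as default)."""
    counts = {
        "null": 20,
        "enriched_only": 3,
        "depleted_only": 3,
        "upregulated": 4,
        "downregulated": 6,
        "low_expression": 10,
        "healthy_low": 8,
    }
    return SimulationConfig(
        n_pairs=6,
        n_endogenous=sum(counts.values()) + 4,
        n_absent_healthy=4,
        n_housekeeping=8,
        class_fractions=fractions_from_counts(counts, sum(counts.values())),
        n_patients=24,
        n_node_positive=14,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


def make_sample(sample_id, counts_by_class, patient_id=None, tissue=None):
    """Build a SampleCounts from {code_class: {name: count}}."""
    probes = []
    for code_class, mapping in counts_by_class.items():
        for name, count in mapping.items():
            probes.append(ProbeRecord(name, code_class, "", int(count)))
    return SampleCounts(
        sample_id=sample_id, probes=probes, patient_id=patient_id, tissue=tissue
    )


def matrix_from_dict(data, code_class, tissues=None):
    """Assemble a CountMatrix directly from plain dicts (tests only)."""
    from metnorm.nanostring import CountMatrix

    values = pd.DataFrame(data, dtype=float)
    classes = pd.Series(code_class).loc[values.index]
    sample_ids = list(values.columns)
    annot = pd.DataFrame(
        {
            "patient_id": [s.split("_")[0] for s in sample_ids],
            "tissue": tissues if tissues else [s.split("_")[-1] for s in sample_ids],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return CountMatrix(values=values, code_class=classes, samples=annot, stage="raw")
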