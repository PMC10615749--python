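import numpy as np
import pytest

from termref import (
    SynthConfig,
    classify_cohort,
    derive_bands,
    estimate_norms,
    generate_cohorts,
    manual_bands,
    records_to_frame,
)
from termref.reference_norms import COMPOSITES


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    """A quick-to-generate study: 6 centers, 30 index children each."""
    return SynthConfig(n_centers=6, index_per_center=30, seed=123)


@pytest.fixture(scope="session")
def small_records(small_config):
    return generate_cohorts(small_config)


@pytest.fixture(scope="session")
def small_frame(small_records):
    return records_to_frame(small_records)


@pytest.fixture(scope="session")
def small_classifications(small_records):
    """Manual and reference classifications of the small index cohort."""
    ref = [r for r in small_records if r.cohort == "reference"]
    norms = {
        c: estimate_norms([getattr(r, c) for r in ref], c) for c in COMPOSITES
    }
    bands = {
        "manual": {c: manual_bands(c) for c in COMPOSITES},
        "reference": {c: derive_bands(norms[c]) for c in COMPOSITES},
    }
    index = records_to_frame([r for r in small_records if r.cohort == "index"])
    return {
        src: classify_cohort(index, bands[src], src)
        for src in ("manual", "reference")
    }


@pytest.fixture
def rng():
    return np.random.default_rng(0)
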