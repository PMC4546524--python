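import numpy as np
import pytest

from lsrcnv import (
    CohortSpec,
    build_profiles,
    filter_segments,
    generate_cohort,
)


@pytest.fixture(scope="session")
def cohort():
    """A study-design-sized cohort (35/55/53) shared across tests."""
    spec = CohortSpec(seed=11)
    segments, records = generate_cohort(spec)
    filtered = filter_segments(segments)
    profiles = build_profiles(filtered)
    return {
        "spec": spec,
        "segments": segments,
        "filtered": filtered,
        "profiles": profiles,
        "records": records,
    }


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort for the heavier protocol-level tests."""
    spec = CohortSpec(
        n_nonrecurrent=18,
        n_recurrent_fast=18,
        n_recurrent_slow=18,
        mean_fragments_per_sample=60,
        seed=23,
    )
    segments, records = generate_cohort(spec)
    profiles = build_profiles(filter_segments(segments))
    return {"spec": spec, "profiles": profiles, "records": records}


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
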