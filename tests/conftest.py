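import numpy as np
import pytest

from modscreen import fixtures
from modscreen.cohort_io import GenotypeCounts, GenotypeMatrix, MISSING


@pytest.fixture(scope="session")
def case_only_fixture():
    return fixtures.load_case_only_strata()


@pytest.fixture(scope="session")
def case_only_strata():
    return fixtures.case_only_strata()


@pytest.fixture(scope="session")
def candidate_fixture():
    return fixtures.load_candidate_variants()


@pytest.fixture(scope="session")
def candidate_records():
    return fixtures.candidate_variant_records()


@pytest.fixture(scope="session")
def validation_fixture():
    return fixtures.load_validation_counts()


@pytest.fixture(scope="session")
def validation_counts():
    return fixtures.validation_counts()


@pytest.fixture
def tiny_matrix():
    """Four samples, one variant, one of each call incl. missing."""
    calls = np.array([[0], [1], [2], [MISSING]], dtype=np.int8)
    return GenotypeMatrix(
        sample_ids=["s1", "s2", "s3", "s4"],
        variant_ids=["v1"],
        calls=calls,
        group_of={s: "g" for s in ("s1", "s2", "s3", "s4")},
    )


def genotype_counts(hom_ref, het, hom_alt):
    return GenotypeCounts(hom_ref=hom_ref, het=het, hom_alt=hom_alt)
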