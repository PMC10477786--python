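from importlib import resources

import pytest

from fshdkit.fixtures import (
    reference_cohort,
    reference_cohort_tsv,
    reference_constraints,
    reference_pedigrees,
    reference_variants,
)


@pytest.fixture(scope="session")
def ref_cohort():
    return reference_cohort()


@pytest.fixture(scope="session")
def ref_variants():
    return reference_variants()


@pytest.fixture(scope="session")
def ref_constraints():
    return reference_constraints()


@pytest.fixture(scope="session")
def ref_pedigrees():
    return {p.family_id: p for p in reference_pedigrees()}


@pytest.fixture
def fixture_dir(tmp_path):
    """Reference input files materialised on disk for path-based APIs."""
    (tmp_path / "cohort.tsv").write_text(reference_cohort_tsv())
    for name in ("reference_variants.tsv", "gene_constraints.tsv", "reference_families.ped"):
        data = resources.files("fshdkit.data").joinpath(name).read_text()
        (tmp_path / name).write_text(data)
    return tmp_path
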