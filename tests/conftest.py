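import pytest

from hervotrace import fixtures as fx
from hervotrace import build_database, load_peptides, load_reference, trace_peptides
from hervotrace.quantify import SampleManifest


@pytest.fixture(scope="session")
def cohort(tmp_path_factory):
    """The default synthetic cohort with planted ground truth (seed 1)."""
    out = tmp_path_factory.mktemp("cohort")
    return fx.make_fixture_cohort(out, seed=1)


@pytest.fixture(scope="session")
def reference_db(cohort):
    regions = load_reference(cohort["region_fa"], cohort["region_bed"])
    return build_database(regions)


@pytest.fixture(scope="session")
def fragments(cohort, reference_db):
    peptides = load_peptides(cohort["peptides_fa"])
    return trace_peptides(peptides, reference_db)


@pytest.fixture(scope="session")
def manifest(cohort):
    return SampleManifest.from_tsv(cohort["manifest"])
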