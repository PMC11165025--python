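import pytest
from hypothesis import HealthCheck, settings

from hlassoc.genotypes import Cohort, SampleGenotype, parse_allele
from hlassoc.simulate import study_fixture

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_cohort(rows, locus="B"):
    """rows: iterable of (sample_id, group, allele1, allele2) label strings."""
    samples = [
        SampleGenotype(sid, group, (parse_allele(a1), parse_allele(a2)))
        for sid, group, a1, a2 in rows
    ]
    return Cohort(samples, locus=locus)


@pytest.fixture(scope="session")
def fx():
    """The deterministic study fixture: (cohort, alignment, cds)."""
    return study_fixture()


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """The study fixture serialised to disk once per session."""
    from hlassoc.simulate import write_fixture

    outdir = tmp_path_factory.mktemp("fixture")
    write_fixture(outdir)
    return outdir
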