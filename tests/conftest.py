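import pytest
from hypothesis import HealthCheck, settings

from eboxscreen import pipeline, simulate

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_fixture():
    """Small two-chromosome genome with planted E-boxes, exons and decoys."""
    return simulate.make_genome(simulate.GenomeFixtureSpec(
        seed=5, n_chromosomes=2, chrom_length=30_000, n_eboxes_per_motif=4,
        fraction_exonic=0.15, n_offtarget_decoys=10))


@pytest.fixture(scope="session")
def design_result(toy_fixture):
    return pipeline.design_library(
        toy_fixture.genome, [s.interval for s in toy_fixture.sites],
        toy_fixture.exons,
        non_targeting=simulate.random_protospacers(8, seed=99),
        positive_controls=[("POS_1", simulate.random_protospacers(1, seed=100)[0])])
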