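import pytest

from cazymeta.io_formats import DomainHit
from cazymeta.pipeline import run_study
from cazymeta.simulate import generate, scenario_estuary


def mk_hit(
    gene_id="g1",
    family="GH13",
    hmm_length=100,
    hmm_from=1,
    hmm_to=100,
    ali_from=1,
    ali_to=100,
    i_evalue=1e-30,
    score=100.0,
    ec_numbers=frozenset(),
):
    return DomainHit(
        gene_id=gene_id,
        family=family,
        hmm_length=hmm_length,
        hmm_from=hmm_from,
        hmm_to=hmm_to,
        ali_from=ali_from,
        ali_to=ali_to,
        i_evalue=i_evalue,
        score=score,
        ec_numbers=ec_numbers,
    )


@pytest.fixture(scope="session")
def noise_free_study():
    """A small noise-free estuary community with its ground-truth ledger."""
    return generate(scenario_estuary(11, n_genomes_per_habitat=8, noise_free=True))


@pytest.fixture(scope="session")
def noise_free_result(noise_free_study):
    return run_study(noise_free_study)
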