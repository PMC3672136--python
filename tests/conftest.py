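import pytest

from specsort.spectral_counting import CountProfile
from specsort.synthetic_data import SyntheticConfig, generate_database


def make_profile(accession, hc=0, nsc=0, per_experiment=None, description=""):
    """CountProfile with counts placed in pseudo-experiment 1 per group."""
    prof = CountProfile(accession=accession, description=description)
    if per_experiment:
        prof.per_experiment.update(per_experiment)
    else:
        if hc:
            prof.per_experiment[(1, "HC")] = hc
        if nsc:
            prof.per_experiment[(1, "NSC")] = nsc
    return prof


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down design: fast to simulate, same structure as default."""
    return SyntheticConfig(
        n_proteins=60,
        n_HC_specific=5,
        n_NSC_specific=5,
        n_HC_enriched=5,
        n_NSC_enriched=5,
        psms_per_run=800,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_database(small_config):
    return generate_database(small_config)
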