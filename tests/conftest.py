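import pytest

from tmbkit.filters import builtin_profile
from tmbkit.simulate import SimConfig, simulate_cohort
from tmbkit.tmb import run_sample


@pytest.fixture(scope="session")
def ic_profile():
    return builtin_profile("IC")


@pytest.fixture(scope="session")
def fo_profile():
    return builtin_profile("FO")


@pytest.fixture(scope="session")
def default_cohort():
    """A mixed FFPE/frozen cohort under the generator's default conditions."""
    return simulate_cohort(SimConfig(seed=101, n_samples=24, samples_per_run=12))


@pytest.fixture(scope="session")
def clean_cohort():
    """Zero artifacts, zero germline leakage: filters should be inert
    beyond the class policy."""
    return simulate_cohort(
        SimConfig(
            seed=202, n_samples=12, samples_per_run=12,
            germline_leak_rate=0.0,
            ffpe_artifact_rate_high=0.0, ffpe_artifact_rate_low=0.0,
            recurrent_sites_per_run=0,
        )
    )


def score_cohort(cohort, profile):
    """Run the full cascade on every sample of a simulated cohort."""
    return [
        run_sample(recs, cohort.metas[sid], cohort.run_of(sid), profile)
        for sid, recs in cohort.variants.items()
    ]
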