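import pytest

from rscore import CohortConfig, generate_cohort, match_calls


@pytest.fixture(scope="session")
def default_cohort():
    """A default-parameter cohort large enough for distributional checks.

    450 samples yield ~720 matched records (each sample carries a driver
    and, ~61% of the time, a T790M).
    """
    return generate_cohort(CohortConfig(n_samples=450, seed=11))


@pytest.fixture(scope="session")
def default_records(default_cohort):
    """Paired records: dPCR reference vs the MAPD-bearing NGS platform."""
    return match_calls(default_cohort.calls_reference, default_cohort.calls_ngs_a)
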