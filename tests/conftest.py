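import numpy as np
import pytest
from hypothesis import settings

from selvote import (
    SVAConfig,
    SVAResult,
    log_normalize,
    run_sva,
)
from selvote.simulate import CohortSpec, GroupMoments, generate_cohort, moments_from_lognormal_params

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def separable_moments(m: int = 4, separation: float = 4.0) -> GroupMoments:
    """Group moments whose log-scale means differ by `separation` pooled SDs."""
    mu_g = np.zeros(m)
    mu_p = np.full(m, separation)
    sigma = np.ones(m)
    Mg, Sg = moments_from_lognormal_params(mu_g, sigma)
    Mp, Sp = moments_from_lognormal_params(mu_p, sigma)
    names = tuple(f"M{i + 1}" for i in range(m))
    return GroupMoments(names, tuple(Mg), tuple(Sg), tuple(Mp), tuple(Sp))


def make_result(sets_g, sets_p, pairs, labels=None, sample_ids=None) -> SVAResult:
    """Minimal SVAResult wrapper around hand-built ensemble-set arrays."""
    sets_g = np.asarray(sets_g, dtype=bool)
    sets_p = np.asarray(sets_p, dtype=bool)
    nb, n, n_pairs = sets_g.shape
    tally_g = sets_g.sum(axis=2)
    tally_p = sets_p.sum(axis=2)
    total_g, total_p = tally_g.sum(axis=0), tally_p.sum(axis=0)
    denom = np.maximum(total_g + total_p, 1)
    return SVAResult(
        sample_ids=sample_ids or [f"S{k}" for k in range(n)],
        pairs=list(pairs),
        g_votes=total_g / denom,
        p_votes=total_p / denom,
        per_realization_labels=np.sign(tally_p - tally_g).astype(np.int8),
        aggregate_labels=np.sign(total_p - total_g).astype(int),
        tally_g=tally_g,
        tally_p=tally_p,
        sets_g=sets_g,
        sets_p=sets_p,
    )


@pytest.fixture(scope="session")
def separable_table():
    """20/20 cohort with 4-pooled-SD log-scale group separation, normalized."""
    spec = CohortSpec(n_gin=20, n_per=20, moments=separable_moments(), seed=42)
    table, _ = generate_cohort(spec)
    return log_normalize(table)


@pytest.fixture(scope="session")
def default_table():
    """Default 40/40 cohort at the reported group moments, normalized."""
    table, _ = generate_cohort(CohortSpec(seed=1))
    return log_normalize(table)


@pytest.fixture(scope="session")
def default_result(default_table):
    """LDA voting run at a reduced realization count for reuse across tests."""
    return run_sva(default_table, SVAConfig(n_realizations=20, classifier="lda", seed=3))
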