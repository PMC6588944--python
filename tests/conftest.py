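import pytest

from tcrpersist import (
    CloneRecord,
    Compartment,
    RepertoireSample,
    SimConfig,
    TcrBeta,
    draw_time_series,
    generate_truth,
)


def make_sample(rows, individual="01", time_point=0, compartment=Compartment.PBMC):
    """Build a sample from (aa, v, j, nt, count, productive) tuples.

    Frequencies are computed over all rows, as the reader would.
    """
    total = sum(r[4] for r in rows)
    records = [
        CloneRecord(
            cdr3_aa=aa, v_gene=v, j_gene=j, cdr3_nt=nt,
            count=count, frequency=count / total, productive=prod,
        )
        for aa, v, j, nt, count, prod in rows
    ]
    return RepertoireSample(individual, time_point, compartment, records)


def tcr(aa, v="TCRBV05-01", j="TCRBJ02-01"):
    return TcrBeta(v, aa, j)


@pytest.fixture(scope="session")
def small_pool():
    """A small but structurally complete synthetic cohort truth pool."""
    cfg = SimConfig(
        seed=20260927, pool_size=2000, depth=30000,
        n_similarity_clusters=12, similarity_cluster_size=4,
    )
    return generate_truth(cfg)


@pytest.fixture(scope="session")
def small_series(small_pool):
    """One individual's full time series drawn from the small pool."""
    return draw_time_series(small_pool, "01", seed=401)


@pytest.fixture(scope="session")
def small_cohort(small_pool):
    return {
        ind: draw_time_series(small_pool, ind, seed=500 + int(ind))
        for ind in small_pool.individual_ids
    }
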