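import warnings

import networkx as nx
import numpy as np
import pytest
from scipy import stats as sps

from tcrpersist import (
    SimConfig,
    cohort_significance,
    correlation_graph,
    draw_time_series,
    find_cohort,
    flag_artifact_suspects,
    generate_truth,
    max_clique,
    select_expanded,
    top_fraction,
    trajectory_matrix,
)

from conftest import tcr
from oracles import brute_force_max_clique_size


class TestSelectExpanded:
    def test_top_twice_selected(self, small_series):
        selected = select_expanded(small_series, fraction=0.01, min_times=2)
        hits = {}
        for s in small_series.pbmc_samples:
            for t in top_fraction(s, 0.01):
                hits[t] = hits.get(t, 0) + 1
        assert selected == {t for t, k in hits.items() if k >= 2}
        assert selected  # the fixture does contain expanded receptors

    def test_never_top_not_selected(self, small_series):
        from tcrpersist import abundance_vector, occurrence_profile

        prof = occurrence_profile(small_series)
        always_present = {t for t, n in prof.items() if n == prof.n_timepoints}
        selected = select_expanded(small_series, 0.01, 2)
        tops = set().union(
            *[top_fraction(s, 0.01) for s in small_series.pbmc_samples]
        )
        never_top = always_present - tops
        assert never_top  # present everywhere yet never expanded
        assert not (never_top & selected)

    def test_fraction_one_min_once_selects_everything(self, small_series):
        from tcrpersist import occurrence_profile

        prof = occurrence_profile(small_series)
        selected = select_expanded(small_series, 1.0, 1)
        assert selected == set(prof.counts)


class TestTrajectoryMatrix:
    def test_imputes_sample_median(self, small_series):
        from tcrpersist import abundance_vector

        candidates = select_expanded(small_series)
        m = trajectory_matrix(small_series, candidates)
        for j, s in enumerate(small_series.pbmc_samples):
            med = np.median(list(abundance_vector(s).values()))
            assert m.medians[j] == pytest.approx(med)
            missing = ~m.observed[:, j]
            if missing.any():
                assert np.allclose(m.values[missing, j], med)

    def test_observed_values_passed_through(self, small_series):
        from tcrpersist import abundance_vector

        candidates = sorted(select_expanded(small_series), key=lambda t: t.key)
        m = trajectory_matrix(small_series, candidates)
        vectors = [abundance_vector(s) for s in small_series.pbmc_samples]
        for i, t in enumerate(m.tcrs):
            for j, v in enumerate(vectors):
                if t in v:
                    assert m.observed[i, j]
                    assert m.values[i, j] == pytest.approx(v[t])

    def test_shape_and_unknown_candidate(self, small_series):
        candidates = select_expanded(small_series)
        m = trajectory_matrix(small_series, candidates)
        assert m.shape == (len(candidates), len(small_series.pbmc_samples))
        with pytest.raises(ValueError, match="never observed"):
            trajectory_matrix(small_series, [tcr("CNEVERSEENF")])


def _matrix_from_rows(rows, tcrs=None):
    from tcrpersist.cohorts import TrajectoryMatrix

    rows = np.asarray(rows, dtype=float)
    n, T = rows.shape
    tcrs = tcrs or [tcr(f"CA{chr(65 + i)}F") for i in range(n)]
    return TrajectoryMatrix(
        tcrs=tcrs,
        time_points=list(range(T)),
        values=rows,
        observed=np.ones_like(rows, dtype=bool),
        medians=np.median(rows, axis=0),
    )


class TestCorrelationGraph:
    def test_positive_scaling_gives_pearson_edge(self):
        m = _matrix_from_rows([[1, 2, 3, 4], [2, 4, 6, 8], [4, 3, 2, 1]])
        g = correlation_graph(m, method="pearson", threshold=0.95)
        assert g.has_edge(m.tcrs[0], m.tcrs[1])
        assert not g.has_edge(m.tcrs[0], m.tcrs[2])

    def test_strict_threshold_excludes_exact_value(self):
        # perfectly correlated rows sit exactly at a threshold of 1.0:
        # the strict default drops the edge, the inclusive option keeps it
        m = _matrix_from_rows([[1, 2, 3, 4], [2, 4, 6, 8]])
        g_strict = correlation_graph(m, method="pearson", threshold=1.0, inclusive=False)
        assert g_strict.number_of_edges() == 0
        g_inc = correlation_graph(m, method="pearson", threshold=1.0, inclusive=True)
        assert g_inc.number_of_edges() == 1

    def test_zero_variance_row_excluded_with_warning(self):
        m = _matrix_from_rows([[1, 1, 1, 1], [1, 2, 3, 4], [2, 4, 6, 8]])
        with pytest.warns(UserWarning, match="zero-variance"):
            g = correlation_graph(m, method="pearson")
        assert m.tcrs[0] not in g

    def test_null_edge_probability_small(self):
        """Independent random trajectories rarely exceed the 0.95 cutoff."""
        rng = np.random.default_rng(0)
        x = rng.normal(size=(2, 8, 10_000))
        r = np.array([sps.pearsonr(x[0, :, i], x[1, :, i]).statistic
                      for i in range(10_000)])
        assert np.mean(r > 0.95) < 0.05


class TestMaxClique:
    def test_triangle_plus_pendant(self):
        g = nx.Graph([(1, 2), (2, 3), (1, 3), (3, 4)])
        assert max_clique(g) == {1, 2, 3}

    def test_edgeless_returns_smallest_node(self):
        g = nx.Graph()
        g.add_nodes_from([tcr("CBF"), tcr("CAF")])
        assert max_clique(g) == {tcr("CAF")}

    def test_empty_graph(self):
        assert max_clique(nx.Graph()) == set()

    @pytest.mark.parametrize("seed", range(20))
    def test_equals_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 16))
        p = rng.uniform(0.15, 0.7)
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        adj = [set(g.neighbors(i)) for i in range(n)]
        assert len(max_clique(g)) == brute_force_max_clique_size(adj, n)

    def test_deterministic_tie_break(self):
        g = nx.Graph([(1, 2), (3, 4)])
        assert max_clique(g) == {1, 2}


class TestCohortSignificance:
    def test_planted_cohort_detected(self, small_pool):
        ts = draw_time_series(small_pool, "02", seed=77)
        truth = small_pool.individuals["02"]
        planted = {t for t, c in zip(truth.tcrs, truth.cohort_id) if c == 0}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # at this scaled-down diversity the per-sample top 1% is only a
            # handful of receptors, so widen the candidate band to 5%
            res = find_cohort(ts, method="pearson", n_perm=199, seed=5,
                              fraction=0.05)
        assert res.clique_size >= 5
        assert len(set(res.members) & planted) >= res.clique_size - 2
        assert res.permutation_p is not None and res.permutation_p <= 0.01

    def test_observed_smaller_than_every_permutation(self, small_series):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = cohort_significance(small_series, observed_clique_size=1,
                                    n_perm=20, seed=3)
        assert p == 1.0

    def test_add_one_lower_bound(self, small_series):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = cohort_significance(small_series, observed_clique_size=10**6,
                                    n_perm=50, seed=3)
        assert p == pytest.approx(1 / 51)

    def test_null_validity(self):
        """Independent trajectories: cohort-size p-values are valid.

        The clique size is a small-support discrete statistic, so its
        permutation p-values carry large atoms and are conservative rather
        than exactly uniform; the operational guarantee is
        P(p <= alpha) <= alpha (plus Monte-Carlo slack).

        The null must be exchangeable across time points with independent
        per-clone noise dominating, hence the iid trajectory model:
        autocorrelated random-walk dynamics (and, at high clonality, the
        compositional coupling of frequencies) correlate even independent
        clones — a property of the correlation-clique method itself, not a
        calibration defect.
        """
        cfg = SimConfig(
            seed=9, pool_size=2000, depth=30000, n_individuals=1,
            n_planted_cohorts=0, n_similarity_clusters=0,
            lognormal_sigma=1.5, trajectory_model="iid", trajectory_sigma=1.0,
        )
        pool = generate_truth(cfg)
        pvals = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for rep in range(100):
                ts = draw_time_series(pool, "01", seed=1000 + rep)
                res = find_cohort(ts, method="spearman", n_perm=0, fraction=0.05)
                size = max(res.clique_size, 1)
                pvals.append(
                    cohort_significance(ts, size, n_perm=200, seed=rep,
                                        method="spearman", fraction=0.05)
                )
        pvals = np.asarray(pvals)
        n = len(pvals)
        for alpha in (0.01, 0.05, 0.1, 0.25, 0.5):
            slack = 3 * np.sqrt(alpha * (1 - alpha) / n)
            assert np.mean(pvals <= alpha) <= alpha + slack


class TestArtifactFlags:
    def test_satellite_flagged(self):
        dom, sat, far = tcr("CASSLGETQYF"), tcr("CASSLGATQYF"), tcr("CWWRKYPLMHF")
        abund = {dom: 0.1, sat: 0.001, far: 0.001}
        flags = flag_artifact_suspects([dom, sat, far], abund)
        assert flags[sat] is True
        assert flags[far] is False

    def test_equal_abundance_dissimilar_members_unflagged(self):
        a, b = tcr("CASSLGETQYF"), tcr("CWWRKYPLMHF")
        flags = flag_artifact_suspects([a, b], {a: 0.01, b: 0.01})
        assert not any(flags.values())

    def test_dominant_never_flagged(self):
        dom, sat = tcr("CASSLGETQYF"), tcr("CASSLGATQYF")
        flags = flag_artifact_suspects([dom, sat], {dom: 0.1, sat: 0.0001})
        assert flags[dom] is False
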