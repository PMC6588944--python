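import numpy as np
import pytest
from scipy import stats as sps

from tcrpersist import (
    Compartment,
    SimConfig,
    abundance_vector,
    draw_sample,
    draw_time_series,
    generate_truth,
    rarefaction_curve,
    truth_sharing_table,
)
from tcrpersist.io import write_repertoire_tsv
from tcrpersist.synthetic import PERSISTENT, SimConfigError, TRANSIENT


class TestConfigValidation:
    def test_infeasible_persistent_fraction(self):
        with pytest.raises(SimConfigError, match="persistent"):
            SimConfig(seed=1, pool_size=50, persistent_fraction=0.01)

    def test_zero_persistent_fraction_allowed(self):
        cfg = SimConfig(seed=1, pool_size=300, persistent_fraction=0.0,
                        n_similarity_clusters=0, n_planted_cohorts=0)
        pool = generate_truth(cfg)
        truth = pool.individuals["01"]
        assert not np.any(truth.persistence_class == PERSISTENT)

    def test_fraction_bounds(self):
        with pytest.raises(SimConfigError):
            SimConfig(seed=1, nonproductive_fraction=1.5)

    def test_depth_bound(self):
        with pytest.raises(SimConfigError):
            SimConfig(seed=1, depth=0)


class TestDeterminism:
    def test_same_seed_same_pool(self):
        cfg = SimConfig(seed=5, pool_size=400, depth=5000,
                        n_similarity_clusters=3)
        p1, p2 = generate_truth(cfg), generate_truth(cfg)
        t1, t2 = p1.individuals["01"], p2.individuals["01"]
        assert t1.tcrs == t2.tcrs
        assert np.array_equal(t1.base_abundance, t2.base_abundance)
        assert np.array_equal(t1.trajectory, t2.trajectory)
        assert np.array_equal(t1.share_count, t2.share_count)

    def test_same_seed_same_sample(self, small_pool):
        s1 = draw_sample(small_pool, "01", 0, seed=9)
        s2 = draw_sample(small_pool, "01", 0, seed=9)
        assert [r.clone_key for r in s1.records] == [r.clone_key for r in s2.records]
        assert [r.count for r in s1.records] == [r.count for r in s2.records]

    def test_identical_seeds_byte_identical_tsvs(self, small_pool, tmp_path):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_repertoire_tsv(draw_sample(small_pool, "01", 1, seed=3), p1)
        write_repertoire_tsv(draw_sample(small_pool, "01", 1, seed=3), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_distinct_seeds_distinct_samples(self, small_pool):
        s1 = draw_sample(small_pool, "01", 0, seed=1)
        s2 = draw_sample(small_pool, "01", 0, seed=2)
        assert [r.count for r in s1.records] != [r.count for r in s2.records]


class TestTruthStructure:
    def test_persistent_trajectories_positive_everywhere(self, small_pool):
        truth = small_pool.individuals["01"]
        pers = truth.persistence_class == PERSISTENT
        assert np.all(truth.trajectory[pers] > 0)

    def test_transient_present_exactly_once(self, small_pool):
        truth = small_pool.individuals["01"]
        trans = truth.persistence_class == TRANSIENT
        assert np.all((truth.trajectory[trans] > 0).sum(axis=1) == 1)

    def test_persistent_boost_raises_mean_abundance(self, small_pool):
        truth = small_pool.individuals["01"]
        pers = truth.persistence_class == PERSISTENT
        trans = truth.persistence_class == TRANSIENT
        assert (np.median(truth.base_abundance[pers])
                > np.median(truth.base_abundance[trans]))

    def test_boost_off_classes_indistinguishable(self):
        """With the abundance boost disabled, persistent and transient base
        abundances come from the same distribution."""
        pvals = []
        for seed in range(20):
            cfg = SimConfig(seed=seed, pool_size=1000, depth=1000,
                            abundance_boost=1.0, n_similarity_clusters=0,
                            n_planted_cohorts=0, n_individuals=1)
            truth = generate_truth(cfg).individuals["01"]
            pers = truth.base_abundance[truth.persistence_class == PERSISTENT]
            trans = truth.base_abundance[truth.persistence_class == TRANSIENT]
            pvals.append(sps.mannwhitneyu(pers, trans).pvalue)
        assert min(pvals) > 0.001 / 20 and np.median(pvals) > 0.05

    def test_nt_redundancy_larger_for_persistent(self, small_pool):
        truth = small_pool.individuals["01"]
        pers = truth.persistence_class == PERSISTENT
        red = np.array([len(v) for v in truth.nt_variants])
        assert red[pers].mean() > red[~pers].mean()

    def test_share_counts_span_deciles(self, small_pool):
        sharing = truth_sharing_table(small_pool)
        fracs = np.array([c / sharing.cohort_size for c in sharing.counts.values()])
        occupied = set((np.minimum((fracs * 10).astype(int), 9)).tolist())
        assert occupied == set(range(10))

    def test_share_counts_bounded(self, small_pool):
        for truth in small_pool.individuals.values():
            assert np.all(truth.share_count >= 0)
            assert np.all(truth.share_count <= small_pool.config.cohort_size)


class TestDrawSample:
    def test_observed_count_matches_binomial_moments(self):
        """A clone at relative abundance ~1e-2 sampled at depth 1e6 lands
        within 3 binomial standard deviations of its expectation."""
        cfg = SimConfig(seed=77, pool_size=500, depth=10**6,
                        n_similarity_clusters=0, n_planted_cohorts=0,
                        n_individuals=1, trajectory_sigma=0.0)
        pool = generate_truth(cfg)
        truth = pool.individuals["01"]
        s = draw_sample(pool, "01", 0, seed=1)
        # realized productive relative abundance per clone at t0
        w = truth.base_abundance * truth.trajectory[:, 0]
        rel = (1 - cfg.nonproductive_fraction) * w / w.sum()
        counts = {}
        for r in s.records:
            if r.productive:
                key = (r.cdr3_aa, r.v_gene, r.j_gene)
                counts[key] = counts.get(key, 0) + r.count
        checked = 0
        for i, t in enumerate(truth.tcrs):
            if 3e-3 < rel[i] < 3e-2:
                mean = rel[i] * cfg.depth
                sigma = np.sqrt(cfg.depth * rel[i] * (1 - rel[i]))
                got = counts.get((t.cdr3_aa, t.v_gene, t.j_gene), 0)
                assert abs(got - mean) < 3 * sigma
                checked += 1
        assert checked >= 3

    def test_rare_clone_rarely_detected(self):
        """Detection probability at depth*abundance = 1e-3 is ~1e-3."""
        rng = np.random.default_rng(0)
        detected = (rng.binomial(1000, 1e-6, size=1000) > 0).sum()
        assert detected <= 10  # 1 - (1-1e-6)^1000 ~ 1e-3

    def test_memory_compartment_only_memory_clones(self, small_pool):
        truth = small_pool.individuals["01"]
        memory_tcrs = {t for t, m in zip(truth.tcrs, truth.memory_flag) if m}
        s = draw_sample(small_pool, "01", 5, Compartment.MEMORY, seed=2)
        assert set(abundance_vector(s)) <= memory_tcrs

    def test_naive_compartment_is_complement(self, small_pool):
        truth = small_pool.individuals["01"]
        memory_tcrs = {t for t, m in zip(truth.tcrs, truth.memory_flag) if m}
        s = draw_sample(small_pool, "01", 5, Compartment.NAIVE, seed=2)
        assert not (set(abundance_vector(s)) & memory_tcrs)

    def test_unknown_compartment_errors(self, small_pool):
        with pytest.raises(ValueError):
            draw_sample(small_pool, "01", 0, "plasma", seed=1)

    def test_unknown_individual_or_timepoint(self, small_pool):
        with pytest.raises(KeyError):
            draw_sample(small_pool, "99", 0, seed=1)
        with pytest.raises(KeyError):
            draw_sample(small_pool, "01", 4, seed=1)

    def test_nonproductive_fraction_near_target(self, small_pool):
        s = draw_sample(small_pool, "01", 0, seed=8)
        npf = 1 - s.productive_fraction
        assert abs(npf - small_pool.config.nonproductive_fraction) < 0.02


class TestRecoveryAndSaturation:
    def test_persistent_above_detection_recovered(self, small_pool):
        """Ground-truth persistent clones whose worst-time-point relative
        abundance clears 10x the detection limit appear at every time point."""
        from tcrpersist import occurrence_profile, persistent_set

        cfg = small_pool.config
        misses = 0
        total = 0
        for ind in small_pool.individual_ids:
            ts = draw_time_series(small_pool, ind, seed=900 + int(ind))
            found = persistent_set(occurrence_profile(ts))
            truth = small_pool.individuals[ind]
            w = truth.base_abundance[:, None] * truth.trajectory
            rel = (1 - cfg.nonproductive_fraction) * w / w.sum(axis=0, keepdims=True)
            detectable = (
                (truth.persistence_class == PERSISTENT)
                & (rel.min(axis=1) >= 10 / cfg.depth)
            )
            for i in np.flatnonzero(detectable):
                total += 1
                if truth.tcrs[i] not in found:
                    misses += 1
        assert total > 50
        assert misses / total <= 0.05

    def test_transient_clones_never_called_persistent(self, small_pool):
        from tcrpersist import occurrence_profile, persistent_set

        ts = draw_time_series(small_pool, "01", seed=901)
        found = persistent_set(occurrence_profile(ts))
        truth = small_pool.individuals["01"]
        transients = {
            t for t, c in zip(truth.tcrs, truth.persistence_class) if c == TRANSIENT
        }
        assert not (found & transients)

    def test_rarefaction_saturates_at_papers_scale_ratio(self):
        """With depth well above pool diversity, richness at full depth is
        within 5% of richness at half depth (sequencing past saturation)."""
        cfg = SimConfig(seed=13, pool_size=500, depth=1_000_000,
                        n_similarity_clusters=0, n_planted_cohorts=0,
                        n_individuals=1)
        pool = generate_truth(cfg)
        s = draw_sample(pool, "01", 0, seed=4)
        total = s.total_count
        curve = rarefaction_curve(s, [total // 2, total], n_reps=3, seed=5)
        assert curve[total] <= 1.05 * curve[total // 2]
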