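import numpy as np
import pytest
from scipy.stats import chi2

from pathpower.datatypes import SurvivalData
from pathpower.power import (
    DegeneratePartitionError,
    PredictiveIndex,
    ResamplingConfig,
    compute_opi,
    compute_ppi,
    logrank_statistic,
    opi_single_partition,
    pathway_dataset_pvalue,
    random_partition,
    separation_pvalue,
)
from pathpower.simulate import SimulationSpec, simulate_study


class TestRandomPartition:
    def test_sizes_and_disjoint_union(self, rng):
        train, test = random_partition(9, 2 / 3, rng)
        assert len(train) == 6 and len(test) == 3
        assert sorted(np.concatenate([train, test])) == list(range(9))

    def test_deterministic(self):
        a = random_partition(20, 2 / 3, np.random.default_rng(4))
        b = random_partition(20, 2 / 3, np.random.default_rng(4))
        np.testing.assert_array_equal(a[0], b[0])

    def test_uniform_membership(self):
        rng = np.random.default_rng(0)
        counts = np.zeros(12)
        for _ in range(1000):
            _, test = random_partition(12, 2 / 3, rng)
            counts[test] += 1
        np.testing.assert_allclose(counts / 1000, 1 / 3, atol=0.05)


class TestLogrank:
    def test_hand_worked_instance(self, small_survival):
        group, surv = small_survival
        stat = logrank_statistic(group, surv)
        assert stat == pytest.approx((2 / 3) ** 2 / (13 / 18))
        assert stat == pytest.approx(0.6154, abs=1e-4)

    def test_label_swap_symmetry(self, small_survival):
        group, surv = small_survival
        assert logrank_statistic(group, surv) == pytest.approx(
            logrank_statistic(~group, surv)
        )

    def test_oracle_equivalence_random_instances(self):
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(99)
        checked = 0
        while checked < 100:
            n = int(rng.integers(8, 31))
            t = np.round(rng.exponential(1, n), 2) + 0.01  # induce some ties
            d = (rng.random(n) < 0.7).astype(int)
            g = rng.random(n) < 0.5
            if d.sum() == 0 or g.all() or not g.any():
                continue
            surv = SurvivalData([f"s{i}" for i in range(n)], t, d)
            try:
                ours = logrank_statistic(g, surv)
            except DegeneratePartitionError:
                continue
            ref = logrank_test(
                t[g], t[~g], event_observed_A=d[g], event_observed_B=d[~g]
            ).test_statistic
            assert ours == pytest.approx(ref, abs=1e-8)
            checked += 1

    def test_degenerate_variance_signalled(self):
        # the only event happens when a single subject remains at risk
        surv = SurvivalData(["a", "b", "c"], [1.0, 2.0, 3.0], [0, 0, 1])
        with pytest.raises(DegeneratePartitionError):
            logrank_statistic(np.array([True, True, False]), surv)


class TestSeparationPvalue:
    def test_identical_vectors_no_separation(self):
        v = PredictiveIndex(np.arange(30, dtype=float))
        assert separation_pvalue(v, v) >= 0.5

    def test_exact_enumeration(self):
        opi = PredictiveIndex([10.0, 11.0, 12.0])
        ppi = PredictiveIndex([1.0, 2.0, 3.0])
        assert separation_pvalue(opi, ppi) == pytest.approx(1 / 20)

    def test_swap_complements(self, rng):
        a = PredictiveIndex(rng.exponential(1, 30))
        b = PredictiveIndex(rng.exponential(2, 30))
        p1 = separation_pvalue(a, b)
        p2 = separation_pvalue(b, a)
        assert p1 + p2 == pytest.approx(1.0, abs=0.02)  # continuity correction

    def test_two_sided_flag(self, rng):
        a = PredictiveIndex(rng.exponential(1, 25) + 3)
        b = PredictiveIndex(rng.exponential(1, 25))
        assert separation_pvalue(a, b, two_sided=True) == pytest.approx(
            2 * separation_pvalue(a, b), rel=0.05
        )


class TestOpiPpi:
    def test_degenerate_when_fully_shrunk(self, null_study):
        ds, genes = null_study
        cfg = ResamplingConfig(B=5, seed=0, lambda_grid=np.array([1e6]))
        with pytest.raises(DegeneratePartitionError):
            opi_single_partition(
                ds.expression.subset_genes(list(genes)), ds.survival, cfg,
                np.random.default_rng(0),
            )

    def test_opi_reproducible_and_length(self, null_study):
        ds, genes = null_study
        sub = ds.expression.subset_genes(list(genes))
        cfg = ResamplingConfig(B=5, seed=3, n_lambda=4)
        a = compute_opi(sub, ds.survival, cfg, name="pw")
        b = compute_opi(sub, ds.survival, cfg, name="pw")
        assert len(a) == 5
        np.testing.assert_array_equal(a.statistics, b.statistics)
        assert a.failed == b.failed

    def test_ppi_reproducible_and_differs_from_opi(self, null_study):
        ds, genes = null_study
        sub = ds.expression.subset_genes(list(genes))
        cfg = ResamplingConfig(B=5, seed=3, n_lambda=4)
        a = compute_ppi(sub, ds.survival, cfg, name="pw")
        b = compute_ppi(sub, ds.survival, cfg, name="pw")
        np.testing.assert_array_equal(a.statistics, b.statistics)
        opi = compute_opi(sub, ds.survival, cfg, name="pw")
        assert not np.array_equal(a.statistics, opi.statistics)

    def test_signal_beats_chi2_quantile(self, signal_study):
        ds, genes = signal_study
        sub = ds.expression.subset_genes(list(genes))
        hits = 0
        for seed in range(10):
            cfg = ResamplingConfig(B=4, seed=seed, n_lambda=4)
            opi = compute_opi(sub, ds.survival, cfg, name=f"s{seed}")
            hits += np.median(opi.statistics) > chi2.ppf(0.95, 1)
        assert hits >= 7

    def test_effect_size_monotonicity(self):
        medians = []
        for effect in (0.5, 1.0, 2.0):
            vals = []
            for seed in range(3):
                spec = SimulationSpec(
                    n_per_study=(150,), n_genes=6, pathway_sizes=(6,),
                    signal_pathways=(0,), genes_per_signal_pathway=2,
                    effect_size=effect, gene_overlap_fraction=1.0,
                    seed=600 + seed,
                )
                ds = simulate_study(spec, 0)
                cfg = ResamplingConfig(B=6, seed=seed, n_lambda=4)
                opi = compute_opi(ds.expression, ds.survival, cfg, name="m")
                vals.append(np.median(opi.statistics))
            medians.append(np.mean(vals))
        assert medians[0] < medians[2]

    def test_ppi_matches_null_opi_distribution(self, signal_study, null_study):
        # permuting outcomes destroys the signal: the PPI of a strongly
        # predictive pathway is indistinguishable from a null pathway's PPI
        sig, sig_genes = signal_study
        nul, nul_genes = null_study
        cfg = ResamplingConfig(B=40, seed=11, n_lambda=4)
        ppi_signal = compute_ppi(
            sig.expression.subset_genes(list(sig_genes)), sig.survival, cfg,
            name="sig",
        )
        ppi_null = compute_ppi(
            nul.expression.subset_genes(list(nul_genes)), nul.survival, cfg,
            name="nul",
        )
        from scipy.stats import ks_2samp

        assert ks_2samp(ppi_signal.statistics, ppi_null.statistics).pvalue > 0.01


class TestPathwayDatasetPvalue:
    def test_deterministic(self, null_study):
        ds, genes = null_study
        cfg = ResamplingConfig(B=5, seed=1, n_lambda=4)
        r1 = pathway_dataset_pvalue(ds, genes, cfg, name="pw")
        r2 = pathway_dataset_pvalue(ds, genes, cfg, name="pw")
        assert r1[0] == r2[0]
        np.testing.assert_array_equal(r1[1].statistics, r2[1].statistics)

    def test_unmeasured_pathway_errors(self, null_study):
        ds, _ = null_study
        cfg = ResamplingConfig(B=5, seed=1)
        with pytest.raises(ValueError, match="no genes"):
            pathway_dataset_pvalue(ds, ("nope1", "nope2"), cfg, name="missing")

    def test_time_relabel_invariance(self, null_study):
        # the whole analysis is rank-based in time: a strictly increasing
        # relabeling of survival times changes nothing
        ds, genes = null_study
        cfg = ResamplingConfig(B=5, seed=2, n_lambda=4)
        p1, opi1, _ = pathway_dataset_pvalue(ds, genes, cfg, name="pw")
        warped = SurvivalData(
            list(ds.survival.sample_ids),
            np.exp(ds.survival.time / ds.survival.time.max()),
            ds.survival.event,
        )
        from pathpower.datatypes import StudyDataset

        ds2 = StudyDataset(ds.label, ds.expression, warped)
        p2, opi2, _ = pathway_dataset_pvalue(ds2, genes, cfg, name="pw")
        assert p1 == p2
        np.testing.assert_allclose(opi1.statistics, opi2.statistics, rtol=1e-9)
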