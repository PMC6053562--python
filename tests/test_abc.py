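import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sealdrift import abc_demography as abcd


PRIORS = abcd.PriorSet()


class TestDrawParameters:
    def test_null_scenario_has_no_free_parameters(self):
        p = abcd.draw_parameters(1, PRIORS, np.random.default_rng(0))
        assert p.scenario == 1
        assert p.n0 == 100_000 and p.npe is None and p.nb is None

    def test_prior_support(self):
        rng = np.random.default_rng(1)
        draws = [abcd.draw_parameters(3, PRIORS, rng) for _ in range(2000)]
        nb = np.array([d.nb for d in draws])
        assert 100 <= nb.min() and nb.max() <= 10_000
        tr = np.array([d.tr for d in draws])
        tb = np.array([d.tb for d in draws])
        assert np.all(tr < tb)

    def test_scenario4_event_ordering(self):
        rng = np.random.default_rng(2)
        for _ in range(500):
            p = abcd.draw_parameters(4, PRIORS, rng)
            assert p.tr < p.tb < p.te


class TestScenarioHistory:
    def test_epoch_structure(self):
        p = abcd.ScenarioParams(scenario=4, npe=2000, npb=50_000, nb=500,
                                tr=50, tb=800)
        h = abcd.scenario_history(p)
        assert h.sizes == (100_000.0, 500, 50_000, 2000)
        assert h.boundaries == (50, 800, 10_000.0)

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            abcd.ScenarioParams(scenario=3, npb=50_000, nb=500, tr=900, tb=800)

    def test_missing_required_parameter(self):
        with pytest.raises(ValueError, match="npe"):
            abcd.ScenarioParams(scenario=2)


class TestSimulateSnpDataset:
    def test_every_locus_polymorphic(self):
        rng = np.random.default_rng(3)
        ds = abcd.simulate_snp_dataset(abcd.ScenarioParams(scenario=1),
                                       32, 500, 0.0, rng)
        assert ds.n_loci == 500
        assert ds.counts.min() >= 1 and ds.counts.max() <= 63

    def test_maf_condition_enforced(self):
        rng = np.random.default_rng(4)
        ds = abcd.simulate_snp_dataset(abcd.ScenarioParams(scenario=1),
                                       32, 400, 0.05, rng)
        p = ds.counts / 64
        assert np.minimum(p, 1 - p).min() >= 0.05
        assert ds.maf_filtered

    def test_bottleneck_shifts_conditional_diversity(self):
        """A partially coalescing bottleneck distorts the gene-diversity
        distribution of polymorphism-conditioned SNPs.

        Because every simulated locus carries exactly one mutation, the
        per-locus diversity depends only on relative branch lengths; a
        bottleneck that lets some lineages survive into the large ancestral
        epoch creates long deep branches and an excess of intermediate
        frequencies, raising mean conditional diversity relative to the
        constant-size null (a bottleneck in which all lineages coalesce
        leaves the Kingman tree shape, hence the statistic, unchanged).
        """
        rng = np.random.default_rng(5)
        null = abcd.simulate_snp_dataset(abcd.ScenarioParams(scenario=1),
                                         32, 2000, 0.0, rng)
        bott = abcd.simulate_snp_dataset(
            abcd.ScenarioParams(scenario=3, nb=500, tr=50, tb=500,
                                npb=100_000),
            32, 2000, 0.0, rng)
        t, p = stats.ttest_ind(bott.gene_diversity(), null.gene_diversity())
        assert t > 0 and p / 2 < 1e-6  # one-sided


class TestSummaryStats:
    def test_worked_example(self):
        s = abcd.summary_stats_from_diversity([0, 0.5, 0.3, 0])
        assert s.prop_zero == pytest.approx(0.5)
        assert s.mean_nonzero == pytest.approx(0.4)
        assert s.var_nonzero == pytest.approx(0.02)
        assert s.mean_all == pytest.approx(0.2)

    def test_all_monomorphic_convention(self):
        s = abcd.summary_stats_from_diversity([0.0, 0.0, 0.0])
        assert s.as_array().tolist() == [1.0, 0.0, 0.0, 0.0]

    def test_no_zeros_means_agree(self):
        s = abcd.summary_stats_from_diversity([0.2, 0.4])
        assert s.prop_zero == 0.0
        assert s.mean_all == pytest.approx(s.mean_nonzero)


def toy_reference(stats_rows, scenarios, priors=PRIORS):
    m = len(stats_rows)
    params = pd.DataFrame(
        {"npe": np.full(m, 5000.0), "npb": np.full(m, 50_000.0),
         "nb": np.full(m, 1000.0), "tr": np.full(m, 50.0),
         "tb": np.full(m, 1000.0)})
    return abcd.ReferenceTable(
        scenario=np.asarray(scenarios, dtype=int), params=params,
        stats=np.asarray(stats_rows, dtype=float), priors=priors,
        n_diploids=32, n_loci=100, maf_min=0.0, seed=0)


class TestBuildReferenceTable:
    def test_cardinality_and_determinism(self):
        a = abcd.build_reference_table(PRIORS, (1, 2, 3, 4), 25, 16, 50, 0.0,
                                       seed=7)
        b = abcd.build_reference_table(PRIORS, (1, 2, 3, 4), 25, 16, 50, 0.0,
                                       seed=7)
        assert a.n_rows == 100
        np.testing.assert_array_equal(a.stats, b.stats)
        assert a.params.equals(b.params)

    def test_round_trip(self, tmp_path):
        a = abcd.build_reference_table(PRIORS, (1, 3), 20, 16, 50, 0.0, seed=8)
        a.write(tmp_path / "ref.tsv")
        b = abcd.ReferenceTable.read(tmp_path / "ref.tsv")
        np.testing.assert_allclose(a.stats, b.stats)
        assert b.priors == a.priors and b.n_diploids == 16

    def test_scenario1_rows_cluster_around_oracle_mean(self):
        """Scenario-1 reference stats agree with direct re-simulation."""
        ref = abcd.build_reference_table(PRIORS, (1,), 60, 32, 400, 0.0, seed=9)
        rng = np.random.default_rng(10)
        oracle = [abcd.summary_stats(abcd.simulate_snp_dataset(
            abcd.ScenarioParams(scenario=1), 32, 400, 0.0, rng)).mean_all
            for _ in range(60)]
        mine = ref.stats[:, 3]
        t, p = stats.ttest_ind(mine, oracle)
        assert p > 0.001


class TestModelChoice:
    def test_nearest_neighbor_identity(self):
        ref = toy_reference(
            [[0, 0.30, 0.01, 0.30], [0, 0.20, 0.02, 0.20],
             [0, 0.10, 0.03, 0.10], [0, 0.40, 0.04, 0.40]] * 25,
            [1, 2, 3, 4] * 25)
        obs = abcd.SummaryStatVector(0, 0.20, 0.02, 0.20)
        post = abcd.abc_model_choice(ref, obs, top_frac=0.01)  # 1 row
        assert post.n_accepted == 1
        assert post.rejection.loc[2, "prob"] == pytest.approx(1.0)

    def test_separable_classes_give_confident_logistic(self):
        rng = np.random.default_rng(11)
        rows, scen = [], []
        for sc, mu in [(1, 0.1), (2, 0.3), (3, 0.5), (4, 0.7)]:
            for _ in range(200):
                v = mu + rng.normal(0, 0.005)
                rows.append([0, v, 0.01 + rng.normal(0, 1e-4), v])
                scen.append(sc)
        ref = toy_reference(rows, scen)
        obs = abcd.SummaryStatVector(0, 0.5, 0.01, 0.5)
        post = abcd.abc_model_choice(ref, obs, top_frac=0.2)
        assert post.logistic.loc[3, "prob"] > 0.99
        assert post.best("logistic") == 3

    def test_posteriors_sum_to_one(self, ):
        rng = np.random.default_rng(12)
        ref = toy_reference(rng.uniform(0, 1, size=(400, 4)),
                            rng.integers(1, 5, size=400))
        obs = abcd.SummaryStatVector(*rng.uniform(0, 1, 4))
        post = abcd.abc_model_choice(ref, obs, top_frac=0.25)
        assert post.rejection["prob"].sum() == pytest.approx(1.0, abs=1e-6)
        assert post.logistic["prob"].sum() == pytest.approx(1.0, abs=1e-6)

    def test_distance_scaling_invariance(self):
        """Multiplying one raw summary by a constant leaves acceptance alone."""
        rng = np.random.default_rng(13)
        stats_rows = rng.uniform(0, 1, size=(300, 4))
        ref1 = toy_reference(stats_rows, rng.integers(1, 5, size=300))
        scaled = stats_rows.copy()
        scaled[:, 1] *= 37.0
        ref2 = toy_reference(scaled, ref1.scenario)
        obs = rng.uniform(0, 1, 4)
        obs_scaled = obs.copy()
        obs_scaled[1] *= 37.0
        d1, *_ = abcd._standardized_distances(
            ref1, abcd.SummaryStatVector(*obs))
        d2, *_ = abcd._standardized_distances(
            ref2, abcd.SummaryStatVector(*obs_scaled))
        np.testing.assert_allclose(d1, d2)

    def test_out_of_range_observation_flagged(self):
        rng = np.random.default_rng(14)
        ref = toy_reference(rng.uniform(0, 1, size=(200, 4)),
                            rng.integers(1, 5, size=200))
        post = abcd.abc_model_choice(
            ref, abcd.SummaryStatVector(0.5, 99.0, 0.5, 0.5), top_frac=0.2)
        assert post.out_of_range


class TestParameterEstimate:
    def test_no_adjustment_limit_recovers_marginal(self):
        """Identical reference stats make the regression adjustment vanish."""
        rng = np.random.default_rng(15)
        m = 200
        nb = rng.uniform(200, 9000, size=m)
        params = pd.DataFrame({
            "npe": np.full(m, np.nan), "npb": rng.uniform(2e4, 1e5, m),
            "nb": nb, "tr": rng.uniform(2, 90, m), "tb": rng.uniform(200, 4000, m)})
        ref = abcd.ReferenceTable(
            scenario=np.full(m, 3), params=params,
            stats=np.tile([0.0, 0.3, 0.02, 0.3], (m, 1)), priors=PRIORS,
            n_diploids=32, n_loci=100, maf_min=0.0, seed=0)
        obs = abcd.SummaryStatVector(0, 0.3, 0.02, 0.3)
        pp = abcd.abc_parameter_estimate(ref, obs, 3, top_frac=1.0)
        assert pp.n_accepted == m
        assert pp.table.loc["nb", "median"] == pytest.approx(
            np.median(nb), rel=0.02)

    def test_quantiles_inside_prior_bounds(self, reference_nomaf):
        rng = np.random.default_rng(16)
        ds = abcd.simulate_snp_dataset(
            abcd.draw_parameters(4, PRIORS, rng), 32, 1000, 0.0, rng)
        pp = abcd.abc_parameter_estimate(reference_nomaf, abcd.summary_stats(ds),
                                         4)
        for name in abcd.SCENARIO_FREE_PARAMS[4]:
            lo, hi = PRIORS.bounds(name)
            row = pp.table.loc[name]
            assert lo <= row["q025"] <= row["median"] <= row["q975"] <= hi

    def test_null_scenario_rejected(self):
        ref = toy_reference(np.zeros((10, 4)), [1] * 10)
        with pytest.raises(ValueError, match="free"):
            abcd.abc_parameter_estimate(
                ref, abcd.SummaryStatVector(0, 0, 0, 0), 1)


def test_scenario_nesting_invariance():
    """Scenario 2 with Npe = N0 and scenario 3 with Nb = Npb = N0 reduce to
    the constant-size null: gene-diversity distributions indistinguishable."""
    rng = np.random.default_rng(17)
    n, L = 32, 2000
    base = abcd.simulate_snp_dataset(abcd.ScenarioParams(scenario=1), n, L,
                                     0.0, rng)
    as2 = abcd.simulate_snp_dataset(
        abcd.ScenarioParams(scenario=2, npe=100_000), n, L, 0.0, rng)
    as3 = abcd.simulate_snp_dataset(
        abcd.ScenarioParams(scenario=3, nb=100_000, npb=100_000, tr=50,
                            tb=1000), n, L, 0.0, rng)
    for other in (as2, as3):
        ks = stats.ks_2samp(base.gene_diversity(), other.gene_diversity())
        assert ks.pvalue > 0.01


def test_confusion_report_bookkeeping():
    ref = abcd.build_reference_table(PRIORS, (1, 3), 150, 16, 120, 0.0, seed=18)
    rep = abcd.confusion_error(ref, PRIORS, (1, 3), pods_per_scenario=10,
                               n_diploids=16, n_loci=120, maf_min=0.0, seed=19)
    assert rep.selection.to_numpy().sum() == 20
    assert ((rep.error_rate >= 0) & (rep.error_rate <= 1)).all()
    rep2 = abcd.confusion_error(ref, PRIORS, (1, 3), pods_per_scenario=10,
                                n_diploids=16, n_loci=120, maf_min=0.0, seed=19)
    assert rep.selection.equals(rep2.selection)


def test_abc_results_summary_is_readable(reference_nomaf):
    from sealdrift.models import DemographicABC

    rng = np.random.default_rng(20)
    ds = abcd.simulate_snp_dataset(
        abcd.ScenarioParams(scenario=3, nb=300, tr=20, tb=2000, npb=80_000),
        32, 1000, 0.0, rng)
    model = DemographicABC(abcd.summary_stats(ds), 32, 1000)
    res = model.fit(reference=reference_nomaf)
    text = res.summary()
    assert "scenario" in text and "logistic" in text
    assert res.model_table().shape == (4, 4)
    assert res.best_scenario in (3, 4)
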