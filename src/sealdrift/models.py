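"""Model / Results interfaces tying the inference stages together.

Two fitted-model pairs in the statsmodels idiom:

* :class:`DemographicABC` -- likelihood-free model choice among the four
  piecewise demographic scenarios for one SNP panel; ``fit()`` returns an
  :class:`ABCResults` carrying posterior model probabilities (rejection and
  logistic, with 95% intervals), regression-adjusted parameter posteriors
  for the scenarios with free parameters, and a ``summary()`` table.
* :class:`TemporalOutlierScan` -- the drift-null outlier scan of a temporally
  sampled cohort series; ``fit()`` simulates the Wright-Fisher/logistic null
  seeded from the oldest cohort, regresses every observed and simulated
  locus on calendar year, and returns an :class:`OutlierScanResults` with
  the slope envelope, outlier calls and slope-distribution tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import abc_demography as abcd
from . import genotype_io as gio
from . import temporal_outliers as outl
from .wf_logistic_sim import CohortFrequencySeries, GrowthSchedule, SamplingPlan, simulate_null

__all__ = ["DemographicABC", "ABCResults", "TemporalOutlierScan",
           "OutlierScanResults"]


class DemographicABC:
    """ABC model choice for one observed SNP panel.

    Parameters
    ----------
    observed : SummaryStatVector
        The four gene-diversity summaries of the observed panel.
    n_diploids, n_loci : int
        Sampling configuration the reference table must match.
    maf_min : float
        Minor-allele-frequency threshold applied to both the observed panel
        (upstream) and every simulated dataset (0 disables).
    """

    def __init__(self, observed: abcd.SummaryStatVector, n_diploids: int,
                 n_loci: int, priors: abcd.PriorSet | None = None,
                 scenarios: tuple[int, ...] = (1, 2, 3, 4),
                 maf_min: float = 0.0):
        self.observed = observed
        self.n_diploids = int(n_diploids)
        self.n_loci = int(n_loci)
        self.priors = priors or abcd.PriorSet()
        self.scenarios = tuple(scenarios)
        self.maf_min = float(maf_min)

    @classmethod
    def from_genotypes(cls, gm: gio.GenotypeMatrix, cohort: str | None = None,
                       min_presence: float = 0.9, n_loci: int = 1000,
                       maf_min: float = 0.0, snp_rule: str = "first",
                       seed: int = 0, **kwargs) -> "DemographicABC":
        """Build the model from a genotype matrix reduced to one cohort.

        Applies the single-cohort presence rule (default 90%), one SNP per
        RAD locus, the optional MAF filter, and a seeded random subsample to
        ``n_loci`` loci; summaries use the per-locus unbiased gene diversity.
        """
        if cohort is None:  # newest cohort by mean sampling year
            cohort = gm.samples.groupby("cohort")["year"].mean().idxmax()
        sub = gm.take_samples((gm.samples["cohort"] == cohort).to_numpy())
        sub = gio.filter_group_presence(sub, min_presence, grouping="all")
        sub = gio.select_one_snp_per_radlocus(sub, rule=snp_rule)
        if maf_min > 0:
            sub = gio.filter_maf(sub, maf_min)
        if sub.n_loci > n_loci:
            rng = np.random.default_rng(seed)
            keep = np.sort(rng.choice(sub.n_loci, size=n_loci, replace=False))
            sub = sub.take_loci(keep)
        ft = gio.allele_frequencies(sub, "all")
        n = ft.n_genes[:, 0].astype(float)
        p = ft.freq[:, 0]
        h = np.where(n > 1, (n / np.maximum(n - 1, 1)) * 2 * p * (1 - p), np.nan)
        obs = abcd.summary_stats_from_diversity(h)
        n_dip = int(np.round(np.median(n) / 2))
        return cls(observed=obs, n_diploids=n_dip, n_loci=sub.n_loci,
                   maf_min=maf_min, **kwargs)

    def build_reference(self, sims_per_scenario: int,
                        seed: int) -> abcd.ReferenceTable:
        return abcd.build_reference_table(
            self.priors, self.scenarios, sims_per_scenario, self.n_diploids,
            self.n_loci, self.maf_min, seed)

    def fit(self, reference: abcd.ReferenceTable | None = None,
            sims_per_scenario: int = 25_000, top_frac: float = 0.01,
            seed: int = 0) -> "ABCResults":
        """Run rejection + logistic model choice and parameter estimation."""
        ref = reference if reference is not None else self.build_reference(
            sims_per_scenario, seed)
        post = abcd.abc_model_choice(ref, self.observed, top_frac=top_frac)
        params = {}
        for sc in self.scenarios:
            if abcd.SCENARIO_FREE_PARAMS[sc]:
                params[sc] = abcd.abc_parameter_estimate(
                    ref, self.observed, sc, top_frac=top_frac)
        return ABCResults(model=self, reference=ref, model_posterior=post,
                          parameter_posteriors=params, top_frac=top_frac)

    def validate(self, reference: abcd.ReferenceTable,
                 pods_per_scenario: int = 200, seed: int = 0,
                 top_frac: float = 0.01,
                 method: str = "logistic") -> abcd.ConfusionReport:
        """Confusion-error validation with prior-drawn pods."""
        return abcd.confusion_error(
            reference, self.priors, self.scenarios, pods_per_scenario,
            self.n_diploids, self.n_loci, self.maf_min, seed,
            top_frac=top_frac, method=method)


@dataclass
class ABCResults:
    """Fitted ABC model choice for one observed panel."""

    model: DemographicABC
    reference: abcd.ReferenceTable
    model_posterior: abcd.ModelPosterior
    parameter_posteriors: dict[int, abcd.ParameterPosterior]
    top_frac: float

    @property
    def best_scenario(self) -> int:
        return self.model_posterior.best()

    def model_table(self) -> pd.DataFrame:
        """Scenario likelihood table (percent, with 95% CI bounds)."""
        lg = self.model_posterior.logistic
        rj = self.model_posterior.rejection
        return pd.DataFrame({
            "logistic_pct": 100 * lg["prob"],
            "logistic_ci_low": 100 * lg["ci_low"],
            "logistic_ci_high": 100 * lg["ci_high"],
            "rejection_pct": 100 * rj["prob"],
        })

    def summary(self) -> str:
        lines = ["ABC demographic model choice",
                 "=" * 60,
                 f"loci: {self.model.n_loci}   diploids: {self.model.n_diploids}"
                 f"   MAF filter: {self.model.maf_min or 'none'}",
                 f"reference rows: {self.reference.n_rows}"
                 f"   accepted: {self.model_posterior.n_accepted}"
                 f" (top {100 * self.top_frac:g}%)"]
        if self.model_posterior.dropped_stats:
            lines.append("degenerate summaries dropped from distance: "
                         + ", ".join(self.model_posterior.dropped_stats))
        if self.model_posterior.out_of_range:
            lines.append("WARNING: observed summaries outside the simulated "
                         "range -- model fit is questionable")
        lines.append("")
        lines.append(f"{'scenario':>8} {'logistic %':>12} {'95% CI':>18} "
                     f"{'rejection %':>12}")
        t = self.model_table()
        for sc, row in t.iterrows():
            ci = f"({row.logistic_ci_low:5.1f}, {row.logistic_ci_high:5.1f})"
            lines.append(f"{sc:>8} {row.logistic_pct:>12.2f} {ci:>18} "
                         f"{row.rejection_pct:>12.2f}")
        for sc, pp in sorted(self.parameter_posteriors.items()):
            lines.append("")
            lines.append(f"scenario {sc} parameter posterior "
                         f"(n accepted = {pp.n_accepted})")
            lines.append(pp.table.round(1).to_string())
        return "\n".join(lines)


class TemporalOutlierScan:
    """Outlier scan of observed cohort frequencies against a drift null."""

    def __init__(self, observed: CohortFrequencySeries,
                 schedule: GrowthSchedule, plan: SamplingPlan | None = None,
                 alpha: float = 0.05, weighted: bool = False,
                 envelope_significant_only: bool = False):
        self.observed = observed
        self.schedule = schedule
        self.alpha = float(alpha)
        self.weighted = bool(weighted)
        self.envelope_significant_only = bool(envelope_significant_only)
        if plan is None:
            offset = schedule.start_year or 0.0
            years = tuple(int(round(y - offset)) for y in observed.years)
            n_dip = tuple(int(n) // 2 for n in np.asarray(observed.n_genes))
            plan = SamplingPlan(years=years, n_diploids=n_dip)
        self.plan = plan

    @classmethod
    def from_genotypes(cls, gm: gio.GenotypeMatrix, schedule: GrowthSchedule,
                       colony: str | None = None, min_presence: float = 0.8,
                       **kwargs) -> "TemporalOutlierScan":
        """Observed series from a genotype matrix: one colony, all cohorts.

        Applies the within-colony presence rule (80% in *all* cohorts), then
        per-cohort allele frequencies ordered by mean sampling year.
        """
        if colony is not None:
            gm = gm.take_samples((gm.samples["colony"] == colony).to_numpy())
        gm = gio.filter_group_presence(gm, min_presence, grouping="cohort",
                                       mode="all")
        ft = gio.allele_frequencies(gm, "cohort")
        years = gm.samples.groupby("cohort")["year"].mean()
        order = np.argsort([years[g] for g in ft.groups])
        freq = ft.freq[:, order]
        n_genes = np.array([int(np.median(ft.n_genes[:, j])) for j in order])
        series = CohortFrequencySeries(
            locus_ids=ft.locus_ids,
            years=np.array([years[ft.groups[j]] for j in order]),
            freq=freq, n_genes=n_genes, origin="observed")
        return cls(series, schedule, **kwargs)

    def fit(self, replicates_per_locus: int = 1, seed: int = 0,
            sampling_mode: str = "binomial_sample") -> "OutlierScanResults":
        """Simulate the null seeded from the oldest cohort and scan."""
        obs = self.observed
        complete = ~np.isnan(obs.freq).any(axis=1)
        obs_freq = obs.freq[complete]
        obs_ids = obs.locus_ids[complete]
        seed_freqs = obs_freq[:, 0]
        plan = self.plan if sampling_mode == self.plan.mode else SamplingPlan(
            years=self.plan.years, n_diploids=self.plan.n_diploids,
            mode=sampling_mode)
        sim = simulate_null(seed_freqs, self.schedule, plan,
                            replicates_per_locus=replicates_per_locus,
                            seed=seed, locus_ids=obs_ids)
        obs_series = CohortFrequencySeries(
            locus_ids=obs_ids, years=obs.years, freq=obs_freq,
            n_genes=obs.n_genes, origin="observed")
        obs_tr = outl.locus_trends(obs_series, weighted=self.weighted)
        sim_tr = outl.locus_trends(sim, weighted=self.weighted)
        env = outl.slope_envelope(
            sim_tr, significant_only=self.envelope_significant_only,
            alpha=self.alpha)
        report = outl.call_outliers(obs_tr, env, alpha=self.alpha)
        F, df, pF, t, pt = outl.compare_slope_distributions(obs_tr, sim_tr)
        report.sim_trends = sim_tr
        report.variance_F, report.variance_F_df, report.variance_F_p = F, df, pF
        report.mean_t, report.mean_t_p = t, pt
        return OutlierScanResults(model=self, report=report,
                                  simulated=sim, seed=seed,
                                  n_loci_dropped=int(np.sum(~complete)))


@dataclass
class OutlierScanResults:
    """Fitted temporal outlier scan."""

    model: TemporalOutlierScan
    report: outl.OutlierReport
    simulated: CohortFrequencySeries
    seed: int
    n_loci_dropped: int = 0

    @property
    def n_outliers(self) -> int:
        return self.report.n_outliers

    @property
    def outlier_ids(self) -> tuple[str, ...]:
        return self.report.outlier_ids

    def summary_row(self) -> pd.DataFrame:
        r = self.report
        return pd.DataFrame([{
            "envelope": r.envelope, "alpha": r.alpha,
            "n_outliers": r.n_outliers, "variance_F": r.variance_F,
            "variance_F_df1": r.variance_F_df[0],
            "variance_F_df2": r.variance_F_df[1],
            "variance_F_p": r.variance_F_p, "mean_t": r.mean_t,
            "mean_t_p": r.mean_t_p,
            "n_degenerate_excluded": r.n_degenerate_excluded,
        }])

    def summary(self) -> str:
        r = self.report
        lines = [
            "Temporal allele-frequency outlier scan",
            "=" * 60,
            f"observed loci: {len(r.obs_trends)} "
            f"(+{self.n_loci_dropped} dropped incomplete)"
            f"   simulated loci: {len(r.sim_trends)}",
            f"slope envelope (max |simulated slope|): {r.envelope:.6f} / yr",
            f"outliers (p < {r.alpha:g} and |slope| > envelope): "
            f"{r.n_outliers}",
            f"variance F = {r.variance_F:.3f}  df = {r.variance_F_df}  "
            f"p = {r.variance_F_p:.3g}",
            f"mean-slope t = {r.mean_t:.3f}  p = {r.mean_t_p:.3g}",
        ]
        return "\n".join(lines)
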