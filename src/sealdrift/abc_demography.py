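"""ABC model choice among four piecewise demographic scenarios for SNP panels.

The four scenarios describe a population of present effective diploid size
``N0`` (fixed at 100,000 in scaled units) looking backward in time:

1. constant size (null);
2. expansion: size ``Npe`` before the post-glacial expansion at ``te``
   (fixed at 10,000 scaled generations before present);
3. bottleneck: size ``Nb`` between the recovery time ``tr`` and the
   bottleneck onset ``tb``, size ``Npb`` earlier;
4. expansion followed (much later) by a bottleneck: all of the above.

Each candidate dataset is ``n_loci`` unlinked single-mutation coalescent SNPs
in a sample of ``n_diploids`` individuals, summarized by four statistics of
the per-locus gene-diversity distribution: the proportion of zero values, the
mean and variance of the nonzero values, and the mean of the complete
distribution.  Model choice is likelihood-free: candidate datasets simulated
from the parameter priors form a reference table, the closest fraction
(``top_frac``) of rows under a standardized Euclidean distance is retained,
and posterior model probabilities are estimated both by rejection (class
frequencies among accepted rows) and by weighted multinomial logistic
regression evaluated at the observed summaries.  Parameter posteriors come
from the standard logit-transform + weighted local-linear regression
adjustment of the accepted rows.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .coalescent import PiecewiseHistory, simulate_derived_counts
from ._mnlogit import MultinomialLogit

__all__ = [
    "ScenarioParams", "PriorSet", "SNPDataset", "SummaryStatVector",
    "ReferenceTable", "ModelPosterior", "ParameterPosterior", "ConfusionReport",
    "draw_parameters", "scenario_history", "simulate_snp_dataset",
    "summary_stats", "summary_stats_from_diversity",
    "build_reference_table", "abc_model_choice",
    "abc_parameter_estimate", "confusion_error",
]

N0_DEFAULT = 100_000.0
TE_DEFAULT = 10_000.0

#: free parameters per scenario, in reporting order
SCENARIO_FREE_PARAMS = {
    1: (),
    2: ("npe",),
    3: ("tr", "tb", "nb", "npb"),
    4: ("tr", "tb", "nb", "npb", "npe"),
}


@dataclass(frozen=True)
class PriorSet:
    """Uniform prior bounds (low, high) for the free scenario parameters."""

    npe: tuple[float, float] = (1_000.0, 10_000.0)
    tb: tuple[float, float] = (100.0, 5_000.0)
    tr: tuple[float, float] = (1.0, 100.0)
    nb: tuple[float, float] = (100.0, 10_000.0)
    npb: tuple[float, float] = (20_000.0, 100_000.0)

    def __post_init__(self):
        for name, (lo, hi) in asdict(self).items():
            if not lo < hi:
                raise ValueError(f"prior {name}: lower bound must be < upper")

    def bounds(self, name: str) -> tuple[float, float]:
        return getattr(self, name)


@dataclass(frozen=True)
class ScenarioParams:
    scenario: int
    n0: float = N0_DEFAULT
    te: float = TE_DEFAULT
    npe: float | None = None
    npb: float | None = None
    nb: float | None = None
    tr: float | None = None
    tb: float | None = None

    def __post_init__(self):
        if self.scenario not in SCENARIO_FREE_PARAMS:
            raise ValueError(f"unknown scenario {self.scenario}")
        for name in SCENARIO_FREE_PARAMS[self.scenario]:
            if getattr(self, name) is None:
                raise ValueError(f"scenario {self.scenario} requires {name}")
        if self.tr is not None and self.tb is not None and not self.tr < self.tb:
            raise ValueError("require tr < tb")
        if self.tb is not None and self.scenario == 4 and not self.tb < self.te:
            raise ValueError("require tb < te")


def scenario_history(params: ScenarioParams) -> PiecewiseHistory:
    """Step-function size history implied by a scenario's parameters."""
    s, p = params.scenario, params
    if s == 1:
        return PiecewiseHistory(sizes=(p.n0,))
    if s == 2:
        return PiecewiseHistory(sizes=(p.n0, p.npe), boundaries=(p.te,))
    if s == 3:
        return PiecewiseHistory(sizes=(p.n0, p.nb, p.npb), boundaries=(p.tr, p.tb))
    return PiecewiseHistory(
        sizes=(p.n0, p.nb, p.npb, p.npe), boundaries=(p.tr, p.tb, p.te))


def draw_parameters(scenario: int, priors: PriorSet,
                    rng: np.random.Generator) -> ScenarioParams:
    """Independent uniform draws of the scenario's free parameters.

    Draws violating the event ordering ``tr < tb`` are rejected and redrawn.
    """
    free = SCENARIO_FREE_PARAMS[scenario]
    for _ in range(10_000):
        vals = {name: rng.uniform(*priors.bounds(name)) for name in free}
        if "tr" in vals and "tb" in vals and not vals["tr"] < vals["tb"]:
            continue
        return ScenarioParams(scenario=scenario, **vals)
    raise RuntimeError("could not satisfy tr < tb from the given priors")


@dataclass
class SNPDataset:
    """Per-locus derived-allele counts out of ``n_genes`` sampled gene copies."""

    counts: np.ndarray
    n_genes: int
    maf_filtered: bool = False

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.n_genes < 2:
            raise ValueError("need >= 2 gene copies")
        if np.any(self.counts < 0) or np.any(self.counts > self.n_genes):
            raise ValueError("counts must lie in [0, n_genes]")

    @property
    def n_loci(self) -> int:
        return self.counts.size

    def gene_diversity(self, unbiased: bool = True) -> np.ndarray:
        p = self.counts / self.n_genes
        h = 2.0 * p * (1.0 - p)
        if unbiased:
            h *= self.n_genes / (self.n_genes - 1.0)
        return h


@dataclass(frozen=True)
class SummaryStatVector:
    """The four summaries of the per-locus gene-diversity distribution."""

    prop_zero: float
    mean_nonzero: float
    var_nonzero: float
    mean_all: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.prop_zero, self.mean_nonzero, self.var_nonzero, self.mean_all])

    @staticmethod
    def names() -> tuple[str, ...]:
        return ("prop_zero", "mean_nonzero", "var_nonzero", "mean_all")


def summary_stats(dataset: SNPDataset, unbiased: bool = True) -> SummaryStatVector:
    """Compute the four gene-diversity summaries of a SNP dataset.

    ``mean_nonzero`` and ``var_nonzero`` are defined as 0 when every locus is
    monomorphic; the variance uses the n-1 denominator.
    """
    return summary_stats_from_diversity(dataset.gene_diversity(unbiased=unbiased))


def summary_stats_from_diversity(h: np.ndarray) -> SummaryStatVector:
    """The four summaries of an arbitrary per-locus gene-diversity vector."""
    h = np.asarray(h, dtype=float)
    h = h[~np.isnan(h)]
    if h.size == 0:
        raise ValueError("no defined gene-diversity values")
    nz = h[h > 0]
    return SummaryStatVector(
        prop_zero=float(np.mean(h == 0)),
        mean_nonzero=float(nz.mean()) if nz.size else 0.0,
        var_nonzero=float(nz.var(ddof=1)) if nz.size > 1 else 0.0,
        mean_all=float(h.mean()),
    )


def _folded_ok(counts: np.ndarray, n: int, maf_min: float) -> np.ndarray:
    p = counts / n
    return np.minimum(p, 1.0 - p) >= maf_min


def simulate_snp_dataset(params: ScenarioParams, n_diploids: int, n_loci: int,
                         maf_min: float, rng: np.random.Generator) -> SNPDataset:
    """Simulate a panel of unlinked single-mutation SNPs under one scenario.

    Every locus is polymorphic in the sample by construction; when
    ``maf_min > 0`` loci failing the sample minor-allele-frequency threshold
    are redrawn until ``n_loci`` pass.
    """
    hist = scenario_history(params)
    n = 2 * n_diploids
    if maf_min <= 0:
        counts = simulate_derived_counts(hist, n, n_loci, rng)
        return SNPDataset(counts, n, maf_filtered=False)
    kept: list[np.ndarray] = []
    have = 0
    while have < n_loci:
        chunk = simulate_derived_counts(hist, n, max(n_loci - have, 256), rng)
        ok = chunk[_folded_ok(chunk, n, maf_min)]
        kept.append(ok)
        have += ok.size
    counts = np.concatenate(kept)[:n_loci]
    return SNPDataset(counts, n, maf_filtered=True)


@dataclass
class ReferenceTable:
    """Prior-predictive (scenario, parameters, summary statistics) rows."""

    scenario: np.ndarray          # (m,) int
    params: pd.DataFrame          # (m, 5) columns npe, npb, nb, tr, tb (NaN if unused)
    stats: np.ndarray             # (m, 4)
    priors: PriorSet
    n_diploids: int
    n_loci: int
    maf_min: float
    seed: int

    @property
    def n_rows(self) -> int:
        return self.scenario.size

    @property
    def stat_sd(self) -> np.ndarray:
        """Per-statistic standard deviations used for distance scaling."""
        return self.stats.std(axis=0, ddof=1)

    # -- persistence (TSV body with a JSON header line) --------------------
    def write(self, path) -> None:
        header = {
            "priors": asdict(self.priors), "n_diploids": self.n_diploids,
            "n_loci": self.n_loci, "maf_min": self.maf_min, "seed": self.seed,
        }
        df = self.params.copy()
        df.insert(0, "scenario", self.scenario)
        for i, name in enumerate(SummaryStatVector.names()):
            df[name] = self.stats[:, i]
        with open(path, "w") as fh:
            fh.write("#sealdrift-reftable " + json.dumps(header) + "\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "ReferenceTable":
        with open(path) as fh:
            first = fh.readline()
            if not first.startswith("#sealdrift-reftable "):
                raise ValueError(f"{path}: not a sealdrift reference table")
            header = json.loads(first.split(" ", 1)[1])
            df = pd.read_csv(io.StringIO(fh.read()), sep="\t")
        stats = df[list(SummaryStatVector.names())].to_numpy()
        params = df[["npe", "npb", "nb", "tr", "tb"]]
        pr = PriorSet(**{k: tuple(v) for k, v in header["priors"].items()})
        return cls(scenario=df["scenario"].to_numpy(int), params=params,
                   stats=stats, priors=pr, n_diploids=header["n_diploids"],
                   n_loci=header["n_loci"], maf_min=header["maf_min"],
                   seed=header["seed"])


def build_reference_table(priors: PriorSet, scenarios: tuple[int, ...],
                          sims_per_scenario: int, n_diploids: int, n_loci: int,
                          maf_min: float, seed: int,
                          progress: bool = False) -> ReferenceTable:
    """Simulate the ABC reference table, reproducibly from ``seed``."""
    rng = np.random.default_rng(seed)
    rows_sc, rows_par, rows_st = [], [], []
    for sc in scenarios:
        for _ in range(sims_per_scenario):
            par = draw_parameters(sc, priors, rng)
            ds = simulate_snp_dataset(par, n_diploids, n_loci, maf_min, rng)
            rows_sc.append(sc)
            rows_par.append([par.npe, par.npb, par.nb, par.tr, par.tb])
            rows_st.append(summary_stats(ds).as_array())
    params = pd.DataFrame(rows_par, columns=["npe", "npb", "nb", "tr", "tb"],
                          dtype=float)
    return ReferenceTable(scenario=np.array(rows_sc, dtype=int), params=params,
                          stats=np.array(rows_st), priors=priors,
                          n_diploids=n_diploids, n_loci=n_loci,
                          maf_min=maf_min, seed=seed)


# ---------------------------------------------------------------------------
# distances and acceptance

def _standardized_distances(ref: ReferenceTable, observed: SummaryStatVector):
    sds = ref.stat_sd
    keep = sds > 0
    obs = observed.as_array()
    diff = (ref.stats[:, keep] - obs[keep]) / sds[keep]
    d = np.sqrt(np.sum(diff * diff, axis=1))
    dropped = tuple(np.array(SummaryStatVector.names())[~keep])
    return d, keep, dropped


def _accept(d: np.ndarray, top_frac: float):
    n_acc = max(1, int(round(top_frac * d.size)))
    idx = np.argpartition(d, n_acc - 1)[:n_acc]
    idx = idx[np.argsort(d[idx], kind="stable")]
    dmax = d[idx[-1]]
    w = 1.0 - (d[idx] / dmax) ** 2 if dmax > 0 else np.ones(n_acc)
    w = np.maximum(w, 1e-12)  # Epanechnikov, strictly positive
    return idx, w


@dataclass
class ModelPosterior:
    """Posterior scenario probabilities with 95% intervals, both ABC flavors."""

    scenarios: tuple[int, ...]
    rejection: pd.DataFrame     # columns prob, ci_low, ci_high; index scenario
    logistic: pd.DataFrame
    n_accepted: int
    dropped_stats: tuple[str, ...] = ()
    out_of_range: bool = False

    def best(self, method: str = "logistic") -> int:
        table = self.logistic if method == "logistic" else self.rejection
        return int(table["prob"].idxmax())


def abc_model_choice(ref: ReferenceTable, observed: SummaryStatVector,
                     top_frac: float = 0.01, ridge: float = 1e-3) -> ModelPosterior:
    """Posterior model probabilities by rejection and by logistic regression.

    Distances are Euclidean on summaries standardized by the reference-table
    standard deviations (zero-variance summaries are dropped); the logistic
    step fits a multinomial model to the accepted rows with Epanechnikov
    weights on distance and evaluates it at the observed summaries.
    """
    d, keep, dropped = _standardized_distances(ref, observed)
    idx, w = _accept(d, top_frac)
    scens = tuple(sorted(np.unique(ref.scenario)))
    obs = observed.as_array()
    out = bool(np.any(obs[keep] < ref.stats[:, keep].min(axis=0)) or
               np.any(obs[keep] > ref.stats[:, keep].max(axis=0)))

    # rejection: class frequencies among accepted, binomial normal CIs
    z = norm.ppf(0.975)
    rej = []
    n_acc = idx.size
    for sc in scens:
        p = float(np.mean(ref.scenario[idx] == sc))
        se = np.sqrt(p * (1 - p) / n_acc)
        rej.append((p, max(p - z * se, 0.0), min(p + z * se, 1.0)))
    rejection = pd.DataFrame(rej, index=list(scens),
                             columns=["prob", "ci_low", "ci_high"])

    # logistic regression on accepted rows (standardized predictors)
    present = tuple(sorted(np.unique(ref.scenario[idx])))
    probs = np.zeros(len(scens))
    lo = np.zeros(len(scens))
    hi = np.zeros(len(scens))
    if len(present) == 1:
        j = scens.index(present[0])
        probs[j] = lo[j] = hi[j] = 1.0
    else:
        sds = ref.stat_sd
        X = (ref.stats[np.ix_(idx, np.flatnonzero(keep))] - obs[keep]) / sds[keep]
        y = np.searchsorted(present, ref.scenario[idx])
        model = MultinomialLogit(n_classes=len(present), ridge=ridge)
        model.fit(X, y, weights=w)
        pi, plo, phi = model.predict_proba_ci(np.zeros(X.shape[1]))
        for c, sc in enumerate(present):
            j = scens.index(sc)
            probs[j], lo[j], hi[j] = pi[c], plo[c], phi[c]
    logistic = pd.DataFrame(
        {"prob": probs, "ci_low": lo, "ci_high": hi}, index=list(scens))

    return ModelPosterior(scenarios=scens, rejection=rejection,
                          logistic=logistic, n_accepted=n_acc,
                          dropped_stats=dropped, out_of_range=out)


@dataclass
class ParameterPosterior:
    """Adjusted-posterior location and 95% interval per free parameter."""

    scenario: int
    table: pd.DataFrame  # index parameter; columns mean, median, q025, q975
    n_accepted: int
    clamped: int = 0     # accepted draws nudged off a prior bound pre-logit


def _weighted_quantile(x: np.ndarray, w: np.ndarray, q) -> np.ndarray:
    order = np.argsort(x)
    x, w = x[order], w[order]
    cw = np.cumsum(w) - 0.5 * w
    cw /= w.sum()
    return np.interp(q, cw, x)


def abc_parameter_estimate(ref: ReferenceTable, observed: SummaryStatVector,
                           scenario: int, top_frac: float = 0.01,
                           clamp: float = 1e-6) -> ParameterPosterior:
    """Regression-adjusted parameter posterior for one scenario.

    Accepted parameter draws are logit-transformed to their prior bounds,
    shifted by a weighted (Epanechnikov) local-linear regression on the
    standardized summary differences, back-transformed, and summarized by
    weighted mean/median/2.5%/97.5% quantiles -- all guaranteed inside the
    prior bounds by the transform.
    """
    free = SCENARIO_FREE_PARAMS[scenario]
    if not free:
        raise ValueError(f"scenario {scenario} has no free parameters")
    mask = ref.scenario == scenario
    if not np.any(mask):
        raise ValueError(f"reference table has no scenario-{scenario} rows")
    sub_stats = ref.stats[mask]
    sub_params = ref.params.loc[mask]

    sds = ref.stat_sd
    keep = sds > 0
    obs = observed.as_array()
    diff = (sub_stats[:, keep] - obs[keep]) / sds[keep]
    d = np.sqrt(np.sum(diff * diff, axis=1))
    idx, w = _accept(d, top_frac)
    X = np.hstack([np.ones((idx.size, 1)), diff[idx]])
    sw = np.sqrt(w)

    rows = []
    clamped = 0
    for name in free:
        lo_b, hi_b = ref.priors.bounds(name)
        theta = sub_params[name].to_numpy()[idx]
        u = (theta - lo_b) / (hi_b - lo_b)
        n_cl = int(np.sum((u <= clamp) | (u >= 1 - clamp)))
        clamped += n_cl
        z = logit(np.clip(u, clamp, 1 - clamp))
        beta, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
        z_adj = z - diff[idx] @ beta[1:]
        theta_adj = lo_b + (hi_b - lo_b) * expit(z_adj)
        mean = float(np.average(theta_adj, weights=w))
        med, q025, q975 = _weighted_quantile(theta_adj, w, [0.5, 0.025, 0.975])
        rows.append((name, mean, med, q025, q975))
    table = pd.DataFrame(rows, columns=["param", "mean", "median", "q025",
                                        "q975"]).set_index("param")
    return ParameterPosterior(scenario=scenario, table=table,
                              n_accepted=idx.size, clamped=clamped)


@dataclass
class ConfusionReport:
    """Model-choice validation on pods (pseudo-observed datasets).

    ``selection`` counts pods by (true scenario row, selected scenario
    column); ``error_rate[s]`` is the fraction of pods simulated under the
    OTHER scenarios for which ``s`` had the highest posterior, pooling the
    alternate scenarios equally.
    """

    selection: pd.DataFrame
    error_rate: pd.Series
    pods_per_scenario: int
    method: str

    @property
    def error_rate_pct(self) -> pd.Series:
        return 100.0 * self.error_rate


def confusion_error(ref: ReferenceTable, priors: PriorSet,
                    scenarios: tuple[int, ...], pods_per_scenario: int,
                    n_diploids: int, n_loci: int, maf_min: float, seed: int,
                    top_frac: float = 0.01,
                    method: str = "logistic") -> ConfusionReport:
    """Estimate per-scenario wrong-selection rates from prior-drawn pods."""
    rng = np.random.default_rng(seed)
    scens = tuple(scenarios)
    counts = pd.DataFrame(0, index=list(scens), columns=list(scens))
    for true_sc in scens:
        for _ in range(pods_per_scenario):
            par = draw_parameters(true_sc, priors, rng)
            ds = simulate_snp_dataset(par, n_diploids, n_loci, maf_min, rng)
            post = abc_model_choice(ref, summary_stats(ds), top_frac=top_frac)
            counts.loc[true_sc, post.best(method)] += 1
    err = {}
    for sc in scens:
        others = [s for s in scens if s != sc]
        wrong = counts.loc[others, sc].sum()
        err[sc] = wrong / (pods_per_scenario * len(others))
    return ConfusionReport(selection=counts, error_rate=pd.Series(err),
                           pods_per_scenario=pods_per_scenario, method=method)
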