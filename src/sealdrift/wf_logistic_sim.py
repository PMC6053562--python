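"""Forward Wright-Fisher drift under deterministic logistic census growth.

This is the neutral null model for the temporal outlier scan: a single
population whose census size follows the discrete logistic recurrence

    N_{t+1} = N_t + r N_t (1 - N_t / K)

with one Wright-Fisher binomial drift step per calendar year, applied to each
locus independently *before* the census update.  Mutation is not modeled; the
scan covers a few decades, over which new mutations contribute negligibly.
Trajectories are seeded from observed allele frequencies (typically the
oldest sequenced cohort) and sampled at the years of the sequenced cohorts,
either as true population frequencies or with binomial cohort-sampling noise.

Two literature parameterizations ship as presets: the Sable Island gray seal
recovery (start 5,000; r = 0.13 for 25 years then 0.04 for 20; K = 500,000)
and the Northeast-US harbor seal recovery (start 67,500; r = 0.066;
K = 100,000).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GrowthSchedule", "SamplingPlan", "CohortFrequencySeries",
    "logistic_step", "drift_step", "simulate_null",
    "GRAY_SEAL_SABLE", "HARBOR_SEAL_NEUS",
]


@dataclass(frozen=True)
class GrowthSchedule:
    """Piecewise-logistic census trajectory for a recovering population.

    ``segments`` is an ordered list of ``(duration_years, r)`` pairs; ``K``
    is the carrying capacity in diploids and ``ne_ratio`` scales census to
    effective size for the drift step.
    """

    n_start: int
    segments: tuple[tuple[int, float], ...]
    K: float
    ne_ratio: float = 1.0
    start_year: float | None = None

    def __post_init__(self):
        if self.n_start < 2:
            raise ValueError("n_start must be >= 2")
        if self.K <= 0:
            raise ValueError("K must be positive")
        if not 0 < self.ne_ratio <= 1:
            raise ValueError("ne_ratio must be in (0, 1]")
        if not self.segments or any(
                d <= 0 or int(d) != d for d, _ in self.segments):
            raise ValueError("segment durations must be positive integers")

    @property
    def duration(self) -> int:
        return int(sum(d for d, _ in self.segments))

    def census_sizes(self) -> np.ndarray:
        """Deterministic census size at each year 0..duration (inclusive)."""
        sizes = [self.n_start]
        n = self.n_start
        for dur, r in self.segments:
            for _ in range(int(dur)):
                n = logistic_step(n, r, self.K)
                sizes.append(n)
        return np.array(sizes, dtype=np.int64)


#: Sable Island gray seals, 1970-2015 recovery
GRAY_SEAL_SABLE = GrowthSchedule(
    n_start=5_000, segments=((25, 0.13), (20, 0.04)), K=500_000.0,
    start_year=1970.0)

#: Northeast United States harbor seals, 1995-2015 recovery
HARBOR_SEAL_NEUS = GrowthSchedule(
    n_start=67_500, segments=((20, 0.066),), K=100_000.0, start_year=1995.0)


@dataclass(frozen=True)
class SamplingPlan:
    """When (years since schedule start) and how cohorts are sampled."""

    years: tuple[int, ...]
    n_diploids: tuple[int, ...] = ()
    mode: str = "binomial_sample"  # or "population_freq"

    def __post_init__(self):
        y = np.asarray(self.years)
        if y.size == 0 or np.any(np.diff(y) <= 0) or np.any(y < 0):
            raise ValueError("years must be non-negative and strictly increasing")
        if self.mode not in ("binomial_sample", "population_freq"):
            raise ValueError(f"unknown sampling mode {self.mode!r}")
        if self.mode == "binomial_sample":
            if len(self.n_diploids) != len(self.years):
                raise ValueError("need one sample size per time point")
            if any(n < 1 for n in self.n_diploids):
                raise ValueError("sample sizes must be >= 1")


@dataclass
class CohortFrequencySeries:
    """Per-locus allele frequencies at dated time points with sample sizes.

    The common currency of the temporal scan: both observed cohort
    frequencies and simulated drift trajectories are carried in this form.
    ``freq`` has shape ``(n_loci, n_timepoints)``.
    """

    locus_ids: np.ndarray
    years: np.ndarray
    freq: np.ndarray
    n_genes: np.ndarray          # per time point
    origin: str = "observed"     # or "simulated"
    seed: int | None = None

    def __post_init__(self):
        self.freq = np.asarray(self.freq, dtype=float)
        self.years = np.asarray(self.years, dtype=float)
        self.locus_ids = np.asarray(self.locus_ids)
        self.n_genes = np.asarray(self.n_genes)
        if self.freq.shape != (self.locus_ids.size, self.years.size):
            raise ValueError("freq must be (n_loci, n_timepoints)")
        with np.errstate(invalid="ignore"):
            bad = (self.freq < 0) | (self.freq > 1)
        if np.any(bad[~np.isnan(self.freq)]):
            raise ValueError("frequencies must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        """Long-format (locus_id, year, freq, n_genes) table."""
        loci = np.repeat(self.locus_ids, self.years.size)
        years = np.tile(self.years, self.locus_ids.size)
        ngen = np.tile(np.asarray(self.n_genes), self.locus_ids.size)
        return pd.DataFrame({"locus_id": loci, "year": years,
                             "freq": self.freq.ravel(), "n_genes": ngen})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, origin: str = "observed"):
        wide = df.pivot(index="locus_id", columns="year", values="freq")
        ngen = df.pivot(index="locus_id", columns="year", values="n_genes")
        return cls(locus_ids=wide.index.to_numpy(),
                   years=wide.columns.to_numpy(float),
                   freq=wide.to_numpy(), n_genes=ngen.iloc[0].to_numpy(),
                   origin=origin)


def logistic_step(n: float, r: float, K: float) -> int:
    """One year of discrete logistic growth, rounded to the nearest integer.

    Ties round to even; the result is floored at 2 diploids so drift never
    divides by zero.
    """
    if K <= 0:
        raise ValueError("K must be positive")
    nxt = n + r * n * (1.0 - n / K)
    return max(int(np.rint(nxt)), 2)


def drift_step(p: np.ndarray, n_e: float, rng: np.random.Generator) -> np.ndarray:
    """One Wright-Fisher generation: Binomial(2*Ne, p) / (2*Ne) per locus.

    0 and 1 are absorbing.
    """
    n2 = int(round(2 * n_e))
    if n2 < 2:
        raise ValueError("effective size must be >= 1 diploid")
    p = np.asarray(p, dtype=float)
    return rng.binomial(n2, p) / n2


def simulate_null(series0: np.ndarray, schedule: GrowthSchedule,
                  plan: SamplingPlan, replicates_per_locus: int = 1,
                  seed: int | None = None,
                  locus_ids: np.ndarray | None = None) -> CohortFrequencySeries:
    """Neutral drift trajectories seeded from observed frequencies.

    Each year applies drift (at ``ne_ratio`` times the census size) *then*
    the logistic census update.  At each plan time point the population
    frequency is recorded directly or resampled as ``Binomial(2 n_c, p)``
    cohort allele counts, per the plan's mode.  Fully deterministic given
    ``seed``; no mutation.
    """
    p0 = np.asarray(series0, dtype=float)
    if np.any((p0 < 0) | (p0 > 1)):
        raise ValueError("seed frequencies must lie in [0, 1]")
    if max(plan.years) > schedule.duration:
        raise ValueError("sampling plan extends beyond the growth schedule")
    rng = np.random.default_rng(seed)
    n_loci = p0.size
    p = np.repeat(p0, replicates_per_locus)
    census = schedule.census_sizes()
    sample_at = dict.fromkeys(int(y) for y in plan.years)

    out = np.empty((p.size, len(plan.years)))
    n_genes_out = np.empty(len(plan.years), dtype=np.int64)

    def record(j: int, year: int) -> None:
        if plan.mode == "binomial_sample":
            n2 = 2 * int(plan.n_diploids[j])
            out[:, j] = rng.binomial(n2, p) / n2
            n_genes_out[j] = n2
        else:
            out[:, j] = p
            n_genes_out[j] = 2 * census[year]

    j = 0
    if 0 in sample_at:
        record(0, 0)
        j += 1
    for year in range(1, schedule.duration + 1):
        n_e = max(schedule.ne_ratio * census[year - 1], 1.0)
        p = drift_step(p, n_e, rng)
        if year in sample_at:
            record(j, year)
            j += 1
        if j == len(plan.years):
            break

    if locus_ids is None:
        locus_ids = np.array([f"L{i:06d}" for i in range(n_loci)])
    if replicates_per_locus > 1:
        locus_ids = np.array([f"{lid}_rep{r}" for lid in locus_ids
                              for r in range(replicates_per_locus)])
    years_abs = np.asarray(plan.years, dtype=float)
    if schedule.start_year is not None:
        years_abs = years_abs + schedule.start_year
    return CohortFrequencySeries(
        locus_ids=np.asarray(locus_ids), years=years_abs, freq=out,
        n_genes=n_genes_out, origin="simulated", seed=seed)
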