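"""Study-shaped synthetic datasets with known ground truth.

Generates the two kinds of inputs the pipeline consumes, without any
downloads: (i) multi-cohort diploid genotype matrices whose allele
frequencies drift forward under the Wright-Fisher/logistic-growth null --
optionally with planted loci under deterministic positive selection -- with
Hardy-Weinberg genotype sampling and i.i.d. missingness; and (ii)
scenario-labeled coalescent SNP datasets (pods) for validating the ABC
stage.  Every generator is reproducible from its seed and returns a
:class:`TruthTable` recording everything that was planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abc_demography import (PriorSet, ScenarioParams, SNPDataset,
                             draw_parameters, simulate_snp_dataset)
from .genotype_io import MISSING, GenotypeMatrix
from .wf_logistic_sim import GRAY_SEAL_SABLE, GrowthSchedule, drift_step

__all__ = [
    "TruthTable", "CohortSpec", "sable_like_design",
    "sample_initial_frequencies", "selection_update",
    "generate_cohort_study", "generate_abc_study",
]


@dataclass(frozen=True)
class CohortSpec:
    """One sampled cohort: colony, label, sampling year offset, diploids."""

    colony: str
    cohort: str
    year_offset: int   # whole years since the schedule start
    n_diploids: int


def sable_like_design() -> tuple[CohortSpec, ...]:
    """Five cohorts over 45 years in one colony, 28-32 diploids each."""
    return (
        CohortSpec("Sable", "1973-74", 4, 28),
        CohortSpec("Sable", "1985", 15, 29),
        CohortSpec("Sable", "1998", 28, 32),
        CohortSpec("Sable", "2004", 34, 32),
        CohortSpec("Sable", "2015", 45, 32),
    )


@dataclass
class TruthTable:
    """Ground truth of a synthetic dataset."""

    seed: int
    founding_freqs: np.ndarray
    planted: dict[str, float] = field(default_factory=dict)  # locus_id -> s
    schedule: GrowthSchedule | None = None
    scenario_params: ScenarioParams | None = None
    missing_rate: float = 0.0

    def planted_frame(self) -> pd.DataFrame:
        return pd.DataFrame(sorted(self.planted.items()),
                            columns=["locus_id", "s"])

    def write(self, path) -> None:
        self.planted_frame().to_csv(path, sep="\t", index=False)


def sample_initial_frequencies(n_loci: int, spectrum: str = "neutral_sfs",
                               maf_min: float = 0.0,
                               rng: np.random.Generator | None = None,
                               beta_params: tuple[float, float] = (0.5, 0.5),
                               grid: int = 100) -> np.ndarray:
    """Founding allele frequencies from a named spectrum.

    ``neutral_sfs`` draws from a gene-count grid with mass proportional to
    1/i (the standing-variation spectrum of a neutral equilibrium
    population, low-frequency enriched); ``beta(a, b)`` and ``uniform`` are
    alternatives.  All draws are truncated to ``[maf_min, 1 - maf_min]``.
    """
    if not 0 <= maf_min < 0.5:
        raise ValueError("maf_min must be in [0, 0.5)")
    rng = np.random.default_rng() if rng is None else rng
    if spectrum == "uniform":
        return rng.uniform(maf_min, 1.0 - maf_min, size=n_loci)
    if spectrum == "beta":
        out = np.empty(0)
        while out.size < n_loci:
            draw = rng.beta(*beta_params, size=2 * n_loci)
            out = np.concatenate(
                [out, draw[(draw >= maf_min) & (draw <= 1 - maf_min)]])
        return out[:n_loci]
    if spectrum == "neutral_sfs":
        freqs = np.arange(1, grid) / grid
        weights = 1.0 / np.arange(1, grid)
        ok = (freqs >= maf_min) & (freqs <= 1 - maf_min)
        freqs, weights = freqs[ok], weights[ok]
        return rng.choice(freqs, size=n_loci, p=weights / weights.sum())
    raise ValueError(f"unknown spectrum {spectrum!r}")


def selection_update(p, s: float):
    """Deterministic one-year frequency update under positive selection.

    Relative fitness 1 + s for the focal allele: p' = p(1+s) / (1 + p s).
    Fixed frequencies (0 and 1) are unchanged.
    """
    if s <= -1:
        raise ValueError("s must be > -1")
    p = np.asarray(p, dtype=float)
    out = p * (1.0 + s) / (1.0 + p * s)
    return out if out.ndim else float(out)


def generate_cohort_study(design: tuple[CohortSpec, ...] | None = None,
                          schedule: GrowthSchedule = GRAY_SEAL_SABLE,
                          n_loci: int = 1000, n_planted: int = 0,
                          s: float = 0.15, missing_rate: float = 0.0,
                          spectrum: str = "neutral_sfs",
                          planted_p0: float | None = None,
                          seed: int = 0) -> tuple[GenotypeMatrix, TruthTable]:
    """Forward-simulate a multi-cohort genotype study with known truth.

    Per locus, the population allele frequency evolves by one annual
    Wright-Fisher drift step (preceded, for planted loci, by the
    deterministic selection update) and then the logistic census update.  At
    each cohort's sampling year, ``2n`` gene copies are drawn binomially and
    paired into Hardy-Weinberg diploid genotypes; each genotype is then
    masked MISSING independently at ``missing_rate``.
    """
    design = sable_like_design() if design is None else tuple(design)
    if not design:
        raise ValueError("design must contain at least one cohort")
    if max(c.year_offset for c in design) > schedule.duration:
        raise ValueError("design years extend beyond the growth schedule")
    rng = np.random.default_rng(seed)
    p = sample_initial_frequencies(n_loci, spectrum=spectrum, rng=rng)
    locus_ids = np.array([f"L{i:06d}" for i in range(n_loci)], dtype=object)
    planted_idx = rng.choice(n_loci, size=n_planted, replace=False) \
        if n_planted else np.empty(0, dtype=int)
    if planted_p0 is not None:
        p[planted_idx] = planted_p0
    founding = p.copy()
    sel_mask = np.zeros(n_loci, dtype=bool)
    sel_mask[planted_idx] = True

    by_year: dict[int, list[CohortSpec]] = {}
    for c in design:
        by_year.setdefault(int(c.year_offset), []).append(c)

    census = schedule.census_sizes()
    blocks, meta_rows = [], []

    def sample_cohorts(year: int) -> None:
        for c in by_year.get(year, []):
            dos = rng.binomial(1, p[:, None], size=(n_loci, c.n_diploids)) \
                + rng.binomial(1, p[:, None], size=(n_loci, c.n_diploids))
            dos = dos.astype(np.int8)
            if missing_rate > 0:
                mask = rng.random(dos.shape) < missing_rate
                dos[mask] = MISSING
            blocks.append(dos)
            start = schedule.start_year if schedule.start_year is not None else 1970.0
            for k in range(c.n_diploids):
                meta_rows.append((f"{c.colony}_{c.cohort}_{k:03d}", c.colony,
                                  c.cohort, start + c.year_offset))

    sample_cohorts(0)
    for year in range(1, schedule.duration + 1):
        p = np.where(sel_mask, selection_update(p, s), p)
        n_e = max(schedule.ne_ratio * census[year - 1], 1.0)
        p = drift_step(p, n_e, rng)
        sample_cohorts(year)

    calls = np.concatenate(blocks, axis=1)
    # the container requires every locus typed at least once
    all_missing = (calls == MISSING).all(axis=1)
    for i in np.flatnonzero(all_missing):
        j = rng.integers(calls.shape[1])
        calls[i, j] = 0
    samples = pd.DataFrame(meta_rows,
                           columns=["sample_id", "colony", "cohort", "year"])
    gm = GenotypeMatrix(locus_ids=locus_ids, radlocus_ids=locus_ids.copy(),
                        calls=calls, samples=samples)
    truth = TruthTable(seed=seed, founding_freqs=founding,
                       planted={locus_ids[i]: s for i in planted_idx},
                       schedule=schedule, missing_rate=missing_rate)
    return gm, truth


def generate_abc_study(scenario: int,
                       params_or_priors: ScenarioParams | PriorSet,
                       n_diploids: int, n_loci: int, maf_min: float,
                       seed: int = 0) -> tuple[SNPDataset, TruthTable]:
    """A pod: one scenario-labeled coalescent SNP dataset with its truth."""
    rng = np.random.default_rng(seed)
    if isinstance(params_or_priors, PriorSet):
        params = draw_parameters(scenario, params_or_priors, rng)
    else:
        params = params_or_priors
        if params.scenario != scenario:
            raise ValueError("params.scenario disagrees with scenario")
    ds = simulate_snp_dataset(params, n_diploids, n_loci, maf_min, rng)
    truth = TruthTable(seed=seed, founding_freqs=np.empty(0),
                       scenario_params=params)
    return ds, truth
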