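"""Cohort diversity metrics: rarefied allelic richness and gene diversity.

Allelic richness ``A_R`` is the expected number of distinct alleles in a
hypergeometric subsample of ``g`` gene copies,

    A_R = sum_i [ 1 - C(N - N_i, g) / C(N, g) ],

with ``N_i`` the count of allele ``i`` and ``N`` the total; rarefaction to a
common ``g`` makes cohorts of different sizes comparable.  Gene diversity
(expected heterozygosity) is ``2 p (1 - p)`` for a biallelic locus, with an
optional ``n/(n-1)`` small-sample correction.  Group comparisons treat loci
as replicates: one-way fixed-effects ANOVA across cohorts, pooled-variance
two-sample t, or a two-sided variance-ratio F.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .genotype_io import GenotypeMatrix, allele_frequencies

__all__ = [
    "DiversitySummary", "GroupComparison", "expected_heterozygosity",
    "allelic_richness", "per_locus_diversity", "summarize_group",
    "compare_groups",
]


def expected_heterozygosity(freq, n_genes=None, unbiased: bool = False):
    """Biallelic gene diversity 2p(1-p), optionally n/(n-1)-corrected.

    NaN frequencies (no typed copies in the group) propagate to NaN.
    """
    p = np.asarray(freq, dtype=float)
    h = 2.0 * p * (1.0 - p)
    if unbiased:
        n = np.asarray(n_genes, dtype=float)
        if np.any(n[~np.isnan(p)] < 2):
            raise ValueError("unbiased estimator needs n_genes >= 2")
        h = h * n / (n - 1.0)
    return h if h.ndim else float(h)


def allelic_richness(allele_counts, g: int) -> float:
    """Rarefied allele count: expected distinct alleles among g of N copies."""
    counts = np.asarray(allele_counts, dtype=np.int64)
    N = int(counts.sum())
    if not 1 <= g <= N:
        raise ValueError(f"g must lie in [1, {N}]")
    # 1 - C(N - Ni, g)/C(N, g), with the ratio zero when N - Ni < g
    out = 0.0
    for ni in counts:
        if ni == 0:
            continue
        if N - ni < g:
            out += 1.0
        else:
            out += 1.0 - math.exp(
                gammaln(N - ni + 1) - gammaln(N - ni - g + 1)
                - gammaln(N + 1) + gammaln(N - g + 1))
    return out


def _richness_biallelic(alt: np.ndarray, n: np.ndarray, g: int) -> np.ndarray:
    """Vectorized A_R over biallelic loci: alt counts out of n gene copies."""
    alt = alt.astype(float)
    n = n.astype(float)
    out = np.full(alt.shape, np.nan)

    def miss_term(ni):  # P(allele with count ni absent from a g-subsample)
        rem = n - ni
        can_miss = rem >= g
        rem_s = np.where(can_miss, rem, g)  # safe args for gammaln
        logratio = (gammaln(rem_s + 1) - gammaln(rem_s - g + 1)
                    - gammaln(n + 1) + gammaln(np.maximum(n - g + 1, 1)))
        return np.where(can_miss, np.exp(logratio), 0.0)

    ok = n >= g
    ref = n - alt
    term = np.zeros_like(alt)
    for ni in (alt, ref):
        present = ni > 0
        term += np.where(present, 1.0 - miss_term(ni), 0.0)
    out[ok] = term[ok]
    return out


@dataclass
class DiversitySummary:
    """Per-group mean/SD of per-locus A_R and H_E at rarefaction size g."""

    group: str
    g: int
    n_samples: int
    ar_mean: float
    ar_sd: float
    he_mean: float
    he_sd: float
    per_locus: pd.DataFrame  # columns ar, he indexed by locus_id


@dataclass(frozen=True)
class GroupComparison:
    """A cohort/colony comparison on per-locus diversity values."""

    kind: str                # "anova" | "ttest" | "varF"
    statistic: float
    df: tuple
    p_value: float
    degenerate: bool = False


def per_locus_diversity(gm: GenotypeMatrix, grouping: str, g: int | str = "auto",
                        unbiased_he: bool = False) -> dict[str, pd.DataFrame]:
    """Per-locus A_R and H_E per group; NaN where a locus has no typed copies."""
    ft = allele_frequencies(gm, grouping)
    groups = ft.groups
    n_genes = ft.n_genes
    if g == "auto":
        pos = n_genes[n_genes > 0]
        if pos.size == 0:
            raise ValueError("no typed gene copies anywhere")
        g = int(pos.min())
    g = int(g)
    out = {}
    for j, grp in enumerate(groups):
        freq = ft.freq[:, j]
        ng = n_genes[:, j]
        alt = np.round(freq * ng)
        ar = _richness_biallelic(alt, ng, g)
        he = expected_heterozygosity(freq, ng if unbiased_he else None,
                                     unbiased=unbiased_he)
        he = np.where(ng > 0, he, np.nan)
        out[grp] = pd.DataFrame({"ar": ar, "he": he},
                                index=pd.Index(gm.locus_ids, name="locus_id"))
    out["__g__"] = g
    return out


def summarize_group(gm: GenotypeMatrix, grouping: str, g: int | str = "auto",
                    unbiased_he: bool = False) -> list[DiversitySummary]:
    """Mean and SD over loci of A_R and H_E for every sample group."""
    per = per_locus_diversity(gm, grouping, g=g, unbiased_he=unbiased_he)
    g_used = per.pop("__g__")
    labels = gm.group_labels(grouping)
    out = []
    for grp, df in per.items():
        n_samp = int(np.sum(labels == grp))
        ar = df["ar"].dropna()
        he = df["he"].dropna()
        out.append(DiversitySummary(
            group=grp, g=g_used, n_samples=n_samp,
            ar_mean=float(ar.mean()), ar_sd=float(ar.std(ddof=1)),
            he_mean=float(he.mean()), he_sd=float(he.std(ddof=1)),
            per_locus=df))
    return out


def compare_groups(values: dict[str, np.ndarray],
                   design: str = "anova") -> GroupComparison:
    """Compare per-locus diversity values between sample groups.

    ``anova``: one-way fixed-effects F across all groups.
    ``ttest``: pooled-variance two-sample t (exactly 2 groups).
    ``varF``:  two-sided variance-ratio F = var(second)/var(first).
    Zero-variance degeneracies return a NaN p with the degenerate flag set.
    """
    groups = [np.asarray(v, dtype=float) for v in values.values()]
    groups = [v[~np.isnan(v)] for v in groups]
    if len(groups) < 2 or any(v.size < 2 for v in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    if design == "anova":
        k = len(groups)
        ntot = sum(v.size for v in groups)
        gm_ = np.concatenate(groups).mean()
        ssb = sum(v.size * (v.mean() - gm_) ** 2 for v in groups)
        ssw = sum(((v - v.mean()) ** 2).sum() for v in groups)
        df = (k - 1, ntot - k)
        if ssw == 0:
            return GroupComparison("anova", np.inf if ssb > 0 else 0.0, df,
                                   np.nan, degenerate=True)
        F = (ssb / df[0]) / (ssw / df[1])
        return GroupComparison("anova", float(F), df,
                               float(stats.f.sf(F, *df)))
    if design == "ttest":
        if len(groups) != 2:
            raise ValueError("ttest needs exactly 2 groups")
        a, b = groups
        sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (
            a.size + b.size - 2)
        df = (a.size + b.size - 2,)
        if sp2 == 0:
            diff = a.mean() - b.mean()
            t = 0.0 if diff == 0 else np.inf * np.sign(diff)
            return GroupComparison("ttest", float(t), df,
                                   1.0 if diff == 0 else np.nan,
                                   degenerate=True)
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / a.size + 1 / b.size))
        return GroupComparison("ttest", float(t), df,
                               float(2 * stats.t.sf(abs(t), df[0])))
    if design == "varF":
        if len(groups) != 2:
            raise ValueError("varF needs exactly 2 groups")
        a, b = groups
        va, vb = a.var(ddof=1), b.var(ddof=1)
        df = (b.size - 1, a.size - 1)
        if va == 0:
            return GroupComparison("varF", np.nan, df, np.nan, degenerate=True)
        F = vb / va
        cdf = stats.f.cdf(F, *df)
        return GroupComparison("varF", float(F), df,
                               float(2 * min(cdf, 1 - cdf)))
    raise ValueError(f"unknown design {design!r}")


def diversity_table(summaries: list[DiversitySummary]) -> pd.DataFrame:
    """Cohort-summary layout: group, N, A_R mean (SD), H_E mean (SD), g."""
    rows = [(s.group, s.n_samples, s.ar_mean, s.ar_sd, s.he_mean, s.he_sd, s.g)
            for s in summaries]
    return pd.DataFrame(rows, columns=["group", "N", "ar_mean", "ar_sd",
                                       "he_mean", "he_sd", "g"])
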