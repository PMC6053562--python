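"""Diploid biallelic SNP panels: data model, VCF/metadata I/O, locus filters.

The central container is :class:`GenotypeMatrix`: a loci x samples matrix of
alternate-allele dosages (0/1/2, with -1 for missing) plus per-sample
metadata (colony, cohort, decimal sampling year) and per-locus bookkeeping
(RAD-locus grouping, coordinates).  The filters implement the RADseq panel
rules used throughout: group-presence thresholds (the "r80" rule and its
within-colony "all cohorts" variant), a pooled minor-allele-frequency
threshold, and one-SNP-per-RAD-locus thinning.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

__all__ = [
    "MISSING", "SampleRecord", "GenotypeMatrix", "FrequencyTable",
    "read_genotypes", "write_genotypes", "filter_group_presence",
    "filter_maf", "select_one_snp_per_radlocus", "allele_frequencies",
    "parse_year",
]

METADATA_COLUMNS = ("sample_id", "colony", "cohort", "year")


def parse_year(value) -> float:
    """Decimal calendar year; cohort spans like '1973-74' give the midpoint."""
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    s = str(value).strip()
    m = re.fullmatch(r"(\d{4})\s*[-–/]\s*(\d{2,4})", s)
    if m:
        y0 = int(m.group(1))
        y1 = int(m.group(2))
        if y1 < 100:
            y1 += (y0 // 100) * 100
        return (y0 + y1) / 2.0
    return float(s)


@dataclass(frozen=True)
class SampleRecord:
    """One sequenced individual with its sampling design labels."""

    sample_id: str
    colony: str
    cohort: str
    year: float

    def __post_init__(self):
        if not np.isfinite(self.year) or self.year <= 1900:
            raise ValueError(f"{self.sample_id}: year must be finite and > 1900")


@dataclass
class GenotypeMatrix:
    """Loci x samples alternate-allele dosages with sample metadata.

    ``calls[i, j]`` counts copies of the alternate allele of locus ``i`` in
    sample ``j`` (0, 1, 2, or MISSING = -1).  ``samples`` is a DataFrame with
    columns sample_id, colony, cohort, year in call-column order.
    """

    locus_ids: np.ndarray
    radlocus_ids: np.ndarray
    calls: np.ndarray
    samples: pd.DataFrame
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None
    ref: np.ndarray | None = None
    alt: np.ndarray | None = None

    def __post_init__(self):
        self.locus_ids = np.asarray(self.locus_ids, dtype=object)
        self.radlocus_ids = np.asarray(self.radlocus_ids, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (loci x samples)")
        n_loci, n_samp = self.calls.shape
        if n_samp < 1:
            raise ValueError("need at least 1 sample")
        # n_loci == 0 is tolerated so filters may legally empty a panel
        if self.locus_ids.size != n_loci or self.radlocus_ids.size != n_loci:
            raise ValueError("locus id arrays must match calls rows")
        if len(self.samples) != n_samp:
            raise ValueError("sample metadata must match calls columns")
        if len(set(self.locus_ids)) != n_loci:
            raise ValueError("duplicated locus identifiers")
        sids = self.samples["sample_id"]
        if sids.duplicated().any():
            dup = sids[sids.duplicated()].iloc[0]
            raise ValueError(f"duplicated sample identifier {dup!r}")
        bad = ~np.isin(self.calls, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("calls must be in {0, 1, 2, MISSING}")
        if (self.calls == MISSING).all(axis=1).any():
            raise ValueError("every locus needs at least one non-missing call")
        if self.pos is None:
            self.pos = np.arange(1, n_loci + 1, dtype=np.int64)
        if self.chrom is None:
            self.chrom = np.asarray(self.radlocus_ids, dtype=object)
        if self.ref is None:
            self.ref = np.full(n_loci, "A", dtype=object)
        if self.alt is None:
            self.alt = np.full(n_loci, "C", dtype=object)

    # -- basic views -------------------------------------------------------
    @property
    def n_loci(self) -> int:
        return self.calls.shape[0]

    @property
    def n_samples(self) -> int:
        return self.calls.shape[1]

    def group_labels(self, grouping: str) -> np.ndarray:
        """Per-sample group label for a grouping rule."""
        s = self.samples
        if grouping == "colony":
            return s["colony"].to_numpy(object)
        if grouping == "cohort":
            return s["cohort"].to_numpy(object)
        if grouping in ("colony_cohort", "colony×cohort", "colony x cohort"):
            return (s["colony"].astype(str) + "/" + s["cohort"].astype(str)
                    ).to_numpy(object)
        if grouping == "all":
            return np.full(self.n_samples, "all", dtype=object)
        raise ValueError(f"unknown grouping {grouping!r}")

    def take_loci(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return replace(
            self, locus_ids=self.locus_ids[index],
            radlocus_ids=self.radlocus_ids[index],
            calls=self.calls[index], chrom=self.chrom[index],
            pos=self.pos[index], ref=self.ref[index], alt=self.alt[index])

    def take_samples(self, mask: np.ndarray) -> "GenotypeMatrix":
        """Subset samples, then drop loci left with no non-missing call."""
        calls = self.calls[:, mask]
        keep = ~(calls == MISSING).all(axis=1)
        return GenotypeMatrix(
            locus_ids=self.locus_ids[keep], radlocus_ids=self.radlocus_ids[keep],
            calls=calls[keep],
            samples=self.samples.loc[mask].reset_index(drop=True),
            chrom=self.chrom[keep], pos=self.pos[keep],
            ref=self.ref[keep], alt=self.alt[keep])


@dataclass
class FrequencyTable:
    """Alternate-allele frequency and typed gene copies per (locus, group)."""

    locus_ids: np.ndarray
    groups: tuple[str, ...]
    freq: np.ndarray      # (n_loci, n_groups), NaN where undefined
    n_genes: np.ndarray   # (n_loci, n_groups) ints

    def __post_init__(self):
        ok = ~np.isnan(self.freq)
        if np.any((self.freq[ok] < 0) | (self.freq[ok] > 1)):
            raise ValueError("frequencies must lie in [0, 1]")
        if np.any(self.n_genes % 2) or np.any(self.n_genes < 0):
            raise ValueError("n_genes must be even and >= 0")
        if not np.array_equal(np.isnan(self.freq), self.n_genes == 0):
            raise ValueError("freq must be NaN exactly where n_genes == 0")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j, grp in enumerate(self.groups):
            rows.append(pd.DataFrame({
                "locus_id": self.locus_ids, "group": grp,
                "freq": self.freq[:, j], "n_genes": self.n_genes[:, j]}))
        return pd.concat(rows, ignore_index=True)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# I/O

def _read_metadata(metadata_path) -> pd.DataFrame:
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    missing_cols = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ValueError(f"metadata missing columns: {missing_cols}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicated sample identifier {dup!r} in metadata")
    meta = meta.copy()
    meta["year"] = meta["year"].map(parse_year)
    return meta


def read_genotypes(vcf_path, metadata_path, rad_info_key: str = "RAD",
                   multiallelic: str = "drop") -> GenotypeMatrix:
    """Read a VCF plus a tab-separated sample metadata table.

    Genotypes become alternate-allele dosages (phase ignored); records that
    are not biallelic SNPs are dropped with a warning (``multiallelic="drop"``,
    the default) or raise (``"error"``).  The RAD-locus id is taken from the
    ``rad_info_key`` INFO field when present, else equals the locus id.
    """
    from cyvcf2 import VCF

    if multiallelic not in ("drop", "error"):
        raise ValueError("multiallelic must be 'drop' or 'error'")
    meta = _read_metadata(metadata_path)
    vcf = VCF(str(vcf_path))
    vcf_samples = list(vcf.samples)
    absent = [s for s in vcf_samples if s not in set(meta["sample_id"])]
    if absent:
        raise ValueError(f"metadata has no row for VCF sample(s): {absent}")
    meta = meta.set_index("sample_id").loc[vcf_samples].reset_index()

    ids, rads, chroms, poss, refs, alts, rows = [], [], [], [], [], [], []
    n_dropped = 0
    for v in vcf:
        snp = (len(v.REF) == 1 and len(v.ALT) == 1 and len(v.ALT[0]) == 1)
        if not snp:
            if multiallelic == "error":
                raise ValueError(
                    f"non-biallelic-SNP record at {v.CHROM}:{v.POS}")
            n_dropped += 1
            continue
        lid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        rad = v.INFO.get(rad_info_key)
        g = np.array([gt[:2] for gt in v.genotypes], dtype=np.int32)
        dos = g.sum(axis=1).astype(np.int8)
        dos[(g < 0).any(axis=1)] = MISSING
        ids.append(lid)
        rads.append(str(rad) if rad is not None else lid)
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        rows.append(dos)
    if n_dropped:
        logger.warning("dropped %d non-biallelic-SNP record(s)", n_dropped)
    if not rows:
        raise ValueError(f"{vcf_path}: no biallelic SNP records")
    return GenotypeMatrix(
        locus_ids=np.array(ids, dtype=object),
        radlocus_ids=np.array(rads, dtype=object),
        calls=np.array(rows, dtype=np.int8), samples=meta,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object), alt=np.array(alts, dtype=object))


_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_genotypes(gm: GenotypeMatrix, vcf_path, metadata_path=None) -> None:
    """Write a minimal VCFv4.2 (GT only, RAD INFO key) and metadata table."""
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=RAD,Number=1,Type=String,'
                 'Description="RAD locus identifier">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(pd.Series(gm.chrom)):
            fh.write(f"##contig=<ID={c}>\n")
        cols = "\t".join(gm.samples["sample_id"])
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
        for i in range(gm.n_loci):
            gts = "\t".join(_GT[int(c)] for c in gm.calls[i])
            fh.write(f"{gm.chrom[i]}\t{gm.pos[i]}\t{gm.locus_ids[i]}\t"
                     f"{gm.ref[i]}\t{gm.alt[i]}\t.\t.\t"
                     f"RAD={gm.radlocus_ids[i]}\tGT\t{gts}\n")
    if metadata_path is not None:
        gm.samples.to_csv(metadata_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# filters

def filter_group_presence(gm: GenotypeMatrix, min_presence: float,
                          grouping: str = "colony_cohort",
                          mode: str = "any") -> GenotypeMatrix:
    """Keep loci typed in >= ``min_presence`` of individuals per group.

    ``mode="any"`` keeps a locus passing in at least one group (the r80
    rule); ``mode="all"`` requires every group.  The sample set is unchanged.
    """
    if not 0 < min_presence <= 1:
        raise ValueError("min_presence must be in (0, 1]")
    if mode not in ("any", "all"):
        raise ValueError("mode must be 'any' or 'all'")
    labels = gm.group_labels(grouping)
    present = gm.calls != MISSING
    per_group = []
    for grp in pd.unique(pd.Series(labels)):
        cols = labels == grp
        frac = present[:, cols].mean(axis=1)
        per_group.append(frac >= min_presence - 1e-12)
    ok = np.any(per_group, axis=0) if mode == "any" else np.all(per_group, axis=0)
    if not ok.any():
        logger.warning("presence filter removed every locus")
    return gm.take_loci(np.flatnonzero(ok))


def pooled_maf(gm: GenotypeMatrix) -> np.ndarray:
    """Folded minor-allele frequency over all non-missing calls per locus."""
    present = gm.calls != MISSING
    alt = np.where(present, gm.calls, 0).sum(axis=1)
    n = 2 * present.sum(axis=1)
    p = alt / n
    return np.minimum(p, 1.0 - p)


def filter_maf(gm: GenotypeMatrix, maf_min: float) -> GenotypeMatrix:
    """Keep loci whose pooled minor-allele frequency is >= ``maf_min``."""
    if not 0 <= maf_min <= 0.5:
        raise ValueError("maf_min must be in [0, 0.5]")
    if maf_min == 0:
        return gm
    ok = pooled_maf(gm) >= maf_min - 1e-12
    if not ok.any():
        logger.warning("MAF filter removed every locus")
    return gm.take_loci(np.flatnonzero(ok))


def select_one_snp_per_radlocus(gm: GenotypeMatrix,
                                rule: str = "first") -> GenotypeMatrix:
    """Thin to one SNP per RAD locus.

    ``rule="first"`` keeps the lowest-coordinate SNP; ``"most_complete"``
    keeps the SNP with the fewest missing calls (ties broken by coordinate).
    """
    if rule not in ("first", "most_complete"):
        raise ValueError("rule must be 'first' or 'most_complete'")
    n_missing = (gm.calls == MISSING).sum(axis=1)
    df = pd.DataFrame({"rad": gm.radlocus_ids, "pos": gm.pos,
                       "miss": n_missing, "row": np.arange(gm.n_loci)})
    if rule == "first":
        df = df.sort_values(["rad", "pos", "row"], kind="stable")
    else:
        df = df.sort_values(["rad", "miss", "pos", "row"], kind="stable")
    keep_rows = df.groupby("rad", sort=False)["row"].first().to_numpy()
    return gm.take_loci(np.sort(keep_rows))


def allele_frequencies(gm: GenotypeMatrix, grouping: str = "all") -> FrequencyTable:
    """Alternate-allele frequency per (locus, group): sum(dosage)/(2 typed)."""
    labels = gm.group_labels(grouping)
    groups = tuple(pd.unique(pd.Series(labels)))
    present = gm.calls != MISSING
    freq = np.empty((gm.n_loci, len(groups)))
    n_genes = np.empty((gm.n_loci, len(groups)), dtype=np.int64)
    for j, grp in enumerate(groups):
        cols = labels == grp
        alt = np.where(present[:, cols], gm.calls[:, cols], 0).sum(axis=1)
        n = 2 * present[:, cols].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq[:, j] = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
        n_genes[:, j] = n
    return FrequencyTable(locus_ids=gm.locus_ids, groups=groups,
                          freq=freq, n_genes=n_genes)
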