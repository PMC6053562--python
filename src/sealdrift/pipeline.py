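"""Configuration-driven orchestration of the analysis stages.

A run is described by one YAML config file naming a stage, a seed, an output
directory and per-stage parameter blocks.  Outputs are plain text (VCF, TSV,
JSON); the config is copied verbatim into the output directory and a
``summary.json`` records parameters, seeds, row counts and warnings, so
every run can be regenerated exactly from its own output directory.
"""

from __future__ import annotations

import json
import shutil
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genotype_io as gio
from .abc_demography import ReferenceTable
from .models import DemographicABC, TemporalOutlierScan
from .diversity import compare_groups, diversity_table, summarize_group
from .synthetic_data import CohortSpec, generate_cohort_study
from .wf_logistic_sim import (GRAY_SEAL_SABLE, HARBOR_SEAL_NEUS,
                              GrowthSchedule, simulate_null)

__all__ = ["ConfigError", "run", "full_study", "STAGES"]


class ConfigError(ValueError):
    """A config schema violation, reported with its key path."""


def _req(cfg: dict, path: str, typ=None):
    node = cfg
    walked = []
    for key in path.split("."):
        walked.append(key)
        if not isinstance(node, dict) or key not in node:
            raise ConfigError(f"missing required config key: {'.'.join(walked)}")
        node = node[key]
    if typ is not None and not isinstance(node, typ):
        raise ConfigError(f"config key {path}: expected {typ.__name__}")
    return node


_SCHEDULES = {"gray_seal_sable": GRAY_SEAL_SABLE,
              "harbor_seal_neus": HARBOR_SEAL_NEUS}


def _schedule(node) -> GrowthSchedule:
    if isinstance(node, str):
        if node not in _SCHEDULES:
            raise ConfigError(f"unknown schedule preset {node!r}; "
                              f"choose from {sorted(_SCHEDULES)}")
        return _SCHEDULES[node]
    if isinstance(node, dict):
        return GrowthSchedule(
            n_start=int(node["n_start"]),
            segments=tuple((int(d), float(r)) for d, r in node["segments"]),
            K=float(node["K"]), ne_ratio=float(node.get("ne_ratio", 1.0)),
            start_year=node.get("start_year"))
    raise ConfigError("schedule: expected preset name or mapping")


def _load_inputs(cfg) -> gio.GenotypeMatrix:
    vcf = _req(cfg, "inputs.vcf")
    meta = _req(cfg, "inputs.metadata")
    return gio.read_genotypes(vcf, meta)


# ---------------------------------------------------------------------------
# stage runners: each returns a summary dict and writes its artifacts

def _stage_synth(cfg, out: Path, seed: int) -> dict:
    c = cfg.get("synth", {})
    design = None
    if "design" in c:
        design = tuple(CohortSpec(d["colony"], str(d["cohort"]),
                                  int(d["year_offset"]), int(d["n"]))
                       for d in c["design"])
    gm, truth = generate_cohort_study(
        design=design, schedule=_schedule(c.get("schedule", "gray_seal_sable")),
        n_loci=int(c.get("n_loci", 1000)), n_planted=int(c.get("n_planted", 0)),
        s=float(c.get("s", 0.15)), missing_rate=float(c.get("missing_rate", 0.0)),
        spectrum=c.get("spectrum", "neutral_sfs"),
        planted_p0=c.get("planted_p0"), seed=seed)
    gio.write_genotypes(gm, out / "study.vcf", out / "metadata.tsv")
    truth.write(out / "truth_planted.tsv")
    pd.DataFrame({"locus_id": gm.locus_ids,
                  "founding_freq": truth.founding_freqs}).to_csv(
        out / "truth_founding_freqs.tsv", sep="\t", index=False)
    return {"n_loci": gm.n_loci, "n_samples": gm.n_samples,
            "n_planted": len(truth.planted),
            "outputs": ["study.vcf", "metadata.tsv", "truth_planted.tsv",
                        "truth_founding_freqs.tsv"]}


def _stage_diversity(cfg, out: Path, seed: int) -> dict:
    c = cfg.get("diversity", {})
    gm = _load_inputs(cfg)
    n_before = gm.n_loci
    gm = gio.filter_group_presence(gm, float(c.get("min_presence", 0.8)),
                                   grouping=c.get("grouping", "cohort"),
                                   mode="all")
    summaries = summarize_group(gm, c.get("grouping", "cohort"),
                                g=c.get("g", "auto"),
                                unbiased_he=bool(c.get("unbiased_he", False)))
    diversity_table(summaries).to_csv(out / "diversity.tsv", sep="\t",
                                      index=False)
    rows = []
    ar = {s.group: s.per_locus["ar"].to_numpy() for s in summaries}
    he = {s.group: s.per_locus["he"].to_numpy() for s in summaries}
    for metric, vals in (("ar", ar), ("he", he)):
        if len(vals) >= 2:
            design = "anova" if len(vals) > 2 else "ttest"
            comp = compare_groups(vals, design=design)
            rows.append((metric, comp.kind, comp.statistic,
                         "x".join(map(str, comp.df)), comp.p_value))
    pd.DataFrame(rows, columns=["metric", "design", "statistic", "df", "p"]
                 ).to_csv(out / "comparisons.tsv", sep="\t", index=False)
    return {"n_loci_input": n_before, "n_loci_retained": gm.n_loci,
            "groups": [s.group for s in summaries],
            "outputs": ["diversity.tsv", "comparisons.tsv"]}


def _stage_simulate_wf(cfg, out: Path, seed: int) -> dict:
    c = cfg.get("scan", {})
    schedule = _schedule(c.get("schedule", "gray_seal_sable"))
    gm = _load_inputs(cfg)
    scan = TemporalOutlierScan.from_genotypes(
        gm, schedule, colony=c.get("colony"),
        min_presence=float(c.get("min_presence", 0.8)))
    seed_freqs = scan.observed.freq[:, 0]
    ok = ~np.isnan(seed_freqs)
    sim = simulate_null(seed_freqs[ok], schedule, scan.plan,
                        replicates_per_locus=int(c.get("replicates_per_locus", 1)),
                        seed=seed, locus_ids=scan.observed.locus_ids[ok])
    sim.to_frame().to_csv(out / "simulated_series.tsv", sep="\t", index=False)
    return {"n_loci": int(ok.sum()), "years": list(map(float, sim.years)),
            "outputs": ["simulated_series.tsv"]}


def _stage_scan(cfg, out: Path, seed: int) -> dict:
    c = cfg.get("scan", {})
    schedule = _schedule(c.get("schedule", "gray_seal_sable"))
    gm = _load_inputs(cfg)
    scan = TemporalOutlierScan.from_genotypes(
        gm, schedule, colony=c.get("colony"),
        min_presence=float(c.get("min_presence", 0.8)),
        alpha=float(c.get("alpha", 0.05)),
        weighted=bool(c.get("weighted", False)))
    res = scan.fit(replicates_per_locus=int(c.get("replicates_per_locus", 1)),
                   seed=seed)
    res.report.obs_trends.to_csv(out / "trends_observed.tsv", sep="\t")
    res.report.sim_trends.to_csv(out / "trends_simulated.tsv", sep="\t")
    res.summary_row().to_csv(out / "scan_summary.tsv", sep="\t", index=False)
    (out / "outliers.json").write_text(
        json.dumps({"outlier_ids": list(res.outlier_ids)}, indent=1))
    return {"n_outliers": res.n_outliers, "envelope": res.report.envelope,
            "outputs": ["trends_observed.tsv", "trends_simulated.tsv",
                        "scan_summary.tsv", "outliers.json"]}


def _abc_model(cfg, seed) -> tuple[DemographicABC, dict]:
    c = cfg.get("abc", {})
    gm = _load_inputs(cfg)
    model = DemographicABC.from_genotypes(
        gm, cohort=c.get("cohort"),
        min_presence=float(c.get("min_presence", 0.9)),
        n_loci=int(c.get("n_loci", 1000)),
        maf_min=float(c.get("maf_min", 0.0)), seed=seed)
    return model, c


def _get_reference(model, c, out, seed) -> ReferenceTable:
    if "reference" in c and Path(c["reference"]).exists():
        return ReferenceTable.read(c["reference"])
    ref = model.build_reference(int(c.get("sims_per_scenario", 5000)), seed)
    ref.write(out / "reference_table.tsv")
    return ref


def _stage_abc_fit(cfg, out: Path, seed: int) -> dict:
    model, c = _abc_model(cfg, seed)
    ref = _get_reference(model, c, out, seed)
    res = model.fit(reference=ref, top_frac=float(c.get("top_frac", 0.01)))
    res.model_table().to_csv(out / "model_posterior.tsv", sep="\t")
    frames = []
    for sc, pp in res.parameter_posteriors.items():
        t = pp.table.reset_index()
        t.insert(0, "scenario", sc)
        frames.append(t)
    pd.concat(frames).to_csv(out / "parameter_posterior.tsv", sep="\t",
                             index=False)
    (out / "abc_summary.txt").write_text(res.summary() + "\n")
    return {"n_loci": model.n_loci, "n_diploids": model.n_diploids,
            "best_scenario": res.best_scenario,
            "outputs": ["model_posterior.tsv", "parameter_posterior.tsv",
                        "abc_summary.txt"]}


def _stage_abc_validate(cfg, out: Path, seed: int) -> dict:
    model, c = _abc_model(cfg, seed)
    ref = _get_reference(model, c, out, seed)
    rep = model.validate(ref, pods_per_scenario=int(
        c.get("pods_per_scenario", 200)), seed=seed + 1,
        top_frac=float(c.get("top_frac", 0.01)))
    rep.selection.to_csv(out / "confusion_selection.tsv", sep="\t")
    rep.error_rate_pct.rename("error_rate_pct").to_csv(
        out / "confusion_error.tsv", sep="\t")
    return {"error_rate_pct": {int(k): float(v)
                               for k, v in rep.error_rate_pct.items()},
            "outputs": ["confusion_selection.tsv", "confusion_error.tsv"]}


STAGES = {
    "synth": _stage_synth,
    "diversity": _stage_diversity,
    "simulate-wf": _stage_simulate_wf,
    "scan-outliers": _stage_scan,
    "abc-fit": _stage_abc_fit,
    "abc-validate": _stage_abc_validate,
}


def _run_stages(cfg: dict, config_path, stages: list[str]) -> dict:
    out = Path(_req(cfg, "out_dir"))
    seed = _req(cfg, "seed", int)
    out.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []
    summary = {"seed": seed, "stages": {}}
    try:
        for name in stages:
            before = set(out.iterdir())
            summary["stages"][name] = STAGES[name](cfg, out, seed)
            created.extend(set(out.iterdir()) - before)
        shutil.copy(config_path, out / "config.yaml")
        (out / "summary.json").write_text(json.dumps(summary, indent=1,
                                                     default=str))
    except Exception:
        for p in created:
            if p.is_file():
                p.unlink(missing_ok=True)
        raise
    return summary


def run(config_path) -> dict:
    """Execute the single stage named in the config; returns its summary."""
    cfg = yaml.safe_load(Path(config_path).read_text())
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    stage = _req(cfg, "stage")
    if stage == "full-study":
        return full_study(config_path)
    if stage not in STAGES:
        raise ConfigError(f"stage: unknown stage {stage!r}; "
                          f"choose from {sorted(STAGES)} or 'full-study'")
    return _run_stages(cfg, config_path, [stage])


def full_study(config_path) -> dict:
    """Synthesize (unless inputs given), then run every analysis stage.

    Hand-offs mirror the study design: the 90%-presence single-cohort rule
    and locus subsampling are applied inside the ABC stage; the 80% all-cohorts
    rule inside the diversity and scan stages; the outlier scan's drift null
    is seeded from the oldest cohort's frequencies.
    """
    cfg = yaml.safe_load(Path(config_path).read_text())
    _req(cfg, "seed", int)
    stages = []
    if "inputs" not in cfg:
        stages.append("synth")
        out = Path(_req(cfg, "out_dir"))
        cfg["inputs"] = {"vcf": str(out / "study.vcf"),
                         "metadata": str(out / "metadata.tsv")}
    stages += ["diversity", "abc-fit", "abc-validate", "scan-outliers"]
    return _run_stages(cfg, config_path, stages)
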