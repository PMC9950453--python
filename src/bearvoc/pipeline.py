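"""End-to-end orchestration: config, stage sequencing, provenance.

``run_pipeline`` executes the canonical analysis chain on a dataset —
preprocessing, Bray-Curtis and Jaccard distances, dispersion check,
sequential PERMANOVA (with a balanced-subsample rerun when one age-sex
class dominates), nMDS, SIMPER with univariate follow-up, per-sample
compound counts, and the compound-uniqueness report — writing one
tab-delimited table per analysis plus a machine-readable provenance
manifest (config hash, seed, package version, stage log).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datatypes import Dataset, metadata_frame
from .dissimilarity import bray_curtis, jaccard
from .io import read_metadata, read_peak_table
from .multivariate import (
    DESIGN_PRESETS,
    PermanovaTable,
    balance_by_subsampling,
    dispersion,
    fdr_across,
    permanova,
)
from .ordination import nmds
from .preprocess import PreprocessParams, count_compounds_per_sample, run_preprocess
from .simper import compound_anova, compound_count_anova, screen_contributors, simper_all_pairs
from .uniqueness import build_treatments, classify_uniqueness, presence_fractions, uniqueness_report

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All pipeline settings; defaults are the analysis conventions
    described in the module docs (5% incidence, both-replicates rule,
    10,000 permutations, k=3 nMDS, 2.0% SIMPER cutoff, 0.50% count
    threshold, alpha 0.05)."""

    peak_table: str | None = None
    metadata: str | None = None
    out_dir: str = "results"
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    metrics: tuple[str, ...] = ("bray_curtis", "jaccard")
    designs: tuple[str, ...] = ("full",)
    n_permutations: int = 10_000
    nmds_k: int = 3
    nmds_restarts: int = 20
    simper_cutoff: float = 2.0
    alpha: float = 0.05
    seed: int = 0
    exclusions: list[tuple[str, str]] = field(default_factory=list)
    balance_class: str | None = "young_M"
    balance_n_individuals: int = 2
    simper_grouping: str = "age_sex_class"
    individual_treatment_exclusions: tuple[str, ...] = ("Y744",)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        pre = raw.pop("preprocess", None)
        cfg = cls(**raw)
        if pre:
            cfg.preprocess = PreprocessParams(**pre)
        return cfg

    def config_hash(self) -> str:
        """Hash of the analysis settings (the output location is not part
        of the analysis identity)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _write(df: pd.DataFrame, path: Path, cfg_hash: str, **index_kw) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, sep="\t", **index_kw)


def _permanova_frame(tables: list[PermanovaTable]) -> pd.DataFrame:
    parts = []
    for t in tables:
        df = t.table.copy()
        df.insert(0, "term", df.index)
        df.insert(0, "metric", t.metric)
        df.insert(0, "design", t.design)
        parts.append(df.reset_index(drop=True))
    return pd.concat(parts, ignore_index=True)


def load_dataset(config: PipelineConfig) -> Dataset:
    if config.peak_table is None or config.metadata is None:
        raise ValueError("config must name peak_table and metadata paths")
    table = read_peak_table(config.peak_table)
    metadata = read_metadata(config.metadata)
    dataset = Dataset(table, metadata)
    drop = [s for s, _ in config.exclusions if s in dataset.table.samples]
    if drop:
        reasons = dict(config.exclusions)
        for s in drop:
            dataset = dataset.drop_samples([s], reasons[s])
    return dataset


def run_pipeline(config: PipelineConfig, dataset: Dataset | None = None) -> Path:
    """Run the full analysis chain; returns the output directory."""
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    stages: list[dict] = []

    def stage(name: str, t0: float, **info) -> None:
        entry = {"stage": name, "elapsed_s": round(time.time() - t0, 3), **info}
        stages.append(entry)
        log.info("stage %s: %s", name, info)

    if dataset is None:
        t0 = time.time()
        dataset = load_dataset(config)
        stage("load", t0, n_samples=dataset.n_samples,
              n_compounds=dataset.table.n_compounds)

    # --- preprocessing ---------------------------------------------------
    t0 = time.time()
    prep = run_preprocess(dataset, config.preprocess)
    stage("preprocess", t0,
          n_samples=prep.transformed.n_samples,
          n_compounds_raw=prep.raw.n_compounds,
          n_compounds_kept=prep.filtered.n_compounds,
          incidence_min_samples=prep.min_samples,
          pseudo_count=prep.pseudo_count)

    # --- distances --------------------------------------------------------
    t0 = time.time()
    dmats = {}
    if "bray_curtis" in config.metrics:
        dmats["bray_curtis"] = bray_curtis(prep.transformed)
    if "jaccard" in config.metrics:
        dmats["jaccard"] = jaccard(prep.detection, list(prep.filtered.samples))
    for name, dm in dmats.items():
        dm.write(out / f"distance_{name}.tsv")
    stage("distances", t0, metrics=list(dmats))

    meta_df = dataset.meta_frame()

    # --- dispersion (variance across groups) ------------------------------
    t0 = time.time()
    disp_rows = []
    for metric, dm in dmats.items():
        for grouping in ("age_class", "sex", "age_sex_class",
                         "body_site", "individual_id"):
            try:
                res = dispersion(dm, meta_df[grouping])
            except ValueError:
                continue
            disp_rows.append({"metric": metric, "grouping": grouping,
                              "F": res.F, "p": res.p,
                              **{f"mean_{g}": v for g, v in res.group_means.items()}})
    _write(pd.DataFrame(disp_rows), out / "dispersion.tsv", cfg_hash, index=False)
    stage("dispersion", t0, n_tests=len(disp_rows))

    # --- PERMANOVA ---------------------------------------------------------
    t0 = time.time()
    tables: list[PermanovaTable] = []
    for design_name in config.designs:
        for metric, dm in dmats.items():
            tables.append(permanova(dm, DESIGN_PRESETS[design_name],
                                    dataset.metadata, config.n_permutations,
                                    seed=config.seed))
    fdr_across(tables)
    _write(_permanova_frame(tables), out / "permanova.tsv", cfg_hash, index=False)
    stage("permanova", t0, designs=list(config.designs),
          n_permutations=config.n_permutations,
          p_resolution=1.0 / (config.n_permutations + 1))

    # --- balanced-subsample rerun -----------------------------------------
    if config.balance_class is not None:
        t0 = time.time()
        classes = meta_df.groupby("age_sex_class")["individual_id"].nunique()
        if (config.balance_class in classes.index
                and classes[config.balance_class] > config.balance_n_individuals):
            balanced = balance_by_subsampling(
                dataset, config.balance_class,
                config.balance_n_individuals, seed=config.seed)
            bprep = run_preprocess(balanced, config.preprocess)
            btables = []
            bdmats = {}
            if "bray_curtis" in config.metrics:
                bdmats["bray_curtis"] = bray_curtis(bprep.transformed)
            if "jaccard" in config.metrics:
                bdmats["jaccard"] = jaccard(bprep.detection,
                                            list(bprep.filtered.samples))
            for design_name in config.designs:
                for metric, dm in bdmats.items():
                    btables.append(permanova(dm, DESIGN_PRESETS[design_name],
                                             balanced.metadata,
                                             config.n_permutations,
                                             seed=config.seed))
            fdr_across(btables)
            _write(_permanova_frame(btables), out / "permanova_balanced.tsv",
                   cfg_hash, index=False)
            stage("permanova_balanced", t0,
                  n_samples=balanced.n_samples,
                  n_individuals=int(balanced.meta_frame()["individual_id"].nunique()))

    # --- nMDS ----------------------------------------------------------------
    t0 = time.time()
    if "bray_curtis" in dmats and dmats["bray_curtis"].n >= config.nmds_k + 2:
        res = nmds(dmats["bray_curtis"], k=config.nmds_k,
                   n_restarts=config.nmds_restarts, seed=config.seed)
        coords = res.frame()
        coords["stress"] = res.stress
        coords["nonmetric_R2"] = res.nonmetric_r2
        coords["linear_R2"] = res.linear_r2
        _write(coords, out / "nmds.tsv", cfg_hash, index_label="sample_id")
        stage("nmds", t0, k=config.nmds_k, stress=res.stress,
              nonmetric_R2=res.nonmetric_r2, linear_R2=res.linear_r2)

    # --- SIMPER + univariate follow-up --------------------------------------
    t0 = time.time()
    grouping = meta_df[config.simper_grouping]
    simper_rows = []
    screened: dict[str, tuple[str, str]] = {}
    for pair, rows in simper_all_pairs(prep.transformed, grouping).items():
        for r in rows:
            simper_rows.append({
                "group_a": pair[0], "group_b": pair[1],
                "compound": r.compound.label,
                "mean_contribution": r.mean_contribution,
                "percent": r.percent_contribution,
                "cumulative_percent": r.cumulative_percent,
            })
        for cid in screen_contributors(rows, config.simper_cutoff):
            screened.setdefault(cid.label, pair)
    _write(pd.DataFrame(simper_rows), out / "simper.tsv", cfg_hash, index=False)

    uni_rows = []
    design = DESIGN_PRESETS["age_sex"]
    for label in screened:
        try:
            row = compound_anova(prep.transformed, dataset.metadata, label,
                                 design, focal_term="age*sex")
        except ValueError:
            continue
        uni_rows.append({"compound": label, "focal_term": row.focal_term,
                         "F": row.F, "p": row.p,
                         "significant": row.p < config.alpha})
    _write(pd.DataFrame(uni_rows), out / "univariate.tsv", cfg_hash, index=False)
    stage("simper", t0, n_screened=len(screened), cutoff=config.simper_cutoff)

    # --- compound counts -------------------------------------------------------
    t0 = time.time()
    counts = count_compounds_per_sample(prep.relative,
                                        config.preprocess.count_threshold_fraction)
    counts_df = pd.DataFrame({"sample_id": list(counts),
                              "n_compounds": list(counts.values())})
    _write(counts_df, out / "compound_counts.tsv", cfg_hash, index=False)
    try:
        cc = compound_count_anova(counts, dataset.metadata)
        _write(cc.anova, out / "compound_counts_anova.tsv", cfg_hash,
               index_label="term")
        _write(cc.group_stats, out / "compound_counts_groups.tsv", cfg_hash,
               index_label="age_sex_class")
    except ValueError as exc:
        log.warning("compound-count ANOVA skipped: %s", exc)
    stage("counts", t0,
          threshold=config.preprocess.count_threshold_fraction)

    # --- uniqueness -------------------------------------------------------------
    t0 = time.time()
    treatments = build_treatments(dataset.metadata,
                                  config.individual_treatment_exclusions)
    reports = []
    for spec in treatments.values():
        presence = presence_fractions(
            dataset.table.values > 0, spec, dataset.metadata,
            sample_ids=list(dataset.table.samples),
            compounds=list(dataset.table.compounds))
        calls = classify_uniqueness(presence)
        reports.append(uniqueness_report(calls, spec))
    _write(pd.concat(reports, ignore_index=True).fillna(0),
           out / "uniqueness.tsv", cfg_hash, index=False)
    stage("uniqueness", t0, n_treatments=len(treatments))

    manifest = {
        "package_version": __version__,
        "config_hash": cfg_hash,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "n_samples": dataset.n_samples,
        "exclusions": list(dataset.exclusions),
        "stages": stages,
        "total_elapsed_s": round(time.time() - t_start, 3),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
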