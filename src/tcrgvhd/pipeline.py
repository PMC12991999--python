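"""End-to-end study-shaped workflow.

``run_pipeline`` executes: simulate (or ingest) → depth-normalize →
per-sample diversity + group tests → specificity-group clustering →
cross-sample similarity and pre-symptomatic query classification →
longitudinal tracking → antigen-annotation scoring → consolidated report.

Stages communicate through manifest TSVs (sample_id, subject_id, group,
stage, path), so real AIRR data can replace the synthetic cohort at any
entry point and every stage can be re-run from its persisted inputs.  All
randomness derives from a single master seed; running the same config twice
produces byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from statsmodels.stats.multitest import multipletests

from . import diversity as dv
from . import io as rio
from .gliph import GliphConfig, build_gliph_groups, groups_to_frames
from .normalize import normalize_cohort
from .repertoire import ConfigError, Repertoire
from .similarity import (
    classify_query,
    group_contrast,
    membership_profiles,
    pairwise_similarity,
)
from .simulate import (
    CohortConfig,
    generate_cohort,
    generate_reference,
    planted_annotation_records,
)
from .tracking import stage_similarity, track

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


def load_config(source) -> dict:
    """Load a YAML (or already-parsed) pipeline configuration."""
    if isinstance(source, Mapping):
        return dict(source)
    with open(source) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("pipeline config must be a mapping")
    return cfg


def cohort_config_from_dict(d: Mapping, seed: int) -> CohortConfig:
    kwargs = dict(d)
    known = set(CohortConfig.__dataclass_fields__)
    unknown = set(kwargs) - known
    if unknown:
        raise ConfigError(f"unknown cohort config keys: {sorted(unknown)}")
    if "stages_per_group" in kwargs:
        kwargs["stages_per_group"] = {
            g: tuple(v) for g, v in kwargs["stages_per_group"].items()
        }
    for key in ("motif_panel", "planted_cdr3s"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    if "spiked_groups" in kwargs:
        kwargs["spiked_groups"] = frozenset(kwargs["spiked_groups"])
    kwargs.setdefault("seed", seed)
    return CohortConfig(**kwargs)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _diversity_tables(cohort: Sequence[Repertoire]) -> tuple[pd.DataFrame, pd.DataFrame]:
    rows = []
    for rep in cohort:
        prof = dv.diversity_profile(rep)
        rows.append(
            {
                "sample_id": rep.sample_id,
                "subject_id": rep.subject_id,
                "group": rep.group or "",
                "stage": "" if rep.stage is None else rep.stage,
                "richness": prof.richness,
                "chao1": prof.chao1,
                "inverse_simpson": prof.inverse_simpson,
                "expanded_count_z2": prof.expanded_count_z2,
                "expanded_mass_z2": prof.expanded_mass_z2,
                "low_freq_count": prof.low_freq_count,
                **{f"mass_{k}": v for k, v in prof.rank_band_mass.items()},
                "richness_le_0.1pct": prof.freq_band_richness["low"],
                "richness_gt_0.1pct": prof.freq_band_richness["high"],
            }
        )
    table = pd.DataFrame(rows)

    metrics = ["richness", "chao1", "inverse_simpson", "expanded_count_z2",
               "low_freq_count"]
    groups = [g for g in ("GVHD", "NO_GVHD", "HI")
              if (table["group"] == g).sum() >= 2]
    tests = []
    for metric in metrics:
        for i, ga in enumerate(groups):
            for gb in groups[i + 1:]:
                va = table.loc[table["group"] == ga, metric].to_numpy(dtype=float)
                vb = table.loc[table["group"] == gb, metric].to_numpy(dtype=float)
                res = dv.compare_groups({ga: va, gb: vb}, test="wilcoxon_rank_sum")
                tests.append(
                    (metric, f"{ga}_vs_{gb}", float(np.median(va)),
                     float(np.median(vb)), res.statistic, res.p)
                )
    test_tab = pd.DataFrame(
        tests, columns=["metric", "contrast", "median_a", "median_b",
                        "statistic", "p"],
    )
    if len(test_tab):
        test_tab["q_bh"] = multipletests(test_tab["p"], method="fdr_bh")[1]
    return table, test_tab


def _gene_usage_tests(cohort: Sequence[Repertoire]) -> pd.DataFrame:
    """Per-V-segment usage contrast (GVHD vs NO_GVHD), BH-adjusted across
    segments."""
    usage = {
        rep.sample_id: dv.gene_usage(rep, "V") for rep in cohort
    }
    genes = sorted({g for u in usage.values() for g in u})
    rows = []
    for gene in genes:
        va = [usage[r.sample_id].get(gene, 0.0) for r in cohort if r.group == "GVHD"]
        vb = [usage[r.sample_id].get(gene, 0.0) for r in cohort if r.group == "NO_GVHD"]
        if len(va) < 2 or len(vb) < 2:
            continue
        res = dv.compare_groups({"a": va, "b": vb}, test="wilcoxon_rank_sum")
        rows.append((gene, float(np.median(va)), float(np.median(vb)), res.p))
    tab = pd.DataFrame(rows, columns=["v_gene", "median_gvhd", "median_nogvhd", "p"])
    if len(tab):
        tab["q_bh"] = multipletests(tab["p"], method="fdr_bh")[1]
    return tab


def run_pipeline(config, out_dir, seed: Optional[int] = None) -> dict:
    """Run every stage; returns the consolidated report (also written as
    ``report.json`` under ``out_dir``)."""
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master_seed = int(cfg.get("seed", 0) if seed is None else seed) % 2**31
    report: dict = {"seed": master_seed, "stages": {}}

    # -- stage: simulate (or ingest via manifest) ---------------------------
    if "manifest" in cfg:
        cohort = rio.read_manifest(cfg["manifest"])
        cohort_cfg = None
    else:
        cohort_cfg = cohort_config_from_dict(cfg.get("cohort", {}), master_seed)
        cohort = generate_cohort(cohort_cfg)
    raw_dir = out / "samples"
    raw_dir.mkdir(exist_ok=True)
    paths = []
    for rep in cohort:
        p = raw_dir / f"{rep.sample_id}.tsv"
        rio.write_repertoire(rep, p)
        paths.append(p.relative_to(out))
    rio.write_manifest(cohort, paths, out / "manifest.tsv")
    report["stages"]["simulate"] = {"n_samples": len(cohort)}

    # -- stage: normalize ---------------------------------------------------
    ncfg = cfg.get("normalize", {})
    cohort, below = normalize_cohort(
        cohort,
        target_reads=int(ncfg.get("target_reads", 1_000_000)),
        policy=ncfg.get("policy", "fixed"),
        seed=master_seed,
    )
    norm_dir = out / "normalized"
    norm_dir.mkdir(exist_ok=True)
    paths = []
    for rep in cohort:
        p = norm_dir / f"{rep.sample_id}.tsv"
        rio.write_repertoire(rep, p)
        paths.append(p.relative_to(out))
    rio.write_manifest(cohort, paths, out / "manifest_normalized.tsv")
    report["stages"]["normalize"] = {
        "target_reads": int(ncfg.get("target_reads", 1_000_000)),
        "policy": ncfg.get("policy", "fixed"),
        "below_depth": sorted(s for s, b in below.items() if b),
    }

    # -- stage: diversity ---------------------------------------------------
    div_tab, div_tests = _diversity_tables(cohort)
    _write(div_tab, out / "diversity.tsv")
    _write(div_tests, out / "diversity_group_tests.tsv")
    vtab = _gene_usage_tests(cohort)
    _write(vtab, out / "v_usage_tests.tsv")
    report["stages"]["diversity"] = {
        "per_group_median_richness": {
            g: float(div_tab.loc[div_tab["group"] == g, "richness"].median())
            for g in sorted(set(div_tab["group"])) if g
        },
        "per_group_median_isi": {
            g: float(div_tab.loc[div_tab["group"] == g, "inverse_simpson"].median())
            for g in sorted(set(div_tab["group"])) if g
        },
        "tests": div_tests.to_dict(orient="records"),
    }

    # -- stage: motif clustering -------------------------------------------
    gcfg_dict = dict(cfg.get("gliph", {}))
    ref_size = gcfg_dict.pop("reference_size", "auto")
    gliph_cfg = GliphConfig(seed=master_seed, **gcfg_dict)
    if ref_size == "auto":
        # reference must be at least as large as the unique pooled CDR3 set
        from .gliph import select_input_clonotypes

        pool_unique = select_input_clonotypes(cohort, gliph_cfg)["cdr3_aa"].nunique()
        ref_size = 2 * pool_unique + 1000
    reference = generate_reference(int(ref_size), seed=master_seed + 1)
    groups = build_gliph_groups(cohort, reference, gliph_cfg)
    gtab, mtab = groups_to_frames(groups)
    _write(gtab, out / "gliph_groups.tsv")
    _write(mtab, out / "gliph_members.tsv")
    report["stages"]["gliph"] = {
        "n_groups": len(groups),
        "n_local": int((gtab["kind"] == "local").sum()),
        "n_global": int((gtab["kind"] == "global").sum()),
    }

    # -- stage: similarity & classification ---------------------------------
    profiles = membership_profiles(groups, cohort)
    matrix = pairwise_similarity(profiles)
    matrix.to_frame().to_csv(out / "similarity_matrix.tsv", sep="\t",
                             float_format=_FLOAT_FMT)
    labels = {r.sample_id: r.group for r in cohort if r.group in
              ("GVHD", "NO_GVHD", "HI")}
    contrasts = group_contrast(matrix, labels)
    _write(pd.DataFrame([asdict(c) for c in contrasts]), out / "similarity_contrasts.tsv")

    gv_lib = {r.sample_id: profiles[r.sample_id] for r in cohort if r.group == "GVHD"}
    ng_lib = {r.sample_id: profiles[r.sample_id] for r in cohort
              if r.group == "NO_GVHD"}
    cls_rows = []
    queries = [r for r in cohort if r.group == "GVHD_PRE"
               and (r.stage is None or r.stage == 0)]
    if len(gv_lib) >= 2 and len(ng_lib) >= 2:
        for q in queries:
            res = classify_query(profiles[q.sample_id], gv_lib, ng_lib)
            cls_rows.append(
                (q.sample_id, res.label, res.score_gvhd, res.score_nogvhd, res.p)
            )
    cls_tab = pd.DataFrame(
        cls_rows, columns=["sample_id", "label", "score_gvhd", "score_nogvhd", "p"]
    )
    _write(cls_tab, out / "classifications.tsv")
    report["stages"]["similarity"] = {
        "contrasts": [asdict(c) for c in contrasts],
        "classifications": cls_tab.to_dict(orient="records"),
    }

    # -- stage: tracking ----------------------------------------------------
    tcfg = cfg.get("tracking", {})
    top_n = int(tcfg.get("top_n", 100))
    by_subject: dict[str, dict[int, Repertoire]] = {}
    for rep in cohort:
        if rep.stage is not None:
            by_subject.setdefault(rep.subject_id, {})[rep.stage] = rep
    track_frames, sim_rows = [], []
    for subject, stages in sorted(by_subject.items()):
        if len(stages) < 2:
            continue
        ref_stage = int(tcfg.get("reference_stage", 1))
        if ref_stage not in stages:
            ref_stage = sorted(stages)[0]
        track_frames.append(track(stages, ref_stage, n=top_n).to_frame())
        st, mat = stage_similarity(stages)
        for i, sa in enumerate(st):
            for sb in st[i + 1:]:
                sim_rows.append((subject, sa, sb, float(mat[i, st.index(sb)])))
    _write(
        pd.concat(track_frames, ignore_index=True) if track_frames
        else pd.DataFrame(columns=["subject_id"]),
        out / "tracking.tsv",
    )
    sim_tab = pd.DataFrame(
        sim_rows, columns=["subject_id", "stage_a", "stage_b", "morisita"]
    )
    _write(sim_tab, out / "stage_similarity.tsv")
    report["stages"]["tracking"] = {
        "n_subjects": len(track_frames),
        "stage_similarity": sim_tab.to_dict(orient="records"),
    }

    # -- stage: annotation ---------------------------------------------------
    acfg = cfg.get("annotation", {})
    sets = {}
    for name, path in (acfg.get("sets") or {}).items():
        sets[name] = rio.read_annotation_table(
            path, dialect=acfg.get("dialect", "simple")
        )
    if not sets and cohort_cfg is not None:
        sets["synthetic_gvhd_panel"] = planted_annotation_records(cohort_cfg)
    if sets:
        rep_tab, ann_tests = cohort_annotation_report_wrapper(
            cohort, sets, float(acfg.get("floor", 0.0001)),
            acfg.get("match_on", "cdr3"),
        )
        _write(rep_tab, out / "annotation_report.tsv")
        _write(ann_tests, out / "annotation_tests.tsv")
        report["stages"]["annotation"] = {
            "sets": sorted(sets),
            "tests": ann_tests.to_dict(orient="records"),
        }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def cohort_annotation_report_wrapper(cohort, sets, floor, match_on):
    from .annotate import cohort_annotation_report

    return cohort_annotation_report(cohort, sets, match_on=match_on, floor=floor)
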