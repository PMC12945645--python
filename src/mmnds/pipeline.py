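"""End-to-end orchestration: synthesis -> quantification -> WBSS -> ROI
features -> classification -> cohort statistics -> report.

The pipeline streams subject by subject (raw series are large; only the
three derived parameter maps per subject are kept), then runs the
group-level stages. Every stage writes plain-text outputs into the run
directory and a manifest records seeds and parameters, so any stage can be
reproduced in isolation.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as cl
from . import quantify as qt
from . import stats as st
from .errors import InvalidParameterError
from .rois import ENTITIES, GROUPS, builtin_catalog, entity_columns, feature_table
from .synth import CohortModel, CohortSpec, RawModalityBundle, SubjectRecord, _child_seed
from .volumes import (
    BinaryMask,
    ScalarVolume,
    gaussian_smooth,
    whole_brain_mask,
    write_mask,
    write_volume,
)
from .wbss import WBSSConfig, modality_overlap, run_wbss

log = logging.getLogger(__name__)

MODALITY_SETS = {"PET": ("PET",), "MRI": ("ASL", "DTI"), "PET/MRI": ("PET", "ASL", "DTI")}


@dataclass
class PipelineConfig:
    """Defaults match the reference analysis protocol where one is stated:
    8 mm smoothing, FDR alpha 0.05 with the 256 mm^3 cluster threshold,
    sensitivity floor 0.5 for A1 tuning, 1000 A2 runs at a 70:30 split."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    smoothing_fwhm_mm: float = 8.0
    brain_mask_fraction: float = 0.35
    m0_smooth_fwhm_mm: float | None = 8.0
    asl_params: qt.ASLQuantParams = field(default_factory=qt.ASLQuantParams)
    wbss: WBSSConfig = field(default_factory=WBSSConfig)
    regularization: float = 1.0
    min_sensitivity: float = 0.5
    a2_runs: int = 1000
    a2_split: float = 0.7
    modalities: tuple[str, ...] = ("PET", "ASL", "DTI")
    save_volumes: bool = False
    run_wbss_stage: bool = True

    def __post_init__(self):
        if self.smoothing_fwhm_mm <= 0:
            raise InvalidParameterError("smoothing_fwhm_mm must be positive")
        for m in self.modalities:
            if m not in ("PET", "ASL", "DTI"):
                raise InvalidParameterError(f"unknown modality {m!r}")
        if not self.modalities:
            raise InvalidParameterError("at least one modality required")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["grid"] = {"shape": list(self.cohort.grid.shape),
                               "voxel_size_mm": list(self.cohort.grid.voxel_size_mm),
                               "origin_mm": list(self.cohort.grid.origin_mm)}
        return d


def demo_config(seed: int = 0, voxel_mm: float = 3.0, effect_size_sd: float = 2.0,
                a2_runs: int = 200, **overrides) -> PipelineConfig:
    """Desk-scale demonstration: reference group sizes on a 3 mm grid."""
    from .synth import default_effects
    from .volumes import mni_grid
    cohort = CohortSpec(grid=mni_grid(voxel_mm),
                        effects=default_effects(effect_size_sd=effect_size_sd),
                        seed=seed)
    return PipelineConfig(cohort=cohort, a2_runs=a2_runs, **overrides)


# ---------------------------------------------------------------------------
# Per-subject quantification

def quantify_bundle(record: SubjectRecord, bundle: RawModalityBundle,
                    config: PipelineConfig) -> dict:
    """Raw series -> smoothed SUVR / rCBF / raw-smoothed FA maps + brain mask.

    Processing order per modality: quantify -> normalize to whole-brain mean
    -> smooth. FA age correction is a cohort-level second pass (the age
    model comes from the SCD group) and is *not* applied here.
    """
    out: dict = {}
    fwhm = config.smoothing_fwhm_mm
    mask = None
    if bundle.pet_activity is not None:
        suv = qt.compute_suv(bundle.pet_activity, record.injected_dose_MBq,
                             record.body_weight_kg)
        mask = whole_brain_mask(gaussian_smooth(suv, fwhm), config.brain_mask_fraction)
        suvr = qt.compute_suvr(suv, mask)
        out["suvr"] = gaussian_smooth(suvr, fwhm)
    if bundle.asl_pairs is not None:
        m0 = bundle.m0
        if config.m0_smooth_fwhm_mm:
            m0 = gaussian_smooth(m0, config.m0_smooth_fwhm_mm)
        if mask is None:
            mask = whole_brain_mask(m0, config.brain_mask_fraction)
        rcbf_maps = []
        for pld, pairs in bundle.asl_pairs.items():
            label_mean = ScalarVolume(bundle.grid,
                                      np.mean([p[0].values for p in pairs], axis=0))
            control_mean = ScalarVolume(bundle.grid,
                                        np.mean([p[1].values for p in pairs], axis=0))
            cbf = qt.quantify_cbf(label_mean, control_mean, m0, pld, config.asl_params)
            rcbf_maps.append(qt.relative_cbf(cbf, mask))
        out["rcbf"] = gaussian_smooth(qt.average_plds(rcbf_maps), fwhm)
    if bundle.dwi is not None:
        tensors = qt.fit_diffusion_tensor(bundle.dwi, bundle.scheme)
        fa = tensors.fa_map()
        if mask is None:
            b0 = bundle.dwi[int(np.argmin(bundle.scheme.b_values))]
            mask = whole_brain_mask(b0, config.brain_mask_fraction)
        out["fa"] = gaussian_smooth(fa, fwhm)
    out["brain_mask"] = mask
    return out


def cohort_parameter_maps(config: PipelineConfig, model: CohortModel | None = None):
    """Quantify the whole cohort; returns (records, {sid: maps}, analysis mask).

    FA maps are age-corrected with a global linear model estimated from the
    SCD subjects' in-mask mean FA (when SCD subjects exist and DTI is in
    scope); the analysis mask is the intersection of subject brain masks.
    """
    model = model or CohortModel(config.cohort)
    records = model.records()
    subject_maps: dict = {}
    analysis = None
    for record in records:
        bundle = model.raw_bundle(record, config.modalities)
        maps = quantify_bundle(record, bundle, config)
        del bundle
        m = maps.pop("brain_mask")
        analysis = m if analysis is None else analysis.intersect(m)
        subject_maps[record.id] = maps
    scd = [r for r in records if r.group == "SCD"]
    if len(scd) >= 3 and "DTI" in config.modalities:
        age_model = qt.estimate_age_model(
            [subject_maps[r.id]["fa"] for r in scd], [r.age for r in scd], analysis)
        log.info("age model: slope %.2e FA/year, reference %.1f years",
                 age_model.slope_per_year, age_model.reference_age_years)
        for record in records:
            subject_maps[record.id]["fa"] = qt.age_correct_fa(
                subject_maps[record.id]["fa"], record.age, age_model)
    return records, subject_maps, analysis


# ---------------------------------------------------------------------------
# Group-level stages

_WBSS_MAP_KEY = {"PET": "suvr", "ASL": "rcbf", "DTI": "fa"}


def wbss_stage(records, subject_maps, analysis_mask, config: PipelineConfig) -> dict:
    """Each syndrome vs SCD, per modality; plus SUVR/rCBF overlap masks."""
    by_group: dict = {}
    for r in records:
        by_group.setdefault(r.group, []).append(r.id)
    results: dict = {}
    for entity in ENTITIES:
        if not by_group.get(entity) or len(by_group.get("SCD", [])) < 2:
            continue
        if len(by_group[entity]) < 2:
            continue
        per_mod = {}
        for modality in config.modalities:
            key = _WBSS_MAP_KEY[modality]
            ga = [subject_maps[s][key] for s in by_group[entity]]
            gb = [subject_maps[s][key] for s in by_group["SCD"]]
            per_mod[modality] = run_wbss(ga, gb, analysis_mask, config.wbss)
        if "PET" in per_mod and "ASL" in per_mod:
            only_a, only_b, both = modality_overlap(per_mod["PET"].surviving,
                                                    per_mod["ASL"].surviving)
            per_mod["overlap"] = {"suvr_only": only_a.n_voxels,
                                  "rcbf_only": only_b.n_voxels,
                                  "intersection": both.n_voxels}
        results[entity] = per_mod
    return results


def classification_stage(features: pd.DataFrame, groups: pd.Series,
                         config: PipelineConfig) -> dict:
    """A1 and A2 for every entity and modality set; subjects with a missing
    feature (e.g. an empty FA ROI) are excluded from that entity's models
    with a logged reason."""
    a2_seed_root = _child_seed(config.cohort.seed, "a2").generate_state(1)[0] % (2 ** 31)
    results: dict = {"a1": {}, "a2": {}, "excluded": {}}
    for mset, mods in MODALITY_SETS.items():
        if not set(mods) <= set(config.modalities):
            continue
        results["a1"][mset] = {}
        results["a2"][mset] = {}
        for i, entity in enumerate(ENTITIES):
            if (groups == entity).sum() < 2:
                continue
            cols = entity_columns(features, entity, "ALL" if mset == "PET/MRI" else mset)
            ok = features[cols].notna().all(axis=1)
            if (~ok).any():
                dropped = list(features.index[~ok])
                results["excluded"][(mset, entity)] = dropped
                log.warning("classify %s/%s: excluding %d subjects with missing "
                            "features: %s", mset, entity, len(dropped), dropped)
            X = features.loc[ok, cols].to_numpy()
            g = groups[ok].to_numpy()
            results["a1"][mset][entity] = cl.run_a1(
                entity, X, g, tuple(cols), config.regularization, config.min_sensitivity)
            results["a2"][mset][entity] = cl.run_a2(
                entity, X, g, config.a2_runs, config.a2_split,
                seed=int(a2_seed_root + i), regularization=config.regularization)
    return results


def composite_stage(features: pd.DataFrame, groups: pd.Series, a1_results: dict) -> dict:
    """Composite categorization percentage C from the all-modality A1 models."""
    feature_cols = {}
    usable = pd.Series(True, index=features.index)
    for entity in a1_results:
        cols = entity_columns(features, entity, "ALL")
        feature_cols[entity] = cols
        usable &= features[cols].notna().all(axis=1)
    X = features[usable]
    g = groups[usable].to_numpy()
    flags = cl.categorize_subjects(a1_results, X, g, feature_cols)
    return {"composite_percent": cl.composite_categorization(flags),
            "n_subjects": int(usable.sum()),
            "correct_flags": {sid: bool(f) for sid, f in zip(X.index, flags)}}


def stats_stage(records, features: pd.DataFrame, groups: pd.Series) -> dict:
    """Demographics table, SCD-scaled bar data and MMSE correlations."""
    meta = pd.DataFrame({
        "group": [r.group for r in records],
        "age": [r.age for r in records],
        "mmse": [np.nan if r.mmse is None else r.mmse for r in records],
    }, index=[r.id for r in records])
    present = [g for g in GROUPS if (meta.group == g).any()]
    table1 = []
    for var in ("age", "mmse"):
        vals = {g: meta.loc[meta.group == g, var].dropna().to_numpy() for g in present}
        vals = {g: v for g, v in vals.items() if v.size}
        row: dict = {"variable": var}
        for g, v in vals.items():
            row[g] = f"{v.mean():.1f} +- {v.std(ddof=1):.1f}" if v.size > 1 else f"{v.mean():.1f}"
        if len(vals) >= 2 and sum(v.size for v in vals.values()) >= 3:
            row["kruskal_p"] = st.kruskal_wallis(list(vals.values()),
                                                 list(vals.keys())).p
        table1.append(row)
    scaled, correlations = {}, {}
    if (meta.group == "SCD").sum() >= 2:
        for entity in ENTITIES:
            if not (meta.group == entity).any():
                continue
            for col in entity_columns(features, entity, "ALL"):
                by_group = {g: features.loc[meta.group == g, col].dropna().to_numpy()
                            for g in present}
                by_group = {g: v for g, v in by_group.items() if v.size}
                try:
                    sc = st.scale_to_reference(by_group, "SCD")
                except Exception:       # degenerate reference, skip the bar
                    continue
                scaled[col] = {g: (float(v.mean()), float(v.std(ddof=1) / np.sqrt(v.size))
                                   if v.size > 1 else 0.0)
                               for g, v in sc.items()}
    for entity in ENTITIES:
        in_group = meta.group == entity
        if in_group.sum() < 3:
            continue
        mmse = meta.loc[in_group, "mmse"]
        pairs = {}
        for col in entity_columns(features, entity, "ALL"):
            x = features.loc[in_group, col]
            ok = x.notna() & mmse.notna()
            if ok.sum() >= 3:
                pairs[col] = (x[ok].to_numpy(), mmse[ok].to_numpy())
        if pairs:
            try:
                correlations[entity] = st.pearson_with_holm(pairs)
            except st.InsufficientDataError:
                pass
    return {"table1": table1, "scaled_bars": scaled, "correlations": correlations}


# ---------------------------------------------------------------------------
# Reporting and persistence

def _confusion_row(cs: cl.ConfusionSummary) -> str:
    p = cs.as_percent()
    return (f"sens {p['sensitivity']:5.1f}%  spec {p['specificity']:5.1f}%  "
            f"acc {p['accuracy']:5.1f}%  (tp={cs.tp} fn={cs.fn} tn={cs.tn} fp={cs.fp})")


def generate_report(results: dict) -> str:
    """Human-readable run summary: per-entity confusion tables, unweighted
    average-accuracy lines over the entities, and the composite percentage."""
    lines = ["run report", "=" * 60]
    clf = results.get("classification", {})
    for mset in clf.get("a1", {}):
        lines.append(f"\n[A1] modality set {mset}")
        accs = {"vs_scd": [], "vs_all": []}
        for entity, res in clf["a1"][mset].items():
            lines.append(f"  {entity:7s} vs SCD : {_confusion_row(res.vs_scd)}")
            lines.append(f"  {entity:7s} vs all : {_confusion_row(res.vs_all)}")
            if not res.specificity_target_met:
                lines.append(f"  {entity:7s} note   : 100% training specificity "
                             "unreachable; best-effort hyperplane")
            accs["vs_scd"].append(100 * res.vs_scd.accuracy)
            accs["vs_all"].append(100 * res.vs_all.accuracy)
        for cmp_, vals in accs.items():
            if vals:
                lines.append(f"  average accuracy {cmp_}: {np.mean(vals):.1f}")
    for mset in clf.get("a2", {}):
        lines.append(f"\n[A2] modality set {mset} "
                     f"({next(iter(clf['a2'][mset].values())).n_runs} runs)"
                     if clf["a2"][mset] else f"\n[A2] modality set {mset}")
        summary_accs = []
        for entity, res in clf["a2"][mset].items():
            for split in ("training", "validation", "summary"):
                agg = res.aggregates[split]
                lines.append(
                    f"  {entity:7s} {split:10s}: "
                    + "  ".join(f"{m[:4]} {v[0]:5.1f} +- {v[1]:4.1f}"
                                for m, v in agg.items()))
            summary_accs.append(res.aggregates["summary"]["accuracy"][0])
        if summary_accs:
            lines.append(f"  average summary accuracy: {np.mean(summary_accs):.1f}")
    if "composite" in results:
        comp = results["composite"]
        lines.append(f"\ncomposite categorization C = {comp['composite_percent']:.1f}% "
                     f"over {comp['n_subjects']} subjects")
    wb = results.get("wbss", {})
    if wb:
        lines.append("\n[WBSS] surviving voxels per entity/modality")
        for entity, per_mod in wb.items():
            for modality, sm in per_mod.items():
                if modality == "overlap":
                    lines.append(f"  {entity:7s} overlap SUVR/rCBF: {sm}")
                else:
                    lines.append(f"  {entity:7s} {modality:3s}: "
                                 f"{sm.surviving.n_voxels} voxels in "
                                 f"{len(sm.clusters)} clusters")
    return "\n".join(lines) + "\n"


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    return str(obj)


def _write_outputs(run_dir: Path, results: dict, config: PipelineConfig,
                   records, subject_maps) -> None:
    run_dir.mkdir(parents=True, exist_ok=True)
    results["metadata"].to_csv(run_dir / "metadata.tsv", sep="\t")
    results["features"].to_csv(run_dir / "features.tsv", sep="\t")
    builtin_catalog().to_frame().to_csv(run_dir / "roi_catalog.tsv", sep="\t", index=False)
    wb_dir = run_dir / "wbss"
    if results.get("wbss"):
        wb_dir.mkdir(exist_ok=True)
        overlap_rows = []
        for entity, per_mod in results["wbss"].items():
            for modality, sm in per_mod.items():
                if modality == "overlap":
                    overlap_rows.append(dict(entity=entity, **sm))
                else:
                    sm.clusters.to_csv(wb_dir / f"{entity}_{modality}_clusters.tsv",
                                       sep="\t", index=False)
        if overlap_rows:
            pd.DataFrame(overlap_rows).to_csv(wb_dir / "suvr_rcbf_overlap.tsv",
                                              sep="\t", index=False)
    clf_dir = run_dir / "classify"
    clf_dir.mkdir(exist_ok=True)
    a1_json = {mset: {e: {"vs_scd": r.vs_scd.as_percent() | dataclasses.asdict(r.vs_scd),
                          "vs_all": r.vs_all.as_percent() | dataclasses.asdict(r.vs_all),
                          "specificity_target_met": r.specificity_target_met,
                          "weights": r.model.weights, "bias": r.model.bias,
                          "feature_order": list(r.model.feature_order)}
                      for e, r in per.items()}
               for mset, per in results["classification"]["a1"].items()}
    (clf_dir / "a1_results.json").write_text(
        json.dumps(a1_json, indent=2, default=_json_default))
    a2_json = {mset: {e: {"n_runs": r.n_runs, "split_fraction": r.split_fraction,
                          "n_skipped": r.n_skipped, "aggregates": r.aggregates}
                      for e, r in per.items()}
               for mset, per in results["classification"]["a2"].items()}
    (clf_dir / "a2_results.json").write_text(
        json.dumps(a2_json, indent=2, default=_json_default))
    stats_dir = run_dir / "stats"
    stats_dir.mkdir(exist_ok=True)
    pd.DataFrame(results["stats"]["table1"]).to_csv(stats_dir / "group_summary.tsv",
                                                    sep="\t", index=False)
    bar_rows = [dict(feature=ftr, group=g, scaled_mean=m, scaled_sem=s)
                for ftr, per_g in results["stats"]["scaled_bars"].items()
                for g, (m, s) in per_g.items()]
    pd.DataFrame(bar_rows).to_csv(stats_dir / "scd_scaled_bars.tsv", sep="\t", index=False)
    corr_rows = [dict(entity=e, feature=c.name, r=c.r, p=c.p,
                      holm_significant=c.holm_significant, n=c.n)
                 for e, lst in results["stats"]["correlations"].items() for c in lst]
    pd.DataFrame(corr_rows).to_csv(stats_dir / "mmse_correlations.tsv",
                                   sep="\t", index=False)
    (run_dir / "report.txt").write_text(results["report"])
    manifest = {"config": config.to_dict(), "n_subjects": len(records),
                "elapsed_s": results.get("elapsed_s"),
                "composite": results.get("composite", {}).get("composite_percent")}
    (run_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=_json_default))
    if config.save_volumes:
        vol_dir = run_dir / "derived"
        vol_dir.mkdir(exist_ok=True)
        for sid, maps in subject_maps.items():
            for key, vol in maps.items():
                write_volume(vol, vol_dir / f"{sid}_{key}.nii.gz")
        if results.get("analysis_mask") is not None:
            write_mask(results["analysis_mask"], vol_dir / "analysis_mask.nii.gz")


def run_pipeline(config: PipelineConfig, run_dir=None) -> dict:
    """Execute the full workflow; returns the in-memory results dict and, if
    ``run_dir`` is given, writes all stage outputs there."""
    t0 = time.time()
    model = CohortModel(config.cohort)
    records, subject_maps, analysis = cohort_parameter_maps(config, model)
    groups = pd.Series({r.id: r.group for r in records})
    results: dict = {"metadata": model.metadata_frame(), "analysis_mask": analysis}
    if config.run_wbss_stage:
        results["wbss"] = wbss_stage(records, subject_maps, analysis, config)
    results["features"] = feature_table(subject_maps)
    results["classification"] = classification_stage(results["features"], groups, config)
    if "PET/MRI" in results["classification"]["a1"] and (groups == "SCD").any():
        results["composite"] = composite_stage(
            results["features"], groups, results["classification"]["a1"]["PET/MRI"])
    results["stats"] = stats_stage(records, results["features"], groups)
    results["elapsed_s"] = time.time() - t0
    results["report"] = generate_report(results)
    if run_dir is not None:
        _write_outputs(Path(run_dir), results, config, records, subject_maps)
    return results
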