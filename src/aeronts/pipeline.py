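"""End-to-end orchestration: simulate -> qc -> assign-formulas ->
pfas-screen -> annotate -> attribute-sources -> contrast, with a
stage-count report and headline summary."""
from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np

from . import annotation, formulas, pfas, qc, sources
from .config import RunConfig
from .model import Feature, SampleRecord
from .multivariate import contrast_descriptors, dichotomize, oplsda, select_markers
from .synthetic import (
    CampaignBundle,
    generate_campaign,
    rti_calibrants,
    synthetic_reference_library,
)


def _round_half_up(x: float) -> int:
    import math
    return int(math.floor(x + 0.5))


@dataclass
class PipelineReport:
    counts: dict[str, int] = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    wall_time_s: dict[str, float] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


@dataclass
class PipelineOutputs:
    bundle: CampaignBundle
    unique_features: list[Feature]
    dedup_pairs: list[tuple[str, str]]
    consensus: dict[str, formulas.Formula]
    candidate_tables: dict[str, list[formulas.FormulaCandidate]]
    pfas_hits: list[pfas.PfasHit]
    annotations: list[annotation.AnnotationRecord]
    clustering: sources.FuzzyClustering | None
    samples_attr: list[SampleRecord]
    pfas_profile: sources.SourceProfile | None
    opls_model: object | None
    markers: tuple[np.ndarray, np.ndarray] | None
    contrast: object | None
    report: PipelineReport = field(default_factory=PipelineReport)


def assign_formulas(features: list[Feature], config: RunConfig,
                    ) -> tuple[dict[str, formulas.Formula],
                               dict[str, list[formulas.FormulaCandidate]]]:
    """Enumerate, rank and consensus-assign formulas for eligible features."""
    consensus: dict[str, formulas.Formula] = {}
    tables: dict[str, list[formulas.FormulaCandidate]] = {}
    for f in features:
        if f.iso_m1_frac is None and f.ms2 is None:
            continue
        neutral = f.neutral_mass
        if not 10 < neutral <= 1000:
            continue
        cands = formulas.enumerate_formulas(
            neutral, config.formula_tol_ppm, config.element_bounds,
            config.ratio_caps)
        if not cands:
            continue
        ranked = formulas.rank_candidates(f, cands, config.formula_tol_ppm)
        tables[f.feature_id] = ranked
        assigned = formulas.consensus_assign(ranked, f)
        if assigned is not None:
            consensus[f.feature_id] = assigned
    return consensus, tables


def top_fragment_formulas(tables: dict[str, list[formulas.FormulaCandidate]]
                          ) -> dict[str, formulas.Formula]:
    """Top-ranked formula per feature by the fragment-explanation scorer."""
    out = {}
    for fid, cands in tables.items():
        top = [c for c in cands if c.rank_B == 1]
        if top:
            out[fid] = top[0].formula
    return out


def run_all(config: RunConfig, n_samples: int = 85, n_features: int = 2000,
            n_blanks: int = 30, seed: int | None = None,
            pfas_chain_lengths: tuple[int, ...] = (6, 7, 8, 9, 10),
            pfas_region: int = 3, **design_kw) -> PipelineOutputs:
    """Run the full synthetic-campaign analysis and report stage counts."""
    if seed is None:
        seed = config.seed
    if seed is None:
        raise ValueError("a seed is required for the synthetic pipeline")
    report = PipelineReport(params={
        "n_samples": n_samples, "n_features": n_features,
        "n_blanks": n_blanks, "seed": seed})

    t0 = time.perf_counter()
    bundle = generate_campaign(n_samples=n_samples, n_features=n_features,
                               n_blanks=n_blanks, seed=seed,
                               pfas_chain_lengths=pfas_chain_lengths,
                               pfas_region=pfas_region, **design_kw)
    report.wall_time_s["simulate"] = time.perf_counter() - t0
    report.counts["features_pos_raw"] = len(bundle.pos_features)
    report.counts["features_neg_raw"] = len(bundle.neg_features)

    # --- QC
    t0 = time.perf_counter()
    kept = {}
    for mode, feats in (("positive", bundle.pos_features),
                        ("negative", bundle.neg_features)):
        res = qc.blank_filter(feats, bundle.samples, config.blank_factor)
        model = qc.fit_is_normalization(bundle.samples)
        kept[mode] = qc.apply_normalization(res.kept, model)
        report.counts[f"features_{'pos' if mode == 'positive' else 'neg'}_kept"] = len(res.kept)
    dd = qc.dedup_across_modes(kept["positive"], kept["negative"],
                               config.dedup_mass_tol_da, config.dedup_rt_tol_min)
    unique = qc.scale_unit_interval(dd.unique)
    report.counts["dedup_pairs"] = len(dd.pairs)
    report.counts["unique_features"] = len(unique)
    report.wall_time_s["qc"] = time.perf_counter() - t0

    # --- formulas
    t0 = time.perf_counter()
    consensus, tables = assign_formulas(unique, config)
    report.counts["consensus_assigned"] = len(consensus)
    report.wall_time_s["assign_formulas"] = time.perf_counter() - t0

    # --- PFAS screen
    t0 = time.perf_counter()
    neg_spectra = {f.feature_id: f.ms2 for f in unique
                   if f.mode == "negative" and f.ms2 is not None}
    hits = pfas.flag_pfas(neg_spectra, top_fragment_formulas(tables),
                          config.pfas_fragment_tol_da,
                          config.pfas_min_rel_intensity)
    report.counts["pfas_fragment_hits"] = sum(
        1 for h in hits if h.status in ("fragment_only", "confirmed_pfas"))
    report.counts["pfas_confirmed"] = sum(
        1 for h in hits if h.status == "confirmed_pfas")
    report.wall_time_s["pfas_screen"] = time.perf_counter() - t0

    # --- annotation
    t0 = time.perf_counter()
    calib = annotation.fit_rti(rti_calibrants())
    library, _ = synthetic_reference_library(bundle, n_entries=40)
    by_id = {f.feature_id: f for f in unique}
    records = []
    for fid, f in by_id.items():
        if f.ms2 is None:
            continue
        recs = annotation.library_match(fid, f.ms2, library,
                                        config.library_score_min,
                                        config.ms1_tol_da, config.ms2_tol_da)
        for r in recs:
            r.feature_rt = f.rt
        records.extend(recs)
    records = annotation.rti_filter(records, calib, config.rti_max_delta)
    records = annotation.assign_levels(records, standards_confirmed=set(),
                                       consensus_formulas=consensus,
                                       score_min=config.library_score_min,
                                       max_delta=config.rti_max_delta)
    report.counts["annotations_level2"] = sum(1 for r in records if r.level == "2")
    report.wall_time_s["annotate"] = time.perf_counter() - t0

    # --- source attribution (recompute cluster weights from trajectories)
    t0 = time.perf_counter()
    clustering = sources.fuzzy_cmeans(
        bundle.trajectories, c=config.n_clusters, m=config.fuzzifier,
        seed=seed, assignment_threshold=config.assignment_threshold)
    from .synthetic import REGION_CENTROIDS
    region_map = sources.label_clusters_by_origin(
        clustering, bundle.trajectories, REGION_CENTROIDS)
    weights = sources.sample_cluster_weights(clustering, region_map)
    samples_attr = [replace(s, cluster_weights=weights.get(s.sample_id, {}))
                    if not s.is_field_blank else s for s in bundle.samples]
    pfas_features = [by_id[h.feature_id] for h in hits
                     if h.status == "confirmed_pfas" and h.feature_id in by_id]
    pfas_profile = (sources.group_source_profile(pfas_features, samples_attr)
                    if pfas_features else None)
    report.counts["clustered_trajectories_pct"] = _round_half_up(
        100 * clustering.clustered_fraction)
    report.wall_time_s["attribute_sources"] = time.perf_counter() - t0

    # --- multivariate contrast (temperature rule)
    t0 = time.perf_counter()
    non_blank = [s for s in samples_attr if not s.is_field_blank]
    X = np.array([[f.areas.get(s.sample_id, 0.0) for f in unique]
                  for s in non_blank])
    y = dichotomize(non_blank, "temperature", config.temperature_split_C)
    opls_model = markers = contrast = None
    if min((y == 1).sum(), (y == -1).sum()) >= config.cv_folds:
        opls_model = oplsda(X, y, config.n_ortho, config.cv_folds,
                            seed=seed, scaling=config.scaling)
        markers = select_markers(opls_model, config.vip_min, config.pcorr_min)
        dbe_a = [formulas.dbe(consensus[unique[j].feature_id])
                 for j in markers[0] if unique[j].feature_id in consensus]
        dbe_b = [formulas.dbe(consensus[unique[j].feature_id])
                 for j in markers[1] if unique[j].feature_id in consensus]
        contrast = contrast_descriptors(dbe_a, dbe_b)
        report.counts["markers_high"] = len(markers[0])
        report.counts["markers_low"] = len(markers[1])
    else:
        report.warnings.append("temperature classes too small for OPLS-DA; skipped")
    report.wall_time_s["contrast"] = time.perf_counter() - t0

    outputs = PipelineOutputs(
        bundle=bundle, unique_features=unique, dedup_pairs=dd.pairs,
        consensus=consensus, candidate_tables=tables, pfas_hits=hits,
        annotations=records, clustering=clustering, samples_attr=samples_attr,
        pfas_profile=pfas_profile, opls_model=opls_model, markers=markers,
        contrast=contrast, report=report)
    report.summary = summarize_campaign(outputs)
    return outputs


def summarize_campaign(out: PipelineOutputs) -> dict:
    """Headline numbers: per-mode totals, redundancy, assignment rates,
    descriptor histograms, PFAS and annotation counts."""
    r = out.report.counts
    n_pos = r.get("features_pos_kept", 0)
    n_neg = r.get("features_neg_kept", 0)
    n_pairs = len(out.dedup_pairs)
    n_unique = len(out.unique_features)
    n_detected = n_pos + n_neg
    n_assigned = len(out.consensus)
    dbes = [formulas.dbe(f) for f in out.consensus.values()]
    classes: dict[str, int] = {}
    for f in out.consensus.values():
        k = formulas.heteroatom_class(f)
        classes[k] = classes.get(k, 0) + 1
    levels: dict[str, int] = {}
    for rec in out.annotations:
        levels[rec.level] = levels.get(rec.level, 0) + 1
    summary = {
        "features_pos": n_pos,
        "features_neg": n_neg,
        "redundant_pairs": n_pairs,
        "unique_features": n_unique,
        "unique_identity_holds": n_unique == n_pos + n_neg - n_pairs,
        "detected_features": n_detected,
        "consensus_assigned": n_assigned,
        "pct_assigned_of_detected": _round_half_up(100 * n_assigned / n_detected)
        if n_detected else 0,
        "frac_assigned_of_detected": n_assigned / n_detected if n_detected else 0.0,
        "pct_assigned_of_unique": _round_half_up(100 * n_assigned / n_unique)
        if n_unique else 0,
        "frac_assigned_of_unique": n_assigned / n_unique if n_unique else 0.0,
        "formula_class_counts": dict(sorted(classes.items(),
                                            key=lambda kv: -kv[1])[:15]),
        "pct_dbe_ge_4": _round_half_up(100 * np.mean([d >= 4 for d in dbes]))
        if dbes else 0,
        "pfas_fragment_hits": r.get("pfas_fragment_hits", 0),
        "pfas_confirmed": r.get("pfas_confirmed", 0),
        "annotation_level_counts": levels,
        "clustered_trajectories_pct": r.get("clustered_trajectories_pct"),
    }
    if out.markers is not None:
        summary["markers_high"] = len(out.markers[0])
        summary["markers_low"] = len(out.markers[1])
    if out.opls_model is not None:
        summary["opls_r2"] = round(float(out.opls_model.r2), 3)
        summary["opls_q2"] = round(float(out.opls_model.q2), 3)
    return summary
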