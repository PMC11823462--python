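"""Feature-table quality control.

Four steps, applied in order: field-blank filtering (5x rule),
internal-standard normalization by the first principal component of the
UVN-scaled IS matrix, cross-mode deduplication of ions detected in both
polarities, and per-feature scaling of areas to [0, 1].
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .model import Feature, SampleRecord


@dataclass
class BlankFilterResult:
    kept: list[Feature]
    removed: list[Feature]
    #: feature_id -> (max sample area, blank mean) that triggered the decision
    stats: dict[str, tuple[float, float]] = field(default_factory=dict)


def blank_filter(features: list[Feature], samples: list[SampleRecord],
                 factor: float = 5.0) -> BlankFilterResult:
    """Keep a feature iff its maximal sample area exceeds ``factor`` times
    the mean area over field blanks (strict inequality)."""
    blank_ids = [s.sample_id for s in samples if s.is_field_blank]
    sample_ids = [s.sample_id for s in samples if not s.is_field_blank]
    if not blank_ids:
        raise ValueError(
            "no field blanks in metadata; pass factor=0 explicitly to disable "
            "blank filtering")
    res = BlankFilterResult(kept=[], removed=[])
    for f in features:
        blank_mean = float(np.mean([f.areas.get(b, 0.0) for b in blank_ids]))
        max_area = max((f.areas.get(s, 0.0) for s in sample_ids), default=0.0)
        res.stats[f.feature_id] = (max_area, blank_mean)
        if max_area > factor * blank_mean:
            res.kept.append(f)
        else:
            res.removed.append(f)
    return res


@dataclass
class NormalizationModel:
    """PCA t1 scores of the internal-standard matrix, UVN scaling."""

    sample_ids: list[str]
    standard_names: list[str]
    t1_scores: dict[str, float]
    scaling: str = "UVN"


def fit_is_normalization(samples: list[SampleRecord]) -> NormalizationModel:
    """First-PC scores of the samples x standards IS-area matrix.

    Columns are scaled to unit variance *without* centering; the t1 score
    is the first right-singular-vector projection, sign-fixed so the mean
    score is positive.
    """
    if len(samples) < 2:
        raise ValueError("need >= 2 samples to fit IS normalization")
    std_names = list(samples[0].is_areas)
    for s in samples:
        if list(s.is_areas) != std_names:
            raise ValueError(f"sample {s.sample_id}: internal-standard set differs")
    X = np.array([[s.is_areas[n] for n in std_names] for s in samples], float)
    if np.any(X <= 0):
        raise ValueError("internal-standard areas must be positive")
    sd = X.std(axis=0, ddof=1)
    zero_var = sd == 0
    if zero_var.any():
        warnings.warn(
            f"internal standards with zero variance passed through unscaled: "
            f"{[n for n, z in zip(std_names, zero_var) if z]}")
        sd = np.where(zero_var, 1.0, sd)
    Xs = X / sd
    # first principal component of the *uncentered* matrix = first SVD pair
    _, _, vt = np.linalg.svd(Xs, full_matrices=False)
    t1 = Xs @ vt[0]
    if t1.mean() < 0:
        t1 = -t1
    if np.any(t1 <= 0):
        raise ValueError("non-positive t1 score; IS matrix is degenerate")
    return NormalizationModel(
        sample_ids=[s.sample_id for s in samples],
        standard_names=std_names,
        t1_scores={s.sample_id: float(v) for s, v in zip(samples, t1)},
    )


def apply_normalization(features: list[Feature],
                        model: NormalizationModel) -> list[Feature]:
    """Divide each area by its sample's t1 score. Not idempotent; callers
    track application through the returned copies."""
    out = []
    for f in features:
        areas = {}
        for sid, a in f.areas.items():
            if sid not in model.t1_scores:
                raise ValueError(f"sample {sid} missing from normalization model")
            areas[sid] = a / model.t1_scores[sid]
        out.append(replace(f, areas=areas))
    return out


@dataclass
class DedupResult:
    unique: list[Feature]
    pairs: list[tuple[str, str]]  # (pos_id, neg_id)
    log: list[str] = field(default_factory=list)


def dedup_across_modes(pos: list[Feature], neg: list[Feature],
                       mass_tol: float = 0.001,
                       rt_tol: float = 0.15) -> DedupResult:
    """Collapse ions detected in both polarities into one unique feature.

    Neutral masses ([M+H]+ / [M-H]- convention) within ``mass_tol`` Da and
    retention times within ``rt_tol`` min flag a redundant pair; ambiguous
    multi-matches resolve greedily by smallest neutral-mass difference.
    The member from the mode with the larger median area is retained.
    """
    cand = []
    for p in pos:
        for n in neg:
            dm = abs(p.neutral_mass - n.neutral_mass)
            drt = abs(p.rt - n.rt)
            # inclusive tolerances; epsilon keeps boundary cases stable
            # against float round-off in the neutral-mass conversion
            if dm <= mass_tol + 1e-12 and drt <= rt_tol + 1e-12:
                cand.append((dm, p.feature_id, n.feature_id))
    cand.sort(key=lambda t: (t[0], t[1], t[2]))
    used_pos: set[str] = set()
    used_neg: set[str] = set()
    pairs: list[tuple[str, str]] = []
    log: list[str] = []
    for dm, pid, nid in cand:
        if pid in used_pos or nid in used_neg:
            log.append(f"ambiguous match {pid}/{nid} (|dM|={dm:.5f} Da) skipped")
            continue
        used_pos.add(pid)
        used_neg.add(nid)
        pairs.append((pid, nid))
    by_id = {f.feature_id: f for f in pos + neg}
    drop: set[str] = set()
    for pid, nid in pairs:
        p, n = by_id[pid], by_id[nid]
        med_p = float(np.median(list(p.areas.values()))) if p.areas else 0.0
        med_n = float(np.median(list(n.areas.values()))) if n.areas else 0.0
        loser = nid if med_p >= med_n else pid
        drop.add(loser)
        log.append(f"pair {pid}/{nid}: kept {'pos' if loser == nid else 'neg'} member")
    unique = [f for f in pos + neg if f.feature_id not in drop]
    return DedupResult(unique=unique, pairs=pairs, log=log)


def expected_unique(n_pos: int, n_neg: int, n_pairs: int) -> int:
    """Unique-feature count identity: |pos| + |neg| - |redundant pairs|."""
    return n_pos + n_neg - n_pairs


def scale_unit_interval(features: list[Feature]) -> list[Feature]:
    """Per-feature max-scaling of areas to [0, 1]; all-zero features stay zero."""
    out = []
    for f in features:
        top = max(f.areas.values(), default=0.0)
        if top > 0:
            areas = {s: a / top for s, a in f.areas.items()}
        else:
            areas = dict(f.areas)
        out.append(replace(f, areas=areas))
    return out
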