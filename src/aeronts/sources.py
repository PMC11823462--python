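"""Back-trajectory source attribution.

Hourly 48 h back-trajectories are featurized as concatenated
(lat, lon) endpoint vectors, clustered into source regions with fuzzy
c-means, and each sample receives per-region cluster weights (the
fraction of its trajectories whose maximal membership exceeds the
assignment threshold). Per-feature source contributions are the
area-weighted shares of those cluster weights over the campaign.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import Feature, SampleRecord, TrajectoryEndpointSet


@dataclass
class FuzzyClustering:
    n_clusters: int
    fuzzifier: float
    centroids: np.ndarray            # (c, d) in feature space
    memberships: np.ndarray          # (n, c), rows sum to 1
    objective: list[float]           # per-iteration objective values
    assignment_threshold: float
    labels: np.ndarray               # argmax cluster per trajectory
    clustered: np.ndarray            # bool, max membership >= threshold
    traj_index: list[tuple[str, str]]  # (sample_id, traj_id) per row

    @property
    def clustered_fraction(self) -> float:
        return float(self.clustered.mean())


def featurize_trajectories(sets: list[TrajectoryEndpointSet]
                           ) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Stack each trajectory's (lat, lon) endpoints into one row vector,
    standardized per coordinate. All trajectories must share the length."""
    rows, index = [], []
    for ts in sets:
        for tid, pts in ts.trajectories.items():
            vec = []
            for _, lat, lon in pts:
                vec.extend((lat, lon))
            rows.append(vec)
            index.append((ts.sample_id, tid))
    if not rows:
        raise ValueError("no trajectories to featurize")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"trajectories have differing endpoint counts: {sorted(lengths)}")
    X = np.asarray(rows, float)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = (X - X.mean(axis=0)) / sd
    return X, index


def fuzzy_cmeans(trajectories: list[TrajectoryEndpointSet], c: int = 6,
                 m: float = 2.0, tol: float = 1e-6, max_iter: int = 300,
                 seed: int = 0, assignment_threshold: float = 0.6,
                 n_init: int = 4) -> FuzzyClustering:
    """Standard fuzzy c-means on featurized trajectories.

    Memberships u_ij = 1 / sum_k (d_ij/d_kj)^(2/(m-1)); centroids are
    membership^m-weighted means. Zero distance to a centroid gives that
    centroid full membership. ``n_init`` random restarts guard against
    poor local optima; the run with the lowest objective is kept.
    """
    if c < 2:
        raise ValueError("need at least 2 clusters")
    if m <= 1:
        raise ValueError("fuzzifier must be > 1")
    X, index = featurize_trajectories(trajectories)
    best = None
    for restart in range(max(1, n_init)):
        run = _fcm_once(X, index, c, m, tol, max_iter,
                        np.random.default_rng([seed, restart]),
                        assignment_threshold)
        if best is None or run.objective[-1] < best.objective[-1]:
            best = run
    return best


def _fcm_once(X: np.ndarray, index, c: int, m: float, tol: float,
              max_iter: int, rng: np.random.Generator,
              assignment_threshold: float) -> FuzzyClustering:
    n = X.shape[0]
    U = rng.dirichlet(np.ones(c), size=n)  # (n, c)
    objective = []
    prev = np.inf
    for _ in range(max_iter):
        Um = U ** m
        centroids = (Um.T @ X) / Um.sum(axis=0)[:, None]
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        obj = float((Um * d2).sum())
        objective.append(obj)
        zero = d2 <= 1e-18
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d2 ** (-1.0 / (m - 1))
            U_new = inv / inv.sum(axis=1, keepdims=True)
        rows_zero = zero.any(axis=1)
        if rows_zero.any():
            U_new[rows_zero] = 0.0
            U_new[rows_zero, np.argmax(zero[rows_zero], axis=1)] = 1.0
        shift = float(np.abs(U_new - U).max())
        U = U_new
        if shift < tol or abs(prev - obj) < tol * max(1.0, abs(obj)):
            break
        prev = obj
    labels = U.argmax(axis=1)
    clustered = U.max(axis=1) >= assignment_threshold
    return FuzzyClustering(
        n_clusters=c, fuzzifier=m, centroids=centroids, memberships=U,
        objective=objective, assignment_threshold=assignment_threshold,
        labels=labels, clustered=clustered, traj_index=index)


def label_clusters_by_origin(clustering: FuzzyClustering,
                             trajectories: list[TrajectoryEndpointSet],
                             region_centroids: dict[int, tuple[float, float]]
                             ) -> dict[int, int]:
    """Map cluster index (0-based) -> named region id by matching each
    cluster's membership-weighted mean origin endpoint (earliest hour) to
    the reference regional centroids (Hungarian assignment)."""
    from scipy.optimize import linear_sum_assignment

    origins = []
    for ts in trajectories:
        for _, pts in ts.trajectories.items():
            h0 = min(p[0] for p in pts)
            lat, lon = next((la, lo) for h, la, lo in pts if h == h0)
            origins.append((lat, lon))
    origins = np.asarray(origins)
    Um = clustering.memberships ** clustering.fuzzifier
    mean_origin = (Um.T @ origins) / Um.sum(axis=0)[:, None]
    regions = sorted(region_centroids)
    cost = np.array([[np.sum((mean_origin[i] - np.asarray(region_centroids[r])) ** 2)
                      for r in regions] for i in range(clustering.n_clusters)])
    rows, cols = linear_sum_assignment(cost)
    return {int(i): regions[j] for i, j in zip(rows, cols)}


def sample_cluster_weights(clustering: FuzzyClustering,
                           region_map: dict[int, int] | None = None
                           ) -> dict[str, dict[int, float]]:
    """Per-sample cluster weights: the fraction of a sample's trajectories
    clustered (max membership >= threshold) to each region (1-based ids,
    optionally relabeled through ``region_map``). The unclustered fraction
    leaves the weights summing below 1."""
    totals: dict[str, int] = {}
    counts: dict[str, dict[int, int]] = {}
    for (sid, _), lab, ok in zip(clustering.traj_index,
                                 clustering.labels, clustering.clustered):
        totals[sid] = totals.get(sid, 0) + 1
        if ok:
            counts.setdefault(sid, {})
            region = region_map[int(lab)] if region_map else int(lab) + 1
            counts[sid][region] = counts[sid].get(region, 0) + 1
    out = {}
    for sid, tot in totals.items():
        out[sid] = {r: n / tot for r, n in sorted(counts.get(sid, {}).items())}
    return out


@dataclass
class SourceProfile:
    per_region_pct: dict[int, float]
    baseline_pct: dict[int, float]
    enrichment: dict[int, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.enrichment:
            self.enrichment = {
                r: self.per_region_pct.get(r, 0.0) - self.baseline_pct.get(r, 0.0)
                for r in self.baseline_pct}


def _baseline(samples: list[SampleRecord], regions: list[int]) -> dict[int, float]:
    means = {r: float(np.mean([s.cluster_weights.get(r, 0.0) for s in samples]))
             for r in regions}
    total = sum(means.values())
    if total <= 0:
        raise ValueError("no clustered trajectory mass in any sample")
    return {r: v / total * 100 for r, v in means.items()}


def _profile_from_areas(area_by_sample: dict[str, float],
                        samples: list[SampleRecord]) -> SourceProfile:
    regions = sorted({r for s in samples for r in s.cluster_weights})
    num = {r: 0.0 for r in regions}
    denom = 0.0
    for s in samples:
        a = area_by_sample.get(s.sample_id, 0.0)
        for r in regions:
            w = s.cluster_weights.get(r, 0.0)
            num[r] += a * w
            denom += a * w
    if denom <= 0:
        raise ValueError("all-zero scaled areas: source profile undefined")
    pct = {r: num[r] / denom * 100 for r in regions}
    return SourceProfile(per_region_pct=pct, baseline_pct=_baseline(samples, regions))


def feature_source_profile(feature: Feature,
                           samples: list[SampleRecord]) -> SourceProfile:
    """Relative contribution (%) of each source region to one feature:
    contribution(r) = sum_s area_s * w_r(s) / sum_s sum_r area_s * w_r(s) * 100.
    """
    non_blank = [s for s in samples if not s.is_field_blank]
    return _profile_from_areas(feature.areas, non_blank)


def group_source_profile(features: list[Feature],
                         samples: list[SampleRecord]) -> SourceProfile:
    """Profile of a feature set, computed on summed scaled areas."""
    if not features:
        raise ValueError("empty feature set")
    non_blank = [s for s in samples if not s.is_field_blank]
    summed: dict[str, float] = {}
    for f in features:
        for sid, a in f.areas.items():
            summed[sid] = summed.get(sid, 0.0) + a
    return _profile_from_areas(summed, non_blank)
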