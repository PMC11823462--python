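"""Fuzzy c-means clustering and source-region contribution profiles."""
import numpy as np
import pytest

from aeronts import sources
from aeronts.model import Feature, SampleRecord, TrajectoryEndpointSet


def _traj_set(sample_id, clouds, rng, n_per_cloud=10, sd=0.3):
    """Trajectory sets as Gaussian clouds around (lat, lon) targets."""
    trajs = {}
    k = 0
    for (lat, lon) in clouds:
        for _ in range(n_per_cloud):
            pts = [(-12.0 + h, lat + rng.normal(0, sd), lon + rng.normal(0, sd))
                   for h in range(0, 12, 3)]
            trajs[f"{sample_id}_t{k}"] = pts
            k += 1
    return TrajectoryEndpointSet(sample_id=sample_id, trajectories=trajs)


class TestFuzzyCmeans:
    def test_memberships_row_sum_to_one(self):
        rng = np.random.default_rng(1)
        sets = [_traj_set("s1", [(40, 130), (25, 110)], rng)]
        cl = sources.fuzzy_cmeans(sets, c=2, seed=1)
        assert np.allclose(cl.memberships.sum(axis=1), 1.0)

    def test_well_separated_clouds_recovered(self):
        rng = np.random.default_rng(2)
        sets = [_traj_set("s1", [(40, 130)], rng, sd=0.05),
                ("placeholder")]
        sets = [_traj_set("s1", [(40, 130)], rng, sd=0.05),
                _traj_set("s2", [(20, 100)], rng, sd=0.05)]
        cl = sources.fuzzy_cmeans(sets, c=2, seed=2)
        # separation ~10 sigma: own-cloud memberships > 0.99
        assert (cl.memberships.max(axis=1) > 0.99).all()
        labels_s1 = {int(l) for (sid, _), l in zip(cl.traj_index, cl.labels)
                     if sid == "s1"}
        labels_s2 = {int(l) for (sid, _), l in zip(cl.traj_index, cl.labels)
                     if sid == "s2"}
        assert labels_s1.isdisjoint(labels_s2)

    def test_objective_nonincreasing(self):
        rng = np.random.default_rng(3)
        sets = [_traj_set("s1", [(40, 130), (30, 120), (20, 110)], rng, sd=2.0)]
        cl = sources.fuzzy_cmeans(sets, c=3, seed=3)
        diffs = np.diff(cl.objective)
        assert (diffs <= 1e-9).all()

    def test_needs_two_clusters(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError):
            sources.fuzzy_cmeans([_traj_set("s", [(40, 130)], rng)], c=1)


def _sample(sid, weights, blank=False):
    return SampleRecord(sid, "2021-01-01", "2021-01-04", 10.0, blank,
                        cluster_weights=weights)


def _feat(areas):
    return Feature("f", "positive", 100.0, 1.0, areas)


class TestProfiles:
    def test_single_sample_split_weights(self):
        prof = sources.feature_source_profile(
            _feat({"s1": 1.0}), [_sample("s1", {1: 0.5, 3: 0.5})])
        assert prof.per_region_pct[1] == pytest.approx(50.0)
        assert prof.per_region_pct[3] == pytest.approx(50.0)

    def test_feature_confined_to_one_region(self):
        samples = [_sample("s1", {5: 1.0}), _sample("s2", {2: 1.0})]
        prof = sources.feature_source_profile(_feat({"s1": 0.8, "s2": 0.0}), samples)
        assert prof.per_region_pct[5] == pytest.approx(100.0)
        assert prof.per_region_pct[2] == pytest.approx(0.0)

    def test_percentages_sum_to_100_and_enrichment_to_zero(self):
        rng = np.random.default_rng(5)
        samples = []
        for i in range(12):
            w = rng.dirichlet(np.ones(6)) * 0.8
            samples.append(_sample(f"s{i}", {r + 1: float(v) for r, v in enumerate(w)}))
        prof = sources.feature_source_profile(
            _feat({s.sample_id: float(rng.uniform(0.1, 1)) for s in samples}), samples)
        assert sum(prof.per_region_pct.values()) == pytest.approx(100.0)
        assert sum(prof.baseline_pct.values()) == pytest.approx(100.0)
        assert sum(prof.enrichment.values()) == pytest.approx(0.0, abs=1e-9)

    def test_profile_scale_invariant(self):
        samples = [_sample("s1", {1: 0.6, 2: 0.4}), _sample("s2", {2: 1.0})]
        a = sources.feature_source_profile(_feat({"s1": 0.2, "s2": 0.5}), samples)
        b = sources.feature_source_profile(_feat({"s1": 0.6, "s2": 1.5}), samples)
        for r in a.per_region_pct:
            assert a.per_region_pct[r] == pytest.approx(b.per_region_pct[r])

    def test_all_zero_areas_flagged(self):
        with pytest.raises(ValueError, match="all-zero"):
            sources.feature_source_profile(_feat({"s1": 0.0}),
                                           [_sample("s1", {1: 1.0})])

    def test_group_of_one_equals_feature_profile(self):
        samples = [_sample("s1", {1: 0.7, 4: 0.3}), _sample("s2", {4: 0.9})]
        f = _feat({"s1": 0.4, "s2": 0.9})
        a = sources.feature_source_profile(f, samples)
        g = sources.group_source_profile([f], samples)
        assert a.per_region_pct == pytest.approx(g.per_region_pct)

    def test_duplicate_features_do_not_change_group_profile(self):
        samples = [_sample("s1", {1: 0.7, 4: 0.3}), _sample("s2", {4: 0.9})]
        f = _feat({"s1": 0.4, "s2": 0.9})
        one = sources.group_source_profile([f], samples)
        two = sources.group_source_profile([f, f], samples)
        assert one.per_region_pct == pytest.approx(two.per_region_pct)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            sources.group_source_profile([], [_sample("s1", {1: 1.0})])


class TestCampaignRecovery:
    def test_noiseless_limit_recovers_emission_weights(self):
        """At area noise sigma = 0.01 on the balanced validation layout, the
        campaign-wide contribution estimate matches the planted emission
        weights within 2 percentage points."""
        from aeronts.qc import scale_unit_interval
        from aeronts.synthetic import design_campaign, realize_campaign

        truth = design_campaign(n_samples=84, n_features=25, n_blanks=4, seed=21,
                                schedule_mode="balanced", sigma_area=0.01,
                                frac_contaminant=0.0, temp_coeff_sd=0.0,
                                detection_floor=0.0, n_traj=48)
        b = realize_campaign(truth)
        feats = {f.feature_id: f
                 for f in scale_unit_interval(b.pos_features + b.neg_features)}
        worst = 0.0
        for c in truth.compounds:
            prof = sources.feature_source_profile(
                feats[b.feature_ids[c.name][0]], b.samples)
            for r in range(1, 7):
                worst = max(worst, abs(prof.per_region_pct.get(r, 0.0)
                                       - 100 * c.emission[r - 1]))
        assert worst < 2.0

    def test_pfas_group_argmax_is_planted_region(self):
        from aeronts.qc import scale_unit_interval
        from aeronts.synthetic import generate_campaign

        b = generate_campaign(n_samples=60, n_features=30, n_blanks=4, seed=17,
                              schedule_mode="balanced", pfas_chain_lengths=(7, 8, 9),
                              pfas_region=3, frac_contaminant=0.0)
        feats = {f.feature_id: f
                 for f in scale_unit_interval(b.pos_features + b.neg_features)}
        group = [feats[fid] for c in b.truth.planted_pfas
                 for fid in b.feature_ids[c.name]]
        prof = sources.group_source_profile(group, b.samples)
        assert max(prof.per_region_pct, key=prof.per_region_pct.get) == 3
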