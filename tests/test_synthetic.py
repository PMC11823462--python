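"""Synthetic campaign generator: determinism, planted truths, round trips."""
import numpy as np
import pytest

from aeronts import io, qc
from aeronts.synthetic import (
    design_campaign,
    generate_campaign,
    plant_pfas_series,
    realize_campaign,
    write_campaign,
)


class TestSchedule:
    def test_sample_and_blank_counts(self):
        b = generate_campaign(n_samples=85, n_features=20, n_blanks=30, seed=1,
                              pfas_chain_lengths=())
        assert sum(1 for s in b.samples if not s.is_field_blank) == 85
        assert sum(1 for s in b.samples if s.is_field_blank) == 30

    def test_seed_is_mandatory(self):
        with pytest.raises(ValueError, match="seed"):
            design_campaign(n_samples=10, n_features=5, n_blanks=2)

    def test_same_seed_identical_outputs(self, tmp_path):
        b1 = generate_campaign(n_samples=12, n_features=30, n_blanks=4, seed=5)
        b2 = generate_campaign(n_samples=12, n_features=30, n_blanks=4, seed=5)
        write_campaign(b1, tmp_path / "a")
        write_campaign(b2, tmp_path / "b")
        for name in ("features_pos.tsv", "features_neg.tsv", "spectra.msp",
                     "samples.tsv", "trajectories.tsv", "truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_different_seed_differs(self):
        b1 = generate_campaign(n_samples=12, n_features=30, n_blanks=4, seed=5)
        b2 = generate_campaign(n_samples=12, n_features=30, n_blanks=4, seed=6)
        assert b1.pos_features[0].mz != b2.pos_features[0].mz

    def test_seasonal_temperatures_cycle(self):
        b = generate_campaign(n_samples=48, n_features=5, n_blanks=2, seed=2,
                              pfas_chain_lengths=())
        temps = [s.mean_temp_C for s in b.samples if not s.is_field_blank]
        assert max(temps) > 18 and min(temps) < 5


class TestAreas:
    def test_degenerate_compound_uniform_across_regions(self):
        """temp_coeff = 0 and uniform emission: expected area independent of
        the dominant source region (up to noise)."""
        truth = design_campaign(n_samples=84, n_features=1, n_blanks=2, seed=3,
                                schedule_mode="balanced", sigma_area=0.05,
                                frac_contaminant=0.0, temp_coeff_sd=0.0,
                                detection_floor=0.0)
        c = truth.compounds[0]
        c.emission = tuple([1 / 6] * 6)
        c.temp_coeff = 0.0
        b = realize_campaign(truth)
        feat = (b.pos_features + b.neg_features)[0]
        by_region = {r: [] for r in range(1, 7)}
        for s in b.samples:
            if s.is_field_blank or not s.cluster_weights:
                continue
            dom = max(s.cluster_weights, key=s.cluster_weights.get)
            by_region[dom].append(feat.areas[s.sample_id])
        means = [np.mean(v) for v in by_region.values() if v]
        assert max(means) / min(means) < 1.2

    def test_contaminants_removed_by_blank_rule_others_survive(self):
        b = generate_campaign(n_samples=30, n_features=200, n_blanks=10, seed=8,
                              pfas_chain_lengths=())
        contam = {fid for c in b.truth.compounds if c.contaminant
                  for fid in b.feature_ids[c.name]}
        for feats in (b.pos_features, b.neg_features):
            res = qc.blank_filter(feats, b.samples)
            removed = {f.feature_id for f in res.removed}
            present = {f.feature_id for f in feats}
            assert present & contam <= removed
            assert removed <= contam

    def test_is_normalization_reduces_drift_cv(self):
        """Per-batch IS drift is multiplicative on all areas; dividing by the
        t1 score reduces the population-mean CV of drift-free compounds."""
        b = generate_campaign(n_samples=40, n_features=150, n_blanks=8, seed=9,
                              pfas_chain_lengths=())
        model = qc.fit_is_normalization(b.samples)
        sids = [s.sample_id for s in b.samples if not s.is_field_blank]
        cv_raw, cv_norm = [], []
        normed = {f.feature_id: f
                  for f in qc.apply_normalization(b.pos_features, model)}
        for c in b.truth.compounds:
            if c.contaminant or abs(c.temp_coeff) > 0.01 or "positive" not in c.modes:
                continue
            fid = b.feature_ids[c.name][0]
            raw = np.array([next(f for f in b.pos_features
                                 if f.feature_id == fid).areas[s] for s in sids])
            nrm = np.array([normed[fid].areas[s] for s in sids])
            if raw.min() <= 0:
                continue
            cv_raw.append(raw.std() / raw.mean())
            cv_norm.append(nrm.std() / nrm.mean())
        assert np.mean(cv_norm) < np.mean(cv_raw)


class TestPfasPlanting:
    def test_single_chain_has_expected_fragments(self):
        truth = design_campaign(n_samples=6, n_features=3, n_blanks=2, seed=4)
        truth = plant_pfas_series(truth, [8], region=3)
        (comp,) = truth.planted_pfas
        assert comp.formula.hill() == "C8HF15O2"
        frag_mzs = [mz for mz, _ in comp.explicit_fragments]
        assert any(abs(m - 168.98937) < 1e-4 for m in frag_mzs)  # C3F7-
        assert any(abs(m - 218.98618) < 1e-4 for m in frag_mzs)  # C4F9-
        assert comp.emission[2] >= 0.6

    def test_empty_chain_list_leaves_truth_unchanged(self):
        truth = design_campaign(n_samples=6, n_features=3, n_blanks=2, seed=4)
        assert plant_pfas_series(truth, [], region=3) is truth

    def test_homolog_series_cf2_spacing(self):
        truth = design_campaign(n_samples=6, n_features=3, n_blanks=2, seed=4)
        truth = plant_pfas_series(truth, [8, 9, 10], region=2)
        masses = sorted(c.formula.mass for c in truth.planted_pfas)
        for a, b in zip(masses, masses[1:]):
            assert b - a == pytest.approx(49.99681, abs=1e-5)

    def test_invalid_region_rejected(self):
        truth = design_campaign(n_samples=6, n_features=3, n_blanks=2, seed=4)
        with pytest.raises(ValueError, match="region"):
            plant_pfas_series(truth, [8], region=7)

    def test_invalid_chain_rejected(self):
        truth = design_campaign(n_samples=6, n_features=3, n_blanks=2, seed=4)
        with pytest.raises(ValueError, match="chain"):
            plant_pfas_series(truth, [3], region=2)


class TestRoundTrip:
    def test_write_then_read_equal_tables(self, tmp_path):
        b = generate_campaign(n_samples=8, n_features=25, n_blanks=3, seed=6)
        out = tmp_path / "camp"
        write_campaign(b, out)
        pos = io.read_feature_table(out / "features_pos.tsv", "positive")
        neg = io.read_feature_table(out / "features_neg.tsv", "negative")
        assert len(pos) == len(b.pos_features)
        assert len(neg) == len(b.neg_features)
        for orig, back in zip(b.pos_features, pos):
            assert back.feature_id == orig.feature_id
            assert back.mz == pytest.approx(orig.mz, abs=1e-9)
            for sid, a in orig.areas.items():
                assert back.areas[sid] == pytest.approx(a, rel=1e-12)
        samples = io.read_sample_table(out / "samples.tsv")
        assert [s.sample_id for s in samples] == [s.sample_id for s in b.samples]
        trajs = io.read_trajectories(out / "trajectories.tsv")
        assert len(trajs) == len(b.trajectories)
        spectra = io.read_msp(out / "spectra.msp")
        assert set(spectra) == set(b.spectra)

    def test_existing_dir_requires_force(self, tmp_path):
        b = generate_campaign(n_samples=6, n_features=5, n_blanks=2, seed=6)
        out = tmp_path / "camp"
        write_campaign(b, out)
        with pytest.raises(FileExistsError):
            write_campaign(b, out)
        write_campaign(b, out, force=True)

    def test_zero_features_valid_empty_table(self, tmp_path):
        b = generate_campaign(n_samples=6, n_features=0, n_blanks=2, seed=6,
                              pfas_chain_lengths=())
        out = tmp_path / "camp"
        write_campaign(b, out)
        assert io.read_feature_table(out / "features_pos.tsv", "positive") == []

    def test_msp_has_one_record_per_ms2_feature(self, tmp_path):
        b = generate_campaign(n_samples=6, n_features=20, n_blanks=2, seed=6)
        out = tmp_path / "camp"
        write_campaign(b, out)
        spectra = io.read_msp(out / "spectra.msp")
        with_ms2 = [f for f in b.pos_features + b.neg_features if f.ms2]
        assert len(spectra) == len(with_ms2)
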