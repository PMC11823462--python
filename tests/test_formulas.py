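"""Formula enumeration, dual rankers, consensus rule, descriptors."""
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aeronts import formulas as fm
from aeronts.constants import MONOISOTOPIC_MASS
from aeronts.model import Feature, Formula, Spectrum


def brute_force_enumerate(neutral_mass, tol_ppm, bounds, caps):
    """Independent oracle: full grid, post-filtered with the same rules."""
    tol = neutral_mass * tol_ppm * 1e-6
    out = []
    ranges = [range(bounds.get(e, 0) + 1) for e in fm.ELEMENTS]
    for combo in itertools.product(*ranges):
        counts = {e: n for e, n in zip(fm.ELEMENTS, combo) if n}
        if counts.get("C", 0) < 1:
            continue
        mass = sum(MONOISOTOPIC_MASS[e] * n for e, n in counts.items())
        if abs(mass - neutral_mass) > tol:
            continue
        if fm.dbe(counts) < 0 or not fm.senior_ok(counts):
            continue
        if not fm._ratios_ok(counts, caps):
            continue
        out.append(Formula(counts))
    return set(out)


class TestEnumeration:
    def test_formic_acid_unique_hit(self):
        res = fm.enumerate_formulas(46.00548, 3, fm.make_bounds(C=4, H=10, O=4))
        assert [f.hill() for f in res] == ["CH2O2"]

    def test_pfoa_found(self):
        res = fm.enumerate_formulas(413.97370, 3,
                                    fm.make_bounds(C=10, H=10, F=20, O=5))
        assert Formula.parse("C8HF15O2") in res

    def test_zero_tolerance_off_mass_empty(self):
        assert fm.enumerate_formulas(200.1234, 0, fm.make_bounds(C=20, H=40, O=5)) == []

    def test_bounds_missing_element_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            fm.enumerate_formulas(100.0, 3, {"C": 10, "H": 20})

    def test_matches_brute_force_oracle(self, config):
        bounds = fm.make_bounds(C=16, H=30, N=3, O=8, S=2, F=10)
        rng = np.random.default_rng(77)
        for mass in rng.uniform(60, 295, size=8):
            fast = set(fm.enumerate_formulas(mass, 5, bounds, config.ratio_caps))
            slow = brute_force_enumerate(mass, 5, bounds, config.ratio_caps)
            assert fast == slow

    def test_masses_agree_with_pyteomics(self):
        from pyteomics.mass import calculate_mass
        for text in ("C8HF15O2", "C10H14N2", "C4H6O4", "C6H5NO4", "C2F5"):
            assert Formula.parse(text).mass == pytest.approx(
                calculate_mass(formula=text), abs=2e-5)


class TestDescriptors:
    @pytest.mark.parametrize("text,expected_dbe", [
        ("C8HF15O2", 1.0),      # perfluorooctanoic acid
        ("C10H14N2", 5.0),      # nicotine
        ("C4H6O4", 2.0),        # succinic acid
    ])
    def test_dbe_reference_values(self, text, expected_dbe):
        assert fm.dbe(Formula.parse(text)) == expected_dbe

    @pytest.mark.parametrize("text,klass", [
        ("C4H6O4", "O4"), ("C6H5NO4", "NO4"), ("C8HF15O2", "F"),
        ("C7H7Cl", "Cl"), ("C10H20", "CH"), ("C6H6N2O3S", "N2SO3"),
    ])
    def test_heteroatom_class(self, text, klass):
        assert fm.heteroatom_class(Formula.parse(text)) == klass

    def test_mass_defect_in_half_open_interval(self):
        for mz in (118.99256, 200.0, 255.4999, 255.5001, 413.98098):
            md = fm.descriptors(Formula.parse("C4H6O4"), mz).mass_defect
            assert -0.5 <= md < 0.5

    @given(st.integers(2, 20), st.integers(2, 30), st.integers(0, 3),
           st.integers(0, 6))
    @settings(max_examples=60, deadline=None)
    def test_dbe_invariant_under_ch2_homologation(self, c, h, n, o):
        base = {"C": c, "H": h, "N": n, "O": o}
        homolog = dict(base, C=c + 1, H=h + 2)
        assert fm.dbe(base) == fm.dbe(homolog)

    def test_negative_dbe_flagged_invalid(self):
        d = fm.descriptors(Formula.parse("CH6"), 35.0)
        assert not d.valid


class TestRanking:
    def _feature(self, formula, mode="negative", iso=True, ms2_peaks=None):
        m1, m2 = fm.isotope_pattern(formula)
        return Feature(
            "q1", mode, formula.ion_mz(mode), 5.0, {},
            iso_m1_frac=m1 if iso else None,
            iso_m2_frac=m2 if iso else None,
            ms2=Spectrum(formula.ion_mz(mode), mode, ms2_peaks)
            if ms2_peaks else None)

    def test_single_candidate_ranked_first_by_both(self):
        f = Formula.parse("C4H6O4")
        feat = self._feature(f, ms2_peaks=[(f.mass - 1.007276 - 43.98983, 1.0)])
        (cand,) = fm.rank_candidates(feat, [f])
        assert cand.rank_A == 1 and cand.rank_B == 1

    def test_fragment_scorer_dominance(self):
        truth = Formula.parse("C6H12O6")
        decoy = Formula.parse("C7H16S")  # cannot explain oxygen-rich losses
        frag = Formula.parse("C2H4O2")
        feat = self._feature(truth, iso=False,
                             ms2_peaks=[(frag.mass - 1.007276, 1.0)])
        ranked = {c.formula: c for c in fm.rank_candidates(feat, [truth, decoy])}
        assert ranked[truth].rank_B == 1
        assert ranked[truth].score_B > ranked[decoy].score_B

    def test_no_evidence_is_rejected(self):
        feat = Feature("q2", "positive", 100.0, 1.0, {})
        with pytest.raises(ValueError, match="ineligible"):
            fm.rank_candidates(feat, [Formula.parse("C5H9NO")])

    def test_isotope_scorer_recovers_truth_under_noise(self):
        """True formula top-ranked by the isotope scorer in >=95% of noisy
        replicates at 5% relative isotope noise."""
        truth = Formula.parse("C12H10Cl2O3")
        others = [Formula.parse(t) for t in ("C13H14O5", "C9H10N2O6", "C12H12SO4")]
        m1, m2 = fm.isotope_pattern(truth)
        rng = np.random.default_rng(11)
        wins = 0
        n_rep = 200
        for _ in range(n_rep):
            feat = Feature("q", "negative", truth.ion_mz("negative"), 1.0, {},
                           iso_m1_frac=max(0.0, m1 * (1 + rng.normal(0, 0.05))),
                           iso_m2_frac=max(0.0, m2 * (1 + rng.normal(0, 0.05))))
            ranked = {c.formula: c for c in
                      fm.rank_candidates(feat, [truth] + others)}
            wins += ranked[truth].rank_A == 1
        assert wins / n_rep >= 0.95


class TestConsensus:
    def _cand(self, formula, ra, rb, err=0.1):
        return fm.FormulaCandidate(formula, 100.0, err, rank_A=ra, rank_B=rb)

    def _feature(self, m2=0.2):
        return Feature("x", "positive", 100.0, 1.0, {},
                       iso_m1_frac=0.1, iso_m2_frac=m2)

    def test_overlap_in_top_two_assigned(self):
        f1, f2, f3 = (Formula.parse(t) for t in ("C6H12O6", "C7H16S", "C5H8N2O5"))
        cands = [self._cand(f1, 1, 3), self._cand(f2, 2, 1), self._cand(f3, 3, 2)]
        assert fm.consensus_assign(cands, self._feature()) == f2

    def test_disjoint_top_two_unassigned(self):
        f1, f2, f3, f4 = (Formula.parse(t) for t in
                          ("C6H12O6", "C7H16S", "C5H8N2O5", "C8H20N2"))
        cands = [self._cand(f1, 1, 3), self._cand(f2, 2, 4),
                 self._cand(f3, 3, 1), self._cand(f4, 4, 2)]
        assert fm.consensus_assign(cands, self._feature()) is None

    def test_chlorine_without_m2_isotope_dropped(self):
        f = Formula.parse("C7H7ClO2")
        cands = [self._cand(f, 1, 1)]
        feat = Feature("x", "positive", 100.0, 1.0, {}, iso_m1_frac=0.08,
                       iso_m2_frac=None)
        assert fm.consensus_assign(cands, feat) is None
        # with a plausible M+2 signal the same assignment is retained
        assert fm.consensus_assign(cands, self._feature(m2=0.31)) == f

    def test_never_returns_formula_outside_both_top_two(self):
        f1, f2 = Formula.parse("C6H12O6"), Formula.parse("C7H16S")
        cands = [self._cand(f1, 1, 1), self._cand(f2, 3, 3)]
        out = fm.consensus_assign(cands, self._feature())
        assert out in (f1, None)


class TestValidation:
    def test_all_recovered_reports_100(self):
        from aeronts.synthetic import reference_standards
        stds = [s for s in reference_standards() if s.observed_mz is None][:10]
        rep = fm.validate_rankers(stds)
        assert rep.frac_both_top == 1.0
        assert rep.frac_top2_any == 1.0

    def test_requires_at_least_two_standards(self):
        with pytest.raises(ValueError):
            fm.validate_rankers([])
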