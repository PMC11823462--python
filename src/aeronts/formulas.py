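"""Molecular-formula enumeration, dual ranking, consensus assignment.

The assignment strategy mirrors conservative nontarget practice: all
elemental compositions within a ppm window of the neutral mass are
enumerated under SENIOR/DBE/element-ratio feasibility rules, then ranked
by two *independent* lines of evidence —

* scorer A: agreement of the observed M+1 / M+2 isotopologue abundances
  with the candidate's first-order theoretical pattern;
* scorer B: fraction of MS2 fragment intensity explainable as subformula
  ions of the candidate (each fragment within 3 ppm);

and a formula is only assigned when both scorers place the same
composition within their top two candidates. Assigned Cl-containing
formulas additionally require a plausible M+2 isotope signal.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .constants import (
    ELECTRON_MASS,
    ISO_M1_RATIO,
    ISO_M2_RATIO,
    MONOISOTOPIC_MASS,
    PROTON_MASS,
    VALENCE,
)
from .model import Feature, Formula, Spectrum

ELEMENTS = ("C", "H", "N", "O", "P", "S", "F", "Cl", "Br", "I")
_HET = ELEMENTS[2:]  # everything but C and H
_HET_MASS = np.array([MONOISOTOPIC_MASS[e] for e in _HET])
_H_MASS = MONOISOTOPIC_MASS["H"]
_C_MASS = MONOISOTOPIC_MASS["C"]


def make_bounds(**kw: int) -> dict[str, int]:
    """Explicit element-bound constructor; unlisted elements are capped at 0."""
    unknown = set(kw) - set(ELEMENTS)
    if unknown:
        raise ValueError(f"unsupported elements: {sorted(unknown)}")
    return {e: int(kw.get(e, 0)) for e in ELEMENTS}


@lru_cache(maxsize=16)
def _het_grid(het_bounds: tuple[int, ...], max_mass: float):
    """All heteroatom count combinations within the bounds and mass cap.

    Returns (counts array k x 8, mass array k) sorted by mass.
    """
    shape = tuple(b + 1 for b in het_bounds)
    grid = np.indices(shape).reshape(len(het_bounds), -1).T  # (k, 8)
    mass = grid @ _HET_MASS
    keep = mass <= max_mass
    grid, mass = grid[keep], mass[keep]
    order = np.argsort(mass)
    return grid[order], mass[order]


def _decompose(target: float, tol_da: float, bounds: dict[str, int],
               c_min: int = 0) -> list[dict[str, int]]:
    """All count vectors under ``bounds`` with mass within ``target +- tol_da``."""
    missing = set(ELEMENTS) - set(bounds)
    if missing:
        raise ValueError(f"element bounds missing {sorted(missing)}")
    lo, hi = target - tol_da, target + tol_da
    if hi <= 0:
        return []
    het_bounds = tuple(int(bounds[e]) for e in _HET)
    grid, het_mass = _het_grid(het_bounds, max(hi, 0.0))
    h_max = int(bounds["H"])
    out: list[dict[str, int]] = []
    for c in range(c_min, int(bounds["C"]) + 1):
        # heteroatom mass must land in [lo - cC - h_max*H, hi - cC]
        i0 = int(np.searchsorted(het_mass, lo - c * _C_MASS - h_max * _H_MASS))
        i1 = int(np.searchsorted(het_mass, hi - c * _C_MASS, side="right"))
        if i0 >= i1:
            continue
        hm = het_mass[i0:i1]
        resid = target - c * _C_MASS - hm
        h = np.rint(resid / _H_MASS)
        mass_total = c * _C_MASS + hm + h * _H_MASS
        ok = (h >= 0) & (h <= h_max) & (mass_total >= lo) & (mass_total <= hi)
        for idx in np.flatnonzero(ok):
            counts = {"C": c, "H": int(h[idx])}
            counts.update({e: int(n) for e, n in zip(_HET, grid[i0 + idx]) if n})
            out.append(counts)
    return out


def _best_decomposition_error(target: float, tol_da: float,
                              bounds: dict[str, int]) -> float | None:
    """Smallest |mass - target| over decompositions, or None if none exist."""
    lo, hi = target - tol_da, target + tol_da
    if hi <= 0:
        return None
    het_bounds = tuple(int(bounds[e]) for e in _HET)
    grid, het_mass = _het_grid(het_bounds, max(hi, 0.0))
    h_max = int(bounds["H"])
    best: float | None = None
    for c in range(0, int(bounds["C"]) + 1):
        i0 = int(np.searchsorted(het_mass, lo - c * _C_MASS - h_max * _H_MASS))
        i1 = int(np.searchsorted(het_mass, hi - c * _C_MASS, side="right"))
        if i0 >= i1:
            continue
        hm = het_mass[i0:i1]
        resid = target - c * _C_MASS - hm
        h = np.rint(resid / _H_MASS)
        err = np.abs(c * _C_MASS + hm + h * _H_MASS - target)
        ok = (h >= 0) & (h <= h_max) & (err <= tol_da)
        if ok.any():
            e = float(err[ok].min())
            if best is None or e < best:
                best = e
    return best


def dbe(formula: Formula | dict[str, int]) -> float:
    """Double-bond equivalents: DBE = C + 1 - H/2 - X/2 + N/2, X = halogens."""
    f = formula.as_dict() if isinstance(formula, Formula) else formula
    x = f.get("F", 0) + f.get("Cl", 0) + f.get("Br", 0) + f.get("I", 0)
    return f.get("C", 0) + 1 - f.get("H", 0) / 2 - x / 2 + f.get("N", 0) / 2


def senior_ok(counts: dict[str, int]) -> bool:
    """SENIOR feasibility: even valence sum, and sum >= 2*(atom count - 1)."""
    vsum = sum(VALENCE[e] * n for e, n in counts.items())
    atoms = sum(counts.values())
    return atoms > 0 and vsum % 2 == 0 and vsum >= 2 * (atoms - 1)


def _ratios_ok(counts: dict[str, int], caps: dict[str, float]) -> bool:
    c = counts.get("C", 0)
    if c < 1:
        return False
    for el, cap in caps.items():
        if counts.get(el, 0) > cap * c:
            return False
    return True


def enumerate_formulas(neutral_mass: float, tol_ppm: float = 3.0,
                       element_bounds: dict[str, int] | None = None,
                       ratio_caps: dict[str, float] | None = None) -> list[Formula]:
    """All plausible organic formulas within ``tol_ppm`` of a neutral mass.

    Feasibility filters: C >= 1, SENIOR rule, DBE >= 0, and heteroatom/C
    ratio caps (element probability check).
    """
    from .config import DEFAULT_ELEMENT_BOUNDS, DEFAULT_RATIO_CAPS
    if not 10 < neutral_mass <= 1000:
        raise ValueError(f"neutral mass {neutral_mass} outside (10, 1000]")
    bounds = element_bounds if element_bounds is not None else DEFAULT_ELEMENT_BOUNDS
    caps = ratio_caps if ratio_caps is not None else DEFAULT_RATIO_CAPS
    tol_da = neutral_mass * tol_ppm * 1e-6
    out = []
    for counts in _decompose(neutral_mass, tol_da, bounds, c_min=1):
        if dbe(counts) < 0:
            continue
        if not senior_ok(counts):
            continue
        if not _ratios_ok(counts, caps):
            continue
        out.append(Formula(counts))
    return sorted(out, key=lambda f: abs(f.mass - neutral_mass))


# ----------------------------------------------------------- isotope model

def isotope_pattern(formula: Formula) -> tuple[float, float]:
    """First-order theoretical (M+1, M+2) abundances relative to M."""
    f = formula.as_dict()
    m1 = sum(f.get(e, 0) * r for e, r in ISO_M1_RATIO.items())
    m2 = sum(f.get(e, 0) * r for e, r in ISO_M2_RATIO.items())
    nc = f.get("C", 0)
    m2 += nc * (nc - 1) / 2 * ISO_M1_RATIO["C"] ** 2  # two 13C
    return m1, m2


def isotope_fit_score(formula: Formula, obs_m1: float, obs_m2: float | None) -> float:
    """Scorer A: negative squared deviation of observed vs theoretical pattern."""
    th1, th2 = isotope_pattern(formula)
    err = (obs_m1 - th1) ** 2
    if obs_m2 is not None:
        err += (obs_m2 - th2) ** 2
    return -err


# ---------------------------------------------------------- fragment model

def _fragment_targets(peak_mz: float, mode: str) -> list[float]:
    """Neutral subformula masses a fragment peak may correspond to.

    Even-electron (protonated / deprotonated) and radical ions are both
    admitted; in-source chemistry does not guarantee either.
    """
    if mode == "positive":
        return [peak_mz - PROTON_MASS, peak_mz + ELECTRON_MASS]
    return [peak_mz + PROTON_MASS, peak_mz - ELECTRON_MASS]


def fragment_explained_fraction(candidate: Formula, spectrum: Spectrum,
                                tol_ppm: float = 3.0) -> float:
    """Scorer B: mass-error-weighted fraction of MS2 intensity explainable
    as candidate subformula ions.

    Each peak contributes intensity * exp(-(err/sigma)^2 / 2) for the best
    matching subformula within ``tol_ppm`` (sigma = half the tolerance),
    so exact subformula matches dominate near-coincidences.
    """
    bounds = {e: candidate[e] for e in ELEMENTS}
    total = sum(i for _, i in spectrum.peaks)
    if total <= 0:
        return 0.0
    explained = 0.0
    for mz, inten in spectrum.peaks:
        tol_da = mz * tol_ppm * 1e-6
        sigma = tol_da / 2
        best_w = 0.0
        for target in _fragment_targets(mz, spectrum.mode):
            if target <= 0:
                continue
            err = _best_decomposition_error(target, tol_da, bounds)
            if err is not None:
                best_w = max(best_w, math.exp(-0.5 * (err / sigma) ** 2))
        explained += inten * best_w
    return explained / total


# ------------------------------------------------------------ ranking

@dataclass
class FormulaCandidate:
    formula: Formula
    theoretical_mz: float
    mass_error_ppm: float
    score_A: float | None = None
    score_B: float | None = None
    rank_A: int | None = None
    rank_B: int | None = None


def _assign_ranks(cands: list[FormulaCandidate], attr: str) -> None:
    scored = [c for c in cands if getattr(c, f"score_{attr}") is not None]
    scored.sort(key=lambda c: (-getattr(c, f"score_{attr}"),
                               abs(c.mass_error_ppm), c.formula.hill()))
    for rank, c in enumerate(scored, start=1):
        setattr(c, f"rank_{attr}", rank)


def rank_candidates(feature: Feature, candidates: list[Formula],
                    tol_ppm: float = 3.0) -> list[FormulaCandidate]:
    """Score and rank enumerated candidates with both internal scorers."""
    if feature.iso_m1_frac is None and feature.ms2 is None:
        raise ValueError(
            f"feature {feature.feature_id}: no isotope data and no MS2 — ineligible")
    neutral = feature.neutral_mass
    out = []
    for f in candidates:
        cand = FormulaCandidate(
            formula=f,
            theoretical_mz=f.ion_mz(feature.mode),
            mass_error_ppm=(neutral - f.mass) / f.mass * 1e6,
        )
        if feature.iso_m1_frac is not None:
            cand.score_A = isotope_fit_score(f, feature.iso_m1_frac, feature.iso_m2_frac)
        if feature.ms2 is not None and feature.ms2.peaks:
            cand.score_B = fragment_explained_fraction(f, feature.ms2, tol_ppm)
        out.append(cand)
    _assign_ranks(out, "A")
    _assign_ranks(out, "B")
    return out


def consensus_assign(cands: list[FormulaCandidate], feature: Feature) -> Formula | None:
    """Assign the formula both scorers place within their top two candidates.

    Cl-containing assignments are dropped unless the observed M+2 fraction
    reaches half the theoretical 37Cl contribution.
    """
    top = [c for c in cands
           if c.rank_A is not None and c.rank_A <= 2
           and c.rank_B is not None and c.rank_B <= 2]
    if not top:
        return None
    best = min(top, key=lambda c: (c.rank_A + c.rank_B,
                                   abs(c.mass_error_ppm), c.formula.hill()))
    f = best.formula
    n_cl = f["Cl"]
    if n_cl:
        floor = 0.5 * n_cl * ISO_M2_RATIO["Cl"]
        if feature.iso_m2_frac is None or feature.iso_m2_frac < floor:
            return None
    return f


# ---------------------------------------------------------- descriptors

@dataclass
class FormulaDescriptors:
    dbe: float
    het_class: str
    mass_defect: float
    valid: bool = True


_HALOGEN_PRIORITY = ("F", "Cl", "Br", "I")
_CLASS_ORDER = ("N", "P", "S", "O")


def heteroatom_class(formula: Formula) -> str:
    """Compositional class label (O4, NO2, SO5, ... ; halogens grouped)."""
    for hal in _HALOGEN_PRIORITY:
        if formula[hal]:
            return hal
    parts = []
    for el in _CLASS_ORDER:
        n = formula[el]
        if n:
            parts.append(el if n == 1 else f"{el}{n}")
    return "".join(parts) or "CH"


def descriptors(formula: Formula, ion_mz: float) -> FormulaDescriptors:
    d = dbe(formula)
    md = ion_mz - round(ion_mz)
    if md >= 0.5:  # round() half-to-even edge
        md -= 1.0
    return FormulaDescriptors(dbe=d, het_class=heteroatom_class(formula),
                              mass_defect=md, valid=d >= 0)


# ---------------------------------------------------------- validation

@dataclass
class ReferenceStandard:
    """One reference compound for the ranker validation harness."""

    name: str
    formula: Formula
    mode: str
    spectrum: Spectrum
    iso_m1_frac: float
    iso_m2_frac: float
    #: element bounds used when enumerating candidates for this standard;
    #: derived from the known composition plus swap slack.
    element_bounds: dict[str, int] = field(default_factory=dict)
    #: measured ion m/z; defaults to the exact theoretical ion mass.
    observed_mz: float | None = None


@dataclass
class ValidationReport:
    n: int
    n_both_top: int
    n_f_free: int
    n_both_top_f_free: int
    n_top2_any: int

    @property
    def frac_both_top(self) -> float:
        return self.n_both_top / self.n

    @property
    def frac_both_top_f_free(self) -> float:
        return self.n_both_top_f_free / self.n_f_free

    @property
    def frac_top2_any(self) -> float:
        return self.n_top2_any / self.n


def _standard_bounds(std: ReferenceStandard) -> dict[str, int]:
    if std.element_bounds:
        return {e: std.element_bounds.get(e, 0) for e in ELEMENTS}
    base = {e: std.formula[e] for e in ELEMENTS}
    base["C"] += 3  # admit the classic S+4H <-> C3 near-isobar
    return base


def validate_rankers(standards: list[ReferenceStandard],
                     tol_ppm: float = 3.0) -> ValidationReport:
    """Run both rankers over reference standards of known composition."""
    if len(standards) < 2:
        raise ValueError("need at least 2 reference standards")
    n_both = n_both_ff = n_ff = n_any2 = 0
    for std in standards:
        mz = std.observed_mz if std.observed_mz is not None else std.formula.ion_mz(std.mode)
        feat = Feature(
            feature_id=std.name, mode=std.mode, mz=mz, rt=1.0,
            areas={}, iso_m1_frac=std.iso_m1_frac, iso_m2_frac=std.iso_m2_frac,
            ms2=std.spectrum,
        )
        cands = enumerate_formulas(feat.neutral_mass, tol_ppm, _standard_bounds(std))
        ranked = rank_candidates(feat, cands, tol_ppm)
        by_formula = {c.formula: c for c in ranked}
        truth = by_formula.get(std.formula)
        top_a = truth is not None and truth.rank_A == 1
        top_b = truth is not None and truth.rank_B == 1
        in2 = truth is not None and (
            (truth.rank_A is not None and truth.rank_A <= 2)
            or (truth.rank_B is not None and truth.rank_B <= 2))
        f_free = std.formula["F"] == 0
        n_ff += f_free
        if top_a and top_b:
            n_both += 1
            n_both_ff += f_free
        n_any2 += in2
    return ValidationReport(n=len(standards), n_both_top=n_both,
                            n_f_free=n_ff, n_both_top_f_free=n_both_ff,
                            n_top2_any=n_any2)
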