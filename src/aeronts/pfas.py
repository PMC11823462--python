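"""PFAS discovery by perfluoroalkyl fragment screening.

Unknown negative-mode features are flagged as per- and polyfluoroalkyl
substances when their MS2 spectra contain at least two members of the
[CxF2x+1]- fragment series AND their top-ranked molecular formula carries
at least two fluorine atoms (a -CF2- moiety).
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .constants import ELECTRON_MASS, MONOISOTOPIC_MASS
from .model import Formula, Spectrum

_C = MONOISOTOPIC_MASS["C"]
_F = MONOISOTOPIC_MASS["F"]


@dataclass(frozen=True)
class SeriesFragment:
    x: int
    formula: Formula
    mz: float  # anion m/z


@dataclass
class FragmentMatch:
    x: int
    theoretical_mz: float
    observed_mz: float
    rel_intensity: float


@dataclass
class PfasHit:
    feature_id: str
    matched_fragments: list[FragmentMatch] = field(default_factory=list)
    formula: Formula | None = None
    status: str = "none"  # fragment_only | formula_only | confirmed_pfas | none


def fragment_series(x_min: int = 2, x_max: int = 14) -> list[SeriesFragment]:
    """The [CxF2x+1]- anion series; default x = 2..14 gives 13 fragments."""
    if not 1 <= x_min <= x_max:
        raise ValueError("require 1 <= x_min <= x_max")
    out = []
    for x in range(x_min, x_max + 1):
        mz = _C * x + _F * (2 * x + 1) + ELECTRON_MASS
        out.append(SeriesFragment(x=x, formula=Formula({"C": x, "F": 2 * x + 1}), mz=mz))
    return out


def search_fragments(spectrum: Spectrum, tol: float = 0.01,
                     min_rel_intensity: float = 0.10,
                     series: list[SeriesFragment] | None = None) -> list[FragmentMatch]:
    """Match series fragments to spectrum peaks.

    Each series entry takes the nearest peak within ``tol`` Da whose
    relative intensity exceeds ``min_rel_intensity``; one peak may satisfy
    only one series entry (nearest-mass wins, ties to lower x).
    """
    if spectrum.mode != "negative":
        raise ValueError("PFAS fragment series is anionic; spectrum must be negative mode")
    if series is None:
        series = fragment_series()
    eligible = [(mz, i) for mz, i in spectrum.peaks if i > min_rel_intensity]
    # candidate (distance, x-order, series entry, peak) tuples, greedy by distance
    cands = []
    for entry in series:
        for p_idx, (mz, inten) in enumerate(eligible):
            d = abs(mz - entry.mz)
            if d <= tol:
                cands.append((d, entry.x, entry, p_idx, mz, inten))
    cands.sort(key=lambda t: (t[0], t[1]))
    used_x: set[int] = set()
    used_peaks: set[int] = set()
    matches = []
    for d, x, entry, p_idx, mz, inten in cands:
        if x in used_x or p_idx in used_peaks:
            continue
        used_x.add(x)
        used_peaks.add(p_idx)
        matches.append(FragmentMatch(x=x, theoretical_mz=entry.mz,
                                     observed_mz=mz, rel_intensity=inten))
    matches.sort(key=lambda m: m.x)
    return matches


def flag_pfas(spectra: dict[str, Spectrum],
              top_formulas: dict[str, Formula],
              tol: float = 0.01, min_rel_intensity: float = 0.10) -> list[PfasHit]:
    """Combine the fragment screen with the formula criterion (F >= 2).

    ``top_formulas`` maps feature_id -> top-ranked formula (fragment
    scorer), the in-package stand-in for a formula-prediction tool.
    """
    series = fragment_series()
    hits = []
    for fid, sp in spectra.items():
        if sp.mode != "negative":
            continue
        matches = search_fragments(sp, tol, min_rel_intensity, series)
        formula = top_formulas.get(fid)
        frag_ok = len(matches) >= 2
        formula_ok = formula is not None and formula["F"] >= 2
        if frag_ok and formula_ok:
            status = "confirmed_pfas"
        elif frag_ok:
            status = "fragment_only"
        elif formula_ok:
            status = "formula_only"
        else:
            status = "none"
        if status != "none":
            hits.append(PfasHit(feature_id=fid, matched_fragments=matches,
                                formula=formula, status=status))
    return hits
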