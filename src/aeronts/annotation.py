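"""Spectral library matching, retention-time-index filtering, and
confidence-level assignment (Schymanski levels 1 / 2 / 4).

Annotation gates: MS2 similarity >= 0.70 (sqrt-intensity greedy cosine),
precursor tolerance 0.01 Da, fragment tolerance 0.015 Da, and |dRTI| <= 30
between the feature's calibrated retention index and the candidate's
predicted index.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import Spectrum


@dataclass
class LibraryEntry:
    library_id: str
    name: str
    spectrum: Spectrum
    predicted_rti: float | None = None
    formula: str | None = None


@dataclass
class AnnotationRecord:
    feature_id: str
    candidate_name: str
    library_id: str
    similarity: float
    delta_mz_ppm: float
    feature_rt: float | None = None
    rti_observed: float | None = None
    rti_predicted: float | None = None
    delta_rti: float | None = None
    level: str = "unknown"  # "1" | "2" | "4" | "unknown"
    flags: list[str] = field(default_factory=list)


def cosine_similarity(a: Spectrum, b: Spectrum, ms2_tol: float = 0.015,
                      intensity_power: float = 0.5) -> float:
    """Greedy-matched cosine over sqrt-weighted peak intensities in [0, 1]."""
    wa = [(mz, i ** intensity_power) for mz, i in a.peaks]
    wb = [(mz, i ** intensity_power) for mz, i in b.peaks]
    cands = []
    for ia, (mza, va) in enumerate(wa):
        for ib, (mzb, vb) in enumerate(wb):
            if abs(mza - mzb) <= ms2_tol:
                cands.append((va * vb, ia, ib))
    cands.sort(key=lambda t: -t[0])
    used_a: set[int] = set()
    used_b: set[int] = set()
    dot = 0.0
    for prod, ia, ib in cands:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        dot += prod
    na = math.sqrt(sum(v * v for _, v in wa))
    nb = math.sqrt(sum(v * v for _, v in wb))
    if na == 0 or nb == 0:
        return 0.0
    return min(1.0, dot / (na * nb))


def library_match(feature_id: str, spectrum: Spectrum,
                  library: list[LibraryEntry], score_min: float = 0.70,
                  ms1_tol: float = 0.01, ms2_tol: float = 0.015) -> list[AnnotationRecord]:
    """Match one query spectrum against library entries of the same mode
    within the precursor tolerance; keep records scoring >= ``score_min``."""
    out = []
    for entry in library:
        ref = entry.spectrum
        if ref.mode != spectrum.mode:
            continue
        if abs(ref.precursor_mz - spectrum.precursor_mz) > ms1_tol:
            continue
        sim = cosine_similarity(spectrum, ref, ms2_tol)
        if sim < score_min:
            continue
        dppm = ((spectrum.precursor_mz - ref.precursor_mz)
                / ref.precursor_mz * 1e6)
        out.append(AnnotationRecord(
            feature_id=feature_id, candidate_name=entry.name,
            library_id=entry.library_id, similarity=sim, delta_mz_ppm=dppm,
            rti_predicted=entry.predicted_rti))
    out.sort(key=lambda r: -r.similarity)
    return out


@dataclass
class RtiCalibration:
    """Linear retention-time -> retention-index mapping RTI = a*RT + b."""

    a: float
    b: float
    calibrants: list[tuple[str, float, float]]  # (name, rt, rti)
    residuals: list[float]

    def predict(self, rt: float) -> float:
        return self.a * rt + self.b


def fit_rti(calibrants: list[tuple[str, float, float]]) -> RtiCalibration:
    """Least-squares linear RTI calibration from (name, RT, RTI) triples."""
    if len(calibrants) < 2:
        raise ValueError("need >= 2 RTI calibrants")
    ordered = sorted(calibrants, key=lambda c: c[1])
    rtis = [c[2] for c in ordered]
    if any(b <= a for a, b in zip(rtis, rtis[1:])):
        raise ValueError("calibrant RTIs are not strictly increasing with RT")
    rt = np.array([c[1] for c in calibrants], float)
    rti = np.array([c[2] for c in calibrants], float)
    a, b = np.polyfit(rt, rti, 1)
    resid = (rti - (a * rt + b)).tolist()
    return RtiCalibration(a=float(a), b=float(b),
                          calibrants=list(calibrants), residuals=resid)


def rti_filter(records: list[AnnotationRecord], calib: RtiCalibration,
               max_delta: float = 30.0) -> list[AnnotationRecord]:
    """Apply the dRTI gate: records with |observed - predicted| RTI above
    ``max_delta`` are demoted to unknown; missing predictions are flagged
    ``rti_unavailable`` but retained."""
    out = []
    for r in records:
        if r.feature_rt is not None:
            r.rti_observed = calib.predict(r.feature_rt)
        if r.rti_predicted is None or r.rti_observed is None:
            r.flags.append("rti_unavailable")
            out.append(r)
            continue
        r.delta_rti = abs(r.rti_observed - r.rti_predicted)
        # inclusive boundary; epsilon guards float fuzz from the calibration fit
        if r.delta_rti <= max_delta + 1e-9:
            r.level = "2"
        else:
            r.level = "unknown"
            r.flags.append("rti_rejected")
        out.append(r)
    return out


def assign_levels(records: list[AnnotationRecord], standards_confirmed: set[str],
                  consensus_formulas: dict[str, object],
                  score_min: float = 0.70, max_delta: float = 30.0,
                  ms1_tol_ppm: float = 5.0) -> list[AnnotationRecord]:
    """Final confidence levels.

    Level 1: all level-2 gates pass and the candidate is confirmed by an
    in-house standard. Level 2: gates pass. Level 4: consensus molecular
    formula only. Else unknown.
    """
    out = []
    for r in records:
        gates = (r.similarity >= score_min
                 and abs(r.delta_mz_ppm) < ms1_tol_ppm
                 and r.delta_rti is not None and r.delta_rti <= max_delta)
        if gates and r.candidate_name in standards_confirmed:
            r.level = "1"
        elif gates:
            r.level = "2"
        elif r.feature_id in consensus_formulas:
            r.level = "4"
        else:
            r.level = "unknown"
        out.append(r)
    return out
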