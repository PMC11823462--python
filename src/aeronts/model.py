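"""Domain types shared by every stage of the pipeline."""
from __future__ import annotations

import re
from dataclasses import dataclass, field

from .constants import ELECTRON_MASS, HILL_ORDER, MONOISOTOPIC_MASS, PROTON_MASS

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class Formula:
    """An elemental composition over {C,H,N,O,P,S,F,Cl,Br,I}.

    Hashable and order-canonical: two formulas with equal counts compare
    equal regardless of construction order.
    """

    counts: tuple[tuple[str, int], ...]

    def __init__(self, counts):
        if isinstance(counts, Formula):
            counts = dict(counts.counts)
        items = []
        for el in HILL_ORDER:
            n = int(counts.get(el, 0))
            if n < 0:
                raise ValueError(f"negative count for {el}")
            if n:
                items.append((el, n))
        unknown = set(counts) - set(HILL_ORDER)
        if unknown:
            raise ValueError(f"unsupported elements: {sorted(unknown)}")
        object.__setattr__(self, "counts", tuple(items))

    def __getitem__(self, el: str) -> int:
        return dict(self.counts).get(el, 0)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    @property
    def mass(self) -> float:
        """Monoisotopic neutral mass in Da."""
        return sum(MONOISOTOPIC_MASS[el] * n for el, n in self.counts)

    def ion_mz(self, mode: str) -> float:
        """m/z of [M+H]+ (positive) or [M-H]- (negative)."""
        if mode == "positive":
            return self.mass + PROTON_MASS
        if mode == "negative":
            return self.mass - PROTON_MASS
        raise ValueError(f"unknown mode {mode!r}")

    def hill(self) -> str:
        """Canonical Hill-order rendering, e.g. C8HF15O2."""
        parts = []
        for el, n in self.counts:
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts) or "∅"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()

    @classmethod
    def parse(cls, text: str) -> "Formula":
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(text):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r}")
            pos = m.end()
            el, num = m.group(1), m.group(2)
            counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        if pos != len(text):
            raise ValueError(f"cannot parse formula {text!r}")
        return cls(counts)


@dataclass
class Spectrum:
    """A centroided MS2 spectrum with base-peak-normalized intensities."""

    precursor_mz: float
    mode: str
    peaks: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self):
        if self.mode not in ("positive", "negative"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.peaks:
            self.peaks = sorted((float(m), float(i)) for m, i in self.peaks)
            if any(m <= 0 for m, _ in self.peaks):
                raise ValueError("peak m/z must be positive")
            top = max(i for _, i in self.peaks)
            if top <= 0:
                raise ValueError("spectrum has no positive-intensity peak")
            if abs(top - 1.0) > 1e-9:
                self.peaks = [(m, i / top) for m, i in self.peaks]

    @property
    def base_peak_mz(self) -> float:
        return max(self.peaks, key=lambda p: p[1])[0]


@dataclass
class Feature:
    """One aligned nontarget ion: m/z, RT and per-sample peak areas."""

    feature_id: str
    mode: str
    mz: float
    rt: float
    areas: dict[str, float] = field(default_factory=dict)
    iso_m1_frac: float | None = None
    iso_m2_frac: float | None = None
    ms2: Spectrum | None = None

    def __post_init__(self):
        if self.mode not in ("positive", "negative"):
            raise ValueError(f"feature {self.feature_id}: unknown mode {self.mode!r}")
        if not self.mz > 0:
            raise ValueError(f"feature {self.feature_id}: mz must be > 0")
        if self.rt < 0:
            raise ValueError(f"feature {self.feature_id}: rt must be >= 0")
        if any(a < 0 for a in self.areas.values()):
            raise ValueError(f"feature {self.feature_id}: negative area")
        for name, v in (("iso_m1_frac", self.iso_m1_frac), ("iso_m2_frac", self.iso_m2_frac)):
            if v is not None and not (0 <= v <= 10):
                raise ValueError(f"feature {self.feature_id}: {name} outside [0, 10]")

    @property
    def neutral_mass(self) -> float:
        """Neutral mass assuming [M+H]+ / [M-H]-."""
        if self.mode == "positive":
            return self.mz - PROTON_MASS
        return self.mz + PROTON_MASS


@dataclass
class SampleRecord:
    """Metadata for one filter sample (or field blank)."""

    sample_id: str
    start_date: str
    end_date: str
    mean_temp_C: float
    is_field_blank: bool
    is_areas: dict[str, float] = field(default_factory=dict)
    cluster_weights: dict[int, float] = field(default_factory=dict)

    def __post_init__(self):
        total = sum(self.cluster_weights.values())
        if total > 1 + 1e-9:
            raise ValueError(
                f"sample {self.sample_id}: cluster weights sum to {total:.4f} > 1"
            )
        if any(not (0 <= w <= 1) for w in self.cluster_weights.values()):
            raise ValueError(f"sample {self.sample_id}: cluster weight outside [0,1]")


@dataclass
class TrajectoryEndpointSet:
    """Hourly 48 h back-trajectories for one sample.

    ``trajectories`` maps trajectory id -> list of (hour_offset, lat, lon),
    hour offsets monotone in [-48, 0].
    """

    sample_id: str
    trajectories: dict[str, list[tuple[float, float, float]]] = field(default_factory=dict)

    def __post_init__(self):
        for tid, pts in self.trajectories.items():
            hours = [h for h, _, _ in pts]
            if any(b <= a for a, b in zip(hours, hours[1:])):
                raise ValueError(f"trajectory {tid}: hour offsets not monotone")
            for h, lat, lon in pts:
                if not (-48 <= h <= 0):
                    raise ValueError(f"trajectory {tid}: hour offset {h} outside [-48, 0]")
                if not (-90 <= lat <= 90 and -180 <= lon <= 180):
                    raise ValueError(f"trajectory {tid}: coordinates out of bounds")


def neutral_mass_from_mz(mz: float, mode: str) -> float:
    if mode == "positive":
        return mz - PROTON_MASS
    if mode == "negative":
        return mz + PROTON_MASS
    raise ValueError(f"unknown mode {mode!r}")


def anion_mz(formula: Formula) -> float:
    """m/z of the radical anion [X]- (sum of atoms plus one electron)."""
    return formula.mass + ELECTRON_MASS
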