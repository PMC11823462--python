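"""Run configuration with campaign-wide threshold defaults.

Every tunable threshold of the pipeline lives here so a single YAML file
reproduces a run. Unknown keys are rejected rather than ignored, to guard
against silent typos.
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

DEFAULT_ELEMENT_BOUNDS: dict[str, int] = {
    "C": 30, "H": 60, "N": 5, "O": 15, "P": 2, "S": 3,
    "F": 20, "Cl": 3, "Br": 1, "I": 1,
}

#: Heteroatom-to-carbon plausibility caps (element probability check).
DEFAULT_RATIO_CAPS: dict[str, float] = {
    "H": 4.0, "N": 4.0, "O": 4.0, "P": 2.0, "S": 2.0,
    "F": 3.0, "Cl": 3.0, "Br": 2.0, "I": 2.0,
}


@dataclass
class RunConfig:
    # blank filtering
    blank_factor: float = 5.0
    # cross-mode deduplication
    dedup_mass_tol_da: float = 0.001
    dedup_rt_tol_min: float = 0.15
    # formula assignment
    formula_tol_ppm: float = 3.0
    element_bounds: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_ELEMENT_BOUNDS))
    ratio_caps: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RATIO_CAPS))
    # spectral library search
    library_score_min: float = 0.70
    ms1_tol_da: float = 0.01
    ms2_tol_da: float = 0.015
    rti_max_delta: float = 30.0
    # PFAS screen
    pfas_fragment_tol_da: float = 0.01
    pfas_min_rel_intensity: float = 0.10
    # source attribution
    n_clusters: int = 6
    fuzzifier: float = 2.0
    assignment_threshold: float = 0.6
    # multivariate contrasts
    vip_min: float = 1.5
    pcorr_min: float = 0.5
    temperature_split_C: float = 15.0
    n_ortho: int = 1
    cv_folds: int = 7
    scaling: str = "pareto"
    # reproducibility
    seed: int | None = None


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a RunConfig from YAML; omitted keys fall back to defaults.

    Raises ``ValueError`` on keys that are not RunConfig fields.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValueError(f"config root must be a mapping, got {type(loaded).__name__}")
            data.update(loaded)
    data.update(overrides)
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)
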