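"""Readers and writers for the pipeline's delimited-text and MSP formats.

Feature tables, sample metadata and trajectory endpoints are plain TSV;
MS2 spectra and libraries use the NIST MSP text dialect. All pairs are
lossless round trips and column/sample order is preserved.
"""
from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd

from .model import Feature, SampleRecord, Spectrum, TrajectoryEndpointSet

_FEATURE_META_COLS = ["feature_id", "mz", "rt", "iso_m1_frac", "iso_m2_frac"]


# ---------------------------------------------------------------- features

def read_feature_table(path: str | Path, mode: str) -> list[Feature]:
    """Read an aligned feature table (one row per feature).

    Columns: feature_id, mz, rt, optional iso_m1_frac / iso_m2_frac, then
    one area column per sample id. Missing areas are read as 0. Rows with
    non-numeric mz/rt or duplicate ids are rejected with the row number.
    """
    df = pd.read_csv(path, sep="\t", dtype={"feature_id": str})
    missing = {"feature_id", "mz", "rt"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df["feature_id"].duplicated().any():
        dupes = df.loc[df["feature_id"].duplicated(), "feature_id"].tolist()
        raise ValueError(f"{path}: duplicate feature ids {dupes[:5]}")
    sample_cols = [c for c in df.columns if c not in _FEATURE_META_COLS]
    features = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        rec = dict(zip(df.columns, row))
        try:
            mz, rt = float(rec["mz"]), float(rec["rt"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path} row {row_no}: non-numeric mz/rt") from exc
        areas = {}
        for c in sample_cols:
            v = rec[c]
            areas[c] = 0.0 if pd.isna(v) else float(v)
        def _iso(key):
            v = rec.get(key)
            return None if v is None or pd.isna(v) else float(v)
        try:
            features.append(Feature(
                feature_id=str(rec["feature_id"]), mode=mode, mz=mz, rt=rt,
                areas=areas, iso_m1_frac=_iso("iso_m1_frac"), iso_m2_frac=_iso("iso_m2_frac"),
            ))
        except ValueError as exc:
            raise ValueError(f"{path} row {row_no}: {exc}") from exc
    return features


def write_feature_table(features: list[Feature], path: str | Path) -> None:
    sample_ids: list[str] = []
    for f in features:
        for s in f.areas:
            if s not in sample_ids:
                sample_ids.append(s)
    rows = []
    for f in features:
        row = {"feature_id": f.feature_id, "mz": f.mz, "rt": f.rt,
               "iso_m1_frac": f.iso_m1_frac, "iso_m2_frac": f.iso_m2_frac}
        for s in sample_ids:
            row[s] = f.areas.get(s, 0.0)
        rows.append(row)
    df = pd.DataFrame(rows, columns=_FEATURE_META_COLS + sample_ids)
    df.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------- MSP

def read_msp(path: str | Path) -> dict[str, Spectrum]:
    """Parse an MSP file into a map feature_id/name -> Spectrum.

    Keys ("Name", "PrecursorMZ", "Ion_mode", "Num Peaks") are matched
    case-insensitively; intensities are rescaled to base peak = 1.
    Records with zero peaks are skipped with a warning; a malformed peak
    line rejects the whole record (also with a warning).
    """
    spectra: dict[str, Spectrum] = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    block: list[str] = []
    for line in lines + [""]:
        if line.strip():
            block.append(line)
            continue
        if block:
            _parse_msp_block(block, spectra)
            block = []
    return spectra


def _parse_msp_block(block: list[str], out: dict[str, Spectrum]) -> None:
    meta: dict[str, str] = {}
    peaks: list[tuple[float, float]] = []
    in_peaks = False
    name = None
    for line in block:
        if not in_peaks and ":" in line:
            key, _, val = line.partition(":")
            lk = key.strip().lower().replace(" ", "").replace("_", "")
            meta[lk] = val.strip()
            if lk == "name":
                name = val.strip()
            if lk == "numpeaks":
                in_peaks = True
            continue
        parts = line.replace(";", " ").split()
        if len(parts) < 2:
            warnings.warn(f"MSP record {name!r}: malformed peak line {line!r}; record skipped")
            return
        try:
            peaks.append((float(parts[0]), float(parts[1])))
        except ValueError:
            warnings.warn(f"MSP record {name!r}: malformed peak line {line!r}; record skipped")
            return
    if name is None:
        warnings.warn("MSP record without Name; skipped")
        return
    if not peaks:
        warnings.warn(f"MSP record {name!r} has zero peaks; skipped")
        return
    mode_raw = meta.get("ionmode", "negative").lower()
    mode = "positive" if mode_raw.startswith("p") or mode_raw == "+" else "negative"
    precursor = float(meta.get("precursormz", 0) or 0)
    out[name] = Spectrum(precursor_mz=precursor, mode=mode, peaks=peaks)


def write_msp(spectra: dict[str, Spectrum], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, sp in spectra.items():
            fh.write(f"Name: {name}\n")
            fh.write(f"PrecursorMZ: {sp.precursor_mz:.5f}\n")
            fh.write(f"Ion_mode: {'Positive' if sp.mode == 'positive' else 'Negative'}\n")
            fh.write(f"Num Peaks: {len(sp.peaks)}\n")
            for mz, inten in sp.peaks:
                fh.write(f"{mz:.5f} {inten:.6f}\n")
            fh.write("\n")


# ---------------------------------------------------------------- metadata

def read_sample_table(path: str | Path) -> list[SampleRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    is_cols = [c for c in df.columns if c.startswith("is_area_")]
    w_cols = [c for c in df.columns if c.startswith("w_region_")]
    records = []
    for row in df.itertuples(index=False):
        rec = dict(zip(df.columns, row))
        records.append(SampleRecord(
            sample_id=str(rec["sample_id"]),
            start_date=str(rec["start_date"]),
            end_date=str(rec["end_date"]),
            mean_temp_C=float(rec["mean_temp_C"]),
            is_field_blank=bool(rec["is_field_blank"]),
            is_areas={c[len("is_area_"):]: float(rec[c]) for c in is_cols},
            cluster_weights={int(c[len("w_region_"):]): float(rec[c]) for c in w_cols},
        ))
    return records


def write_sample_table(samples: list[SampleRecord], path: str | Path) -> None:
    std_names = list(samples[0].is_areas) if samples else []
    regions = sorted({r for s in samples for r in s.cluster_weights}) if samples else []
    rows = []
    for s in samples:
        row = {"sample_id": s.sample_id, "start_date": s.start_date,
               "end_date": s.end_date, "mean_temp_C": s.mean_temp_C,
               "is_field_blank": s.is_field_blank}
        for n in std_names:
            row[f"is_area_{n}"] = s.is_areas.get(n, 0.0)
        for r in regions:
            row[f"w_region_{r}"] = s.cluster_weights.get(r, 0.0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------- trajectories

def read_trajectories(path: str | Path) -> list[TrajectoryEndpointSet]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "traj_id": str})
    sets = []
    for sid, grp in df.groupby("sample_id", sort=False):
        trajs: dict[str, list[tuple[float, float, float]]] = {}
        for tid, tgrp in grp.groupby("traj_id", sort=False):
            trajs[str(tid)] = [
                (float(h), float(la), float(lo))
                for h, la, lo in zip(tgrp["hour_offset"], tgrp["lat"], tgrp["lon"])
            ]
        sets.append(TrajectoryEndpointSet(sample_id=str(sid), trajectories=trajs))
    return sets


def write_trajectories(sets: list[TrajectoryEndpointSet], path: str | Path) -> None:
    rows = []
    for ts in sets:
        for tid, pts in ts.trajectories.items():
            for h, lat, lon in pts:
                rows.append({"sample_id": ts.sample_id, "traj_id": tid,
                             "hour_offset": h, "lat": lat, "lon": lon})
    pd.DataFrame(rows, columns=["sample_id", "traj_id", "hour_offset", "lat", "lon"]).to_csv(
        path, sep="\t", index=False)
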