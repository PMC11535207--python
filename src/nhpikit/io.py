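"""Tabular and raster I/O: Movebank-style tracks, nests, coefficients.

All tabular formats are headed CSV; rasters are paired ASCII grids
(see :mod:`nhpikit.landscape`); the PCA model is JSON.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .landscape import LandscapeRaster, read_landscape
from .steps import Track

TRACK_COLUMNS = ("individual", "timestamp", "x", "y")


class SchemaError(ValueError):
    """A required column is missing or rows are malformed."""


def read_tracks(path: str | Path) -> list[Track]:
    """Parse a Movebank-style track CSV into per-individual tracks.

    Required columns: individual, timestamp (ISO 8601), x, y (planar
    metres).  Optional: phase, year (year defaults to the timestamp's
    calendar year; phase to "prospecting").  Duplicate
    (individual, timestamp) pairs are rejected.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    try:
        ts = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    except (ValueError, TypeError):
        bad = pd.to_datetime(df["timestamp"], utc=True, errors="coerce", format="mixed")
        lines = (df.index[bad.isna()] + 2).tolist()  # +2: header + 1-based
        raise SchemaError(f"{path}: unparseable timestamps at lines {lines[:10]}")
    df = df.assign(_ts=ts.dt.tz_localize(None))
    dup = df.duplicated(subset=["individual", "_ts"], keep=False)
    if dup.any():
        pairs = df.loc[dup, ["individual", "timestamp"]].drop_duplicates().head(10)
        raise SchemaError(f"{path}: duplicated (individual, timestamp) pairs:\n{pairs}")
    if "phase" not in df.columns:
        df["phase"] = "prospecting"
    if "year" not in df.columns:
        df["year"] = df["_ts"].dt.year
    tracks = []
    for ind, grp in df.groupby("individual", sort=True):
        grp = grp.sort_values("_ts")
        tracks.append(
            Track(
                individual=str(ind),
                times=grp["_ts"].to_numpy().astype("datetime64[s]"),
                x=grp["x"].to_numpy(dtype=float),
                y=grp["y"].to_numpy(dtype=float),
                phase=grp["phase"].to_numpy(dtype=object),
                year=grp["year"].to_numpy(dtype=int),
            )
        )
    return tracks


def write_tracks(tracks: list[Track], path: str | Path) -> None:
    frames = []
    for tr in tracks:
        frames.append(
            pd.DataFrame(
                {
                    "individual": tr.individual,
                    "timestamp": np.datetime_as_string(tr.times, unit="s", timezone="UTC"),
                    "x": tr.x,
                    "y": tr.y,
                    "phase": tr.phase,
                    "year": tr.year,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_nests(path: str | Path) -> pd.DataFrame:
    """Nest table CSV: individual, nest_x, nest_y (+ optional tagging_year)."""
    df = pd.read_csv(path)
    missing = [c for c in ("individual", "nest_x", "nest_y") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    df["individual"] = df["individual"].astype(str)
    return df


def read_raster(elevation_path: str | Path, land_cover_path: str | Path) -> LandscapeRaster:
    """Load and validate a landscape from paired ASCII grids."""
    return read_landscape(elevation_path, land_cover_path)


def write_coefficients(fits, path: str | Path) -> pd.DataFrame:
    """Flatten FitResult objects into the coefficients CSV."""
    rows = []
    for fit in fits:
        row = {
            "individual": fit.individual,
            "label": fit.label,
            "nhpi": fit.nhpi,
            "loglik": fit.loglik,
            "n_strata": fit.n_strata,
            "converged": fit.converged,
            "flags": ";".join(fit.flags),
        }
        for name, b, s in zip(fit.covariates, fit.beta, fit.se):
            base = name.split("_z")[0]
            row[f"beta_{base}"] = float(b)
            row[f"se_{base}"] = float(s)
        rows.append(row)
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False)
    return df
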