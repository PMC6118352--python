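"""Readers and writers for coordinate tables, curves and scalar summaries.

Coordinate input is delimited text with header columns ``sheet_id``,
``channel`` (optional), ``x``, ``y`` and optionally ``condition``.  ImageJ
measurement exports are supported through a column map (e.g. ``{"X": "x",
"Y": "y"}``) plus a ``pixel_size_nm`` scale in the analysis config.  Sheets
carrying both ``big`` and ``small`` channels become
:class:`~nanospat.patterns.BivariatePattern`; all others become univariate
:class:`~nanospat.patterns.PointPattern`.

Curves are written as CSV with columns ``r_nm, value, kind`` and round-trip
losslessly (pandas writes shortest-repr floats).  Scalar summaries go to
JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .patterns import (
    BivariatePattern,
    PointPattern,
    RadialCurve,
    StudyRegion,
    ValidationError,
)

__all__ = [
    "FormatError",
    "read_coordinates",
    "write_coordinates",
    "write_curve",
    "read_curve",
    "write_json",
]

CHANNEL_LABELS = ("big", "small")


class FormatError(ValueError):
    """The file does not match the expected tabular layout."""


def read_coordinates(
    path: str | Path,
    config: AnalysisConfig | None = None,
) -> list[PointPattern | BivariatePattern]:
    """Parse a coordinate CSV into one pattern per sheet.

    Coordinates are scaled by ``config.pixel_size_nm`` when set (pixels ->
    nm); columns are renamed through ``config.column_map`` first.  Points
    outside the configured region raise a validation error naming the sheet
    and row.
    """
    config = config or AnalysisConfig()
    df = pd.read_csv(path, float_precision="round_trip")
    if config.column_map:
        df = df.rename(columns=config.column_map)
    missing = {"sheet_id", "x", "y"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    scale = config.pixel_size_nm or 1.0
    region = config.region
    xy = df[["x", "y"]].to_numpy(dtype=float) * scale
    if not np.all(np.isfinite(xy)):
        bad = int(np.nonzero(~np.isfinite(xy).all(axis=1))[0][0])
        raise ValidationError(f"{path}: non-finite coordinate at data row {bad}")
    inside = region.contains(xy)
    if not np.all(inside):
        bad = int(np.nonzero(~inside)[0][0])
        raise ValidationError(
            f"{path}: point {tuple(xy[bad])} nm at data row {bad} of sheet "
            f"{df['sheet_id'].iloc[bad]!r} lies outside the "
            f"{region.width} x {region.height} nm region"
        )
    has_channel = "channel" in df.columns
    if has_channel:
        labels = df["channel"].astype(str)
        unknown = set(labels.unique()) - set(CHANNEL_LABELS)
        if unknown:
            raise ValidationError(
                f"{path}: unknown channel labels {sorted(unknown)}; expected {CHANNEL_LABELS}"
            )
    conditions = df["condition"].astype(str) if "condition" in df.columns else None

    patterns: list[PointPattern | BivariatePattern] = []
    for sid in df["sheet_id"].astype(str).unique():
        sel = df["sheet_id"].astype(str) == sid
        cond = str(conditions[sel].iloc[0]) if conditions is not None else ""
        if has_channel:
            chan = df.loc[sel, "channel"].astype(str)
            present = set(chan.unique())
            if present == set(CHANNEL_LABELS):
                big = PointPattern(xy[sel.to_numpy() & (labels == "big").to_numpy()],
                                   region, sheet_id=sid, condition=cond)
                small = PointPattern(xy[sel.to_numpy() & (labels == "small").to_numpy()],
                                     region, sheet_id=sid, condition=cond)
                patterns.append(BivariatePattern(big, small))
                continue
        patterns.append(PointPattern(xy[sel.to_numpy()], region, sheet_id=sid, condition=cond))
    return patterns


def write_coordinates(
    patterns: Sequence[PointPattern | BivariatePattern], path: str | Path
) -> None:
    """Write patterns back to the coordinate-CSV dialect the reader consumes."""
    rows = []
    for p in patterns:
        if isinstance(p, BivariatePattern):
            for label, chan in (("big", p.big), ("small", p.small)):
                for x, y in chan.points:
                    rows.append((p.sheet_id, p.condition, label, x, y))
        else:
            for x, y in p.points:
                rows.append((p.sheet_id, p.condition, "", x, y))
    df = pd.DataFrame(rows, columns=["sheet_id", "condition", "channel", "x", "y"])
    if not df["channel"].astype(bool).any():
        df = df.drop(columns=["channel"])
    df.to_csv(path, index=False, float_format="%.17g")


def write_curve(curve: RadialCurve, path: str | Path) -> None:
    """CSV with columns r_nm, value, kind (one data row per radius)."""
    df = pd.DataFrame({"r_nm": curve.radii, "value": curve.values, "kind": curve.kind})
    if curve.flags is not None:
        df["clamped"] = curve.flags.astype(int)
    df.to_csv(path, index=False, float_format="%.17g")  # %.17g round-trips float64


def read_curve(path: str | Path) -> RadialCurve:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"r_nm", "value", "kind"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing curve columns {sorted(missing)}")
    kinds = df["kind"].unique()
    if len(kinds) != 1:
        raise FormatError(f"{path}: mixed curve kinds {list(kinds)}")
    flags = df["clamped"].to_numpy(dtype=bool) if "clamped" in df.columns else None
    return RadialCurve(
        df["r_nm"].to_numpy(dtype=float),
        df["value"].to_numpy(dtype=float),
        str(kinds[0]),
        flags=flags,
    )


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, cls=_NumpyEncoder)
        fh.write("\n")
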