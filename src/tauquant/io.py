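"""Tidy-CSV readers/writers and image I/O for every pipeline stage.

All tables are long format, one observation per row, with unit-suffixed
numeric columns (``_M``, ``_uM``, ``_min``, ``_um``).  Images are
written as 2-channel TIFF (tubulin first) with PNG mask sidecars and a
JSON truth sidecar for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .binding import TitrationSeries
from .errors import ValidationError
from .imaging import CellImage
from .kinetics import AggregationTimeCourse
from .migration import Track
from .synthetic import SyntheticCellImage
from .viability import DoseResponse

__all__ = [
    "read_table",
    "TABLE_SCHEMAS",
    "titrations_to_frame",
    "titrations_from_frame",
    "timecourses_to_frame",
    "timecourses_from_frame",
    "dose_responses_to_frame",
    "dose_responses_from_frame",
    "tracks_to_frame",
    "tracks_from_frame",
    "write_cell_image",
    "read_cell_image",
]

# required columns per table kind; optional columns in the second set
TABLE_SCHEMAS: dict[str, tuple[set[str], set[str]]] = {
    "titration": ({"compound", "conc_M", "F_obs"}, {"A_ex", "A_em", "protein_conc_M"}),
    "timecourse": ({"well", "compound", "conc_uM", "time_min", "intensity"}, {"tau_conc_uM"}),
    "plate": ({"compound", "dose_uM", "viability"}, {"cell_line"}),
    "plate_raw": ({"compound", "cell_line", "dose_uM", "replicate", "absorbance"}, set()),
    "tracks": ({"track_id", "frame", "time_min", "x_um", "y_um"}, {"group", "condition"}),
}

_UNIT_SUFFIXES = ("_M", "_uM", "_min", "_um")


def _check_columns(df: pd.DataFrame, kind: str, path) -> None:
    required, _ = TABLE_SCHEMAS[kind]
    for col in sorted(required):
        if col in df.columns:
            continue
        # a column present without its unit suffix gets a pointed message
        for suffix in _UNIT_SUFFIXES:
            if col.endswith(suffix) and col[: -len(suffix)] in df.columns:
                raise ValidationError(
                    f"{path}: column {col[:-len(suffix)]!r} lacks its unit suffix; "
                    f"expected {col!r}"
                )
        raise ValidationError(f"{path}: missing required column {col!r}")
    numeric = {c for c in df.columns if any(c.endswith(s) for s in _UNIT_SUFFIXES)}
    numeric |= {"F_obs", "A_ex", "A_em", "intensity", "viability", "absorbance"}
    for col in numeric & set(df.columns):
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValidationError(f"{path}: column {col!r} must be numeric")


def read_table(path, kind: str) -> pd.DataFrame:
    """Read and schema-validate a tidy CSV of the given kind."""
    if kind not in TABLE_SCHEMAS:
        raise ValidationError(f"unknown table kind {kind!r}")
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{path}: file not found")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: no records") from None
    if df.empty:
        raise ValidationError(f"{path}: no records")
    _check_columns(df, kind, path)
    return df


# --------------------------------------------------------------------------
# titrations

def titrations_to_frame(series: Sequence[TitrationSeries]) -> pd.DataFrame:
    rows = []
    for s in series:
        for i in range(s.quencher_conc.size):
            row = {
                "compound": s.compound_id,
                "conc_M": s.quencher_conc[i],
                "F_obs": s.F_obs[i],
                "protein_conc_M": s.protein_conc,
            }
            if s.has_absorbances:
                row["A_ex"] = s.A_ex[i]
                row["A_em"] = s.A_em[i]
            rows.append(row)
    return pd.DataFrame(rows)


def titrations_from_frame(df: pd.DataFrame) -> list[TitrationSeries]:
    out = []
    for cid, grp in df.groupby("compound", sort=False):
        grp = grp.sort_values("conc_M")
        has_abs = {"A_ex", "A_em"} <= set(grp.columns) and not (
            grp[["A_ex", "A_em"]].isna().any().any()
        )
        out.append(
            TitrationSeries(
                compound_id=str(cid),
                quencher_conc=grp["conc_M"].to_numpy(),
                F_obs=grp["F_obs"].to_numpy(),
                A_ex=grp["A_ex"].to_numpy() if has_abs else None,
                A_em=grp["A_em"].to_numpy() if has_abs else None,
                protein_conc=float(grp["protein_conc_M"].iloc[0])
                if "protein_conc_M" in grp.columns
                else 5e-6,
            )
        )
    return out


# --------------------------------------------------------------------------
# ThS time courses

def timecourses_to_frame(tcs: Sequence[AggregationTimeCourse]) -> pd.DataFrame:
    rows = []
    for tc in tcs:
        for t, y in zip(tc.times, tc.intensity):
            rows.append(
                {
                    "well": tc.well_id,
                    "compound": tc.compound_id,
                    "conc_uM": tc.compound_conc,
                    "tau_conc_uM": tc.tau_conc,
                    "time_min": t,
                    "intensity": y,
                }
            )
    return pd.DataFrame(rows)


def timecourses_from_frame(df: pd.DataFrame) -> list[AggregationTimeCourse]:
    out = []
    for well, grp in df.groupby("well", sort=False):
        grp = grp.sort_values("time_min")
        out.append(
            AggregationTimeCourse(
                well_id=str(well),
                compound_id=str(grp["compound"].iloc[0]),
                compound_conc=float(grp["conc_uM"].iloc[0]),
                tau_conc=float(grp["tau_conc_uM"].iloc[0])
                if "tau_conc_uM" in grp.columns
                else float("nan"),
                times=grp["time_min"].to_numpy(),
                intensity=grp["intensity"].to_numpy(),
            )
        )
    return out


# --------------------------------------------------------------------------
# viability plates

def dose_responses_to_frame(drs: Sequence[DoseResponse]) -> pd.DataFrame:
    rows = []
    for dr in drs:
        for d, v in zip(dr.doses, dr.viability):
            rows.append(
                {
                    "compound": dr.compound_id,
                    "cell_line": dr.cell_line,
                    "dose_uM": d,
                    "viability": v,
                }
            )
    return pd.DataFrame(rows)


def dose_responses_from_frame(df: pd.DataFrame) -> list[DoseResponse]:
    keys = ["compound"] + (["cell_line"] if "cell_line" in df.columns else [])
    out = []
    for key, grp in df.groupby(keys, sort=False):
        key = key if isinstance(key, tuple) else (key,)
        grp = grp.sort_values("dose_uM")
        out.append(
            DoseResponse(
                compound_id=str(key[0]),
                cell_line=str(key[1]) if len(key) > 1 else "",
                doses=grp["dose_uM"].to_numpy(),
                viability=grp["viability"].to_numpy(),
            )
        )
    return out


# --------------------------------------------------------------------------
# migration tracks

def tracks_to_frame(tracks: Sequence[Track], group: str | None = None) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        for i, (t, x, y) in enumerate(zip(tr.times, tr.x, tr.y)):
            row = {
                "track_id": tr.track_id,
                "frame": i,
                "time_min": t,
                "x_um": x,
                "y_um": y,
            }
            if group is not None:
                row["group"] = group
            rows.append(row)
    return pd.DataFrame(rows)


def tracks_from_frame(df: pd.DataFrame) -> list[Track]:
    out = []
    for tid, grp in df.groupby("track_id", sort=False):
        grp = grp.sort_values("frame")
        out.append(
            Track(
                track_id=str(tid),
                times=grp["time_min"].to_numpy(),
                x=grp["x_um"].to_numpy(),
                y=grp["y_um"].to_numpy(),
            )
        )
    return out


def grouped_tracks_from_frame(df: pd.DataFrame, group_col: str = "group"):
    if group_col not in df.columns:
        raise ValidationError(f"missing required column {group_col!r}")
    return {
        str(g): tracks_from_frame(sub) for g, sub in df.groupby(group_col, sort=False)
    }


# --------------------------------------------------------------------------
# images

def write_cell_image(sci: SyntheticCellImage, stem) -> dict[str, Path]:
    """Write TIFF + mask PNGs + truth JSON; returns the paths."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    stack = np.stack(
        [sci.image.tubulin_channel, sci.image.actin_channel]
    ).astype(np.float32)
    paths = {
        "image": stem.with_suffix(".tif"),
        "cell_mask": Path(f"{stem}_cell_mask.png"),
        "mt_mask": Path(f"{stem}_mt_mask.png"),
        "truth": stem.with_suffix(".json"),
    }
    tifffile.imwrite(paths["image"], stack)
    iio.imwrite(paths["cell_mask"], (sci.cell_mask * 255).astype(np.uint8))
    iio.imwrite(paths["mt_mask"], (sci.mt_mask * 255).astype(np.uint8))
    paths["truth"].write_text(json.dumps(asdict(sci.truth), indent=2))
    return paths


def read_cell_image(tiff_path, label: str = "") -> CellImage:
    """Read a 2-channel TIFF (tubulin first, actin second)."""
    stack = tifffile.imread(tiff_path)
    if stack.ndim != 3 or stack.shape[0] != 2:
        raise ValidationError(f"{tiff_path}: expected a 2-channel TIFF stack")
    return CellImage(
        tubulin_channel=stack[0].astype(float),
        actin_channel=stack[1].astype(float),
        label=label or str(tiff_path),
    )
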