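"""Reading and writing landmark coordinate tables and definition files.

The canonical on-disk format is tidy ("long") CSV with columns
``specimen,group,landmark,x,y,z`` (UTF-8, '.' decimal separator,
coordinates in mm). A "wide" dialect — one row per specimen with
``<label>_x,<label>_y,<label>_z`` columns — is supported for
convenience. Subset and bilateral-pairing definitions are read from
YAML or CSV.
"""
from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .landmarks import (
    LandmarkConfiguration,
    LandmarkDataset,
    SubsetDefinition,
    ValidationError,
)

__all__ = [
    "read_landmark_table",
    "write_landmark_table",
    "read_subset_definitions",
    "read_bilateral_pairing",
]

_LONG_COLUMNS = ["specimen", "group", "landmark", "x", "y", "z"]


def read_landmark_table(path: str | Path, dialect: str = "long") -> LandmarkDataset:
    """Read a landmark CSV into a validated :class:`LandmarkDataset`.

    Landmark order is taken from the first specimen and enforced for all
    others; any specimen with a missing, extra, or non-numeric coordinate
    raises :class:`ValidationError` naming the specimen and landmark.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    if dialect == "long":
        return _read_long(path)
    if dialect == "wide":
        return _read_wide(path)
    raise ValidationError(f"unknown dialect {dialect!r} (expected 'long' or 'wide')")


def _read_long(path: Path) -> LandmarkDataset:
    df = pd.read_csv(path, dtype={"specimen": str, "group": str, "landmark": str})
    missing_cols = [c for c in _LONG_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"{path}: missing columns {missing_cols}")
    for axis in ("x", "y", "z"):
        vals = pd.to_numeric(df[axis], errors="coerce")
        bad = df.index[vals.isna() & df[axis].notna()]
        if len(bad):
            row = df.loc[bad[0]]
            raise ValidationError(
                f"{path}: non-numeric {axis} coordinate for specimen "
                f"{row['specimen']!r}, landmark {row['landmark']!r}"
            )
        if vals.isna().any():
            row = df.loc[vals.index[vals.isna()][0]]
            raise ValidationError(
                f"{path}: missing {axis} coordinate for specimen "
                f"{row['specimen']!r}, landmark {row['landmark']!r}"
            )
        df[axis] = vals

    specimen_order = list(dict.fromkeys(df["specimen"]))
    first = df[df["specimen"] == specimen_order[0]]
    labels = tuple(first["landmark"])
    if len(set(labels)) != len(labels):
        raise ValidationError(
            f"{path}: duplicate landmark rows for specimen {specimen_order[0]!r}"
        )

    configs = []
    groups: dict[str, str] = {}
    for sid in specimen_order:
        sub = df[df["specimen"] == sid]
        have = dict(zip(sub["landmark"], zip(sub["x"], sub["y"], sub["z"])))
        if len(have) != len(sub):
            raise ValidationError(f"{path}: duplicate landmark rows for specimen {sid!r}")
        missing = [lbl for lbl in labels if lbl not in have]
        if missing:
            raise ValidationError(
                f"{path}: specimen {sid!r} lacks landmark(s) {missing}"
            )
        extra = [lbl for lbl in have if lbl not in labels]
        if extra:
            raise ValidationError(
                f"{path}: specimen {sid!r} has unexpected landmark(s) {extra}"
            )
        coords = np.array([have[lbl] for lbl in labels], dtype=float)
        configs.append(LandmarkConfiguration(sid, labels, coords))
        grp = sub["group"].iloc[0]
        if (sub["group"] != grp).any():
            raise ValidationError(
                f"{path}: specimen {sid!r} has inconsistent group labels"
            )
        groups[sid] = str(grp)
    return LandmarkDataset(configs, groups)


def _read_wide(path: Path) -> LandmarkDataset:
    df = pd.read_csv(path, dtype={"specimen": str, "group": str})
    for col in ("specimen", "group"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    coord_cols = [c for c in df.columns if c not in ("specimen", "group")]
    labels: list[str] = []
    for c in coord_cols:
        if c.endswith("_x"):
            labels.append(c[:-2])
    for lbl in labels:
        for axis in ("x", "y", "z"):
            if f"{lbl}_{axis}" not in df.columns:
                raise ValidationError(
                    f"{path}: landmark {lbl!r} lacks a _{axis} column"
                )
    if not labels:
        raise ValidationError(f"{path}: no <label>_x/_y/_z coordinate columns found")

    configs = []
    groups: dict[str, str] = {}
    for _, row in df.iterrows():
        sid = str(row["specimen"])
        coords = np.empty((len(labels), 3), dtype=float)
        for i, lbl in enumerate(labels):
            for j, axis in enumerate(("x", "y", "z")):
                val = row[f"{lbl}_{axis}"]
                try:
                    coords[i, j] = float(val)
                except (TypeError, ValueError):
                    raise ValidationError(
                        f"{path}: non-numeric {axis} coordinate for specimen "
                        f"{sid!r}, landmark {lbl!r}"
                    ) from None
                if not np.isfinite(coords[i, j]):
                    raise ValidationError(
                        f"{path}: missing {axis} coordinate for specimen "
                        f"{sid!r}, landmark {lbl!r}"
                    )
        configs.append(LandmarkConfiguration(sid, tuple(labels), coords))
        groups[sid] = str(row["group"])
    return LandmarkDataset(configs, groups)


def write_landmark_table(
    dataset: LandmarkDataset, path: str | Path, dialect: str = "long"
) -> None:
    """Write a dataset to CSV, lossless to full float precision."""
    if dataset is None:
        raise ValidationError("no dataset to write")
    path = Path(path)
    if dialect == "long":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(_LONG_COLUMNS)
            for c in dataset.configurations:
                grp = dataset.group_labels[c.specimen_id]
                for lbl, (x, y, z) in zip(c.landmark_labels, c.coordinates):
                    w.writerow([c.specimen_id, grp, lbl,
                                repr(float(x)), repr(float(y)), repr(float(z))])
    elif dialect == "wide":
        labels = dataset.landmark_labels
        header = ["specimen", "group"]
        for lbl in labels:
            header += [f"{lbl}_x", f"{lbl}_y", f"{lbl}_z"]
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(header)
            for c in dataset.configurations:
                row = [c.specimen_id, dataset.group_labels[c.specimen_id]]
                for x, y, z in c.coordinates:
                    row += [repr(float(x)), repr(float(y)), repr(float(z))]
                w.writerow(row)
    else:
        raise ValidationError(f"unknown dialect {dialect!r}")


def read_subset_definitions(path: str | Path) -> list[SubsetDefinition]:
    """Read named landmark subsets from YAML (``name: [labels]``) or CSV
    (columns ``name,landmark``)."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    if path.suffix.lower() in (".yaml", ".yml"):
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValidationError(f"{path}: expected a mapping name -> [labels]")
        return [SubsetDefinition(str(k), tuple(v)) for k, v in data.items()]
    df = pd.read_csv(path, dtype=str)
    for col in ("name", "landmark"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    out = []
    for name, sub in df.groupby("name", sort=False):
        out.append(SubsetDefinition(str(name), tuple(sub["landmark"])))
    return out


def read_bilateral_pairing(path: str | Path) -> list[tuple[str, str]]:
    """Read (left, right) landmark homolog pairs from YAML
    (``left_label: right_label`` mapping or list of pairs) or CSV
    (columns ``left,right``)."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    if path.suffix.lower() in (".yaml", ".yml"):
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if isinstance(data, dict):
            return [(str(k), str(v)) for k, v in data.items()]
        if isinstance(data, list):
            return [(str(a), str(b)) for a, b in data]
        raise ValidationError(f"{path}: expected mapping or list of pairs")
    df = pd.read_csv(path, dtype=str)
    for col in ("left", "right"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    return list(zip(df["left"], df["right"]))
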