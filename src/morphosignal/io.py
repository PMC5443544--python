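"""Readers and writers for landmark data (TPS, CSV/XLSX) and trees (Newick).

The TPS dialect accepted is the one produced by common 2-D digitizers:
``LM=`` opens a record, followed by that many ``x y`` lines, then optional
``ID=``, ``IMAGE=`` and ``SCALE=`` keys.  Unknown keys are ignored with a
logged warning.  Coordinates are stored exactly as read (digitizer y-up
convention); no axis is flipped.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .datatypes import LandmarkConfiguration, LandmarkDataset, Phylogeny
from .errors import ParseError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

_KNOWN_TPS_KEYS = {"LM", "ID", "IMAGE", "SCALE"}

DEFAULT_COLUMN_MAP: dict[str, str] = {
    "specimen": "specimen_id",
    "species": "species_id",
    "side": "anchor_side",
    "layout": "auto",
    "landmark": "landmark",
    "x": "x",
    "y": "y",
    "scale": "scale_factor",
}


# ---------------------------------------------------------------- TPS


def read_tps(
    path,
    scale_policy: str = "ignore",
    anchor_side: str = "ventral",
    species_map: Mapping[str, str] | Callable[[str], str] | None = None,
) -> LandmarkDataset:
    """Parse a TPS file into a validated :class:`LandmarkDataset`.

    ``scale_policy='apply'`` multiplies coordinates by the record's SCALE=
    value (and clears the stored factor); ``'ignore'`` keeps raw digitizer
    units with the factor retained on each configuration.  TPS carries no
    species or side field, so ``anchor_side`` labels every record and
    ``species_map`` (mapping or callable on the specimen id) supplies
    species labels; by default the specimen id doubles as the species id.
    """
    if scale_policy not in ("apply", "ignore"):
        raise ValueError(f"unknown scale_policy {scale_policy!r}")
    text = Path(path).read_text(encoding="utf-8")
    configs: list[LandmarkConfiguration] = []
    record_coords: list[list[float]] = []
    expected = None
    meta: dict[str, str] = {}
    start_line = 0

    def flush(line_no: int) -> None:
        nonlocal expected, record_coords, meta
        if expected is None:
            return
        if len(record_coords) != expected:
            ident = meta.get("ID") or meta.get("IMAGE") or f"record at line {start_line}"
            raise ParseError(
                f"{ident}: LM={expected} but {len(record_coords)} coordinate "
                f"lines found (before line {line_no})"
            )
        specimen = meta.get("ID") or meta.get("IMAGE") or f"record_{len(configs)}"
        scale = float(meta["SCALE"]) if "SCALE" in meta else None
        coords = np.asarray(record_coords, dtype=float)
        if scale_policy == "apply" and scale is not None:
            coords = coords * scale
            scale = None
        if callable(species_map):
            species = species_map(specimen)
        elif species_map is not None:
            species = species_map.get(specimen, specimen)
        else:
            species = specimen
        configs.append(
            LandmarkConfiguration(
                specimen_id=specimen,
                species_id=species,
                anchor_side=anchor_side,
                coords=coords,
                scale_factor=scale,
            )
        )
        expected = None
        record_coords = []
        meta = {}

    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        m = re.match(r"^([A-Za-z][A-Za-z0-9_]*)=(.*)$", line)
        if m:
            key, value = m.group(1).upper(), m.group(2).strip()
            if key == "LM":
                flush(line_no)
                try:
                    expected = int(value)
                except ValueError as exc:
                    raise ParseError(f"line {line_no}: bad LM count {value!r}") from exc
                start_line = line_no
            elif key in _KNOWN_TPS_KEYS:
                meta[key] = value
            else:
                logger.warning("ignoring unknown TPS key %s= at line %d", key, line_no)
            continue
        if expected is None:
            raise ParseError(f"line {line_no}: coordinates before any LM= record")
        parts = line.split()
        if len(parts) != 2:
            raise ParseError(f"line {line_no}: expected 'x y', got {line!r}")
        try:
            record_coords.append([float(parts[0]), float(parts[1])])
        except ValueError as exc:
            raise ParseError(f"line {line_no}: non-numeric coordinate {line!r}") from exc
    flush(line_no=len(text.splitlines()) + 1)
    if not configs:
        raise ParseError(f"{path}: no TPS records found")
    return LandmarkDataset(configs)


def write_tps(dataset: LandmarkDataset, path) -> None:
    """Write a dataset in TPS form (full float precision, round-trip safe)."""
    lines: list[str] = []
    for c in dataset:
        lines.append(f"LM={c.k}")
        for x, y in c.coords:
            lines.append(f"{x:.17g} {y:.17g}")
        lines.append(f"ID={c.specimen_id}")
        if c.scale_factor is not None:
            lines.append(f"SCALE={c.scale_factor:.17g}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------- tables


def _resolve_format(path, format: str | None) -> str:
    if format is not None:
        if format not in ("csv", "xlsx"):
            raise ValueError(f"unknown table format {format!r}")
        return format
    suffix = Path(path).suffix.lower()
    return "xlsx" if suffix in (".xlsx", ".xls") else "csv"


def read_table(
    path,
    format: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> LandmarkDataset:
    """Read landmarks from a CSV or XLSX table.

    Two layouts are supported and auto-detected unless ``column_map['layout']``
    pins one down: *wide* (one row per configuration with columns
    ``x1..xk, y1..yk``) and *long* (one row per landmark with columns for the
    landmark index, x and y).
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    fmt = _resolve_format(path, format)
    if fmt == "xlsx":
        frame = pd.read_excel(path)
    else:
        frame = pd.read_csv(path)

    for role in ("specimen", "species", "side"):
        if cmap[role] not in frame.columns:
            raise SchemaError(
                f"missing mapped column {cmap[role]!r} for {role!r} in {path}"
            )

    layout = cmap.get("layout", "auto")
    long_cols = {cmap["landmark"], cmap["x"], cmap["y"]}
    wide_x = sorted(
        (c for c in frame.columns if re.fullmatch(r"x\d+", str(c))),
        key=lambda c: int(str(c)[1:]),
    )
    if layout == "auto":
        layout = "long" if long_cols <= set(frame.columns) else "wide"
    if layout == "long":
        missing = long_cols - set(frame.columns)
        if missing:
            raise SchemaError(f"long layout requires columns {sorted(missing)}")
        return _read_long(frame, cmap)
    if layout == "wide":
        if not wide_x:
            raise SchemaError("wide layout requires columns x1..xk / y1..yk")
        return _read_wide(frame, cmap, wide_x)
    raise SchemaError(f"unknown layout {layout!r}")


def _config_from_row(row, cmap, coords) -> LandmarkConfiguration:
    scale_col = cmap.get("scale")
    scale = None
    if scale_col and scale_col in row.index and pd.notna(row[scale_col]):
        scale = float(row[scale_col])
    return LandmarkConfiguration(
        specimen_id=str(row[cmap["specimen"]]),
        species_id=str(row[cmap["species"]]),
        anchor_side=str(row[cmap["side"]]),
        coords=coords,
        scale_factor=scale,
    )


def _read_wide(frame, cmap, x_cols) -> LandmarkDataset:
    y_cols = [f"y{str(c)[1:]}" for c in x_cols]
    missing = [c for c in y_cols if c not in frame.columns]
    if missing:
        raise SchemaError(f"wide layout: missing y columns {missing}")
    configs = []
    for _, row in frame.iterrows():
        coords = np.column_stack(
            [row[x_cols].to_numpy(dtype=float), row[y_cols].to_numpy(dtype=float)]
        )
        configs.append(_config_from_row(row, cmap, coords))
    return LandmarkDataset(configs)


def _read_long(frame, cmap) -> LandmarkDataset:
    configs = []
    keys = [cmap["specimen"], cmap["side"]]
    ks = set()
    for _, group in frame.groupby(keys, sort=False):
        group = group.sort_values(cmap["landmark"])
        coords = np.column_stack(
            [
                group[cmap["x"]].to_numpy(dtype=float),
                group[cmap["y"]].to_numpy(dtype=float),
            ]
        )
        ks.add(len(group))
        configs.append(_config_from_row(group.iloc[0], cmap, coords))
    if len(ks) > 1:
        raise ValidationError(f"inconsistent landmark counts across rows: {sorted(ks)}")
    return LandmarkDataset(configs)


def write_table(dataset: LandmarkDataset, path, format: str | None = None) -> None:
    """Write a dataset as a wide-layout table (CSV or XLSX)."""
    k = dataset.k
    records = []
    for c in dataset:
        rec: dict[str, object] = {
            "specimen_id": c.specimen_id,
            "species_id": c.species_id,
            "anchor_side": c.anchor_side,
        }
        for i in range(k):
            rec[f"x{i + 1}"] = c.coords[i, 0]
            rec[f"y{i + 1}"] = c.coords[i, 1]
        if c.scale_factor is not None:
            rec["scale_factor"] = c.scale_factor
        records.append(rec)
    frame = pd.DataFrame.from_records(records)
    if _resolve_format(path, format) == "xlsx":
        frame.to_excel(path, index=False)
    else:
        frame.to_csv(path, index=False)


# ---------------------------------------------------------------- trees


def read_newick(path) -> Phylogeny:
    """Read a rooted Newick tree; absent branch lengths stay absent."""
    return Phylogeny.from_path(path)


def write_newick(tree: Phylogeny, path) -> None:
    Path(path).write_text(tree.to_newick() + "\n", encoding="utf-8")
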