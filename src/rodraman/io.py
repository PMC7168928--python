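"""Delimited-text file contracts for maps, features, metrics and configs.

All artifacts are plain text: map matrices and feature tables as CSV,
metrics as flat JSON key-value documents, configuration as YAML. Numeric
round-trips are exact (floats are written with 17 significant digits).

Map files carry one pixel per row in row-major order. The first header row
is the wavenumber grid, preceded by a ``reference`` column holding each
pixel's laser-line intensity; map geometry and labels live in a single
``#``-comment line above the header.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .biomarkers import BIOMARKER_NAMES
from .synth import SimConfig, SpectralMap

__all__ = [
    "write_map", "read_map",
    "write_manifest", "read_manifest",
    "write_features", "read_features",
    "write_metrics", "read_metrics",
    "write_config", "read_config",
]

_FLOAT_FMT = "%.17g"

FEATURE_COLUMNS = ("spectrum_id", "sample_id", "class") + BIOMARKER_NAMES


def write_map(path, smap: SpectralMap) -> None:
    """Write one map as CSV: comment line with geometry/labels, wavenumber
    header, then one pixel per row (reference intensity first)."""
    path = Path(path)
    h, w = smap.shape
    header = "reference," + ",".join(_FLOAT_FMT % x for x in smap.wavenumbers)
    mat = np.column_stack([smap.reference_intensities.reshape(h * w),
                           smap.to_matrix()])
    with open(path, "w") as fh:
        fh.write(f"# sample_id={smap.sample_id} class={smap.class_label} "
                 f"height={h} width={w}\n")
        fh.write(header + "\n")
        np.savetxt(fh, mat, fmt=_FLOAT_FMT, delimiter=",")


def read_map(path) -> SpectralMap:
    """Read a map written by ``write_map``; validates the wavenumber header
    and row shapes, reporting the offending column or line."""
    path = Path(path)
    with open(path) as fh:
        meta_line = fh.readline().strip()
        if not meta_line.startswith("#"):
            raise ValueError(f"{path}: missing '#' metadata line")
        meta = dict(kv.split("=", 1) for kv in meta_line[1:].split())
        header = fh.readline().strip().split(",")
        if header[0] != "reference":
            raise ValueError(f"{path}: first header column must be 'reference'")
        try:
            wn = np.array([float(x) for x in header[1:]])
        except ValueError as e:
            raise ValueError(f"{path}: non-numeric wavenumber header: {e}") from e
        bad = np.where(np.diff(wn) <= 0)[0]
        if bad.size:
            # +3: 1-based, 'reference' column first, offender is diff index + 1
            raise ValueError(
                f"{path}: wavenumber header not strictly increasing at "
                f"column {bad[0] + 3} (value {wn[bad[0] + 1]:g})"
            )
        rows = []
        for lineno, line in enumerate(fh, start=3):
            line = line.strip()
            if not line:
                continue
            cells = line.split(",")
            if len(cells) != wn.size + 1:
                raise ValueError(
                    f"{path}: line {lineno}: expected {wn.size + 1} cells, "
                    f"got {len(cells)}"
                )
            try:
                rows.append([float(c) for c in cells])
            except ValueError as e:
                raise ValueError(f"{path}: line {lineno}: non-numeric cell: {e}") from e
    h, w = int(meta["height"]), int(meta["width"])
    mat = np.asarray(rows)
    if mat.shape[0] != h * w:
        raise ValueError(f"{path}: expected {h * w} pixel rows, got {mat.shape[0]}")
    return SpectralMap(
        sample_id=meta["sample_id"],
        class_label=meta["class"],
        wavenumbers=wn,
        intensities=mat[:, 1:].reshape(h, w, wn.size),
        reference_intensities=mat[:, 0].reshape(h, w),
    )


def write_manifest(path, manifest: pd.DataFrame) -> None:
    manifest.to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("sample_id", "class") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: manifest missing columns {missing}")
    return df


def write_features(path, features: pd.DataFrame) -> None:
    features.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_features(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: feature table missing required columns {missing}; "
            f"required: {list(FEATURE_COLUMNS)}"
        )
    return df


def write_metrics(path, metrics: dict) -> None:
    """Flat key-value metrics document (JSON)."""
    flat = {k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
            for k, v in metrics.items()}
    Path(path).write_text(json.dumps(flat, indent=2, allow_nan=True) + "\n")


def read_metrics(path) -> dict:
    return json.loads(Path(path).read_text())


def write_config(path, config) -> None:
    """YAML dump of a (dataclass) configuration; round-trips losslessly."""
    payload = asdict(config) if not isinstance(config, dict) else config
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_config(path, cls=SimConfig):
    data = yaml.safe_load(Path(path).read_text())
    return cls(**data) if cls is not None else data
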