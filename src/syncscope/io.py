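"""File formats: TIFF movies with JSON sidecars, CSV cell tables.

Movies are multi-page TIFFs in (T, Z, Y, X) order; the axis order,
frame interval, pixel size and saturation value live in a ``.json``
sidecar next to the TIFF so the round trip is lossless and
self-describing.  Architectures travel as two CSVs (cells, contacts),
cell traces as a wide CSV (one row per cell), masks and label maps as
8/16-bit TIFFs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import InputError
from .movie import IsletMovie
from .network import CellTraceSet
from .simulate import ArchitectureMap

AXES = "TZYX"


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_movie(movie: IsletMovie, path: str | Path) -> Path:
    """Write a movie as multi-page TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, movie.data)
    meta = {
        "axes": AXES,
        "frame_interval_s": movie.frame_interval_s,
        "pixel_size_um": movie.pixel_size_um,
        "saturation_value": movie.saturation_value
        if np.isfinite(movie.saturation_value)
        else None,
        "z_spacing_um": movie.z_spacing_um,
    }
    _sidecar(path).write_text(json.dumps(meta, sort_keys=True))
    return path


def read_movie(path: str | Path, axes: str | None = None) -> IsletMovie:
    """Read a TIFF movie; axis order comes from the sidecar unless overridden."""
    path = Path(path)
    data = np.asarray(tifffile.imread(path))
    side = _sidecar(path)
    if not side.exists():
        raise InputError(f"missing metadata sidecar {side}")
    meta = json.loads(side.read_text())
    order = axes or meta.get("axes", AXES)
    if data.ndim == 3:
        data = data[:, None, :, :] if order.startswith("T") else data[None]
    if sorted(order) != sorted(AXES):
        raise InputError(f"unsupported axis order {order!r}")
    perm = [order.index(ax) for ax in AXES]
    data = np.transpose(data, perm)
    sat = meta.get("saturation_value")
    return IsletMovie(
        data=data,
        frame_interval_s=float(meta["frame_interval_s"]),
        pixel_size_um=float(meta["pixel_size_um"]),
        saturation_value=np.inf if sat is None else float(sat),
        z_spacing_um=float(meta.get("z_spacing_um", 8.0)),
    )


def write_architecture(arch: ArchitectureMap, cells_path: str | Path) -> tuple[Path, Path]:
    """Write cells (id, x, y, type) and contacts (a, b) as CSV."""
    cells_path = Path(cells_path)
    cells = pd.DataFrame(
        {
            "cell_id": arch.cell_ids,
            "x_um": arch.positions_um[:, 0],
            "y_um": arch.positions_um[:, 1],
            "type": arch.types,
        }
    )
    cells.to_csv(cells_path, index=False)
    contacts_path = cells_path.with_name(cells_path.stem + "_contacts.csv")
    pd.DataFrame(arch.contacts, columns=["a", "b"]).to_csv(contacts_path, index=False)
    return cells_path, contacts_path


def read_architecture(cells_path: str | Path) -> ArchitectureMap:
    """Read an architecture written by :func:`write_architecture`."""
    cells_path = Path(cells_path)
    cells = pd.read_csv(cells_path)
    for col in ("cell_id", "x_um", "y_um", "type"):
        if col not in cells.columns:
            raise InputError(f"cell table missing column {col!r}")
    if cells["type"].isna().any():
        rows = cells.index[cells["type"].isna()].tolist()
        raise InputError(f"cell table has missing types at rows {rows}")
    contacts_path = cells_path.with_name(cells_path.stem + "_contacts.csv")
    if contacts_path.exists():
        contacts = pd.read_csv(contacts_path)[["a", "b"]].to_numpy()
    else:
        contacts = np.empty((0, 2), dtype=int)
    order = np.argsort(cells["cell_id"].to_numpy())
    cells = cells.iloc[order]
    return ArchitectureMap(
        positions_um=cells[["x_um", "y_um"]].to_numpy(float),
        types=cells["type"].to_numpy(str),
        contacts=contacts,
    )


def write_cell_traces(traces: CellTraceSet, path: str | Path) -> Path:
    """Wide CSV: cell_id, y, x, then one column per frame."""
    path = Path(path)
    n, t = traces.traces.shape
    df = pd.DataFrame(traces.traces, columns=[f"t{i}" for i in range(t)])
    df.insert(0, "x", traces.centroids[:, 1])
    df.insert(0, "y", traces.centroids[:, 0])
    df.insert(0, "cell_id", traces.cell_ids)
    df.to_csv(path, index=False)
    return path


def read_cell_traces(path: str | Path) -> CellTraceSet:
    df = pd.read_csv(path)
    for col in ("cell_id", "y", "x"):
        if col not in df.columns:
            raise InputError(f"trace table missing column {col!r}")
    tcols = [c for c in df.columns if c.startswith("t") and c[1:].isdigit()]
    tcols.sort(key=lambda c: int(c[1:]))
    return CellTraceSet(
        traces=df[tcols].to_numpy(float),
        centroids=df[["y", "x"]].to_numpy(float),
        cell_ids=df["cell_id"].to_numpy(),
    )


def write_labels(labels: np.ndarray, path: str | Path) -> Path:
    """Write an integer label image/volume as 16-bit TIFF."""
    path = Path(path)
    arr = np.asarray(labels)
    if arr.min() < 0:
        arr = arr + 1  # shift -1 background to 0
    tifffile.imwrite(path, arr.astype(np.uint16))
    return path


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Write a boolean mask as 8-bit TIFF (255 = included)."""
    path = Path(path)
    tifffile.imwrite(path, (np.asarray(mask, bool) * 255).astype(np.uint8))
    return path


def read_mask(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(path)) > 0
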