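"""File formats: detector/detection CSVs, ESRI ASCII grids, JSON exports.

All tabular formats are plain CSV with fixed headers; rasters are ESRI
ASCII grids (``ncols/nrows/xllcorner/yllcorner/cellsize/NODATA_value``
header followed by whitespace-separated rows, northernmost row first).
Coordinates are detector-center point locations in the declared unit
(du by default; a unit declaration is metadata only — all computation is
unit-agnostic).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import CaptureHistory, PopulationTruth
from .windows import DetectorArray, LESSIndex, SpatialDomain

__all__ = [
    "read_detectors",
    "write_detectors",
    "read_detections",
    "write_detections",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_habitat",
    "write_habitat",
    "write_truth",
    "read_truth",
    "export_less_index",
]


# --------------------------------------------------------------------- #
# detectors
def read_detectors(path: str | Path) -> DetectorArray:
    """Read a detector table CSV with header ``detector_id,x,y``."""
    df = pd.read_csv(path)
    required = {"detector_id", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: detector CSV must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    coords = df[["x", "y"]].to_numpy(dtype=float)
    return DetectorArray(coords, ids=df["detector_id"].to_numpy())


def write_detectors(detectors: DetectorArray, path: str | Path) -> None:
    pd.DataFrame(
        dict(detector_id=detectors.ids, x=detectors.x, y=detectors.y)
    ).to_csv(path, index=False)


# --------------------------------------------------------------------- #
# detections
def read_detections(path: str | Path, detectors: DetectorArray) -> CaptureHistory:
    """Read a detections CSV (``individual_id,detector_id``) into a binary
    capture history.

    Unknown detector ids are an error; duplicate (individual, detector)
    pairs collapse to a single binary detection.
    """
    df = pd.read_csv(path)
    required = {"individual_id", "detector_id"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: detections CSV must have columns {sorted(required)}"
        )
    if len(df) == 0:
        raise ValueError(f"{path}: no detected individuals")
    id_to_col = {d: k for k, d in enumerate(np.asarray(detectors.ids))}
    unknown = sorted(set(df["detector_id"]) - set(id_to_col))
    if unknown:
        raise ValueError(f"{path}: unknown detector ids in detections: {unknown}")
    individuals = pd.unique(df["individual_id"])
    y = np.zeros((len(individuals), detectors.count), dtype=np.int8)
    row_of = {ind: r for r, ind in enumerate(individuals)}
    for ind, det in zip(df["individual_id"], df["detector_id"]):
        y[row_of[ind], id_to_col[det]] = 1
    return CaptureHistory(y=y, individual_ids=np.asarray(individuals))


def write_detections(captures: CaptureHistory, detectors: DetectorArray,
                     path: str | Path) -> None:
    rows_i, rows_d = [], []
    ids = np.asarray(detectors.ids)
    for r in range(captures.n_detected):
        for j in np.flatnonzero(captures.y[r]):
            rows_i.append(captures.individual_ids[r])
            rows_d.append(ids[j])
    pd.DataFrame(dict(individual_id=rows_i, detector_id=rows_d)).to_csv(
        path, index=False
    )


# --------------------------------------------------------------------- #
# ESRI ASCII grids
def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII grid; returns (values south-up, header dict)."""
    lines = Path(path).read_text().splitlines()
    header: dict[str, float] = {}
    data_start = 0
    for k, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
        ):
            header[parts[0].lower()] = float(parts[1])
            data_start = k + 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: line {data_start + 1}: missing '{key}' in "
                             "ASCII grid header")
    try:
        rows = [
            [float(v) for v in line.split()]
            for line in lines[data_start:]
            if line.strip()
        ]
    except ValueError as exc:
        raise ValueError(f"{path}: malformed raster data: {exc}") from exc
    values = np.array(rows)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(
            f"{path}: raster is {values.shape}, header says "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    return values[::-1], header  # file is north-up; flip to south-up


def write_ascii_grid(
    values: np.ndarray,
    xllcorner: float,
    yllcorner: float,
    cellsize: float,
    path: str | Path,
    nodata: float = -9999,
) -> None:
    """Write a south-up array as an ESRI ASCII grid."""
    v = np.asarray(values, dtype=float)
    ny, nx = v.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {nx}\n")
        fh.write(f"nrows {ny}\n")
        fh.write(f"xllcorner {xllcorner:.10g}\n")
        fh.write(f"yllcorner {yllcorner:.10g}\n")
        fh.write(f"cellsize {cellsize:.10g}\n")
        fh.write(f"NODATA_value {nodata:.10g}\n")
        for row in v[::-1]:
            fh.write(" ".join(f"{x:.10g}" for x in row) + "\n")


def read_habitat(path: str | Path, buffer_width: float = 0.0) -> SpatialDomain:
    """Read a 0/1 habitat mask ASCII grid into a SpatialDomain."""
    values, header = read_ascii_grid(path)
    cell = header["cellsize"]
    x_min, y_min = header["xllcorner"], header["yllcorner"]
    ny, nx = values.shape
    hab = values > 0.5
    return SpatialDomain(
        bounds=(x_min, x_min + nx * cell, y_min, y_min + ny * cell),
        habitat=hab,
        cell_size=cell,
        buffer_width=buffer_width,
    )


def write_habitat(domain: SpatialDomain, path: str | Path) -> None:
    write_ascii_grid(
        domain.habitat.astype(float),
        domain.x_min, domain.y_min, domain.cell_size, path,
    )


# --------------------------------------------------------------------- #
# truth / index JSON
def write_truth(truth: PopulationTruth, path: str | Path, seed: int | None = None) -> None:
    payload = dict(
        seed=seed,
        N=truth.n,
        sigma=truth.sigma,
        p0=truth.p0,
        ac_locations=truth.ac_locations.tolist(),
    )
    Path(path).write_text(json.dumps(payload, indent=2))


def read_truth(path: str | Path) -> PopulationTruth:
    payload = json.loads(Path(path).read_text())
    return PopulationTruth(
        ac_locations=np.array(payload["ac_locations"], dtype=float),
        sigma=payload["sigma"],
        p0=payload["p0"],
    )


def export_less_index(less: LESSIndex, path: str | Path) -> None:
    """Dump the per-individual LESS geometry as JSON for inspection."""
    payload = dict(
        n_detected=less.n_detected,
        n_augmented=less.n_augmented,
        xy_bounds=less.xy_bounds.tolist(),
        n_detectors=less.n_detectors.tolist(),
        detector_index=[
            less.detectors_of(i).tolist() for i in range(less.n_individuals)
        ],
        prop_habitat=less.prop_habitat.tolist(),
    )
    Path(path).write_text(json.dumps(payload))
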