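"""Local-evaluation geometry for spatial capture-recapture.

Local evaluation of the individual state-space (LESS) restricts, for each
individual, (a) the area in which its latent activity center (AC) may lie
(the *AC evaluation window*) and (b) the set of detectors that enter its
detection likelihood (the *detector evaluation window*).  Detected
individuals receive square windows centered on the centroid of their
detections; augmented (all-zero) individuals receive windows tiled
edge-to-edge across the spatial domain, optionally in several superimposed
layers, so augmented ACs keep a constant density over the domain.

All geometry is in continuous Cartesian distance units (du).  Windows use
half-open membership ``lo <= v < hi`` so that juxtaposed tiles partition the
domain exactly and a width-``w`` window on a unit lattice holds at most
``ceil(w)`` points per axis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - annotation only
    from .simulate import CaptureHistory

__all__ = [
    "Window",
    "DetectorArray",
    "SpatialDomain",
    "AugmentationTiling",
    "LESSIndex",
    "detection_centroid",
    "build_ac_window",
    "build_detector_window",
    "index_detectors_in_window",
    "tile_augmentation_windows",
    "prop_habitat",
    "default_n_layers",
    "build_less_index",
]


@dataclass(frozen=True)
class Window:
    """Axis-aligned rectangle with half-open membership.

    AC and detector windows are square; tiles truncated at the domain
    boundary may be rectangular.
    """

    x_lo: float
    x_hi: float
    y_lo: float
    y_hi: float
    #: Nominal (untruncated) window width; set on boundary-truncated tiles so
    #: the habitat-proportion denominator stays the full window area.
    nominal_width: float | None = None

    def __post_init__(self) -> None:
        if not (self.x_hi > self.x_lo and self.y_hi > self.y_lo):
            raise ValueError("window must have positive extent on both axes")

    @property
    def width(self) -> float:
        return self.x_hi - self.x_lo

    @property
    def height(self) -> float:
        return self.y_hi - self.y_lo

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return (self.x_lo, self.x_hi, self.y_lo, self.y_hi)

    def contains(self, x: float, y: float) -> bool:
        return (self.x_lo <= x < self.x_hi) and (self.y_lo <= y < self.y_hi)


@dataclass(frozen=True)
class DetectorArray:
    """A set of detector locations (camera, hair snare, searched cell ...).

    Parameters
    ----------
    coordinates
        ``(J, 2)`` array of detector center coordinates in du.
    spacing
        Lattice spacing for regular grids, in du; ``None`` for irregular
        arrays.
    ids
        Optional external detector identifiers (defaults to ``0..J-1``).
    """

    coordinates: np.ndarray
    spacing: float | None = None
    ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2 or coords.shape[0] < 1:
            raise ValueError("coordinates must be a (J, 2) array with J >= 1")
        if len(np.unique(coords, axis=0)) != len(coords):
            raise ValueError("detector coordinates must be distinct")
        object.__setattr__(self, "coordinates", coords)
        ids = self.ids
        if ids is None:
            ids = np.arange(len(coords))
        object.__setattr__(self, "ids", np.asarray(ids))

    @property
    def count(self) -> int:
        return self.coordinates.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.coordinates[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.coordinates[:, 1]

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        return (
            float(self.x.min()),
            float(self.x.max()),
            float(self.y.min()),
            float(self.y.max()),
        )

    @classmethod
    def grid(
        cls, nx: int, ny: int, spacing: float = 1.0, origin: tuple[float, float] = (0.0, 0.0)
    ) -> "DetectorArray":
        """Regular ``nx x ny`` lattice of detectors, ``spacing`` du apart."""
        xs = origin[0] + spacing * np.arange(nx)
        ys = origin[1] + spacing * np.arange(ny)
        gx, gy = np.meshgrid(xs, ys, indexing="xy")
        coords = np.column_stack([gx.ravel(), gy.ravel()])
        return cls(coords, spacing=spacing)


@dataclass(frozen=True)
class SpatialDomain:
    """The SCR state-space S: a habitat raster plus buffer.

    The raster is a grid of square cells of side ``cell_size`` tiling
    ``bounds`` exactly; ``habitat[iy, ix]`` is True where the cell is
    suitable.  Row 0 is the southernmost row (y increasing with row index).
    ``buffer_mask`` flags cells belonging to the buffer strip around the
    detector array; these stay part of S but are excluded from density-map
    comparisons.
    """

    bounds: tuple[float, float, float, float]  # x_min, x_max, y_min, y_max
    habitat: np.ndarray
    cell_size: float = 1.0
    buffer_width: float = 0.0
    buffer_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        hab = np.asarray(self.habitat, dtype=bool)
        x_min, x_max, y_min, y_max = self.bounds
        ny, nx = hab.shape
        if not (
            math.isclose(x_min + nx * self.cell_size, x_max, rel_tol=0, abs_tol=1e-9)
            and math.isclose(y_min + ny * self.cell_size, y_max, rel_tol=0, abs_tol=1e-9)
        ):
            raise ValueError("habitat raster must tile the domain bounds exactly")
        object.__setattr__(self, "habitat", hab)
        if self.buffer_mask is not None:
            bm = np.asarray(self.buffer_mask, dtype=bool)
            if bm.shape != hab.shape:
                raise ValueError("buffer_mask shape must match habitat raster")
            object.__setattr__(self, "buffer_mask", bm)

    @property
    def nx(self) -> int:
        return self.habitat.shape[1]

    @property
    def ny(self) -> int:
        return self.habitat.shape[0]

    @property
    def x_min(self) -> float:
        return self.bounds[0]

    @property
    def y_min(self) -> float:
        return self.bounds[2]

    @property
    def extent(self) -> tuple[float, float]:
        return (self.bounds[1] - self.bounds[0], self.bounds[3] - self.bounds[2])

    @property
    def area(self) -> float:
        """Area of S = number of suitable cells x cell_size^2 (du^2)."""
        return float(self.habitat.sum()) * self.cell_size**2

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        cx = self.x_min + (np.arange(self.nx) + 0.5) * self.cell_size
        cy = self.y_min + (np.arange(self.ny) + 0.5) * self.cell_size
        return cx, cy

    def suitable_at(self, x: float, y: float) -> bool:
        """Habitat suitability at a point; outside the bounds is unsuitable."""
        ix = int(math.floor((x - self.x_min) / self.cell_size))
        iy = int(math.floor((y - self.y_min) / self.cell_size))
        if ix < 0 or iy < 0 or ix >= self.nx or iy >= self.ny:
            return False
        return bool(self.habitat[iy, ix])

    @classmethod
    def around_detectors(
        cls,
        detectors: DetectorArray,
        buffer_width: float,
        cell_size: float = 1.0,
        habitat: np.ndarray | None = None,
    ) -> "SpatialDomain":
        """Domain = detector bounding box + buffer, cell-aligned on detectors.

        Bounds extend ``buffer_width + cell_size/2`` beyond the detector
        bounding box so that habitat cells are centered on the detector
        lattice (a 50x50 unit-spaced array with a 4-du buffer yields a
        58x58-du domain of 58x58 cells, of which the central 50x50 block is
        non-buffer).
        """
        if buffer_width < 0:
            raise ValueError("buffer_width must be >= 0")
        bx0, bx1, by0, by1 = detectors.bbox
        pad = buffer_width + cell_size / 2.0
        x_min, x_max = bx0 - pad, bx1 + pad
        y_min, y_max = by0 - pad, by1 + pad
        nx = int(round((x_max - x_min) / cell_size))
        ny = int(round((y_max - y_min) / cell_size))
        x_max = x_min + nx * cell_size
        y_max = y_min + ny * cell_size
        if habitat is None:
            habitat = np.ones((ny, nx), dtype=bool)
        cx = x_min + (np.arange(nx) + 0.5) * cell_size
        cy = y_min + (np.arange(ny) + 0.5) * cell_size
        eps = 1e-9
        in_core_x = (cx >= bx0 - eps) & (cx <= bx1 + eps)
        in_core_y = (cy >= by0 - eps) & (cy <= by1 + eps)
        buffer_mask = ~(in_core_y[:, None] & in_core_x[None, :])
        return cls(
            bounds=(x_min, x_max, y_min, y_max),
            habitat=habitat,
            cell_size=cell_size,
            buffer_width=buffer_width,
            buffer_mask=buffer_mask,
        )


@dataclass(frozen=True)
class AugmentationTiling:
    """Juxtaposed AC windows for augmented individuals, in identical layers."""

    tiles_per_layer: int
    n_layers: int
    windows: tuple[Window, ...]

    def __post_init__(self) -> None:
        if len(self.windows) != self.tiles_per_layer * self.n_layers:
            raise ValueError("total windows must equal tiles_per_layer * n_layers")


def detection_centroid(capture_row: np.ndarray, detectors: DetectorArray) -> np.ndarray:
    """Centroid of an individual's detection locations.

    With binary data each detector with a detection counts once; the
    centroid is the arithmetic mean of those detector coordinates.
    """
    row = np.asarray(capture_row)
    hit = np.flatnonzero(row)
    if hit.size == 0:
        raise ValueError("individual has no detections; centroid undefined")
    return detectors.coordinates[hit].mean(axis=0)


def build_ac_window(center: Sequence[float], width: float) -> Window:
    """Square AC evaluation window centered on ``center``.

    The window is *not* clipped to the domain; unusable (non-habitat or
    out-of-domain) area is absorbed by the per-individual habitat
    proportion in the inclusion probability.
    """
    if width <= 0:
        raise ValueError("window width must be > 0")
    cx, cy = float(center[0]), float(center[1])
    h = width / 2.0
    return Window(cx - h, cx + h, cy - h, cy + h)


def build_detector_window(ac_window: Window, extension: float) -> Window:
    """Concentric detector window extending ``extension`` du beyond the AC window."""
    if extension < 0:
        raise ValueError("detector-window extension must be >= 0")
    return Window(
        ac_window.x_lo - extension,
        ac_window.x_hi + extension,
        ac_window.y_lo - extension,
        ac_window.y_hi + extension,
    )


def index_detectors_in_window(window: Window, detectors: DetectorArray) -> np.ndarray:
    """Ascending indices of detectors inside ``window`` (half-open membership)."""
    x, y = detectors.x, detectors.y
    inside = (
        (x >= window.x_lo) & (x < window.x_hi) & (y >= window.y_lo) & (y < window.y_hi)
    )
    return np.flatnonzero(inside)


def tile_augmentation_windows(
    domain: SpatialDomain, width: float, n_layers: int
) -> AugmentationTiling:
    """Tile the domain with juxtaposed AC windows, ``n_layers`` identical copies.

    Tiles are laid edge-to-edge from the domain's lower-left corner; the last
    row/column is truncated at the boundary so each layer exactly partitions
    the bounds under half-open membership.
    """
    if width <= 0:
        raise ValueError("window width must be > 0")
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    x_min, x_max, y_min, y_max = domain.bounds
    if width > (x_max - x_min) or width > (y_max - y_min):
        warnings.warn(
            "tile width exceeds the domain extent; using a single truncated "
            "tile per axis",
            stacklevel=2,
        )
    x_edges = _tile_edges(x_min, x_max, width)
    y_edges = _tile_edges(y_min, y_max, width)
    layer = [
        Window(x0, x1, y0, y1, nominal_width=width)
        for (y0, y1) in zip(y_edges[:-1], y_edges[1:])
        for (x0, x1) in zip(x_edges[:-1], x_edges[1:])
    ]
    windows = tuple(layer) * n_layers
    return AugmentationTiling(
        tiles_per_layer=len(layer), n_layers=n_layers, windows=windows
    )


def _tile_edges(lo: float, hi: float, width: float) -> np.ndarray:
    n = max(1, math.ceil((hi - lo) / width - 1e-12))
    edges = lo + width * np.arange(n + 1)
    edges[-1] = hi
    return edges


def prop_habitat(window: Window, domain: SpatialDomain) -> float:
    """Fraction of a window's nominal area that is suitable habitat.

    The numerator is the exact geometric overlap between the window and the
    suitable cells of the habitat raster; area outside the domain bounds
    counts as non-suitable.  The denominator is the *nominal* window area
    (``nominal_width ** 2`` for boundary-truncated tiles, otherwise the
    window's own unclipped area): a truncated edge tile must keep the full
    window area in the denominator so the inclusion-probability correction
    leaves the density of augmented activity centers constant across the
    domain.
    """
    c = domain.cell_size
    nx, ny = domain.nx, domain.ny
    x_min, y_min = domain.x_min, domain.y_min

    ix_lo = max(0, int(math.floor((window.x_lo - x_min) / c)))
    ix_hi = min(nx - 1, int(math.ceil((window.x_hi - x_min) / c)) - 1)
    iy_lo = max(0, int(math.floor((window.y_lo - y_min) / c)))
    iy_hi = min(ny - 1, int(math.ceil((window.y_hi - y_min) / c)) - 1)
    if ix_lo > ix_hi or iy_lo > iy_hi:
        return 0.0

    ix = np.arange(ix_lo, ix_hi + 1)
    iy = np.arange(iy_lo, iy_hi + 1)
    ox = np.minimum(window.x_hi, x_min + (ix + 1) * c) - np.maximum(
        window.x_lo, x_min + ix * c
    )
    oy = np.minimum(window.y_hi, y_min + (iy + 1) * c) - np.maximum(
        window.y_lo, y_min + iy * c
    )
    ox = np.clip(ox, 0.0, None)
    oy = np.clip(oy, 0.0, None)
    hab = domain.habitat[iy_lo : iy_hi + 1, ix_lo : ix_hi + 1]
    suitable_area = float(np.einsum("y,x,yx->", oy, ox, hab.astype(float)))
    nominal = (
        window.nominal_width**2 if window.nominal_width is not None else window.area
    )
    return min(1.0, suitable_area / nominal)


def default_n_layers(tiles_per_layer: int, expected_n: int, factor: float = 4.0) -> int:
    """Smallest layer count giving strictly more than ``factor * expected_n``
    augmented individuals."""
    if tiles_per_layer < 1 or expected_n < 1:
        raise ValueError("tiles_per_layer and expected_n must be >= 1")
    return int(math.floor(factor * expected_n / tiles_per_layer)) + 1


@dataclass(frozen=True)
class LESSIndex:
    """Per-individual LESS geometry for detected + augmented individuals.

    Ragged per-individual detector lists are stored as a padded integer
    matrix ``detector_index`` (pad value -1) together with per-individual
    counts ``n_detectors``, mirroring the published indexing layout
    (``detector.index`` / ``n.detectors``); ``xy_bounds`` holds each AC
    window as ``(x_lo, x_hi, y_lo, y_hi)``.
    """

    ac_windows: tuple[Window, ...]
    detector_windows: tuple[Window, ...]
    detector_index: np.ndarray  # (M, K) int64, padded with -1
    n_detectors: np.ndarray  # (M,) int64
    xy_bounds: np.ndarray  # (M, 4) float64
    prop_habitat: np.ndarray  # (M,)
    n_detected: int
    n_augmented: int
    tiling: AugmentationTiling | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        m = len(self.ac_windows)
        if not (
            m
            == len(self.detector_windows)
            == self.detector_index.shape[0]
            == self.n_detectors.shape[0]
            == self.xy_bounds.shape[0]
            == self.prop_habitat.shape[0]
            == self.n_detected + self.n_augmented
        ):
            raise ValueError("inconsistent per-individual array lengths")
        if np.any(self.prop_habitat < 0) or np.any(self.prop_habitat > 1 + 1e-12):
            raise ValueError("prop_habitat must lie in [0, 1]")

    @property
    def n_individuals(self) -> int:
        return self.n_detected + self.n_augmented

    @property
    def max_detectors(self) -> int:
        """Largest per-individual detector count (drives the LESS speedup)."""
        return int(self.n_detectors.max()) if len(self.n_detectors) else 0

    def detectors_of(self, i: int) -> np.ndarray:
        return self.detector_index[i, : self.n_detectors[i]]


def build_less_index(
    captures: "CaptureHistory",
    detectors: DetectorArray,
    domain: SpatialDomain,
    ac_width: float,
    extension: float,
    n_layers: int | None = None,
    expected_n: int | None = None,
) -> LESSIndex:
    """Build the full LESS geometry for a capture history.

    Detected individuals get AC/detector windows centered on their detection
    centroid; augmented individuals get tiled windows expanded by the same
    ``extension``.  Validates that every detection falls inside its owner's
    detector window — a violation means the chosen ``ac_width``/``extension``
    cannot represent that individual and is an error, never silently widened.

    Parameters
    ----------
    n_layers
        Number of superimposed augmentation layers.  If ``None``,
        ``expected_n`` must be given and the smallest count yielding more
        than four times ``expected_n`` augmented individuals is used.
    """
    y = np.asarray(captures.y)
    if y.ndim != 2 or y.shape[1] != detectors.count:
        raise ValueError("capture matrix must be n_detected x n_detectors")
    if np.any(y.sum(axis=1) < 1):
        raise ValueError("every detected individual needs at least one detection")

    ac_windows: list[Window] = []
    det_windows: list[Window] = []
    for i in range(y.shape[0]):
        center = detection_centroid(y[i], detectors)
        acw = build_ac_window(center, ac_width)
        ac_windows.append(acw)
        det_windows.append(build_detector_window(acw, extension))

    tiling = None
    if n_layers is None:
        if expected_n is None:
            raise ValueError("provide n_layers or expected_n")
        probe = tile_augmentation_windows(domain, ac_width, 1)
        n_layers = default_n_layers(probe.tiles_per_layer, expected_n)
    tiling = tile_augmentation_windows(domain, ac_width, n_layers)
    for acw in tiling.windows:
        ac_windows.append(acw)
        det_windows.append(build_detector_window(acw, extension))

    m = len(ac_windows)
    index_lists = [index_detectors_in_window(w, detectors) for w in det_windows]
    n_det = np.array([len(ix) for ix in index_lists], dtype=np.int64)
    k = max(1, int(n_det.max()))
    det_index = np.full((m, k), -1, dtype=np.int64)
    for i, ix in enumerate(index_lists):
        det_index[i, : len(ix)] = ix

    # every observed detection must be reachable inside its detector window
    for i in range(y.shape[0]):
        hit = np.flatnonzero(y[i])
        missing = np.setdiff1d(hit, index_lists[i])
        if missing.size:
            raise ValueError(
                f"individual {i} has a detection at detector {int(missing[0])} "
                f"outside its detector window {det_windows[i].bounds}; "
                "increase ac_width and/or extension"
            )

    xy_bounds = np.array([w.bounds for w in ac_windows], dtype=float)
    prop = np.array([prop_habitat(w, domain) for w in ac_windows], dtype=float)
    return LESSIndex(
        ac_windows=tuple(ac_windows),
        detector_windows=tuple(det_windows),
        detector_index=det_index,
        n_detectors=n_det,
        xy_bounds=xy_bounds,
        prop_habitat=prop,
        n_detected=y.shape[0],
        n_augmented=m - y.shape[0],
        tiling=tiling,
    )
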