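"""Spatiotemporal parameter heterogeneity: prepatterns for the kinetics.

Any parameter of a kinetic family (S, C, a, U, ...) may be promoted from a
scalar to a field over the simulation grid, optionally switching in time
as a square wave.  Spatial steps are smoothed with a tanh profile to avoid
discretization artefacts; temporal switching is kept exactly piecewise
constant and handled by restarting the integrator at switch times.
Grayscale images (PNG/PGM) can be segmented by intensity thresholds and
each segment mapped to parameter values, turning an arbitrary picture into
a patterning landscape.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Grid1D",
    "Grid2D",
    "ParamField",
    "SegmentMap",
    "tanh_step",
    "time_square_wave",
    "square_wave_value",
    "schedule_from_square_wave",
    "image_to_segments",
    "segments_to_params",
    "intensity_to_steady_state",
    "make_fixture_image",
    "load_grayscale",
    "SEGMENT_PRESET_SPOT_STRIPE_INVERSE",
    "SEGMENT_PRESET_PRESERVED_CENTRE",
]


# ---------------------------------------------------------------------------
# Grids
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Grid1D:
    """Node-centred 1D grid on [0, L]: x_i = i·h, boundary nodes on 0 and L."""

    nx: int
    Lx: float

    def __post_init__(self) -> None:
        if self.nx < 3:
            raise ValueError("need at least 3 nodes")
        if self.Lx <= 0:
            raise ValueError("domain length must be positive")

    @property
    def hx(self) -> float:
        return self.Lx / (self.nx - 1)

    @property
    def x(self) -> np.ndarray:
        return np.linspace(0.0, self.Lx, self.nx)

    @property
    def shape(self) -> tuple[int, ...]:
        return (self.nx,)

    @property
    def ndim(self) -> int:
        return 1


@dataclass(frozen=True)
class Grid2D:
    """Node-centred rectangular grid on [0, Lx] × [0, Ly].

    Fields are stored with shape (ny, nx): row index varies along y,
    column index along x.  Row 0 corresponds to y = Ly when a field comes
    from an image (image convention: top row first), and to y = 0 for
    analytically constructed fields; :func:`image_to_segments` flips rows
    so both conventions agree on the grid.
    """

    nx: int
    ny: int
    Lx: float
    Ly: float

    def __post_init__(self) -> None:
        if self.nx < 3 or self.ny < 3:
            raise ValueError("need at least 3 nodes per axis")
        if self.Lx <= 0 or self.Ly <= 0:
            raise ValueError("domain extents must be positive")

    @property
    def hx(self) -> float:
        return self.Lx / (self.nx - 1)

    @property
    def hy(self) -> float:
        return self.Ly / (self.ny - 1)

    @property
    def x(self) -> np.ndarray:
        return np.linspace(0.0, self.Lx, self.nx)

    @property
    def y(self) -> np.ndarray:
        return np.linspace(0.0, self.Ly, self.ny)

    @property
    def shape(self) -> tuple[int, ...]:
        return (self.ny, self.nx)

    @property
    def ndim(self) -> int:
        return 2

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.x, self.y, indexing="xy")


# ---------------------------------------------------------------------------
# Parameter fields and time schedules
# ---------------------------------------------------------------------------

@dataclass
class ParamField:
    """A named scalar parameter as a field over the grid.

    ``values`` holds the static (or initial-epoch) field.  ``schedule`` is
    an optional piecewise-constant time program: a list of
    ``(t_switch, values)`` epochs with strictly increasing switch times,
    each epoch active on the right-open interval [t_switch, next switch).
    """

    name: str
    values: np.ndarray
    schedule: list[tuple[float, np.ndarray]] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field values must be finite")
        if self.schedule is not None:
            times = [t for t, _ in self.schedule]
            if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
                raise ValueError("schedule times must be strictly increasing")

    def at(self, t: float) -> np.ndarray:
        """Field active at time t (right-open epoch intervals)."""
        if self.schedule is None:
            return self.values
        current = self.values
        for t_switch, vals in self.schedule:
            if t >= t_switch:
                current = np.asarray(vals, dtype=float)
            else:
                break
        return current

    def switch_times(self, t_end: float) -> list[float]:
        if self.schedule is None:
            return []
        return [t for t, _ in self.schedule if 0.0 < t < t_end]


def tanh_step(grid, axis: str = "x", center: float = 0.0, width: float = 1.0,
              low: float = 0.0, high: float = 1.0, name: str = "") -> ParamField:
    """Smoothed spatial step low → high across ``center`` along an axis.

    value = low + (high − low)·(1 + tanh((coord − center)/width))/2, so the
    midpoint value (low+high)/2 sits exactly at ``center``; width defaults
    to one unit of the coordinate.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    if isinstance(grid, Grid1D):
        coord = grid.x
    elif axis == "x":
        coord = grid.meshgrid()[0]
    elif axis == "y":
        coord = grid.meshgrid()[1]
    else:
        raise ValueError("axis must be 'x' or 'y'")
    vals = low + (high - low) * (1.0 + np.tanh((coord - center) / width)) / 2.0
    return ParamField(name=name or "step", values=vals)


def square_wave_value(period: float, t: float) -> int:
    """The Heaviside square wave H(cos(2πt/period)) ∈ {0, 1}.

    Equals 1 on [0, period/4), 0 on (period/4, 3·period/4), then 1 again:
    the value toggles every period/2 time units, with the first switch at
    period/4.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    return 1 if math.cos(2.0 * math.pi * t / period) >= 0 else 0


def time_square_wave(
    period: float,
    values_high: np.ndarray,
    values_low: np.ndarray,
    t_end: float,
    name: str = "",
) -> ParamField:
    """Square-wave time program: alias of :func:`schedule_from_square_wave`."""
    return schedule_from_square_wave(period, values_high, values_low, t_end, name=name)


def schedule_from_square_wave(
    period: float,
    values_high: np.ndarray,
    values_low: np.ndarray,
    t_end: float,
    name: str = "",
) -> ParamField:
    """Piecewise-constant schedule realizing H(cos(2πt/period)) switching.

    The field equals ``values_high`` while the square wave is 1 and
    ``values_low`` while it is 0, with switches at period/4 + k·period/2
    up to ``t_end``.  With period 6000 the parameter toggles every 3000
    time units.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    vh = np.asarray(values_high, dtype=float)
    vl = np.asarray(values_low, dtype=float)
    epochs: list[tuple[float, np.ndarray]] = []
    t = period / 4.0
    state = 0  # value after the first switch
    while t < t_end:
        epochs.append((t, vl if state == 0 else vh))
        state = 1 - state
        t += period / 2.0
    return ParamField(name=name or "square_wave", values=vh, schedule=epochs or None)


# ---------------------------------------------------------------------------
# Image prepatterns
# ---------------------------------------------------------------------------

@dataclass
class SegmentMap:
    """Integer region labels per grid node plus the thresholds used.

    By convention label 0 is the brightest class (white) and the highest
    label the darkest (black), matching intensity-inverted segmentation.
    """

    labels: np.ndarray
    thresholds: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integers")

    @property
    def n_labels(self) -> int:
        return int(self.labels.max()) + 1

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label


def load_grayscale(path) -> np.ndarray:
    """Read a PNG/PGM image as a 2D float array of intensities."""
    import imageio.v3 as iio

    img = iio.imread(path)
    if img.ndim == 3:
        raise ValueError(
            "multi-channel image: convert to grayscale first "
            "(or pass convert=True to image_to_segments)"
        )
    return np.asarray(img, dtype=float)


def image_to_segments(
    image: np.ndarray,
    n_levels: int,
    thresholds: Sequence[float] | None = None,
    grid: Grid2D | None = None,
    convert: bool = False,
    flip_rows: bool = False,
) -> SegmentMap:
    """Threshold a grayscale image into ``n_levels`` intensity classes.

    Pixels below the first threshold (darkest) get the highest label,
    pixels above the last threshold (brightest) get label 0.  Thresholds
    default to the k-quantiles of the intensity distribution.  With
    ``grid`` given the label map is resampled to the simulation grid by
    nearest neighbour; ``flip_rows`` maps image row 0 (top) to y = Ly.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim == 3:
        if not convert:
            raise ValueError("multi-channel image; pass convert=True to average channels")
        image = image.mean(axis=2)
    if image.ndim != 2:
        raise ValueError("expected a 2D grayscale image")
    if thresholds is None:
        qs = np.linspace(0, 1, n_levels + 1)[1:-1]
        thresholds = tuple(float(np.quantile(image, q)) for q in qs)
    thresholds = tuple(float(t) for t in thresholds)
    if len(thresholds) != n_levels - 1:
        raise ValueError("need n_levels - 1 thresholds")
    if any(t1 >= t2 for t1, t2 in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")

    labels = (n_levels - 1) - np.digitize(image, thresholds).astype(np.int64)
    for lab in range(n_levels):
        if not np.any(labels == lab):
            warnings.warn(f"segment label {lab} is empty for the given thresholds")
    if flip_rows:
        labels = labels[::-1]
    if grid is not None:
        labels = _resample_nearest(labels, grid.shape)
    return SegmentMap(labels=labels, thresholds=thresholds)


def _resample_nearest(arr: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    ny, nx = shape
    rows = np.minimum((np.arange(ny) * arr.shape[0] / ny).astype(int), arr.shape[0] - 1)
    cols = np.minimum((np.arange(nx) * arr.shape[1] / nx).astype(int), arr.shape[1] - 1)
    return arr[np.ix_(rows, cols)]


#: Three-region preset mapping (label 0 = white, 1 = grey, 2 = black):
#: spots in the black region, stripes in the white region, inverted
#: spots/stripes in the grey region (phase-switching family with D = 50).
SEGMENT_PRESET_SPOT_STRIPE_INVERSE: dict[int, dict[str, float]] = {
    0: {"C": 0.0, "a": 1.0},   # white
    1: {"C": 0.4, "a": 6.0},   # grey
    2: {"C": 1.0, "a": 1.0},   # black
}

#: Three-region preset for preserving a detailed prepattern in the centre:
#: Turing-unstable outside (S = 1, spots then labyrinth), stabilised
#: inside (S = −1 with a large cubic C = 20 pinning u near U(x)).
SEGMENT_PRESET_PRESERVED_CENTRE: dict[int, dict[str, float]] = {
    0: {"S": 1.0, "C": 0.0},    # white outer
    1: {"S": 1.0, "C": 2.0},    # grey ring
    2: {"S": -1.0, "C": 20.0},  # dark centre
}


def segments_to_params(
    seg: SegmentMap, mapping: Mapping[int, Mapping[str, float]]
) -> dict[str, ParamField]:
    """Expand a label map into one ParamField per mapped parameter name."""
    present = set(np.unique(seg.labels).tolist())
    missing = present - set(mapping)
    if missing:
        raise ValueError(f"mapping does not cover labels {sorted(missing)}")
    names = sorted({name for vals in mapping.values() for name in vals})
    out: dict[str, ParamField] = {}
    for name in names:
        vals = np.zeros(seg.labels.shape, dtype=float)
        for lab, pv in mapping.items():
            if name not in pv:
                raise ValueError(f"label {lab} is missing a value for parameter {name!r}")
            vals[seg.labels == lab] = pv[name]
        out[name] = ParamField(name=name, values=vals)
    return out


def intensity_to_steady_state(
    image: np.ndarray, low_value: float = 1.0, high_value: float = 11.0,
    grid: Grid2D | None = None, flip_rows: bool = False,
) -> ParamField:
    """Map image intensity inversely and linearly to a steady-state field U.

    The brightest pixel maps to ``low_value`` and black (intensity 0) to
    ``high_value``: U(x) = low + (high − low)·(1 − I/I_max).
    """
    if low_value <= 0 or high_value <= 0:
        raise ValueError("steady-state values must be positive")
    image = np.asarray(image, dtype=float)
    imax = image.max()
    rel = image / imax if imax > 0 else np.ones_like(image)
    vals = low_value + (high_value - low_value) * (1.0 - rel)
    if flip_rows:
        vals = vals[::-1]
    if grid is not None:
        vals = _bilinear_resample(vals, grid.shape)
    return ParamField(name="U", values=vals)


def _bilinear_resample(arr: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    from scipy.ndimage import zoom

    fy = shape[0] / arr.shape[0]
    fx = shape[1] / arr.shape[1]
    out = zoom(arr, (fy, fx), order=1, grid_mode=True, mode="nearest")
    return out[: shape[0], : shape[1]]


# ---------------------------------------------------------------------------
# Synthetic fixture images
# ---------------------------------------------------------------------------

def make_fixture_image(
    shape: tuple[int, int],
    shapes: Sequence[Mapping] = (),
    background: int = 255,
) -> np.ndarray:
    """Deterministic grayscale raster from a shape list (test fixture).

    Each entry of ``shapes`` is a dict with ``kind`` = ``"rect"``
    (keys ``row0, row1, col0, col1``, half-open bounds) or ``"disc"``
    (keys ``center`` = (row, col), ``radius``) plus an ``intensity`` in
    0..255.  Later shapes overwrite earlier ones (draw order resolves
    overlaps).  An empty list yields a uniform background.
    """
    img = np.full(shape, background, dtype=np.uint8)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    for spec in shapes:
        kind = spec.get("kind", "rect")
        val = int(spec["intensity"])
        if kind == "rect":
            img[spec["row0"]: spec["row1"], spec["col0"]: spec["col1"]] = val
        elif kind == "disc":
            r0, c0 = spec["center"]
            mask = (rr - r0) ** 2 + (cc - c0) ** 2 <= spec["radius"] ** 2
            img[mask] = val
        else:
            raise ValueError(f"unknown shape kind {kind!r}")
    return img
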