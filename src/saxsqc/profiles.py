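"""1-D scattering profiles, 2-D detector patterns and the maps between them.

The central objects are :class:`Profile1D` — a 1-D solution-scattering
curve I(q) with optional per-point uncertainties — and :class:`Pattern2D`,
a detector image together with the :class:`Geometry` needed to assign a
scattering-vector magnitude

    q = (4 pi / lambda) * sin(theta / 2),   tan(theta) = r * pixel / L,

to every pixel (lambda: wavelength in angstrom, L: sample-detector
distance, r: distance from the beam center in pixels).  Directional 1-D
cuts are produced by azimuthal averaging restricted to a pie slice, which
is what the beam-center verification consumes.

Profiles round-trip through the conventional 3-column ASCII ``.dat``
format (q, I, sigma; ``#`` comments).  Patterns round-trip through TIFF
plus a YAML geometry sidecar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import (
    DomainError,
    EmptySliceError,
    InvalidGeometryError,
    RangeError,
)

__all__ = [
    "Profile1D",
    "Geometry",
    "Pattern2D",
    "read_dat",
    "write_dat",
    "load_pattern",
    "save_pattern",
    "compute_q_map",
    "compute_azimuth_map",
    "pie_slice_average",
    "water_peak_magnitude",
    "WATER_WINDOW",
]

#: Default q window (angstrom^-1) bracketing the solvent (water) peak.
WATER_WINDOW = (1.8, 2.2)


@dataclass
class Profile1D:
    """A 1-D scattering curve on a strictly ascending q grid.

    Parameters
    ----------
    q : array
        Scattering-vector magnitudes in angstrom^-1, strictly increasing,
        all >= 0 (q = 0 is allowed for near-beam points).
    intensity : array
        Intensities in arbitrary units.  Subtracted curves may carry
        negative values; generators emit non-negative curves.
    sigma : array, optional
        Per-point 1-sigma uncertainties, same units as ``intensity``.
    label : str
        Free-text identifier carried through I/O.
    empty : boolean array, optional
        Marks bins that received no pixels during azimuthal averaging.
        Flagged bins are skipped by downstream comparisons.
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    label: str = ""
    empty: np.ndarray | None = None

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.ndim != 1 or self.q.size == 0:
            raise DomainError("q must be a non-empty 1-D array")
        if np.any(np.diff(self.q) <= 0):
            raise DomainError("q must be strictly increasing")
        if np.any(self.q < 0):
            raise DomainError("q must be non-negative")
        if self.intensity.shape != self.q.shape:
            raise DomainError("intensity and q must have the same length")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise DomainError("sigma and q must have the same length")
            if np.any(self.sigma < 0):
                raise DomainError("sigma must be non-negative")
        if self.empty is not None:
            self.empty = np.asarray(self.empty, dtype=bool)
            if self.empty.shape != self.q.shape:
                raise DomainError("empty flags and q must have the same length")

    def __len__(self):
        return self.q.size

    def restrict(self, qmin: float | None = None, qmax: float | None = None) -> "Profile1D":
        """Return the sub-profile with qmin <= q <= qmax."""
        sel = np.ones(self.q.shape, dtype=bool)
        if qmin is not None:
            sel &= self.q >= qmin
        if qmax is not None:
            sel &= self.q <= qmax
        if not sel.any():
            raise RangeError("restriction leaves no points")
        return Profile1D(
            self.q[sel],
            self.intensity[sel],
            None if self.sigma is None else self.sigma[sel],
            self.label,
            None if self.empty is None else self.empty[sel],
        )

    def scaled(self, factor: float) -> "Profile1D":
        """Return a copy with intensity (and sigma) multiplied by ``factor``."""
        return Profile1D(
            self.q.copy(),
            self.intensity * factor,
            None if self.sigma is None else self.sigma * abs(factor),
            self.label,
            None if self.empty is None else self.empty.copy(),
        )


@dataclass(frozen=True)
class Geometry:
    """Scattering geometry: wavelength (A), sample-detector distance (mm),
    square pixel size (mm) and beam center in fractional 0-based pixel
    coordinates ``(col, row)``."""

    wavelength: float
    distance: float
    pixel_size: float
    center: tuple[float, float]

    def __post_init__(self):
        if self.wavelength <= 0 or self.distance <= 0 or self.pixel_size <= 0:
            raise InvalidGeometryError(
                "wavelength, distance and pixel_size must all be positive"
            )
        object.__setattr__(self, "center", (float(self.center[0]), float(self.center[1])))

    def q_per_pixel(self) -> float:
        """q increment (A^-1) corresponding to one pixel at the beam center."""
        theta = math.atan(self.pixel_size / self.distance)
        return 4.0 * math.pi / self.wavelength * math.sin(theta / 2.0)

    def shifted(self, dcol: float = 0.0, drow: float = 0.0) -> "Geometry":
        return Geometry(
            self.wavelength,
            self.distance,
            self.pixel_size,
            (self.center[0] + dcol, self.center[1] + drow),
        )

    def to_dict(self) -> dict:
        return {
            "wavelength": self.wavelength,
            "distance": self.distance,
            "pixel_size": self.pixel_size,
            "center": [self.center[0], self.center[1]],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Geometry":
        return cls(
            float(d["wavelength"]),
            float(d["distance"]),
            float(d["pixel_size"]),
            (float(d["center"][0]), float(d["center"][1])),
        )


@dataclass
class Pattern2D:
    """A 2-D detector image (counts) with its geometry and an optional
    exclusion mask (True = exclude pixel from all averages)."""

    image: np.ndarray
    geometry: Geometry
    mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2:
            raise DomainError("image must be 2-D")
        if np.any(self.image < 0):
            raise DomainError("image counts must be non-negative")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.image.shape:
                raise DomainError("mask and image shapes must match")

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape


# ---------------------------------------------------------------------------
# 1-D profile I/O (3-column ASCII .dat)

def write_dat(profile: Profile1D, path) -> None:
    """Write a profile as 3-column ASCII (q, I, sigma) to 6 significant digits."""
    path = Path(path)
    sigma = profile.sigma if profile.sigma is not None else np.zeros_like(profile.q)
    with path.open("w") as fh:
        if profile.label:
            fh.write(f"# {profile.label}\n")
        fh.write("# q (1/A)  intensity  sigma\n")
        for qi, ii, si in zip(profile.q, profile.intensity, sigma):
            fh.write(f"{qi:.6e} {ii:.6e} {si:.6e}\n")


def read_dat(path, label: str | None = None) -> Profile1D:
    """Read a 2- or 3-column whitespace-delimited ``.dat`` profile."""
    path = Path(path)
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] < 2:
        raise DomainError(f"{path}: need at least 2 columns (q, I)")
    sigma = data[:, 2] if data.shape[1] >= 3 else None
    if sigma is not None and not np.any(sigma):
        sigma = None
    return Profile1D(data[:, 0], data[:, 1], sigma, label or path.stem)


# ---------------------------------------------------------------------------
# 2-D pattern I/O (TIFF + YAML sidecar)

def save_pattern(pattern: Pattern2D, image_path, geometry_path=None) -> None:
    import tifffile
    import yaml

    image_path = Path(image_path)
    tifffile.imwrite(image_path, pattern.image.astype(np.float32))
    if geometry_path is None:
        geometry_path = image_path.with_suffix(".yaml")
    with Path(geometry_path).open("w") as fh:
        yaml.safe_dump(pattern.geometry.to_dict(), fh)


def load_pattern(image_path, geometry_path=None, mask=None) -> Pattern2D:
    import tifffile
    import yaml

    image_path = Path(image_path)
    if geometry_path is None:
        geometry_path = image_path.with_suffix(".yaml")
    with Path(geometry_path).open() as fh:
        geom = Geometry.from_dict(yaml.safe_load(fh))
    return Pattern2D(tifffile.imread(image_path), geom, mask)


# ---------------------------------------------------------------------------
# Geometry maps

def compute_q_map(geometry: Geometry, shape: tuple[int, int]) -> np.ndarray:
    """Per-pixel q (A^-1) for an image of the given (rows, cols) shape.

    q is evaluated at pixel centers; the beam center is given in fractional
    0-based (col, row) coordinates.
    """
    if not isinstance(geometry, Geometry):
        raise InvalidGeometryError("geometry must be a Geometry instance")
    rows = np.arange(shape[0], dtype=float)[:, None]
    cols = np.arange(shape[1], dtype=float)[None, :]
    cx, cy = geometry.center
    r_mm = np.hypot(cols - cx, rows - cy) * geometry.pixel_size
    theta = np.arctan(r_mm / geometry.distance)
    return 4.0 * np.pi / geometry.wavelength * np.sin(theta / 2.0)


def compute_azimuth_map(geometry: Geometry, shape: tuple[int, int]) -> np.ndarray:
    """Per-pixel azimuth in degrees, in [0, 360).

    0 deg points toward increasing column; 90 deg points toward decreasing
    row ("up" when the image is displayed with row 0 on top), so that the
    angle runs counter-clockwise on screen.
    """
    rows = np.arange(shape[0], dtype=float)[:, None]
    cols = np.arange(shape[1], dtype=float)[None, :]
    cx, cy = geometry.center
    return np.degrees(np.arctan2(cy - rows, cols - cx)) % 360.0


def _bin_edges(q_grid: np.ndarray) -> np.ndarray:
    """Edges at midpoints of the (ascending) bin centers, extrapolated at the ends."""
    mid = 0.5 * (q_grid[1:] + q_grid[:-1])
    first = q_grid[0] - (mid[0] - q_grid[0]) if q_grid.size > 1 else q_grid[0] - 0.5
    last = q_grid[-1] + (q_grid[-1] - mid[-1]) if q_grid.size > 1 else q_grid[-1] + 0.5
    return np.concatenate([[max(first, 0.0)], mid, [last]])


def pie_slice_average(
    pattern: Pattern2D,
    direction: float,
    half_angle: float = 10.0,
    q_grid: np.ndarray | None = None,
) -> Profile1D:
    """Azimuthal average restricted to a pie slice.

    Parameters
    ----------
    direction : float
        Central azimuth of the slice in degrees (see
        :func:`compute_azimuth_map` for the convention).
    half_angle : float
        Angular half-width of the slice in degrees, in (0, 90].
    q_grid : array
        Ascending bin centers (A^-1) for the output profile.

    Returns
    -------
    Profile1D
        Mean intensity per q bin, with ``sigma = std / sqrt(count)`` and
        bins that received no pixels flagged in ``empty`` (intensity 0).
    """
    if not (0 < half_angle <= 90):
        raise DomainError("half_angle must be in (0, 90] degrees")
    q_grid = np.asarray(q_grid, dtype=float)
    if q_grid.ndim != 1 or q_grid.size == 0 or np.any(np.diff(q_grid) <= 0):
        raise DomainError("q_grid must be 1-D and strictly ascending")

    qmap = compute_q_map(pattern.geometry, pattern.shape)
    amap = compute_azimuth_map(pattern.geometry, pattern.shape)
    dang = np.abs((amap - direction + 180.0) % 360.0 - 180.0)
    sel = dang <= half_angle
    if pattern.mask is not None:
        sel &= ~pattern.mask

    edges = _bin_edges(q_grid)
    qsel = qmap[sel]
    isel = pattern.image[sel]
    idx = np.searchsorted(edges, qsel, side="right") - 1
    inside = (idx >= 0) & (idx < q_grid.size)
    idx, isel = idx[inside], isel[inside]

    count = np.bincount(idx, minlength=q_grid.size).astype(float)
    total = np.bincount(idx, weights=isel, minlength=q_grid.size)
    total2 = np.bincount(idx, weights=isel**2, minlength=q_grid.size)

    empty = count == 0
    if empty.all():
        raise EmptySliceError(
            f"slice at {direction} deg contains no pixels in any q bin"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(empty, 0.0, total / np.maximum(count, 1))
        var = np.maximum(total2 / np.maximum(count, 1) - mean**2, 0.0)
        sem = np.where(count > 1, np.sqrt(var / np.maximum(count, 1)), 0.0)
    return Profile1D(q_grid, mean, sem, f"slice@{direction:g}deg", empty)


def water_peak_magnitude(profile: Profile1D, window: tuple[float, float] = WATER_WINDOW) -> float:
    """Maximum intensity within the water-peak window (default 1.8-2.2 A^-1).

    The windowed maximum is used as the peak "magnitude": it is robust to
    the baseline and needs no peak model.  Raises :class:`RangeError` when
    the profile does not cover the window.
    """
    lo, hi = window
    if lo >= hi:
        raise DomainError("window must be (low, high) with low < high")
    if profile.q[0] > lo or profile.q[-1] < hi:
        raise RangeError(
            f"profile q range [{profile.q[0]:g}, {profile.q[-1]:g}] does not "
            f"cover the water window [{lo:g}, {hi:g}]"
        )
    sel = (profile.q >= lo) & (profile.q <= hi)
    if profile.empty is not None:
        sel &= ~profile.empty
    if not sel.any():
        raise RangeError("no usable points inside the water window")
    return float(profile.intensity[sel].max())
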