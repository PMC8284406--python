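"""Synthetic solution-scattering data with planted ground truth.

Everything the quality-control and logistics modules consume can be
generated here deterministically from a seed: 1-D sample/buffer profile
pairs with a known buffer-mixing factor, 2-D isotropic detector
patterns with a known beam center, and plate/measurement spreadsheets
with (optionally) planted rule violations.  The generators are pure
functions of their parameters and seed, so every planted truth can be
recovered by the corresponding analysis module in tests.

The protein model is a homogeneous sphere of radius R, whose form
factor

    P(x) = [3 (sin x - x cos x) / x^3]^2,   x = qR,

has a closed form and known zeros (first at qR ~ 4.493) — realism is
not required to exercise the algorithms.  The buffer model is a flat
baseline, a weak low-q power law (empty-cell scattering) and a Gaussian
water peak at q = 2 A^-1.  Noise is Poisson on counts
(= intensity x counts-per-intensity), rescaled back to intensity units,
so sigma = sqrt(counts) / counts-per-intensity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import DomainError, GridMismatchError
from .logistics import (
    MeasurementRow,
    MeasurementSheet,
    PlateRow,
    PlateSheet,
    POSITIONS_PER_ROW,
    PLATE_ROWS,
)
from .profiles import Geometry, Pattern2D, Profile1D, compute_q_map

__all__ = [
    "SynthParams",
    "sphere_form_factor",
    "default_q_grid_1d",
    "default_geometry",
    "buffer_intensity",
    "protein_intensity",
    "make_buffer_profile",
    "make_sample_profile",
    "make_profile_pair",
    "make_pattern2d",
    "make_sheets",
    "PLANTABLE_RULES",
]


@dataclass(frozen=True)
class SynthParams:
    """Ground-truth parameters of the synthetic scattering model.

    Attributes
    ----------
    radius : float
        Sphere radius R in angstrom (default 20, roughly a small
        globular protein).
    i0 : float
        Forward protein intensity I(0), in the same arbitrary units as
        the buffer baseline (default 5: a concentrated sample).
    buffer_level : float
        Flat buffer/solvent baseline (default 1.0; the intensity unit).
    powerlaw_amp, powerlaw_slope : float
        Weak low-q empty-cell term ``amp * q**(-slope)``.
    water_amp, water_center, water_width : float
        Gaussian water peak: amplitude above baseline, center (2.0
        A^-1) and sigma width in A^-1.
    planted_factor : float
        True buffer fraction c mixed into the sample (default 0.995,
        the working value of the manual procedure).
    counts_per_intensity : float
        Poisson counts corresponding to unit intensity for 1-D profiles
        (default 1e8, i.e. ~0.01% relative noise at the baseline —
        azimuthally averaged synchrotron data are this quiet).
    counts_per_pixel : float
        Poisson counts per unit intensity per *pixel* for 2-D patterns
        (default 1e4: moderate single-pixel noise).
    """

    radius: float = 20.0
    i0: float = 5.0
    buffer_level: float = 1.0
    powerlaw_amp: float = 0.002
    powerlaw_slope: float = 1.0
    water_amp: float = 1.0
    water_center: float = 2.0
    water_width: float = 0.1
    planted_factor: float = 0.995
    counts_per_intensity: float = 1e8
    counts_per_pixel: float = 1e4

    def __post_init__(self):
        for name in ("radius", "i0", "buffer_level", "water_amp", "water_width",
                     "counts_per_intensity", "counts_per_pixel"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")


def sphere_form_factor(x) -> np.ndarray:
    """Normalized sphere form factor P(x) with P(0) = 1."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    nz = np.abs(x) > 1e-6
    xs = x[nz]
    out[nz] = (3.0 * (np.sin(xs) - xs * np.cos(xs)) / xs**3) ** 2
    return out


def default_q_grid_1d(qmin: float = 0.01, qmax: float = 3.2, dq: float = 0.005) -> np.ndarray:
    """Uniform q grid covering the Guinier region through the water peak."""
    return np.arange(qmin, qmax + dq / 2, dq)


def default_geometry(shape: tuple[int, int] = (320, 320)) -> Geometry:
    """A plausible SAXS geometry: 1 A beam, 3 m camera, 0.172 mm pixels,
    beam centered on the image."""
    return Geometry(1.0, 3000.0, 0.172, ((shape[1] - 1) / 2.0, (shape[0] - 1) / 2.0))


def buffer_intensity(q, params: SynthParams) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    with np.errstate(divide="ignore"):
        power = np.where(q > 0, params.powerlaw_amp * q ** (-params.powerlaw_slope), 0.0)
    peak = params.water_amp * np.exp(
        -((q - params.water_center) ** 2) / (2.0 * params.water_width**2)
    )
    return params.buffer_level + power + peak


def protein_intensity(q, params: SynthParams) -> np.ndarray:
    return params.i0 * sphere_form_factor(np.asarray(q, dtype=float) * params.radius)


def _poissonize(intensity: np.ndarray, cpi: float, rng: np.random.Generator):
    counts = rng.poisson(np.maximum(intensity, 0.0) * cpi)
    return counts / cpi, np.sqrt(counts) / cpi


def _as_rng(rng) -> np.random.Generator:
    return rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)


def make_buffer_profile(
    params: SynthParams,
    q_grid: np.ndarray | None = None,
    rng=None,
    noise: bool = True,
) -> Profile1D:
    """Buffer profile: baseline + weak power law + water peak (+ noise).

    Deterministic given (params, seed); ``noise=False`` returns the
    noiseless model with no uncertainties.
    """
    q = default_q_grid_1d() if q_grid is None else np.asarray(q_grid, dtype=float)
    if np.any(q <= 0):
        raise DomainError("q grid must be strictly positive")
    model = buffer_intensity(q, params)
    if not noise:
        return Profile1D(q, model, None, "buffer(model)")
    intensity, sigma = _poissonize(model, params.counts_per_intensity, _as_rng(rng))
    return Profile1D(q, intensity, sigma, "buffer")


def make_sample_profile(
    params: SynthParams,
    buffer: Profile1D,
    rng=None,
    noise: bool = True,
) -> Profile1D:
    """Sample profile I = i0 * P_sphere(qR) + c * I_buffer (+ noise),
    with the planted buffer fraction c = ``params.planted_factor``."""
    model = protein_intensity(buffer.q, params) + params.planted_factor * buffer.intensity
    if not noise:
        return Profile1D(buffer.q.copy(), model, None, "sample(model)")
    intensity, sigma = _poissonize(model, params.counts_per_intensity, _as_rng(rng))
    return Profile1D(buffer.q.copy(), intensity, sigma, "sample")


def make_profile_pair(
    params: SynthParams,
    q_grid: np.ndarray | None = None,
    rng=None,
    noise: bool = True,
) -> tuple[Profile1D, Profile1D, dict]:
    """Independent sample and buffer measurements of the same system.

    The sample is built from the *noiseless* buffer model (so its
    planted factor is exact) and the measured buffer carries its own
    independent noise.  Returns ``(sample, buffer, truth)`` with
    ``truth = {"planted_factor": c}``.
    """
    rng = _as_rng(rng)
    model_buffer = make_buffer_profile(params, q_grid, noise=False)
    sample = make_sample_profile(params, model_buffer, rng, noise=noise)
    buffer = make_buffer_profile(params, q_grid, rng, noise=noise)
    return sample, buffer, {"planted_factor": params.planted_factor}


def make_pattern2d(
    model,
    geometry: Geometry | None = None,
    shape: tuple[int, int] = (320, 320),
    center_offset: tuple[float, float] = (0.0, 0.0),
    counts_per_pixel: float | None = None,
    params: SynthParams | None = None,
    rng=None,
    noise: bool = True,
) -> Pattern2D:
    """Isotropic 2-D pattern with a known (possibly offset) beam center.

    ``model`` maps q -> intensity: a callable, a :class:`Profile1D`
    (interpolated), or None to use the default sample model from
    ``params``.  The image is synthesized about the *true* center =
    nominal center + ``center_offset`` (pixels, (dcol, drow)), while the
    returned pattern carries the nominal geometry — exactly the
    situation the beam-center verification faces.  Truth is recorded in
    ``pattern.meta``.
    """
    params = params or SynthParams()
    geometry = geometry or default_geometry(shape)
    cpp = params.counts_per_pixel if counts_per_pixel is None else counts_per_pixel

    dcol, drow = center_offset
    true_center = (geometry.center[0] + dcol, geometry.center[1] + drow)
    if not (0 <= true_center[0] <= shape[1] - 1 and 0 <= true_center[1] <= shape[0] - 1):
        raise DomainError("center offset pushes the true beam center off the image")

    if model is None:
        func = lambda q: protein_intensity(q, params) + params.planted_factor * buffer_intensity(q, params)  # noqa: E731
    elif isinstance(model, Profile1D):
        func = lambda q: np.interp(q, model.q, model.intensity)  # noqa: E731
    elif callable(model):
        func = model
    else:
        raise DomainError("model must be callable, a Profile1D, or None")

    qmap = compute_q_map(geometry.shifted(dcol, drow), shape)
    image = np.asarray(func(qmap), dtype=float)
    if np.any(image < 0):
        raise DomainError("model produced negative intensities")
    if noise:
        image = _as_rng(rng).poisson(image * cpp).astype(float)
    else:
        image = image * cpp
    pat = Pattern2D(image, geometry)
    pat.meta.update(true_center=true_center, center_offset=(dcol, drow),
                    counts_per_pixel=cpp, noise=noise)
    return pat


# ---------------------------------------------------------------------------
# spreadsheet fixtures

#: Rule ids accepted by make_sheets and the sheet each is planted in.
PLANTABLE_RULES = {
    "well_rule": "plate",
    "dangling_mix_source": "plate",
    "dup_name": "measurement",
    "buffer_every_5": "measurement",
    "holder_name_len": "measurement",
    "missing_buffer": "measurement",
    "name_rule": "measurement",
    "dup_position": "measurement",
}


def _clean_sheets(n_wells: int, proposal: str, saf: str, plate_id: str):
    """Clean plate + measurement sheets with n_wells occupied measured
    wells (columns 1-9, top-down), buffers interleaved so that every
    sample resolves and no buffer serves more than five samples:
    each 9-well row is [buffer, 5 samples, buffer, 2 samples]."""
    if not (2 <= n_wells <= 8 * POSITIONS_PER_ROW):
        raise DomainError("n_samples must be between 2 and 72 occupied wells")
    prows: list[PlateRow] = []
    mrows: list[MeasurementRow] = []
    holder_names: list[str] = []
    for i in range(n_wells):
        k, col0 = divmod(i, POSITIONS_PER_ROW)
        col = col0 + 1
        well = f"{PLATE_ROWS[k]}{col}"
        holder_idx = k // 2
        holder = f"M{holder_idx + 1}"
        if holder not in holder_names:
            holder_names.append(holder)
        position = (k % 2) * POSITIONS_PER_ROW + col
        is_buffer = col in (1, 7)
        name = f"{'buf' if is_buffer else 's'}_{PLATE_ROWS[k]}{col}"
        ref = None if is_buffer else f"buf_{PLATE_ROWS[k]}{1 if col <= 6 else 7}"
        prows.append(PlateRow(well, name, 50.0, buffer_ref=ref))
        mrows.append(MeasurementRow(
            holder, position, name,
            role="buffer" if is_buffer else "sample",
            buffer_ref=ref, volume_ul=50.0,
            plate_origin=f"{plate_id}:{well}",
        ))
    # a lone trailing buffer reference (row shorter than 2 wells) cannot
    # happen: col 1 is always a buffer and col 2+ reference it
    plate = PlateSheet(prows, proposal, saf, plate_id)
    meas = MeasurementSheet(mrows, proposal, saf)
    return plate, meas


def make_sheets(
    n_samples: int,
    planted_errors=(),
    seed: int = 0,
    proposal: str = "301111",
    saf: str = "312222",
    plate_id: str = "01",
) -> tuple[PlateSheet, MeasurementSheet]:
    """Plate + measurement sheet fixtures with optional planted errors.

    ``n_samples`` counts occupied measured wells (samples plus their
    interleaved buffers): 72 fills the plate (8 rows of 9), which maps
    to 4 holders.  Clean sheets validate with zero errors; each rule id
    in ``planted_errors`` (see :data:`PLANTABLE_RULES`) introduces
    exactly the corresponding validation error in the sheet it applies
    to.  Unknown ids raise :class:`DomainError`.  ``seed`` is accepted
    for interface uniformity; sheet construction is deterministic.
    """
    del seed  # deterministic construction; kept for a uniform interface
    for rule in planted_errors:
        if rule not in PLANTABLE_RULES:
            raise DomainError(f"unknown plantable rule id {rule!r}")
    plate, meas = _clean_sheets(n_samples, proposal, saf, plate_id)

    for rule in planted_errors:
        if rule == "well_rule":
            # move the first sample well into column 10
            for r in plate.rows:
                if r.buffer_ref is not None:
                    r.well = f"{r.well[0]}10"
                    break
        elif rule == "dangling_mix_source":
            for r in plate.rows:
                if r.buffer_ref is not None:
                    r.mixing_sources = [("H12", 10.0)]
                    break
        elif rule == "dup_name":
            srows = [r for r in meas.rows if r.role == "sample"]
            if len(srows) < 2:
                raise DomainError("dup_name needs at least two samples")
            srows[1].sample_name = srows[0].sample_name
        elif rule == "buffer_every_5":
            # within the first holder, re-point every sample at its first buffer
            if n_samples < POSITIONS_PER_ROW:
                raise DomainError("buffer_every_5 needs a full 9-well row")
            first_holder = meas.rows[0].holder_name
            first_buf = meas.rows[0].sample_name
            for r in meas.rows:
                if r.holder_name == first_holder and r.role == "sample":
                    r.buffer_ref = first_buf
        elif rule == "holder_name_len":
            target = meas.rows[0].holder_name
            for r in meas.rows:
                if r.holder_name == target:
                    r.holder_name = "ABCDE"
        elif rule == "missing_buffer":
            srows = [r for r in meas.rows if r.role == "sample"]
            srows[-1].buffer_ref = "no_such_buffer"
        elif rule == "name_rule":
            srows = [r for r in meas.rows if r.role == "sample"]
            srows[-1].sample_name = "bad name!"
        elif rule == "dup_position":
            if len(meas.rows) < 3:
                raise DomainError("dup_position needs at least three rows")
            meas.rows[2].position = meas.rows[1].position
    return plate, meas
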