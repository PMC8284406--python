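"""Buffer subtraction: water-peak matching and the automated scaling factor.

Solvent (buffer) scattering is removed from a sample measurement as

    I_sub(q) = I_sample(q) - f * I_buffer(q).

The buffer is first brought onto the sample's intensity scale by
matching the magnitude of the water peak near q = 2 A^-1, an internal
intensity standard present in both curves.  Because the protein also
scatters under the water peak, the matched buffer must then be scaled
*down* slightly (f just below 1, typically ~0.995) to avoid
over-subtraction artifacts.

The automated estimator walks f upward from 0.9 and stops when a
subtraction first looks over-subtracted, judged by two empirical
criteria:

1. the subtracted intensity must be non-negative, and q*I_sub must not
   develop a minimum under the water peak (the weighting by q removes
   the gentle high-q fall-off of the atomic scattering factors);
2. the dynamic range of the subtracted data beyond q = 0.3 A^-1 —
   log10 span between the highest and lowest positive intensities,
   where no structural features can exist — must not grow by more than
   a threshold as a consequence of adjusting f.

On a violation the search backs off to the last acceptable factor and
refines with a 10x smaller step, until the step falls below the desired
precision (default 0.0001).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    DegenerateBufferError,
    DomainError,
    GridMismatchError,
    StartInfeasibleError,
)
from .profiles import WATER_WINDOW, Profile1D, water_peak_magnitude

__all__ = [
    "ScalingOptions",
    "ScalingResult",
    "match_water_peak",
    "subtract",
    "log_span",
    "criterion_violations",
    "estimate_scaling_factor",
    "auto_subtract",
]


@dataclass(frozen=True)
class ScalingOptions:
    """Configuration of the scaling-factor search.

    Attributes
    ----------
    start : float
        Initial scaling factor the search grows from (default 0.9).
    initial_step : float
        First step size (default 0.01); refined by factors of 10.
    precision : float
        Terminal step size, i.e. the resolution of the returned factor
        (default 0.0001).
    max_factor : float
        Hard cap; a water-peak-matched buffer should never be scaled up,
        so the default is 1.0.  Cap termination is reported, not silent.
    q_floor : float
        Criterion 2 is evaluated only for q > q_floor (default 0.3
        A^-1), where the scattering carries no structural features.
    span_threshold : float
        Maximum allowed growth of the log10 dynamic range per accepted
        adjustment, in decades (default 0.05).
    water_window : (float, float)
        q window bracketing the water peak (default 1.8-2.2 A^-1).
    dip_bins : int
        Number of coarse bins the water window is rebinned into for the
        minimum search (default 9; at least 3).
    dip_nsigma : float
        Significance (in propagated sigma of the coarse bins) a dip must
        reach below both window edges to count as a minimum (default
        2.0; inert for noiseless data without uncertainties).
    """

    start: float = 0.9
    initial_step: float = 0.01
    precision: float = 0.0001
    max_factor: float = 1.0
    q_floor: float = 0.3
    span_threshold: float = 0.05
    water_window: tuple[float, float] = WATER_WINDOW
    dip_bins: int = 9
    dip_nsigma: float = 2.0

    def __post_init__(self):
        if not (0 < self.start < self.max_factor <= 1.5):
            raise DomainError("require 0 < start < max_factor <= 1.5")
        if not (0 < self.precision < self.initial_step):
            raise DomainError("require 0 < precision < initial_step")
        if self.dip_bins < 3:
            raise DomainError("dip_bins must be >= 3")


@dataclass
class ScalingResult:
    """Result of the automated scaling-factor search.

    ``trace`` lists every probed factor with its criterion flags, in
    probe order; ``terminated_by`` is ``criterion_1``, ``criterion_2``
    or ``max_factor_cap``.
    """

    factor: float
    trace: list[tuple[float, bool, bool]] = field(default_factory=list)
    terminated_by: str = ""

    def to_dict(self) -> dict:
        return {
            "factor": self.factor,
            "terminated_by": self.terminated_by,
            "trace": [
                {"factor": f, "criterion_1": c1, "criterion_2": c2}
                for f, c1, c2 in self.trace
            ],
        }


def _check_common_grid(a: Profile1D, b: Profile1D) -> None:
    if a.q.shape != b.q.shape or not np.allclose(a.q, b.q, rtol=1e-9, atol=1e-12):
        raise GridMismatchError("profiles must share an identical q grid")


def match_water_peak(
    sample: Profile1D,
    buffer: Profile1D,
    window: tuple[float, float] = WATER_WINDOW,
) -> tuple[Profile1D, float]:
    """Scale the buffer so its water-peak magnitude equals the sample's.

    Returns ``(scaled_buffer, prefactor)`` with
    ``prefactor = peak(sample) / peak(buffer)``.
    """
    # window coverage is the more informative failure: check it first
    peak_s = water_peak_magnitude(sample, window)
    peak_b = water_peak_magnitude(buffer, window)
    _check_common_grid(sample, buffer)
    if peak_b <= 0:
        raise DegenerateBufferError("buffer water-peak magnitude must be positive")
    prefactor = peak_s / peak_b
    return buffer.scaled(prefactor), prefactor


def subtract(sample: Profile1D, buffer: Profile1D, factor: float) -> Profile1D:
    """I_sub = I_sample - factor * I_buffer, with uncertainties added in
    quadrature (sigma_sub = sqrt(sigma_s^2 + factor^2 sigma_b^2))."""
    _check_common_grid(sample, buffer)
    intensity = sample.intensity - factor * buffer.intensity
    sigma = None
    if sample.sigma is not None or buffer.sigma is not None:
        ss = sample.sigma if sample.sigma is not None else 0.0
        sb = buffer.sigma if buffer.sigma is not None else 0.0
        sigma = np.sqrt(np.square(ss) + factor**2 * np.square(sb))
    label = f"{sample.label} - {factor:g}*{buffer.label}".strip()
    return Profile1D(sample.q.copy(), intensity, sigma, label)


def log_span(profile: Profile1D, q_floor: float = 0.3) -> float:
    """log10 span between the highest and lowest *positive* intensities
    over q > q_floor.  0.0 when the tail is identically zero (a perfect
    subtraction preserves, rather than expands, the dynamic range);
    +inf when negatives exist but no positive value does."""
    sel = profile.q > q_floor
    tail = profile.intensity[sel]
    if tail.size == 0:
        raise DomainError(f"no points beyond q_floor = {q_floor:g}")
    pos = tail[tail > 0]
    if pos.size == 0:
        return 0.0 if np.all(tail == 0) else math.inf
    return float(np.log10(pos.max()) - np.log10(pos.min()))


def _smooth3(y: np.ndarray) -> np.ndarray:
    """3-point moving average with clamped ends."""
    if y.size < 3:
        return y
    out = y.copy()
    out[1:-1] = (y[:-2] + y[1:-1] + y[2:]) / 3.0
    return out


def _water_dip(sub: Profile1D, opts: ScalingOptions) -> bool:
    """True when q * I_sub has a significant interior minimum inside the
    water window — the signature of over-subtracting the water peak.

    The window is rebinned into ``opts.dip_bins`` coarse bins (after a
    3-point smoothing pass); a violation requires an interior bin to
    fall below *both* edge bins by more than ``dip_nsigma`` times the
    propagated bin uncertainty.  For data without uncertainties this
    reduces to a plain interior-minimum test.
    """
    lo, hi = opts.water_window
    sel = (sub.q >= lo) & (sub.q <= hi)
    if sel.sum() < 3:
        return False
    y = _smooth3(sub.q[sel] * sub.intensity[sel])
    if sub.sigma is not None:
        # smoothing correlates neighbours; sigma/sqrt(3) is close enough
        sig = sub.q[sel] * sub.sigma[sel] / np.sqrt(3.0)
    else:
        sig = np.zeros_like(y)

    nbins = min(opts.dip_bins, y.size)
    if nbins < 3:
        return False
    edges = np.linspace(0, y.size, nbins + 1).astype(int)
    means = np.empty(nbins)
    errs = np.empty(nbins)
    for i in range(nbins):
        seg = slice(edges[i], edges[i + 1])
        cnt = edges[i + 1] - edges[i]
        means[i] = y[seg].mean()
        errs[i] = np.sqrt(np.sum(sig[seg] ** 2)) / max(cnt, 1)

    interior = np.argmin(means[1:-1]) + 1
    depth_left = means[0] - means[interior]
    depth_right = means[-1] - means[interior]
    tol_left = opts.dip_nsigma * math.hypot(errs[0], errs[interior])
    tol_right = opts.dip_nsigma * math.hypot(errs[-1], errs[interior])
    return bool(depth_left > tol_left and depth_right > tol_right)


def criterion_violations(
    sub: Profile1D,
    baseline_span: float,
    opts: ScalingOptions | None = None,
) -> tuple[bool, bool]:
    """Evaluate the two over-subtraction criteria on a subtracted profile.

    Parameters
    ----------
    sub : Profile1D
        The subtracted curve on the full q grid.
    baseline_span : float
        Reference log10 dynamic range (decades) over q > q_floor that the
        subtracted curve is compared against; the estimator passes the
        span at the last accepted factor.
    Returns
    -------
    (c1, c2) : (bool, bool)
        c1: any negative intensity, or a significant minimum of q*I_sub
        under the water peak.  c2: the span over q > q_floor exceeds
        ``baseline_span + span_threshold`` (a tail with negatives but no
        positive values counts as a degenerate c2 violation).
    """
    if opts is None:
        opts = ScalingOptions()
    c1 = bool(np.any(sub.intensity < 0)) or _water_dip(sub, opts)
    span = log_span(sub, opts.q_floor)
    c2 = bool(span > baseline_span + opts.span_threshold)
    return c1, c2


def estimate_scaling_factor(
    sample: Profile1D,
    buffer: Profile1D,
    opts: ScalingOptions | None = None,
) -> ScalingResult:
    """Coarse-to-fine search for the buffer scaling factor.

    The buffer is assumed to be water-peak matched already (see
    :func:`match_water_peak`).  Starting from ``opts.start`` the factor
    grows by ``opts.initial_step`` while neither criterion fires; on a
    violation the search resumes from the last accepted factor with a
    10x smaller step, stopping when the step falls below
    ``opts.precision`` or the factor reaches ``opts.max_factor``.  The
    returned factor is always the largest *accepted* (feasible) one, on
    the precision grid.
    """
    if opts is None:
        opts = ScalingOptions()
    _check_common_grid(sample, buffer)

    # integer arithmetic on the precision grid avoids float drift
    unit = opts.precision
    f_units = round(opts.start / unit)
    cap_units = round(opts.max_factor / unit)
    step_units = max(1, round(opts.initial_step / unit))

    sub0 = subtract(sample, buffer, f_units * unit)
    ref_span = log_span(sub0, opts.q_floor)
    c1, c2 = criterion_violations(sub0, ref_span, opts)
    trace: list[tuple[float, bool, bool]] = [(f_units * unit, c1, c2)]
    if c1 or c2:
        raise StartInfeasibleError(
            f"criteria already violated at the start factor {opts.start:g}; "
            "a factor below it signals a pathological sample/buffer pair"
        )

    terminated_by = ""
    while True:
        violated = None
        while f_units + step_units <= cap_units:
            nf = f_units + step_units
            sub = subtract(sample, buffer, nf * unit)
            c1, c2 = criterion_violations(sub, ref_span, opts)
            trace.append((nf * unit, c1, c2))
            if c1 or c2:
                violated = "criterion_1" if c1 else "criterion_2"
                break
            f_units = nf
            ref_span = log_span(sub, opts.q_floor)
        if f_units >= cap_units:
            terminated_by = "max_factor_cap"
            break
        if step_units == 1:
            terminated_by = violated if violated else "max_factor_cap"
            break
        step_units = max(1, step_units // 10)

    return ScalingResult(f_units * unit, trace, terminated_by)


def auto_subtract(
    sample: Profile1D,
    buffer: Profile1D,
    opts: ScalingOptions | None = None,
) -> tuple[Profile1D, ScalingResult, float]:
    """Full pipeline: water-peak match, estimate the factor, subtract.

    Returns ``(subtracted, scaling_result, prefactor)`` where the
    effective buffer scale relative to the *raw* buffer is
    ``prefactor * scaling_result.factor``.
    """
    if opts is None:
        opts = ScalingOptions()
    matched, prefactor = match_water_peak(sample, buffer, opts.water_window)
    result = estimate_scaling_factor(sample, matched, opts)
    sub = subtract(sample, matched, result.factor)
    return sub, result, prefactor
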