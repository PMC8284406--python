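"""The "coin toss" similarity statistic for scattering profiles.

When two noisy measurements of the same curve are compared point by
point, each point is equally likely to be higher in either dataset, so
the sign sequence of their difference behaves like a fair coin-toss
series.  Systematic disagreement shows up as improbably long runs
("patches") of one sign.  The statistic reported here is the length L of
the longest patch together with the exact null probability

    p = P(longest run >= L | n fair tosses),

computed by dynamic programming over (position, current run length) —
no asymptotic approximation, since n is at most a few hundred.

By default runs of *either* symbol count (a patch is a maximal stretch
of consecutive +1 or consecutive -1); the heads-only variant (runs of +1
alone) is available via ``heads_only=True``.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import groupby

import numpy as np

from .exceptions import (
    DegenerateComparisonError,
    DomainError,
    GridMismatchError,
)
from .profiles import Profile1D

__all__ = [
    "ComparisonResult",
    "sign_sequence",
    "patch_histogram",
    "longest_run_pvalue",
    "compare_intensities",
    "compare_profiles",
]


@dataclass
class ComparisonResult:
    """Outcome of a coin-toss comparison of two intensity sequences.

    Attributes
    ----------
    signs : int array over {+1, -1}
        Sign of (I1 - I2) per compared point, exact ties removed.
    n : int
        Number of compared points after tie removal.
    patch_hist : dict[int, int]
        Patch length -> number of patches of that length.
    longest : int
        Length of the longest patch (0 for an empty sequence).
    p_value : float
        Exact null probability of observing a longest patch >= ``longest``
        in ``n`` fair tosses (1.0 when n == 0: nothing to test).
    heads_only : bool
        Whether only runs of +1 were scored.
    """

    signs: np.ndarray
    n: int
    patch_hist: dict[int, int]
    longest: int
    p_value: float
    heads_only: bool = False

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "longest": self.longest,
            "p_value": self.p_value,
            "patch_hist": {str(k): v for k, v in sorted(self.patch_hist.items())},
            "heads_only": self.heads_only,
        }


def sign_sequence(I1, I2) -> np.ndarray:
    """Signs of I1 - I2, elementwise, with exact ties dropped.

    Ties carry no directional information and are rare for floating-point
    data; the returned sequence preserves the original order.
    """
    I1 = np.asarray(I1, dtype=float)
    I2 = np.asarray(I2, dtype=float)
    if I1.shape != I2.shape or I1.ndim != 1:
        raise GridMismatchError("intensity sequences must be 1-D with equal length")
    if I1.size < 1:
        raise DomainError("need at least one point")
    diff = I1 - I2
    signs = np.sign(diff[diff != 0]).astype(np.int8)
    return signs


def patch_histogram(signs) -> tuple[dict[int, int], int]:
    """Decompose a +/-1 sequence into maximal same-sign runs.

    Returns ``(hist, longest)`` where ``hist`` maps patch length to count.
    An empty input yields ``({}, 0)``.
    """
    signs = np.asarray(signs)
    if signs.size == 0:
        return {}, 0
    if not np.isin(signs, (-1, 1)).all():
        raise DomainError("signs must be +1 or -1")
    hist: dict[int, int] = {}
    longest = 0
    for _, grp in groupby(signs.tolist()):
        length = sum(1 for _ in grp)
        hist[length] = hist.get(length, 0) + 1
        longest = max(longest, length)
    return hist, longest


def _count_no_long_run_either(n: int, l: int) -> int:
    """Number of +/-1 sequences of length n whose every run is < l."""
    if l <= 1:
        return 0
    # ways[r] = sequences counted by trailing-run length r (1 <= r <= l-1)
    ways = [0] * l
    ways[1] = 2
    for _ in range(n - 1):
        switch = sum(ways)
        new = [0] * l
        for r in range(1, l - 1):
            new[r + 1] = ways[r]
        new[1] = switch  # the opposite symbol always restarts at run length 1
        ways = new
    return sum(ways)


def _count_no_long_run_heads(n: int, l: int) -> int:
    """Number of +/-1 sequences of length n with every run of +1 < l."""
    if l <= 0:
        return 0
    # ways[r] = sequences counted by trailing +1-run length r (0 <= r <= l-1)
    ways = [0] * l
    ways[0] = 1  # empty sequence
    total = 1
    for _ in range(n):
        new = [0] * l
        new[0] = total  # append -1
        for r in range(l - 1):
            new[r + 1] += ways[r]  # append +1
        ways = new
        total = sum(ways)
    return total


def longest_run_pvalue(n: int, l: int, heads_only: bool = False) -> float:
    """Exact P(longest run >= l) over the 2**n equiprobable +/-1 sequences.

    ``heads_only=True`` scores only runs of +1.  Exact integer counting;
    the result is deterministic and agrees with brute-force enumeration.
    """
    n = int(n)
    l = int(l)
    if n < 1:
        raise DomainError("n must be >= 1")
    if l < 1 or l > n:
        raise DomainError("l must satisfy 1 <= l <= n")
    if heads_only:
        ok = _count_no_long_run_heads(n, l)
    else:
        ok = _count_no_long_run_either(n, l)
    return float(1 - Fraction(ok, 2**n))


def compare_intensities(I1, I2, heads_only: bool = False) -> ComparisonResult:
    """Assemble the full coin-toss comparison for two aligned intensity arrays."""
    signs = sign_sequence(I1, I2)
    n = int(signs.size)
    if n == 0:
        raise DegenerateComparisonError("all points tie exactly; nothing to compare")
    hist, longest = patch_histogram(signs)
    p = longest_run_pvalue(n, longest, heads_only=heads_only)
    return ComparisonResult(signs, n, hist, longest, p, heads_only)


def compare_profiles(
    p1: Profile1D,
    p2: Profile1D,
    q_range: tuple[float | None, float | None] | None = None,
    heads_only: bool = False,
) -> ComparisonResult:
    """Coin-toss comparison of two profiles on a common q grid.

    Both profiles are restricted to ``q_range`` (no interpolation is
    performed — the grids must match exactly after restriction), bins
    flagged empty in either profile are skipped, and the remaining
    intensities are compared.
    """
    if q_range is not None:
        p1 = p1.restrict(*q_range)
        p2 = p2.restrict(*q_range)
    if p1.q.shape != p2.q.shape or not np.allclose(p1.q, p2.q, rtol=1e-9, atol=1e-12):
        raise GridMismatchError("profiles are not on a common q grid after restriction")
    keep = np.ones(p1.q.shape, dtype=bool)
    if p1.empty is not None:
        keep &= ~p1.empty
    if p2.empty is not None:
        keep &= ~p2.empty
    if not keep.any():
        raise DegenerateComparisonError("no usable (non-empty) bins in common")
    return compare_intensities(p1.intensity[keep], p2.intensity[keep], heads_only)
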