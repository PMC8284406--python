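import numpy as np
import pytest

from saxsqc.synthetic import SynthParams, default_q_grid_1d


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def params():
    return SynthParams()


@pytest.fixture
def q_grid():
    return default_q_grid_1d()


def enumerate_longest_run_tail(n: int, heads_only: bool = False) -> np.ndarray:
    """Independent brute-force null: tail[l] = P(longest run >= l) for
    l = 0..n, by walking all 2**n sign sequences."""
    from itertools import product

    counts = np.zeros(n + 2, dtype=np.int64)
    for seq in product((1, -1), repeat=n):
        best = run = 0
        prev = 0
        for s in seq:
            if heads_only:
                run = run + 1 if s == 1 else 0
            else:
                run = run + 1 if s == prev else 1
            prev = s
            best = max(best, run)
        counts[best] += 1
    tail = np.cumsum(counts[::-1])[::-1]
    return tail[: n + 1] / 2.0**n


def grid_search_scaling_oracle(sample, buffer, opts=None) -> float:
    """Brute-force scaling-factor search on the uniform precision grid,
    independent of the coarse-to-fine estimator's control flow."""
    from saxsqc.subtraction import ScalingOptions, criterion_violations, log_span, subtract

    opts = opts or ScalingOptions()
    unit = opts.precision
    f = round(opts.start / unit)
    cap = round(opts.max_factor / unit)
    ref = log_span(subtract(sample, buffer, f * unit), opts.q_floor)
    while f < cap:
        sub = subtract(sample, buffer, (f + 1) * unit)
        c1, c2 = criterion_violations(sub, ref, opts)
        if c1 or c2:
            break
        f += 1
        ref = log_span(sub, opts.q_floor)
    return f * unit
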