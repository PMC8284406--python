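import numpy as np
import pytest

from saxsqc.exceptions import (
    DegenerateBufferError,
    GridMismatchError,
    RangeError,
    StartInfeasibleError,
)
from saxsqc.profiles import Profile1D
from saxsqc.subtraction import (
    ScalingOptions,
    auto_subtract,
    criterion_violations,
    estimate_scaling_factor,
    log_span,
    match_water_peak,
    subtract,
)
from saxsqc.synthetic import SynthParams, make_buffer_profile, make_profile_pair

from conftest import grid_search_scaling_oracle


@pytest.fixture
def model_buffer(params, q_grid):
    return make_buffer_profile(params, q_grid, noise=False)


class TestMatchWaterPeak:
    def test_identity(self, model_buffer):
        scaled, pref = match_water_peak(model_buffer, model_buffer)
        assert pref == pytest.approx(1.0)
        assert np.allclose(scaled.intensity, model_buffer.intensity)

    def test_prescaled_buffer_recovers_factor(self, model_buffer):
        half = model_buffer.scaled(0.5)
        _, pref = match_water_peak(model_buffer, half)
        assert pref == pytest.approx(2.0)

    def test_truncated_buffer_raises(self, model_buffer):
        short = model_buffer.restrict(None, 1.5)
        with pytest.raises(RangeError):
            match_water_peak(model_buffer, short)

    def test_zero_peak_degenerate(self, q_grid):
        sample = Profile1D(q_grid, np.ones_like(q_grid))
        buffer = Profile1D(q_grid, np.zeros_like(q_grid))
        with pytest.raises(DegenerateBufferError):
            match_water_peak(sample, buffer)


class TestSubtract:
    def test_factor_zero_identity(self, model_buffer):
        out = subtract(model_buffer, model_buffer, 0.0)
        assert np.allclose(out.intensity, model_buffer.intensity)

    def test_self_subtraction_is_zero(self, model_buffer):
        out = subtract(model_buffer, model_buffer, 1.0)
        assert np.all(out.intensity == 0.0)

    def test_sigma_quadrature(self):
        q = np.array([0.1, 0.2])
        s = Profile1D(q, [10.0, 10.0], [3.0, 3.0])
        b = Profile1D(q, [1.0, 1.0], [4.0, 4.0])
        out = subtract(s, b, 1.0)
        assert np.allclose(out.sigma, 5.0)

    def test_grid_mismatch(self, model_buffer):
        other = Profile1D(model_buffer.q + 1e-3, model_buffer.intensity)
        with pytest.raises(GridMismatchError):
            subtract(model_buffer, other, 1.0)


class TestCriteria:
    def _flat_sub(self, q_grid):
        # strictly positive, q*I monotone through the window
        return Profile1D(q_grid, 1.0 / (1.0 + q_grid))

    def test_clean_subtraction_passes(self, q_grid):
        sub = self._flat_sub(q_grid)
        c1, c2 = criterion_violations(sub, log_span(sub), ScalingOptions())
        assert (c1, c2) == (False, False)

    def test_negative_intensity_fires_c1(self, q_grid):
        I = np.ones_like(q_grid)
        I[-5] = -0.01
        c1, _ = criterion_violations(Profile1D(q_grid, I), 0.0, ScalingOptions())
        assert c1

    def test_planted_dip_in_qI_fires_c1(self, q_grid):
        # flat q*I == 1 with a dip at 2.0 A^-1
        I = 1.0 / q_grid * (1.0 - 0.3 * np.exp(-((q_grid - 2.0) ** 2) / (2 * 0.05**2)))
        sub = Profile1D(q_grid, I)
        c1, _ = criterion_violations(sub, log_span(sub), ScalingOptions())
        assert c1

    def test_bump_in_qI_does_not_fire_c1(self, q_grid):
        I = 1.0 / q_grid * (1.0 + 0.3 * np.exp(-((q_grid - 2.0) ** 2) / (2 * 0.05**2)))
        sub = Profile1D(q_grid, I)
        c1, _ = criterion_violations(sub, log_span(sub), ScalingOptions())
        assert not c1

    def test_span_growth_fires_c2(self, q_grid):
        base = self._flat_sub(q_grid)
        baseline = log_span(base)
        shrunk = base.intensity.copy()
        shrunk[q_grid > 3.0] /= 10.0  # min positive 10x smaller, max fixed
        _, c2 = criterion_violations(Profile1D(q_grid, shrunk), baseline, ScalingOptions())
        assert c2
        _, c2_loose = criterion_violations(
            Profile1D(q_grid, shrunk), baseline, ScalingOptions(span_threshold=1.5)
        )
        assert not c2_loose


class TestEstimateScalingFactor:
    def test_identity_pair_terminates_at_cap(self, model_buffer):
        res = estimate_scaling_factor(model_buffer, model_buffer)
        assert res.factor == pytest.approx(1.0)
        assert res.terminated_by == "max_factor_cap"

    def test_planted_factor_recovered(self, params, rng):
        sample, buffer, truth = make_profile_pair(params, rng=rng)
        res = estimate_scaling_factor(sample, buffer)
        assert abs(res.factor - truth["planted_factor"]) <= 0.002
        assert 0.99 <= res.factor < 1.0  # the ~0.995 operating regime

    def test_matches_grid_search_oracle(self, rng):
        for c in (0.992, 0.995, 0.998):
            sample, buffer, _ = make_profile_pair(
                SynthParams(planted_factor=c), rng=rng
            )
            res = estimate_scaling_factor(sample, buffer)
            oracle = grid_search_scaling_oracle(sample, buffer)
            assert abs(res.factor - oracle) <= 0.0001 + 1e-12

    def test_factor_on_precision_grid_and_feasible(self, params, rng):
        sample, buffer, _ = make_profile_pair(params, rng=rng)
        res = estimate_scaling_factor(sample, buffer)
        assert round(res.factor / 0.0001) * 0.0001 == pytest.approx(res.factor)
        # the returned factor is the last *accepted* probe, so the probe
        # closest to it in the trace must be non-violating
        nearest = min(res.trace, key=lambda t: abs(t[0] - res.factor))
        assert not (nearest[1] or nearest[2])
        # and it never reaches the violation that terminated the search
        last_f, last_c1, last_c2 = res.trace[-1]
        if last_c1 or last_c2:
            assert res.factor < last_f

    def test_monotone_feasibility_within_stage(self, params, rng):
        sample, buffer, _ = make_profile_pair(params, rng=rng)
        res = estimate_scaling_factor(sample, buffer)
        # within each step-size stage the first violation ends the stage,
        # so violations only appear as the last probe of a stage
        stage = []
        prev_gap = None
        for (f1, c11, c21), (f2, c12, c22) in zip(res.trace, res.trace[1:]):
            gap = round(f2 - f1, 6)
            if prev_gap is not None and gap != prev_gap:
                stage = []
            stage.append((f2, c12 or c22))
            prev_gap = gap
            if len(stage) >= 2:
                assert not stage[-2][1], "violation must terminate its stage"

    def test_start_infeasible_raises(self, q_grid):
        # sample already below the buffer: f = 0.9 over-subtracts
        buffer = Profile1D(q_grid, np.ones_like(q_grid))
        sample = Profile1D(q_grid, 0.5 * np.ones_like(q_grid))
        with pytest.raises(StartInfeasibleError):
            estimate_scaling_factor(sample, buffer)

    def test_trace_and_result_deterministic(self, params):
        sample, buffer, _ = make_profile_pair(params, rng=42)
        r1 = estimate_scaling_factor(sample, buffer)
        r2 = estimate_scaling_factor(sample, buffer)
        assert r1.factor == r2.factor and r1.trace == r2.trace


def test_auto_subtract_pipeline(params, rng):
    sample, buffer, truth = make_profile_pair(params, rng=rng)
    sub, result, prefactor = auto_subtract(sample, buffer)
    # water peaks matched before scaling: prefactor near planted c
    assert prefactor == pytest.approx(truth["planted_factor"], abs=0.01)
    assert np.all(sub.q == sample.q)
    assert result.terminated_by in ("criterion_1", "criterion_2", "max_factor_cap")
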