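import math

import numpy as np
import pytest
from scipy.special import stdtr

from nirsbp.analyze import (
    PLANNED_CONTRASTS,
    coupling_regression,
    one_sample_t,
    planned_comparisons,
    response_metrics,
    two_sample_t,
)
from nirsbp.synthgen import gamma_pulse

# ---------------------------------------------------------------------------
# closed-form oracles (independent of scipy.stats test functions)


def _t_p(t, df):
    return 2.0 * stdtr(df, -abs(t))


def _one_sample_oracle(v):
    n = len(v)
    mean = sum(v) / n
    sd = math.sqrt(sum((x - mean) ** 2 for x in v) / (n - 1))
    t = mean / (sd / math.sqrt(n))
    return t, _t_p(t, n - 1)


def _two_sample_oracle(a, b):
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    sp = math.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    t = (ma - mb) / (sp * math.sqrt(1 / na + 1 / nb))
    return t, _t_p(t, na + nb - 2)


def _regression_oracle(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxx = sum((xi - mx) ** 2 for xi in x)
    syy = sum((yi - my) ** 2 for yi in y)
    sxy = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    slope = sxy / sxx
    intercept = my - slope * mx
    r = sxy / math.sqrt(sxx * syy)
    t = r * math.sqrt((n - 2) / (1 - r * r))
    return slope, intercept, r, _t_p(t, n - 2)


def _metrics4(rng, shift=0.0):
    """Four populated condition cells of per-trial metrics."""
    out = {}
    for cell in ("1500ms_nomove", "3000ms_nomove", "1500ms_move", "3000ms_move"):
        out[cell] = {
            "amplitude": rng.normal(0.3 + shift, 0.1, 15),
            "latency": rng.normal(8.0, 1.0, 15),
        }
    return out


# ---------------------------------------------------------------------------


class TestResponseMetrics:
    def test_gamma_pulse_by_construction(self):
        t = np.arange(-0.5, 12.0, 0.002)
        x = gamma_pulse(t, 6.0, 0.4, 8.0)
        m = response_metrics(x, t, "max")
        assert m.amplitude == pytest.approx(0.4, rel=1e-4)
        assert m.latency_s == pytest.approx(6.0, abs=0.01)

    def test_negated_pulse_with_min_polarity(self):
        t = np.arange(-0.5, 12.0, 0.002)
        x = -gamma_pulse(t, 6.0, 0.4, 8.0)
        m = response_metrics(x, t, "min")
        assert m.amplitude == pytest.approx(-0.4, rel=1e-4)
        assert m.latency_s == pytest.approx(6.0, abs=0.01)
        assert m.polarity == "min"

    def test_auto_picks_larger_extremum(self):
        t = np.arange(-0.5, 12.0, 0.02)
        x = gamma_pulse(t, 4.0, 0.2, 8.0) - gamma_pulse(t, 8.0, 0.5, 8.0)
        m = response_metrics(x, t, "auto")
        assert m.polarity == "min"
        assert m.amplitude < 0

    def test_pulse_plus_ramp_matches_bruteforce_argmax(self, rng):
        t = np.arange(-0.5, 12.0, 0.02)
        x = gamma_pulse(t, 7.0, 0.4, 10.0) + 0.02 * t + rng.normal(0, 0.01, t.size)
        m = response_metrics(x, t, "max")
        # oracle: exhaustive scan over the strictly post-onset samples
        best_v, best_t = -np.inf, None
        for ti, xi in zip(t, x):
            if ti > 0 and xi > best_v:
                best_v, best_t = xi, ti
        assert m.amplitude == best_v
        assert m.latency_s == best_t

    def test_flat_epoch_flagged(self):
        t = np.arange(-0.5, 12.0, 0.02)
        m = response_metrics(np.zeros_like(t), t, "max")
        assert m.amplitude == 0.0
        assert math.isnan(m.latency_s)
        assert m.undefined_latency

    def test_latency_inside_post_window(self, rng):
        t = np.arange(-0.5, 12.0, 0.02)
        for _ in range(20):
            m = response_metrics(rng.normal(size=t.size), t, "auto")
            assert 0 < m.latency_s <= 12.0


class TestOneSampleT:
    def test_symmetric_values(self):
        res = one_sample_t([-2.0, -1.0, 1.0, 2.0])
        assert res.statistic == pytest.approx(0.0, abs=1e-15)
        assert res.p == pytest.approx(1.0)

    def test_hand_picked_closed_form(self):
        v = [0.4, 0.1, 0.7, 0.3, 0.5]
        t, p = _one_sample_oracle(v)
        res = one_sample_t(v)
        assert res.statistic == pytest.approx(t, abs=1e-12)
        assert res.p == pytest.approx(p, abs=1e-12)
        assert res.df == 4

    def test_zero_variance_branch(self):
        res = one_sample_t([2.0, 2.0, 2.0])
        assert math.isinf(res.statistic) and res.statistic > 0
        assert res.p == 0.0
        assert res.degenerate

    def test_needs_two(self):
        with pytest.raises(ValueError):
            one_sample_t([1.0])


class TestTwoSampleT:
    def test_identical_groups(self):
        res = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0, abs=1e-15)

    def test_hand_built_pooled_formula(self):
        a = [5.1, 4.8, 5.5, 5.0]
        b = [4.2, 4.6, 4.1, 4.4, 4.3]
        t, p = _two_sample_oracle(a, b)
        res = two_sample_t(a, b)
        assert res.statistic == pytest.approx(t, abs=1e-12)
        assert res.p == pytest.approx(p, abs=1e-12)
        assert res.df == 7

    def test_paired_constant_shift_degenerate(self):
        x = np.array([1.0, 2.0, 3.0])
        res = two_sample_t(x, x + 1.0, paired=True)
        assert math.isinf(res.statistic) and res.statistic < 0
        assert res.degenerate

    def test_paired_equals_one_sample_on_differences(self, rng):
        a = rng.normal(size=10)
        b = rng.normal(size=10)
        res = two_sample_t(a, b, paired=True)
        ref = one_sample_t(a - b)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.p, abs=1e-12)


class TestPlannedComparisons:
    def test_bonferroni_display_alpha(self, rng):
        pc = planned_comparisons(_metrics4(rng), family_alpha=0.05)
        assert pc["alpha_display"] == 0.017
        assert pc["alpha_exact"] == pytest.approx(0.05 / 3)

    def test_alpha_003(self, rng):
        pc = planned_comparisons(_metrics4(rng), family_alpha=0.03)
        assert pc["alpha_display"] == 0.010

    def test_identical_cells_all_null(self, rng):
        cell = {"amplitude": rng.normal(size=15), "latency": rng.normal(size=15)}
        metrics = {
            c: {k: v.copy() for k, v in cell.items()}
            for c in ("1500ms_nomove", "3000ms_nomove", "1500ms_move", "3000ms_move")
        }
        pc = planned_comparisons(metrics)
        for entry in pc["tests"]:
            assert entry["result"].statistic == pytest.approx(0.0, abs=1e-12)
            assert not entry["significant"]

    def test_six_tests_three_contrasts(self, rng):
        pc = planned_comparisons(_metrics4(rng))
        assert len(pc["tests"]) == 6
        assert {e["contrast"] for e in pc["tests"]} == {c[0] for c in PLANNED_CONTRASTS}

    def test_missing_cell_named(self, rng):
        m = _metrics4(rng)
        del m["3000ms_move"]
        with pytest.raises(ValueError, match="3000ms_move"):
            planned_comparisons(m)


class TestCouplingRegression:
    def test_exact_linear_relation(self):
        t = np.arange(-0.5, 10.0, 0.02)
        x = np.sin(2 * np.pi * 0.1 * t)
        res = coupling_regression(2 * x + 1, t, x, t)
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)

    def test_orthogonal_signals(self):
        t = np.arange(0, 10.0, 0.01)  # whole periods of a 1 Hz pair
        res = coupling_regression(np.sin(2 * np.pi * t), t, np.cos(2 * np.pi * t), t)
        assert abs(res.r) < 0.01

    def test_normal_equations_oracle(self, rng):
        t = np.arange(20) * 0.5
        x = rng.normal(size=20)
        y = 0.7 * x + rng.normal(0, 0.3, 20)
        res = coupling_regression(y, t, x, t)
        slope, intercept, r, p = _regression_oracle(list(x), list(y))
        assert res.slope == pytest.approx(slope, abs=1e-12)
        assert res.intercept == pytest.approx(intercept, abs=1e-12)
        assert res.r == pytest.approx(r, abs=1e-12)
        assert res.p == pytest.approx(p, abs=1e-10)

    def test_window_cropping(self):
        tn = np.arange(-0.5, 12.0, 0.02)
        tm = np.arange(-0.5, 10.0, 0.02)
        res = coupling_regression(
            np.sin(tn), tn, np.sin(tm), tm, common_window_s=(-0.5, 9.985)
        )
        assert res.n == tm.size
        assert res.r == pytest.approx(1.0)

    def test_constant_regressor_rejected(self):
        t = np.arange(0, 5.0, 0.1)
        with pytest.raises(ValueError, match="constant"):
            coupling_regression(np.sin(t), t, np.ones_like(t), t)

    def test_mismatched_grids_rejected(self):
        ta = np.arange(0, 5.0, 0.1)
        tb = ta + 0.003
        with pytest.raises(ValueError, match="grid"):
            coupling_regression(np.sin(ta), ta, np.sin(tb), tb)


class TestStatisticsOracleSweep:
    def test_1000_random_small_samples(self):
        """t-tests and regressions agree with closed-form arithmetic to 1e-10."""
        rng = np.random.default_rng(77)
        for _ in range(1000):
            n = int(rng.integers(3, 12))
            v = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2.0), n)
            t, p = _one_sample_oracle(list(v))
            res = one_sample_t(v)
            assert abs(res.statistic - t) < 1e-10
            assert abs(res.p - p) < 1e-10

            m = int(rng.integers(3, 12))
            w = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2.0), m)
            t2, p2 = _two_sample_oracle(list(v), list(w))
            res2 = two_sample_t(v, w)
            assert abs(res2.statistic - t2) < 1e-10
            assert abs(res2.p - p2) < 1e-10

        for _ in range(1000):
            n = int(rng.integers(4, 25))
            x = rng.normal(size=n)
            y = rng.normal(size=n) + 0.5 * x
            slope, intercept, r, p = _regression_oracle(list(x), list(y))
            res = coupling_regression(y, np.arange(n, dtype=float), x, np.arange(n, dtype=float))
            assert abs(res.slope - slope) < 1e-10
            assert abs(res.r - r) < 1e-10
            assert abs(res.p - p) < 1e-10


class TestSignRecoverySmoke:
    """Few-seed coupling-sign smoke check (the full 50-seed sweep runs in
    the acceptance suite)."""

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_coupling_signs(self, seed):
        from nirsbp import pipeline as pl
        from nirsbp import synthgen as sg

        s = sg.simulate_session(sg.SimulationConfig(seed=seed))
        b = pl.analyze_session(s.nirs, s.pressure, s.schedule, pl.AnalysisParams())
        r = b.regressions.set_index(["signal", "condition"])["r"]
        assert r[("shallow_o2hb", "move")] > 0
        assert r[("deep_o2hb", "move")] > 0
        assert r[("deep_hhb", "move")] < 0
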