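import numpy as np
import pytest

from leukotrace.motility import (
    dunn_msd, fit_dunn, group_summaries, meandering_index, msd, summarize_fragment,
)
from leukotrace.synthetic import simulate_ou_fragments
from leukotrace.tracking import TrackFragment


def path_fragment(xs, ys, state="luminal"):
    fr = TrackFragment(fragment_id=0)
    for t, (x, y) in enumerate(zip(xs, ys)):
        fr.append(t, float(x), float(y), state, t)
    return fr


class TestMeanderingIndex:
    def test_straight_line_is_one(self):
        fr = path_fragment(range(20), [0] * 20)
        assert meandering_index(fr) == pytest.approx(1.0)

    def test_closed_loop_is_zero(self):
        xs = [0, 1, 1, 0, 0]
        ys = [0, 0, 1, 1, 0]
        assert meandering_index(path_fragment(xs, ys)) == pytest.approx(0.0)

    def test_l_path_pythagoras(self):
        fr = path_fragment([0, 3, 3], [0, 0, 4])
        assert meandering_index(fr) == pytest.approx(5 / 7)

    def test_stationary_path_defined_as_zero(self):
        assert meandering_index(path_fragment([2, 2, 2], [3, 3, 3])) == 0.0


class TestMsd:
    def test_ballistic_closed_form_exact(self):
        v = 1.7  # px/frame; with 4 s frames speed is v/4 px/s
        fr = path_fragment(np.arange(200) * v, np.zeros(200))
        curve = msd(fr, frame_interval_s=4.0, tau_max_s=120.0)
        assert curve.shape == (30, 2)
        speed = v / 4.0
        assert np.allclose(curve[:, 1], speed**2 * curve[:, 0] ** 2)

    def test_stationary_track_is_zero(self):
        fr = path_fragment(np.zeros(150), np.zeros(150))
        assert np.allclose(msd(fr)[:, 1], 0.0)

    def test_lattice_random_walk_linear_within_3se(self):
        # independent oracle: 2-D lattice walk, step s each frame, has
        # E[MSD at lag k] = s^2 k; check the time-averaged estimate
        rng = np.random.default_rng(5)
        n, s = 10_000, 2.0
        axis = rng.integers(0, 2, size=n)
        sign = rng.choice([-1.0, 1.0], size=n)
        steps = np.zeros((n, 2))
        steps[np.arange(n), axis] = sign * s
        pos = np.concatenate([np.zeros((1, 2)), np.cumsum(steps, axis=0)])
        fr = path_fragment(pos[:, 0], pos[:, 1])
        curve = msd(fr, frame_interval_s=1.0, tau_max_s=30.0)
        for k, (lag, m) in enumerate(curve, start=1):
            sq = (pos[k:, 0] - pos[:-k, 0]) ** 2 + (pos[k:, 1] - pos[:-k, 1]) ** 2
            n_eff = len(sq) / k  # overlapping pairs decorrelate after ~k steps
            se = sq.std() / np.sqrt(n_eff)
            assert abs(m - s * s * k) <= 3 * se

    def test_msd_nonnegative_and_first_lag_bounded(self):
        rng = np.random.default_rng(9)
        fr = path_fragment(np.cumsum(rng.normal(0, 1.5, 200)),
                           np.cumsum(rng.normal(0, 1.5, 200)))
        curve = msd(fr)
        assert np.all(curve[:, 1] >= 0)
        max_step = np.max(np.hypot(np.diff(fr.xs), np.diff(fr.ys)))
        assert curve[0, 1] <= max_step**2

    def test_gapped_fragment_rejected(self):
        fr = TrackFragment(fragment_id=0)
        for t in [0, 1, 3]:
            fr.append(t, float(t), 0.0, "luminal", t)
        with pytest.raises(ValueError, match="gap-free"):
            msd(fr)


class TestDunnFit:
    def test_noiseless_self_consistency(self):
        t = np.arange(1, 31) * 4.0
        S, P, rss, ok = fit_dunn(np.column_stack([t, dunn_msd(t, 0.2, 30.0)]))
        assert ok
        assert S == pytest.approx(0.2, rel=1e-3)
        assert P == pytest.approx(30.0, rel=1e-3)

    def test_ballistic_curve_gives_speed_and_huge_persistence(self):
        t = np.arange(1, 31) * 4.0
        v = 0.25
        S, P, rss, ok = fit_dunn(np.column_stack([t, v**2 * t**2]))
        assert S == pytest.approx(v, rel=0.02)
        assert P > 10 * t[-1]  # persistence lower-bounded far beyond tau_max

    def test_scale_consistency(self):
        t = np.arange(1, 31) * 4.0
        base = dunn_msd(t, 0.15, 40.0)
        k = 3.5
        S, P, *_ = fit_dunn(np.column_stack([t, k**2 * base]))
        assert S == pytest.approx(0.15 * k, rel=1e-3)
        assert P == pytest.approx(40.0, rel=1e-3)

    def test_model_limits(self):
        # ballistic at t << P, diffusive at t >> P
        S, P = 0.2, 50.0
        t_small, t_big = P / 100.0, 100.0 * P
        assert dunn_msd(t_small, S, P) == pytest.approx(2 * (S * t_small) ** 2 / 2, rel=0.01)
        assert dunn_msd(t_big, S, P) == pytest.approx(2 * S * S * P * t_big, rel=0.01)

    def test_parameter_recovery_single_condition(self):
        frags = simulate_ou_fragments(60, 450, S=0.15, P=40.0, seed=8)
        fits = np.array([fit_dunn(msd(f))[:2] for f in frags])
        assert np.mean(fits[:, 0]) == pytest.approx(0.15, rel=0.10)
        assert np.mean(fits[:, 1]) == pytest.approx(40.0, rel=0.25)


class TestGroups:
    def make_summaries(self):
        frags = simulate_ou_fragments(20, 120, S=0.1, P=20.0, seed=2)
        out = []
        for i, fr in enumerate(frags):
            s = summarize_fragment(fr)
            # pin MI so the reactive/non-reactive split is unambiguous
            s.meandering_index = 0.05 if i < 5 else 0.5
            out.append(s)
        return out

    def test_group_table_structure_and_nonreactive_fraction(self):
        table = group_summaries(self.make_summaries(), n_select=15, seed=0)
        table = table.set_index("group")
        assert table.loc["nonreactive", "n"] == 5
        assert table.loc["reactive", "n"] == 15
        assert table.loc["longest15", "n"] == 15
        assert table.loc["random15", "n"] == 15

    def test_identical_fragments_have_equal_group_means(self):
        s = self.make_summaries()[:1] * 4
        table = group_summaries(s, n_select=2, seed=1).set_index("group")
        for g in ("all_long", "longest2", "random2"):
            assert table.loc[g, "speed_mean"] == pytest.approx(s[0].speed)

    def test_mi_threshold_splits_nonreactive(self):
        summaries = self.make_summaries()[:2]
        summaries[0].meandering_index = 0.05
        summaries[1].meandering_index = 0.5
        table = group_summaries(summaries, seed=0).set_index("group")
        assert table.loc["nonreactive", "n"] == 1
        assert table.loc["reactive", "n"] == 1
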