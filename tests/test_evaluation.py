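"""Metric definitions, evaluation harness, and robustness protocols."""

import math

import numpy as np
import pytest

from flockcast import Window
from flockcast.evaluation import (
    MetricsReport,
    evaluate,
    grouped_evaluate,
    horizon_sweep,
    min_ade,
    min_fde,
    mode_trajectories,
    nll,
    noise_robustness,
)
from flockcast.studentt import MixtureParams, StudentTParams
from flockcast.trackio import reconstruct_positions

from conftest import make_straight_window


def mixture_from_displacements(disp_list, weights=None, scale=1.0, nu=6.0):
    """Build a mixture whose component means are the given (T_fut, 2) paths."""
    K = len(disp_list)
    comps = [
        StudentTParams(np.asarray(d, dtype=float).ravel(),
                       np.full(2 * len(d), scale), nu)
        for d in disp_list
    ]
    w = np.full(K, 1.0 / K) if weights is None else np.asarray(weights, float)
    return MixtureParams(w, comps)


class OracleModel:
    """Predicts each window's true future displacements as a K=1 mixture."""

    def forward(self, w: Window) -> MixtureParams:
        return mixture_from_displacements([w.future_displacements])


# ---------------------------------------------------------------------------
# Mode trajectories
# ---------------------------------------------------------------------------

def test_zero_mean_modes_are_standstill():
    mix = mixture_from_displacements([np.zeros((5, 2))] * 3)
    modes = mode_trajectories(mix, np.array([2.0, -1.0]), 5)
    assert np.allclose(modes, np.tile([2.0, -1.0], (3, 5, 1)))


def test_constant_displacement_mode_is_straight_line():
    mix = mixture_from_displacements([np.tile([1.0, 0.0], (4, 1))])
    modes = mode_trajectories(mix, np.array([3.0, 7.0]), 4)
    assert np.allclose(modes[0, :, 0], [4, 5, 6, 7])
    assert np.allclose(modes[0, :, 1], 7.0)


def test_modes_match_reconstruct_positions_per_component():
    rng = np.random.default_rng(0)
    disp = [rng.standard_normal((6, 2)) for _ in range(4)]
    mix = mixture_from_displacements(disp)
    last = rng.standard_normal(2)
    modes = mode_trajectories(mix, last, 6)
    for k in range(4):
        assert np.allclose(modes[k], reconstruct_positions(last, disp[k]), atol=1e-12)


def test_mode_dimension_mismatch_rejected():
    mix = mixture_from_displacements([np.zeros((5, 2))])
    with pytest.raises(ValueError):
        mode_trajectories(mix, np.zeros(2), 7)


# ---------------------------------------------------------------------------
# minADE / minFDE
# ---------------------------------------------------------------------------

def test_perfect_mode_gives_zero_error():
    gt = np.cumsum(np.ones((6, 2)), axis=0)
    modes = np.stack([gt, gt + 5.0])
    assert min_ade(modes, gt, 6) == 0.0
    assert min_fde(modes, gt, 6) == 0.0


def test_constant_offset_three_four_five():
    gt = np.cumsum(np.ones((6, 2)), axis=0)
    modes = (gt + np.array([3.0, 4.0]))[None]
    assert min_ade(modes, gt, 6) == pytest.approx(5.0)
    assert min_fde(modes, gt, 6) == pytest.approx(5.0)


def test_min_metrics_match_brute_force_over_modes():
    rng = np.random.default_rng(1)
    gt = rng.standard_normal((8, 2)).cumsum(axis=0)
    modes = np.stack([gt + rng.standard_normal((8, 2)) for _ in range(3)])
    for h in (1, 4, 8):
        ades = [np.linalg.norm(m[:h] - gt[:h], axis=1).mean() for m in modes]
        fdes = [np.linalg.norm(m[h - 1] - gt[h - 1]) for m in modes]
        assert min_ade(modes, gt, h) == pytest.approx(min(ades))
        assert min_fde(modes, gt, h) == pytest.approx(min(fdes))


def test_ade_and_fde_argmin_modes_may_differ():
    # mode A: perfect until the end, bad final step; mode B: constant small offset
    gt = np.array([[0.0, 0.0], [1.0, 0.0]])
    mode_a = np.array([[0.0, 0.0], [1.0, 3.0]])   # ADE (0+3)/2, FDE 3
    mode_b = np.array([[0.0, 1.0], [1.0, 1.0]])   # ADE 1, FDE 1
    modes = np.stack([mode_a, mode_b])
    assert min_ade(modes, gt, 2) == pytest.approx(1.0)    # B wins ADE
    assert min_fde(modes, gt, 2) == pytest.approx(1.0)    # B wins FDE
    mode_c = np.array([[0.0, 0.1], [1.0, 2.0]])   # ADE 1.05, FDE 2
    modes = np.stack([mode_a, mode_c])
    assert min_ade(modes, gt, 1) == pytest.approx(0.0)    # A wins at h=1
    assert min_fde(modes, gt, 2) == pytest.approx(2.0)    # C wins FDE at h=2


def test_metrics_non_increasing_when_modes_are_appended():
    rng = np.random.default_rng(2)
    gt = rng.standard_normal((6, 2)).cumsum(axis=0)
    modes = [gt + rng.standard_normal((6, 2)) * s for s in (2.0, 1.0, 0.5, 0.1)]
    prev_ade, prev_fde = math.inf, math.inf
    for k in range(1, 5):
        stack = np.stack(modes[:k])
        a, f = min_ade(stack, gt, 6), min_fde(stack, gt, 6)
        assert a <= prev_ade + 1e-12 and f <= prev_fde + 1e-12
        prev_ade, prev_fde = a, f


def test_metrics_invariant_under_joint_translation():
    rng = np.random.default_rng(3)
    gt = rng.standard_normal((5, 2)).cumsum(axis=0)
    modes = np.stack([gt + rng.standard_normal((5, 2)) for _ in range(2)])
    shift = np.array([17.0, -4.0])
    assert min_ade(modes, gt, 5) == pytest.approx(min_ade(modes + shift, gt + shift, 5))
    assert min_fde(modes, gt, 5) == pytest.approx(min_fde(modes + shift, gt + shift, 5))


def test_horizon_validation():
    gt = np.zeros((4, 2))
    with pytest.raises(ValueError):
        min_ade(np.zeros((1, 4, 2)), gt, 5)


# ---------------------------------------------------------------------------
# NLL
# ---------------------------------------------------------------------------

def test_nll_gaussian_limit_at_the_mode():
    mu = np.array([0.3, -0.8])
    mix = MixtureParams([1.0], [StudentTParams(mu, [1.0, 1.0], 1e6)])
    joint = nll(mix, mu.reshape(1, 2), normalization="joint")
    assert joint == pytest.approx(math.log(2 * math.pi), abs=1e-6)
    assert nll(mix, mu.reshape(1, 2)) == pytest.approx(joint)  # T_fut = 1


def test_nll_per_step_is_joint_over_t_fut():
    rng = np.random.default_rng(4)
    disp = [rng.standard_normal((5, 2)) for _ in range(2)]
    mix = mixture_from_displacements(disp)
    gt = rng.standard_normal((5, 2))
    assert nll(mix, gt) == pytest.approx(nll(mix, gt, "joint") / 5)


def test_nll_matches_log_mixture_oracle():
    from flockcast.studentt import log_mixture

    rng = np.random.default_rng(5)
    disp = [rng.standard_normal((3, 2)) for _ in range(3)]
    mix = mixture_from_displacements(disp)
    gt = rng.standard_normal((3, 2))
    assert nll(mix, gt, "joint") == pytest.approx(-log_mixture(gt.ravel(), mix))


def test_nll_invariant_under_component_relabeling():
    rng = np.random.default_rng(6)
    disp = [rng.standard_normal((3, 2)) for _ in range(3)]
    mix = mixture_from_displacements(disp, weights=[0.5, 0.3, 0.2])
    perm = MixtureParams(mix.weights[[2, 0, 1]],
                         [mix.components[i] for i in (2, 0, 1)])
    gt = rng.standard_normal((3, 2))
    assert nll(mix, gt) == pytest.approx(nll(perm, gt), rel=1e-12)


# ---------------------------------------------------------------------------
# evaluate / grouped / sweeps
# ---------------------------------------------------------------------------

def linear_windows(n, seed, T_fut=6):
    rng = np.random.default_rng(seed)
    return [
        make_straight_window(T_past=4, T_fut=T_fut, velocity=rng.uniform(-1, 1, 2),
                             start=rng.uniform(-5, 5, 2))
        for _ in range(n)
    ]


def test_oracle_model_scores_zero_displacement_error():
    ws = linear_windows(5, 0)
    rep = evaluate(OracleModel(), ws, horizons=(3, 6))
    assert rep.min_ade == {3: 0.0, 6: 0.0}
    assert rep.min_fde == {3: 0.0, 6: 0.0}
    assert rep.n_windows == 5


def test_evaluate_matches_scripted_per_window_loop():
    ws = linear_windows(10, 1)
    model = OracleModel()

    class Jittery:
        def forward(self, w):
            rng = np.random.default_rng(abs(hash(w.past_positions.tobytes())) % 2**31)
            disp = [w.future_displacements + 0.3 * rng.standard_normal(w.future_displacements.shape)
                    for _ in range(3)]
            return mixture_from_displacements(disp)

    model = Jittery()
    rep = evaluate(model, ws, horizons=(3, 6))
    accum = {3: [], 6: []}
    nlls = []
    for w in ws:
        mix = model.forward(w)
        modes = mode_trajectories(mix, w.last_observed, 6)
        for h in (3, 6):
            accum[h].append(min_ade(modes, w.future_positions, h))
        nlls.append(nll(mix, w.future_displacements))
    for h in (3, 6):
        assert rep.min_ade[h] == pytest.approx(np.mean(accum[h]))
    assert rep.nll == pytest.approx(np.mean(nlls))


def test_single_window_reduces_to_per_window_operations():
    (w,) = linear_windows(1, 2)
    model = OracleModel()
    rep = evaluate(model, [w], horizons=(6,))
    mix = model.forward(w)
    modes = mode_trajectories(mix, w.last_observed, 6)
    assert rep.min_ade[6] == pytest.approx(min_ade(modes, w.future_positions, 6))
    assert rep.nll == pytest.approx(nll(mix, w.future_displacements))


def test_evaluate_rejects_horizon_beyond_forecast():
    with pytest.raises(ValueError):
        evaluate(OracleModel(), linear_windows(2, 3), horizons=(30,))


def test_metrics_report_scalar_surface():
    rep = MetricsReport(min_ade={30: 1.0, 60: 2.0}, min_fde={30: 1.5, 60: 2.5},
                        nll=0.1, n_windows=4)
    assert (rep.min_ade_30, rep.min_ade_60, rep.min_fde_30, rep.min_fde_60) == (1.0, 2.0, 1.5, 2.5)


def test_grouped_evaluation_identities():
    ws = linear_windows(8, 4)
    model = OracleModel()
    one = grouped_evaluate(model, ws, ["all"] * 8, horizons=(6,))
    assert one["all"].min_ade[6] == evaluate(model, ws, horizons=(6,)).min_ade[6]
    # two identical groups -> identical reports
    two = grouped_evaluate(model, ws + ws, ["a"] * 8 + ["b"] * 8, horizons=(6,))
    assert two["a"].min_ade[6] == two["b"].min_ade[6]
    # weighted mean of group minADEs equals the overall minADE
    labels = ["a", "b"] * 4

    class Jittery:
        def forward(self, w):
            rng = np.random.default_rng(abs(hash(w.past_positions.tobytes())) % 2**31)
            return mixture_from_displacements(
                [w.future_displacements + rng.standard_normal(w.future_displacements.shape)])

    jm = Jittery()
    grouped = grouped_evaluate(jm, ws, labels, horizons=(6,))
    counts = {lab: labels.count(lab) for lab in set(labels)}
    weighted = sum(grouped[lab].min_ade[6] * c for lab, c in counts.items()) / len(ws)
    assert weighted == pytest.approx(evaluate(jm, ws, horizons=(6,)).min_ade[6])


def test_grouped_label_mismatch_rejected():
    with pytest.raises(ValueError):
        grouped_evaluate(OracleModel(), linear_windows(3, 5), ["a", "b"])


def test_horizon_sweep_examples():
    ws = linear_windows(4, 6)
    # single horizon equals plain evaluate
    curve = horizon_sweep(OracleModel(), ws, [6])
    assert curve.values == [evaluate(OracleModel(), ws, horizons=(6,)).min_ade[6]]
    # oracle is zero at all horizons
    zeros = horizon_sweep(OracleModel(), ws, [1, 2, 4, 6])
    assert zeros.values == [0.0] * 4

    class GrowingError:
        def forward(self, w):
            disp = w.future_displacements.copy()
            disp[:, 1] += 1.0  # constant per-step drift -> error grows with horizon
            return mixture_from_displacements([disp])

    g = horizon_sweep(GrowingError(), ws, [1, 2, 4, 6])
    # hand computation: at horizon h the ADE is mean_t(t) = (h+1)/2
    assert g.values == pytest.approx([(h + 1) / 2 for h in (1, 2, 4, 6)])
    assert np.all(np.diff(g.values) > 0)
    with pytest.raises(ValueError):
        horizon_sweep(OracleModel(), ws, [7])


def test_noise_robustness_zero_level_is_bitwise_plain_evaluation():
    ws = linear_windows(6, 7)
    curve = noise_robustness(OracleModel(), ws, [0.0, 0.5], n_repeats=3, seed=1)
    plain = evaluate(OracleModel(), ws, horizons=(6,)).min_ade[6]
    assert curve.values[0] == plain  # bitwise
    again = noise_robustness(OracleModel(), ws, [0.0, 0.5], n_repeats=3, seed=1)
    assert curve.values == again.values  # seed determinism
    assert curve.metric_name == "min_ade@6"
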