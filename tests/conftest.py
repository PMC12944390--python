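"""Shared fixtures: small synthetic window sets and trained desk-scale models.

The expensive fixtures are session-scoped so the head-ablation experiment and
the robustness protocol share one set of trained models.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from flockcast import (
    MiniFormer,
    ModelConfig,
    SimConfig,
    TrainConfig,
    Window,
    evaluate,
    make_benchmark,
)
from flockcast.training import train

# Desk-scale study conditions: heavy-tailed simulator (innovation dof 3),
# 8-frame history, 10-frame horizon, ~2000 train / 500 test windows.
DESK_SIM = SimConfig(n_tracks=6, track_length=90, innovation_nu=3.0, seed=7)
DESK_MODEL = ModelConfig(d_model=48, ffn_dim=96, head_hidden=96, T_fut=10, K=5)
DESK_EPOCHS = 12
ABLATION_SEEDS = (0, 1, 2, 3, 4)


def desk_model_config(**overrides) -> ModelConfig:
    return dataclasses.replace(DESK_MODEL, **overrides)


def make_straight_window(T_past: int = 8, T_fut: int = 10, velocity=(1.0, 0.0),
                         start=(0.0, 0.0)) -> Window:
    """A noise-free constant-velocity observation-prediction window."""
    v = np.asarray(velocity, dtype=float)
    p0 = np.asarray(start, dtype=float)
    t = np.arange(T_past + T_fut)[:, None]
    pos = p0 + t * v
    return Window("line", T_past - 1, pos[:T_past], pos[T_past:])


@pytest.fixture(scope="session")
def desk_benchmark():
    """Train/val/test windows under the desk-scale study conditions."""
    tr, va, te = make_benchmark(DESK_SIM, T_past=8, T_fut=10, n_flocks=30)
    return tr[:2000], va[:800], te[:500]


def _train_head(family: str, seed: int, benchmark) -> tuple[MiniFormer, float]:
    tr, va, te = benchmark
    cfg = desk_model_config(family=family, K=1 if family == "gaussian" else 5)
    model = MiniFormer(cfg, seed=seed)
    train(model, tr, va, TrainConfig(epochs=DESK_EPOCHS, seed=seed, early_stop_patience=5))
    report = evaluate(model, te, horizons=(5, 10))
    return model, report.nll


@pytest.fixture(scope="session")
def head_ablation(desk_benchmark):
    """Student-t vs Gaussian heads, identically trained over five seeds.

    Returns {"student_t": [...nll per seed], "gaussian": [...], "model": one
    trained Student-t forecaster for reuse}.
    """
    out = {"student_t": [], "gaussian": [], "model": None}
    for seed in ABLATION_SEEDS:
        m_t, nll_t = _train_head("student_t", seed, desk_benchmark)
        _, nll_g = _train_head("gaussian", seed, desk_benchmark)
        out["student_t"].append(nll_t)
        out["gaussian"].append(nll_g)
        if seed == ABLATION_SEEDS[0]:
            out["model"] = m_t
    return out


@pytest.fixture(scope="session")
def trained_student_t(head_ablation) -> MiniFormer:
    return head_ablation["model"]
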