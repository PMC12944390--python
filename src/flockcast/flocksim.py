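"""Synthetic heavy-tailed flock-trajectory generator.

Emulates the statistical structure of video-derived bird tracklets: flocks
of a handful of agents sampled at ~30 Hz, smooth cruising interrupted by
abrupt heavy-tailed turns and accelerations, mild cohesion toward the flock
centroid, and additive Gaussian tracking jitter on the observed positions.

Each agent follows a regime-switching correlated random walk in the plane:

* heading: small Gaussian increments while cruising; with per-frame
  probability ``turn_switch_prob`` the agent enters a one-frame sharp-turn
  regime whose increment is Student-t distributed (dof ``innovation_nu``,
  standard deviation ``turn_rate_std``);
* speed: mean-reverting walk around ``cruise_speed_mean`` with Student-t
  innovations of per-frame scale ``cruise_speed_std``;
* position: advanced along the heading, plus an optional linear pull of
  strength ``cohesion_strength`` toward the current flock centroid.

Student-t innovations are standardized to unit variance before scaling, so
the Gaussian-innovation control (``innovation_family="gaussian"``) has
matched variance and differs only in tail weight.  All randomness flows
from one seed through named ``SeedSequence`` substreams, so every output is
bit-reproducible and the per-purpose streams (simulation, jitter, splits)
are independent.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .trackio import Tracklet, Window, make_windows

__all__ = ["SimConfig", "simulate_flock", "add_jitter", "make_benchmark"]


@dataclass
class SimConfig:
    n_tracks: int = 6
    track_length: int = 200
    frame_rate: float = 30.0
    cruise_speed_mean: float = 6.0     # units/frame
    cruise_speed_std: float = 0.1      # per-frame speed innovation scale
    turn_switch_prob: float = 0.03
    turn_rate_std: float = 0.5         # rad/frame in the sharp-turn regime
    cruise_turn_std: float = 0.05      # rad/frame Gaussian drift while cruising
    speed_reversion: float = 0.05      # pull of speed back to the cruise mean
    innovation_nu: float = 3.0
    innovation_family: str = "student_t"  # or "gaussian" (matched-variance control)
    cohesion_strength: float = 0.0
    jitter_std: float = 0.5
    spawn_radius: float = 40.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.turn_switch_prob <= 1.0):
            raise ValueError("turn_switch_prob must be a probability")
        if self.n_tracks < 1 or self.track_length < 2:
            raise ValueError("need n_tracks >= 1 and track_length >= 2")
        if self.innovation_nu <= 2:
            raise ValueError("innovation_nu must exceed 2 (finite variance)")
        if self.cohesion_strength < 0 or self.jitter_std < 0:
            raise ValueError("cohesion_strength and jitter_std must be nonnegative")
        if self.frame_rate <= 0 or self.cruise_speed_mean <= 0:
            raise ValueError("frame_rate and cruise_speed_mean must be positive")
        if self.innovation_family not in ("student_t", "gaussian"):
            raise ValueError("innovation_family must be 'student_t' or 'gaussian'")

    def to_dict(self) -> dict:
        return asdict(self)


def _standardized_innovations(rng: np.random.Generator, nu: float, family: str,
                              size) -> np.ndarray:
    """Unit-variance innovations: Student-t(nu)/sqrt(nu/(nu-2)) or N(0,1)."""
    if family == "gaussian":
        return rng.standard_normal(size)
    return rng.standard_t(nu, size) / np.sqrt(nu / (nu - 2.0))


def simulate_flock(cfg: SimConfig) -> list[Tracklet]:
    """Simulate one flock; returns n_tracks contiguous tracklets."""
    root = np.random.SeedSequence([cfg.seed, 0x51D])
    rng = np.random.default_rng(root)
    n, L = cfg.n_tracks, cfg.track_length

    theta = rng.uniform(0, 2 * np.pi) + 0.2 * rng.standard_normal(n)
    speed = cfg.cruise_speed_mean * (1.0 + 0.05 * rng.standard_normal(n))
    pos = cfg.spawn_radius * rng.standard_normal((n, 2))
    out = np.empty((L, n, 2))
    out[0] = pos
    for t in range(1, L):
        in_turn = rng.random(n) < cfg.turn_switch_prob
        dtheta = np.where(
            in_turn,
            cfg.turn_rate_std * _standardized_innovations(rng, cfg.innovation_nu,
                                                          cfg.innovation_family, n),
            cfg.cruise_turn_std * rng.standard_normal(n),
        )
        theta = theta + dtheta
        eps = _standardized_innovations(rng, cfg.innovation_nu, cfg.innovation_family, n)
        speed = speed + cfg.speed_reversion * (cfg.cruise_speed_mean - speed) \
            + cfg.cruise_speed_std * eps
        step = speed[:, None] * np.stack([np.cos(theta), np.sin(theta)], axis=1)
        if cfg.cohesion_strength > 0 and n > 1:
            centroid = pos.mean(axis=0, keepdims=True)
            step = step + cfg.cohesion_strength * (centroid - pos)
        pos = pos + step
        out[t] = pos

    frames = np.arange(L)
    return [
        Tracklet(track_id=f"sim{cfg.seed}_{i}", frames=frames,
                 positions=out[:, i], frame_rate=cfg.frame_rate)
        for i in range(n)
    ]


def add_jitter(tracks: list[Tracklet], jitter_std: float, seed: int) -> list[Tracklet]:
    """Add i.i.d. zero-mean Gaussian observation noise to every position."""
    if jitter_std < 0:
        raise ValueError("jitter_std must be nonnegative")
    if jitter_std == 0:
        return list(tracks)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x117]))
    out = []
    for tr in tracks:
        noisy = tr.positions + jitter_std * rng.standard_normal(tr.positions.shape)
        out.append(Tracklet(track_id=tr.track_id, frames=tr.frames.copy(),
                            positions=noisy, frame_rate=tr.frame_rate))
    return out


def make_benchmark(cfg: SimConfig, split_fractions=(0.6, 0.2, 0.2), *,
                   T_past: int = 8, T_fut: int = 60, stride: int = 1,
                   n_flocks: int = 1) -> tuple[list[Window], list[Window], list[Window]]:
    """Simulate, jitter and window a train/val/test benchmark.

    Splitting happens at the TRACK level with a seeded shuffle, before
    windowing, so no track contributes windows to two splits.  With
    ``n_flocks > 1`` several independent flocks (seeds derived from
    ``cfg.seed``) are pooled for more tracks.
    """
    fr = np.asarray(split_fractions, dtype=float)
    if fr.size != 3 or np.any(fr <= 0) or abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("split fractions must be three positives summing to 1")
    tracks: list[Tracklet] = []
    for j in range(n_flocks):
        sub = SimConfig(**{**cfg.to_dict(), "seed": cfg.seed * 100003 + j})
        flock = simulate_flock(sub)
        flock = add_jitter(flock, cfg.jitter_std, seed=sub.seed + 1)
        for tr in flock:
            tracks.append(Tracklet(track_id=f"f{j}_{tr.track_id}", frames=tr.frames,
                                   positions=tr.positions, frame_rate=tr.frame_rate))
    n = len(tracks)
    n_train = int(round(fr[0] * n))
    n_val = int(round(fr[1] * n))
    n_test = n - n_train - n_val
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(
            f"{n} tracks are too few for nonempty splits with fractions {tuple(fr)}"
        )
    order = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5711])).permutation(n)
    groups = (order[:n_train], order[n_train:n_train + n_val], order[n_train + n_val:])
    splits = []
    for idx in groups:
        ws: list[Window] = []
        for i in idx:
            ws.extend(make_windows(tracks[i], T_past=T_past, T_fut=T_fut, stride=stride))
        splits.append(ws)
    return tuple(splits)
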