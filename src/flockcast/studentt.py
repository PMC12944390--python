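"""Multivariate Student-t mixture densities with diagonal scale matrices.

The predictive distribution of the forecaster is a K-component mixture of
multivariate Student-t distributions over the vectorized future displacement
sequence (dimension d = 2*T_fut).  The density of one component is

    T(y; mu, Sigma, nu) = c(nu, d, Sigma) * (1 + q/nu)^(-(nu+d)/2),
    q = (y - mu)^T Sigma^{-1} (y - mu),

with normalizing constant

    c(nu, d, Sigma) = Gamma((nu+d)/2) / (Gamma(nu/2) * (nu*pi)^{d/2} * |Sigma|^{1/2}).

Sigma is restricted to a diagonal matrix whose entries are the per-dimension
scale parameters (``scale_diag``), so determinant and inverse are trivial.
As nu -> infinity the component converges to the diagonal Gaussian;
``nu = inf`` is accepted and evaluated with the Gaussian closed form, which
lets Gaussian-head baselines share the mixture container.

All log densities are computed entirely in log space (log-gamma, log1p,
log-sum-exp), so they are finite for every finite input.  The same code path
serves plain numpy arrays and autodiff tensors (see :mod:`flockcast._autodiff`),
so the training loss and the evaluation math cannot drift apart.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from . import _autodiff as ad

__all__ = [
    "StudentTParams",
    "MixtureParams",
    "RawHeadOutput",
    "log_student_t",
    "log_mixture",
    "component_log_densities",
    "gaussian_log_density",
    "constrain_params",
    "sample_mixture",
    "log_student_t_terms",
    "log_gaussian_terms",
    "LOG_SCALE_CLAMP",
]

LOG_SCALE_CLAMP = 10.0  # raw log-scales are clamped to [-10, 10]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class StudentTParams:
    """One mixture component: location, diagonal scale, degrees of freedom."""

    mu: np.ndarray
    scale_diag: np.ndarray
    nu: float

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=np.float64).ravel()
        self.scale_diag = np.asarray(self.scale_diag, dtype=np.float64).ravel()
        if self.mu.shape != self.scale_diag.shape:
            raise ValueError("mu and scale_diag must have the same length")
        if self.mu.size < 1:
            raise ValueError("dimension must be >= 1")
        if not np.all(self.scale_diag > 0):
            raise ValueError("all scale entries must be strictly positive")
        if not (self.nu > 2):
            raise ValueError("degrees of freedom must exceed 2 (finite covariance)")

    @property
    def d(self) -> int:
        return self.mu.size


@dataclass
class MixtureParams:
    """K-component Student-t mixture over a d-dimensional target."""

    weights: np.ndarray
    components: list[StudentTParams] = field(default_factory=list)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64).ravel()
        if len(self.components) != self.weights.size or self.weights.size < 1:
            raise ValueError("need one weight per component, K >= 1")
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be nonnegative and sum to 1")
        dims = {c.d for c in self.components}
        if len(dims) != 1:
            raise ValueError("all components must share the same dimension")

    @property
    def K(self) -> int:
        return self.weights.size

    @property
    def d(self) -> int:
        return self.components[0].d

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "K": int(self.K),
            "d": int(self.d),
            "weights": self.weights.tolist(),
            "components": [
                {
                    "mu": c.mu.tolist(),
                    "scale_diag": c.scale_diag.tolist(),
                    "nu": None if math.isinf(c.nu) else float(c.nu),
                }
                for c in self.components
            ],
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "MixtureParams":
        comps = [
            StudentTParams(
                mu=np.asarray(c["mu"]),
                scale_diag=np.asarray(c["scale_diag"]),
                nu=math.inf if c["nu"] is None else float(c["nu"]),
            )
            for c in obj["components"]
        ]
        return cls(weights=np.asarray(obj["weights"]), components=comps)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "MixtureParams":
        return cls.from_dict(json.loads(s))


@dataclass
class RawHeadOutput:
    """Unconstrained density-head outputs, before the constraint transforms."""

    weight_logits: np.ndarray  # (K,)
    raw_mu: np.ndarray         # (K, d)
    raw_log_scale: np.ndarray  # (K, d)
    raw_nu: np.ndarray | None  # (K,) or None for Gaussian-family heads

    def __post_init__(self):
        for name in ("weight_logits", "raw_mu", "raw_log_scale"):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite entries")
            setattr(self, name, arr)
        if self.raw_nu is not None:
            self.raw_nu = np.asarray(self.raw_nu, dtype=np.float64)
            if not np.all(np.isfinite(self.raw_nu)):
                raise ValueError("raw_nu contains non-finite entries")


# ---------------------------------------------------------------------------
# Core log-density terms (dual-use: numpy arrays or autodiff tensors)
# ---------------------------------------------------------------------------

def log_student_t_terms(y, mu, scale_diag, nu, d: int):
    """Batched Student-t log density; trailing axis of y/mu/scale is d.

    Works on numpy arrays or autodiff Tensors alike; ``nu`` broadcasts
    against the leading axes.  Finite nu only.
    """
    z = (y - mu)
    q = (z * z / scale_diag).sum(axis=-1)
    logdet = ad.log(scale_diag).sum(axis=-1)
    half = 0.5
    logc = (
        ad.gammaln((nu + d) * half)
        - ad.gammaln(nu * half)
        - (d * half) * ad.log(nu * math.pi)
        - half * logdet
    )
    return logc - (nu + d) * half * ad.log1p(q / nu)


def log_gaussian_terms(y, mu, scale_diag, d: int):
    """Batched diagonal-Gaussian log density (scale_diag = variances)."""
    z = (y - mu)
    q = (z * z / scale_diag).sum(axis=-1)
    logdet = ad.log(scale_diag).sum(axis=-1)
    return -0.5 * (d * math.log(2.0 * math.pi) + logdet + q)


# ---------------------------------------------------------------------------
# Public numpy API over the containers
# ---------------------------------------------------------------------------

def _check_vector(y, d: int) -> np.ndarray:
    y = np.asarray(y, dtype=np.float64).ravel()
    if y.size != d:
        raise ValueError(f"dimension mismatch: y has {y.size} entries, expected {d}")
    return y


def log_student_t(y, params: StudentTParams) -> float:
    """Log density of one multivariate Student-t component at y."""
    y = _check_vector(y, params.d)
    if math.isinf(params.nu):
        return float(log_gaussian_terms(y, params.mu, params.scale_diag, params.d))
    return float(
        log_student_t_terms(y, params.mu, params.scale_diag, params.nu, params.d)
    )


def gaussian_log_density(y, mu, scale_diag) -> float:
    """Diagonal multivariate normal log density (scale_diag = variances)."""
    mu = np.asarray(mu, dtype=np.float64).ravel()
    scale_diag = np.asarray(scale_diag, dtype=np.float64).ravel()
    if not np.all(scale_diag > 0):
        raise ValueError("all scale entries must be strictly positive")
    y = _check_vector(y, mu.size)
    return float(log_gaussian_terms(y, mu, scale_diag, mu.size))


def component_log_densities(y, mix: MixtureParams) -> np.ndarray:
    """Per-component log densities log T_k(y), shape (K,)."""
    y = _check_vector(y, mix.d)
    return np.array([log_student_t(y, c) for c in mix.components])


def log_mixture(y, mix: MixtureParams) -> float:
    """log sum_k pi_k T_k(y) via log-sum-exp; finite for any finite y."""
    comp = component_log_densities(y, mix)
    with np.errstate(divide="ignore"):  # zero weights are legal
        logw = np.log(mix.weights)
    return float(ad.logsumexp(logw + comp, axis=-1))


def constrain_params(raw: RawHeadOutput) -> MixtureParams:
    """Map unconstrained head outputs onto the mixture parameter space.

    weights = softmax(logits); scale = exp(clamped log-scale);
    nu = 2 + softplus(raw_nu), or infinity (Gaussian) when raw_nu is None.
    """
    weights = ad.softmax(raw.weight_logits, axis=-1)
    log_scale = np.clip(raw.raw_log_scale, -LOG_SCALE_CLAMP, LOG_SCALE_CLAMP)
    scales = np.exp(log_scale)
    K = raw.weight_logits.size
    if raw.raw_nu is None:
        nus = np.full(K, math.inf)
    else:
        nus = 2.0 + ad.softplus(raw.raw_nu)
    comps = [
        StudentTParams(mu=raw.raw_mu[k], scale_diag=scales[k], nu=float(nus[k]))
        for k in range(K)
    ]
    return MixtureParams(weights=weights, components=comps)


def sample_mixture(mix: MixtureParams, n: int, seed: int) -> np.ndarray:
    """Draw n samples via the Gaussian / chi-square composition.

    If u ~ N(0, Sigma) and w ~ chi2(nu)/nu then mu + u / sqrt(w) is
    Student-t(mu, Sigma, nu).  Reproducible from the seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    ks = rng.choice(mix.K, size=n, p=mix.weights)
    out = np.empty((n, mix.d))
    for k in range(mix.K):
        idx = np.flatnonzero(ks == k)
        if idx.size == 0:
            continue
        c = mix.components[k]
        u = rng.standard_normal((idx.size, mix.d)) * np.sqrt(c.scale_diag)
        if math.isinf(c.nu):
            out[idx] = c.mu + u
        else:
            w = rng.chisquare(c.nu, size=(idx.size, 1)) / c.nu
            out[idx] = c.mu + u / np.sqrt(w)
    return out
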