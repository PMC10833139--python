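"""Synthetic multiview fixtures with analytically known ground truth.

Two generator families: a two-view rank-one latent-factor model with sparse
canonical directions (population canonical correlation 1/(1+sigma2)), and a
multiclass multiview model whose class means and shared latent factor live on
the same sparse per-view directions, giving a closed-form per-view Bayes
error for two classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .core_data import MultiViewData, Outcome
from .exceptions import ValidationError
from .sida import VariableNetwork

__all__ = [
    "GroundTruth",
    "generate_selp_data",
    "generate_sida_data",
    "generate_network_for_support",
    "generate_survival_from_scores",
]


@dataclass
class GroundTruth:
    """What the generator planted: supports, population quantities, seed."""

    supports: list[np.ndarray]
    seed: int | None
    rho_star: float | None = None  # population canonical correlation
    delta: float | None = None
    psi: float | None = None
    sigma2: float | None = None
    bayes_error: list[float] = field(default_factory=list)  # per view, K = 2 only
    directions: list[np.ndarray] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "supports": [s.tolist() for s in self.supports],
            "seed": self.seed,
            "rho_star": self.rho_star,
            "delta": self.delta,
            "psi": self.psi,
            "sigma2": self.sigma2,
            "bayes_error": list(self.bayes_error),
        }


def _sparse_direction(p: int, s: int, rng, random_weights: bool) -> np.ndarray:
    if not 1 <= s <= p:
        raise ValidationError(f"support size {s} invalid for p={p}")
    w = np.zeros(p)
    if random_weights:
        vals = rng.uniform(0.5, 1.5, size=s) * rng.choice([-1.0, 1.0], size=s)
        w[:s] = vals / np.linalg.norm(vals)
    else:
        w[:s] = 1.0 / np.sqrt(s)
    return w


def _assemble(views, outcome, seed_tag=""):
    n = views[0].shape[0]
    return MultiViewData(
        views=views,
        view_names=[f"view{i + 1}" for i in range(len(views))],
        feature_names=[
            [f"view{i + 1}_f{j + 1}" for j in range(v.shape[1])]
            for i, v in enumerate(views)
        ],
        sample_ids=[f"S{i + 1}" for i in range(n)],
        outcome=outcome,
    )


def generate_selp_data(
    n: int,
    p1: int,
    p2: int,
    s1: int,
    s2: int,
    sigma2: float,
    seed: int | None = None,
    random_weights: bool = False,
) -> tuple[MultiViewData, GroundTruth]:
    """Two-view latent-factor data: X_d = Z w_d' + E_d.

    Z is standard normal, w_d a unit vector supported on the first s_d
    coordinates (equal weights by default), E_d iid N(0, sigma2).  The
    population canonical correlation is 1/(1+sigma2).  A binary outcome
    indicator(Z + noise > 0) is attached for downstream prediction tests.
    """
    if sigma2 <= 0:
        raise ValidationError("sigma2 must be positive")
    rng = np.random.default_rng(seed)
    w1 = _sparse_direction(p1, s1, rng, random_weights)
    w2 = _sparse_direction(p2, s2, rng, random_weights)
    Z = rng.standard_normal(n)
    X1 = np.outer(Z, w1) + rng.normal(scale=np.sqrt(sigma2), size=(n, p1))
    X2 = np.outer(Z, w2) + rng.normal(scale=np.sqrt(sigma2), size=(n, p2))
    y = (Z + 0.5 * rng.standard_normal(n) > 0).astype(int)
    data = _assemble([X1, X2], Outcome("binary", values=y))
    truth = GroundTruth(
        supports=[np.arange(s1), np.arange(s2)],
        seed=seed,
        rho_star=1.0 / (1.0 + sigma2),
        sigma2=sigma2,
        directions=[w1, w2],
    )
    return data, truth


def generate_sida_data(
    n_per_class: int,
    K: int = 2,
    D: int = 2,
    p: list[int] | None = None,
    s: list[int] | None = None,
    delta: float = 2.0,
    psi: float = 0.5,
    sigma2: float = 0.25,
    seed: int | None = None,
) -> tuple[MultiViewData, GroundTruth]:
    """Multiclass multiview data with sparse discriminant directions.

    In view d, sample i of class k is (delta_k + psi Z_i) u_d' + noise with
    delta_k = (k - (K+1)/2) * delta and u_d the equal-weight unit vector on
    the first s_d coordinates; Z_i is a shared standard-normal latent factor
    inducing cross-view association.  For K = 2 the per-view Bayes error
    along u_d is Phi(-delta / (2 sqrt(psi^2 + sigma2))).
    """
    if K < 2:
        raise ValidationError("K must be >= 2")
    if sigma2 <= 0:
        raise ValidationError("sigma2 must be positive")
    p = p if p is not None else [50] * D
    s = s if s is not None else [10] * D
    if len(p) != D or len(s) != D:
        raise ValidationError("p and s must have one entry per view")
    rng = np.random.default_rng(seed)
    n = n_per_class * K
    labels = np.repeat(np.arange(1, K + 1), n_per_class)
    deltas = (labels - (K + 1) / 2.0) * delta
    Z = rng.standard_normal(n)
    signal = deltas + psi * Z
    views = []
    dirs = []
    for d in range(D):
        u = _sparse_direction(p[d], s[d], rng, False)
        X = np.outer(signal, u) + rng.normal(scale=np.sqrt(sigma2), size=(n, p[d]))
        views.append(X)
        dirs.append(u)
    perm = rng.permutation(n)
    views = [X[perm] for X in views]
    labels = labels[perm]
    kind = "binary" if K == 2 else "multiclass"
    data = _assemble(views, Outcome(kind, values=labels))
    bayes = [float(stats.norm.cdf(-delta / (2.0 * np.sqrt(psi**2 + sigma2))))] * D \
        if K == 2 else []
    truth = GroundTruth(
        supports=[np.arange(sd) for sd in s],
        seed=seed,
        delta=delta,
        psi=psi,
        sigma2=sigma2,
        bayes_error=bayes,
        directions=dirs,
    )
    return data, truth


def generate_network_for_support(
    p: int,
    support: np.ndarray,
    extra_edges: int = 0,
    seed: int | None = None,
    view_name: str = "view",
) -> VariableNetwork:
    """Adjacency with a connected module (path + random chords) on the support
    indices plus ``extra_edges`` random edges among the remaining variables."""
    support = np.asarray(support, dtype=int)
    if support.size and (support.min() < 0 or support.max() >= p):
        raise ValidationError("support indices out of range")
    rng = np.random.default_rng(seed)
    A = np.zeros((p, p))
    for a, b in zip(support[:-1], support[1:]):
        A[a, b] = A[b, a] = 1.0
    s = support.size
    if s > 2:
        for _ in range(s // 2):  # random chords inside the module
            i, j = rng.choice(support, size=2, replace=False)
            if i != j:
                A[i, j] = A[j, i] = 1.0
    others = np.setdiff1d(np.arange(p), support)
    if others.size >= 2:
        for _ in range(extra_edges):
            i, j = rng.choice(others, size=2, replace=False)
            A[i, j] = A[j, i] = 1.0
    return VariableNetwork(view_name=view_name, adjacency=A)


def generate_survival_from_scores(
    scores: np.ndarray,
    beta: np.ndarray | float,
    censor_rate: float = 0.0,
    seed: int | None = None,
) -> Outcome:
    """Exponential survival times with rate exp(scores . beta) and independent
    exponential censoring calibrated to the requested censored fraction."""
    if not 0 <= censor_rate < 1:
        raise ValidationError("censor_rate must be in [0, 1)")
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] == 1 and scores.shape[1] > 1 and np.ndim(beta) == 0:
        scores = scores.T
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    rng = np.random.default_rng(seed)
    rate = np.exp(scores @ beta)
    T = rng.exponential(1.0 / rate)
    if censor_rate == 0:
        return Outcome("survival", time=T, event=np.ones_like(T))

    def expected_censored(rc):
        return float(np.mean(rc / (rc + rate))) - censor_rate

    rc = optimize.brentq(expected_censored, 1e-10, 1e6)
    C = rng.exponential(1.0 / rc, size=T.shape)
    time = np.minimum(T, C)
    event = (T <= C).astype(float)
    return Outcome("survival", time=time, event=event)
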