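"""Critical dynamics of gene-regulatory networks.

The aging-at-criticality picture: the linearized regulatory network
``dx/dt = K x + noise`` sits next to an order-disorder bifurcation, so exactly
one eigenvalue of the interaction matrix ``K`` is small and positive (the
network "stiffness" ``alpha``) while all others are strongly negative.  The
amplitude ``z`` of the unstable mode — the biological age — then follows the
scalar Langevin equation

    dz = alpha * z * dt + sigma * dW,

deviating exponentially from the youthful state.  Death is modelled as the
first passage of the deviation magnitude ``|z|`` over a threshold ``z_crit``:
large excursions of gene expression from the youthful state, in either
direction along the critical mode, are incompatible with survival.  This
mechanism yields Gompertz-like mortality near the mean lifespan and a
late-life mortality plateau at the level of ``alpha`` itself.

The module provides the scalar process, its first-passage mortality, the
Gompertz closed forms, and the full near-critical network SDE used to verify
the one-factor reduction (covariance ~ b_i b_j exp(alpha t)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import rng_from
from .events import event_table

__all__ = [
    "LangevinParams",
    "GompertzLaw",
    "NetworkModel",
    "simulate_z_paths",
    "first_passage_times",
    "gompertz_survival",
    "gompertz_cumhaz",
    "build_near_critical_network",
    "simulate_network_sde",
]

# Paths are advanced in blocks of this many time steps to bound memory for
# large cohorts (2e4 paths x ~1e3-1e4 steps).
_CHUNK_STEPS = 512


@dataclass(frozen=True)
class LangevinParams:
    """Parameters of the scalar critical-mode Langevin process.

    Attributes
    ----------
    alpha:
        Network stiffness / Gompertz exponent, 1/day.
    sigma:
        Noise amplitude, z-units per sqrt(day).
    z0:
        Initial order parameter (>= 0).
    z_crit:
        Death threshold on ``|z|``; must exceed ``z0``.
    dt:
        Euler-Maruyama step, days.  A good default is ``0.01 / alpha``.
    t_max:
        Simulation horizon, days.  Paths alive at ``t_max`` are censored.
    seed:
        Integer seed; all randomness derives from it.
    """

    alpha: float
    sigma: float
    z0: float
    z_crit: float
    dt: float
    t_max: float
    seed: int = 0

    def __post_init__(self) -> None:
        vals = [self.alpha, self.sigma, self.z0, self.z_crit, self.dt, self.t_max]
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("LangevinParams requires finite parameters")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.t_max < 0:
            raise ValueError("t_max must be >= 0")
        if not (self.z_crit > self.z0 >= 0):
            raise ValueError("need z_crit > z0 >= 0")

    @classmethod
    def for_rate(
        cls,
        alpha: float,
        sigma: float,
        z0: float = 0.01,
        z_crit: float = 1.0,
        horizon_lifespans: float = 3.2,
        seed: int = 0,
    ) -> "LangevinParams":
        """Convenience constructor: dt = 0.01/alpha, horizon in units of the
        deterministic lifespan ln(z_crit/z0)/alpha (requires z0 > 0)."""
        if z0 <= 0:
            raise ValueError("for_rate needs z0 > 0 to set the horizon")
        t_det = math.log(z_crit / z0) / alpha
        return cls(alpha, sigma, z0, z_crit, 0.01 / alpha, horizon_lifespans * t_det, seed)

    @property
    def n_steps(self) -> int:
        return int(math.floor(self.t_max / self.dt + 1e-9))

    def time_grid(self) -> np.ndarray:
        return np.arange(self.n_steps + 1) * self.dt

    def mean_z(self, t) -> np.ndarray:
        """E z(t) = z0 exp(alpha t) for the free process."""
        return self.z0 * np.exp(self.alpha * np.asarray(t, float))

    def var_z(self, t) -> np.ndarray:
        """Var z(t) = sigma^2 (exp(2 alpha t) - 1) / (2 alpha)."""
        t = np.asarray(t, float)
        return self.sigma**2 * np.expm1(2.0 * self.alpha * t) / (2.0 * self.alpha)


def simulate_z_paths(params: LangevinParams, n_paths: int) -> np.ndarray:
    """Euler-Maruyama paths of the free (unbounded) critical mode.

    Returns an array of shape ``(n_paths, n_steps + 1)`` whose column 0 is
    ``z0``.  The free process has the closed-form moments exposed by
    :meth:`LangevinParams.mean_z` / :meth:`LangevinParams.var_z`, which tests
    use as the oracle.
    """
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    rng = rng_from(params.seed, 1)
    n_steps = params.n_steps
    out = np.empty((n_paths, n_steps + 1), dtype=float)
    out[:, 0] = params.z0
    z = out[:, 0].copy()
    a_dt = params.alpha * params.dt
    s_dt = params.sigma * math.sqrt(params.dt)
    for k in range(1, n_steps + 1):
        z = z + a_dt * z + s_dt * rng.standard_normal(n_paths)
        out[:, k] = z
    return out


def first_passage_times(
    params: LangevinParams, n_paths: int, group: str = "sim"
) -> pd.DataFrame:
    """First-passage death times of the critical mode.

    A path dies at the first grid time where ``|z| >= z_crit``; paths that
    never cross within ``t_max`` are right-censored (event = 0).  The noise
    stream matches :func:`simulate_z_paths` draw-for-draw, so at a fixed seed
    raising ``z_crit`` can only delay any individual death.
    """
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    rng = rng_from(params.seed, 1)
    n_steps = params.n_steps
    z = np.full(n_paths, params.z0, dtype=float)
    t_death = np.full(n_paths, params.t_max, dtype=float)
    dead = np.zeros(n_paths, dtype=bool)
    a_dt = params.alpha * params.dt
    s_dt = params.sigma * math.sqrt(params.dt)
    for k in range(1, n_steps + 1):
        # Draw for every path (dead ones included) to keep the stream aligned
        # with simulate_z_paths and invariant under the threshold.
        z = z + a_dt * z + s_dt * rng.standard_normal(n_paths)
        crossed = (~dead) & (np.abs(z) >= params.z_crit)
        if crossed.any():
            t_death[crossed] = k * params.dt
            dead[crossed] = True
    return event_table(t_death, dead.astype(int), group)


@dataclass(frozen=True)
class GompertzLaw:
    """Gompertz mortality: hazard M(t) = M0 exp(alpha t).

    ``alpha`` is the mortality-rate doubling exponent (doubling time
    ln2/alpha); ``alpha = 0`` is the constant-hazard (exponential) limit.
    """

    M0: float
    alpha: float

    def __post_init__(self) -> None:
        if not (self.M0 > 0):
            raise ValueError("M0 must be > 0")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")

    def hazard(self, t) -> np.ndarray:
        return self.M0 * np.exp(self.alpha * np.asarray(t, float))

    def mean_lifespan(self) -> float:
        """Numerical mean of the law, integral of S(t)."""
        from scipy.integrate import quad

        scale = 1.0 / max(self.alpha, self.M0)
        val, _ = quad(lambda t: gompertz_survival(self, t), 0, 200 * scale, limit=500)
        return float(val)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Inverse-CDF sampling of death times."""
        u = rng.uniform(size=n)
        if self.alpha == 0:
            return -np.log(u) / self.M0
        return np.log1p(-self.alpha * np.log(u) / self.M0) / self.alpha


def _check_t(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    return t


def gompertz_cumhaz(law: GompertzLaw, t) -> np.ndarray:
    """Cumulative hazard m(t) = (M0/alpha)(exp(alpha t) - 1); M0*t as alpha->0."""
    t = _check_t(t)
    if law.alpha == 0:
        return law.M0 * t
    return law.M0 / law.alpha * np.expm1(law.alpha * t)


def gompertz_survival(law: GompertzLaw, t) -> np.ndarray:
    """Survival fraction S(t) = exp(-m(t))."""
    return np.exp(-gompertz_cumhaz(law, t))


@dataclass(frozen=True)
class NetworkModel:
    """Near-critical linear regulatory network.

    ``K`` has exactly one eigenvalue with positive real part (= ``alpha``);
    every other eigenvalue has real part <= -``gap``.  ``b`` is the unit-norm
    right eigenvector of the critical mode, ``a`` the left eigenvector
    normalized so that a . b = 1; projecting trajectories on ``a`` recovers
    the scalar order parameter.  ``f0`` is the constant drive, zero by the
    centering convention (the baseline state is absorbed into the observation
    model).
    """

    K: np.ndarray
    alpha: float
    b: np.ndarray
    a: np.ndarray
    gap: float
    f0: float = 0.0

    def validate(self, rtol: float = 1e-8) -> None:
        eig = np.linalg.eigvals(self.K)
        pos = eig[eig.real > 0]
        if len(pos) != 1:
            raise ValueError("K must have exactly one eigenvalue with Re > 0")
        if abs(pos[0].real - self.alpha) > 1e-9 * max(1.0, abs(self.alpha)):
            raise ValueError("positive eigenvalue does not equal alpha")
        neg = eig[eig.real <= 0]
        if np.any(neg.real > -self.gap * (1 - 1e-9)):
            raise ValueError("stable eigenvalues violate the spectral gap")
        if abs(np.linalg.norm(self.b) - 1.0) > 1e-12:
            raise ValueError("b must be unit norm")
        if abs(float(self.a @ self.b) - 1.0) > 1e-12:
            raise ValueError("a . b must equal 1")
        if np.linalg.norm(self.K @ self.b - self.alpha * self.b) > rtol * abs(self.alpha):
            raise ValueError("b is not a right eigenvector at alpha")
        if np.linalg.norm(self.a @ self.K - self.alpha * self.a) > rtol * abs(self.alpha):
            raise ValueError("a is not a left eigenvector at alpha")

    @property
    def n_genes(self) -> int:
        return self.K.shape[0]


def build_near_critical_network(
    G: int,
    alpha: float,
    gap: float,
    seed: int = 0,
    max_tries: int = 10,
    max_cond: float = 100.0,
) -> NetworkModel:
    """Construct K = Q diag(alpha, -lam_2 ... -lam_G) Q^-1.

    ``Q`` is a random, well-conditioned basis (redrawn up to ``max_tries``
    times if its condition number exceeds ``max_cond``); the stable rates
    ``lam_k`` are drawn uniformly in [gap, 3 gap].
    """
    if G < 2:
        raise ValueError("G must be >= 2")
    if not (gap > alpha > 0):
        raise ValueError("need gap > alpha > 0")
    rng = rng_from(seed, 2)
    for _ in range(max_tries):
        Q = rng.standard_normal((G, G))
        if np.linalg.cond(Q) <= max_cond:
            break
    else:
        raise RuntimeError(
            f"could not draw a basis with condition number <= {max_cond}"
        )
    lam = rng.uniform(gap, 3.0 * gap, size=G - 1)
    D = np.diag(np.concatenate([[alpha], -lam]))
    Qinv = np.linalg.inv(Q)
    K = Q @ D @ Qinv
    b = Q[:, 0] / np.linalg.norm(Q[:, 0])
    a_raw = Qinv[0, :]
    a = a_raw / float(a_raw @ b)
    model = NetworkModel(K=K, alpha=alpha, b=b, a=a, gap=float(lam.min()))
    model.validate()
    return model


def simulate_network_sde(
    net: NetworkModel,
    noise_sd: float,
    dt: float,
    t_max: float,
    n_paths: int,
    seed: int = 0,
    x0: np.ndarray | None = None,
) -> np.ndarray:
    """Euler-Maruyama trajectories of dx = K x dt + noise_sd dW (per gene).

    Returns ``(n_paths, n_steps + 1, G)``.  The explicit scheme requires
    ``dt * gap <= 0.5``; violating it raises a stability error.  At times
    ``t >> 1/gap`` the empirical covariance is dominated by the critical
    mode, so its leading eigenvector aligns with ``b``.
    """
    if dt * net.gap > 0.5:
        raise ValueError(
            f"dt*gap = {dt * net.gap:.3g} > 0.5: explicit scheme unstable; reduce dt"
        )
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    G = net.n_genes
    n_steps = int(math.floor(t_max / dt + 1e-9))
    rng = rng_from(seed, 3)
    out = np.empty((n_paths, n_steps + 1, G), dtype=float)
    if x0 is None:
        x0 = np.zeros(G)
    out[:, 0, :] = np.asarray(x0, float)
    x = out[:, 0, :].copy()
    s_dt = noise_sd * math.sqrt(dt)
    for k in range(1, n_steps + 1):
        x = x + dt * (x @ net.K.T) + s_dt * rng.standard_normal((n_paths, G))
        out[:, k, :] = x
    return out
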