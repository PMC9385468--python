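"""Gaussian mean-field approximation of the steady densities.

For dimensions where a grid solve of the generalized Fokker-Planck equation
is impractical, both steady densities are approximated by Gaussian mixtures
with one component per stable fixed point of the deterministic flow
dx/dt = b(x):

    p(x) ~ sum_k rho^(k) N(x; mu_(k), eps Sigma_(k)).

Component moments come from the small-noise moment closure

    d mu/dt    = b(mu) + (eps/2) * [sum_jl d2b_i/dx_j dx_l * Sigma_jl]_i,
    d Sigma/dt = J(mu) Sigma + Sigma J(mu)^T + 2 I,

(the covariance in Sigma-units; the physical covariance is eps Sigma, and the
noise term is 2I because the diffusion coefficient is sqrt(2 eps)).  The
closure is exact for linear drift, where the steady Sigma solves the
Lyapunov equation J Sigma + Sigma J^T = -2I.

Mixture weights: rho0 (no birth-death) are basin-occupancy fractions of
trajectories started uniformly on the domain; rhoU corrects them with the
component-averaged birth-death rates R_k and basin exit rates q_k via

    rhoU^(k) = rho0^(k) q_k / (q_k - R_k),

closed with 1/q_k proportional to rho0^(k) (long-lived basins are the big
ones).  The single proportionality constant is fixed by the steady balance
sum_k rhoU^(k) R_k = 0 when that equation admits a root; otherwise an
explicit exit-rate scale is used and the rates are recentred so the balance
holds for R - lambda (a warning is emitted).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import linalg, optimize
from scipy.integrate import solve_ivp

from .models import DifferentiationModel, numeric_derivatives

logger = logging.getLogger(__name__)

__all__ = [
    "FixedPoint",
    "GaussianComponent",
    "GaussianMixture",
    "RateSummary",
    "find_fixed_points",
    "moment_odes",
    "component_rate",
    "estimate_rho0",
    "estimate_rhoU",
    "assemble_mixture",
    "evolve_weights",
    "save_mixture",
    "load_mixture",
]


@dataclass
class FixedPoint:
    """A root of the drift with its linear stability classification."""

    location: np.ndarray
    stability: str  # stable | saddle | unstable
    eigenvalues_real: np.ndarray

    def __post_init__(self):
        self.location = np.asarray(self.location, dtype=float)
        self.eigenvalues_real = np.asarray(self.eigenvalues_real, dtype=float)


@dataclass
class GaussianComponent:
    """One mixture component: mean mu and shape Sigma (covariance eps*Sigma)."""

    mu: np.ndarray
    sigma: np.ndarray
    basin: int = 0

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.sigma.shape != (self.mu.size, self.mu.size):
            raise ValueError("sigma must be n x n")
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-10):
            raise ValueError("sigma must be symmetric")
        if np.linalg.eigvalsh(self.sigma).min() <= 0:
            raise ValueError("sigma must be positive definite")


class GaussianMixture:
    """Evaluable Gaussian mixture sum_k w_k N(x; mu_k, eps Sigma_k)."""

    def __init__(
        self,
        components: Sequence[GaussianComponent],
        weights: Sequence[float],
        epsilon: float,
        kind: str = "P0",
    ):
        weights = np.asarray(weights, dtype=float).ravel()
        if len(components) != weights.size:
            raise ValueError("weight/component count mismatch")
        if np.any(weights <= 0):
            raise ValueError("mixture weights must be positive")
        if abs(weights.sum() - 1.0) > 1e-8:
            raise ValueError("mixture weights must sum to 1")
        if kind not in ("P0", "PU"):
            raise ValueError("kind must be 'P0' or 'PU'")
        self.components = list(components)
        self.weights = weights / weights.sum()
        self.epsilon = float(epsilon)
        self.kind = kind
        self._prepare()

    def _prepare(self):
        self._chol = []
        self._logdet = []
        n = self.dim
        for c in self.components:
            cov = self.epsilon * c.sigma
            L = np.linalg.cholesky(cov)
            self._chol.append(L)
            self._logdet.append(2.0 * np.log(np.diag(L)).sum())
        self._lognorm = [
            -0.5 * (n * np.log(2.0 * np.pi) + ld) for ld in self._logdet
        ]

    @property
    def dim(self) -> int:
        return self.components[0].mu.size

    @property
    def n_components(self) -> int:
        return len(self.components)

    def component_logpdfs(self, x: np.ndarray) -> np.ndarray:
        """Log densities of each component at x, shape (..., K)."""
        x = np.asarray(x, dtype=float)
        out = np.empty(x.shape[:-1] + (self.n_components,))
        for k, c in enumerate(self.components):
            d = x - c.mu
            sol = linalg.solve_triangular(
                self._chol[k], d.reshape(-1, self.dim).T, lower=True
            )
            q = (sol**2).sum(axis=0).reshape(x.shape[:-1])
            out[..., k] = self._lognorm[k] - 0.5 * q
        return out

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        from scipy.special import logsumexp

        lp = self.component_logpdfs(x)
        return logsumexp(lp + np.log(self.weights), axis=-1)

    def pdf(self, x: np.ndarray) -> np.ndarray:
        return np.exp(self.logpdf(x))

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.pdf(x)


@dataclass
class RateSummary:
    """Component rates R_k, exit rates q_k and the closure constant c."""

    component_rates: np.ndarray
    exit_rates: np.ndarray
    closure_constant: float
    growth_rate: float = 0.0
    fallback: bool = False

    def __post_init__(self):
        self.component_rates = np.asarray(self.component_rates, dtype=float)
        self.exit_rates = np.asarray(self.exit_rates, dtype=float)
        if np.any(self.exit_rates <= 0):
            raise ValueError("exit rates must be positive")
        if np.any(self.exit_rates <= self.component_rates - self.growth_rate):
            raise ValueError("exit rates must exceed the (recentred) basin rates")


# ---------------------------------------------------------------------------
# fixed points
# ---------------------------------------------------------------------------


def find_fixed_points(
    model: DifferentiationModel,
    n_starts: int = 64,
    seed: int = 0,
    tol: float = 1e-9,
) -> list[FixedPoint]:
    """Multistart root census of the drift, deduplicated and classified.

    Random uniform starts on the domain (plus the domain center) are polished
    with a damped Newton/hybrid solver; roots with ||b|| < tol are kept,
    deduplicated at 1e-6 of the domain extent, and classified by the real
    parts of the drift-Jacobian eigenvalues.  Deterministic given the seed.
    """
    if n_starts < 25:
        raise ValueError("use at least 25 starts for a trustworthy census")
    rng = np.random.default_rng(seed)
    starts = model.domain.sample_uniform(rng, n_starts)
    center = 0.5 * (np.asarray(model.domain.lower) + np.asarray(model.domain.upper))
    starts = np.vstack([center, starts])
    der = numeric_derivatives(model)

    def b_point(x):
        return np.asarray(model.drift(np.asarray(x, dtype=float)), dtype=float)

    dedup_tol = 1e-6 * float(model.domain.extent.max())
    roots: list[np.ndarray] = []
    for x0 in starts:
        sol = optimize.root(
            b_point, x0, jac=lambda x: np.asarray(der.jacobian(x), dtype=float),
            method="hybr", tol=1e-12,
        )
        if not sol.success:
            continue
        x = sol.x
        if np.linalg.norm(b_point(x)) >= tol:
            continue
        lo = np.asarray(model.domain.lower) - 0.05 * model.domain.extent
        hi = np.asarray(model.domain.upper) + 0.05 * model.domain.extent
        if np.any(x < lo) or np.any(x > hi):
            continue
        if all(np.linalg.norm(x - r) > dedup_tol for r in roots):
            roots.append(x)

    out = []
    for x in roots:
        J = np.asarray(der.jacobian(x), dtype=float)
        re = np.sort(np.real(np.linalg.eigvals(J)))
        if np.all(re < 0):
            stability = "stable"
        elif np.all(re > 0):
            stability = "unstable"
        else:
            stability = "saddle"
        out.append(FixedPoint(location=x, stability=stability, eigenvalues_real=re))
    out.sort(key=lambda fp: tuple(np.round(fp.location, 9)))
    if not any(fp.stability == "stable" for fp in out):
        raise RuntimeError("no stable fixed point found; increase n_starts")
    return out


# ---------------------------------------------------------------------------
# moment closure
# ---------------------------------------------------------------------------


def _hessian_contraction(hess, x, sigma):
    H = np.asarray(hess(x), dtype=float)  # (n, n, n): H[i, j, l]
    return np.einsum("ijl,jl->i", H, sigma)


def moment_odes(
    model: DifferentiationModel,
    start: FixedPoint,
    t_end: float = 20.0,
    epsilon: Optional[float] = None,
) -> GaussianComponent:
    """Steady component moments (mu, Sigma) around a stable fixed point.

    Integrates the moment closure from (mu = fixed point, Sigma = 0), then
    polishes to the exact steady state by alternating a Lyapunov solve for
    Sigma with a Newton solve for mu.  At eps = 0 the mean equation reduces
    to b(mu) = 0 and mu stays at the fixed point.

    Aborts with a diagnostic when Sigma loses positive definiteness or the
    alternation does not contract -- both indicate a non-attracting (or
    marginally stable, near-bifurcation) start or an eps too large for the
    Gaussian regime.
    """
    if start.stability != "stable":
        raise ValueError("moment closure requires a stable starting point")
    eps = model.epsilon if epsilon is None else float(epsilon)
    n = model.dim
    der = numeric_derivatives(model)
    scale = float(model.domain.extent.max())

    def jac(x):
        return np.asarray(der.jacobian(x), dtype=float)

    def mean_rhs(mu, sigma):
        b = np.asarray(model.drift(mu), dtype=float)
        if eps == 0.0:
            return b
        return b + 0.5 * eps * _hessian_contraction(der.hessian, mu, sigma)

    def rhs(t, y):
        mu = y[:n]
        sigma = y[n:].reshape(n, n)
        J = jac(mu)
        dmu = mean_rhs(mu, sigma)
        dsig = J @ sigma + sigma @ J.T + 2.0 * np.eye(n)
        return np.concatenate([dmu, dsig.ravel()])

    def runaway(t, y):
        # stop if the mean wanders basin-scale away or Sigma blows up
        return (2.0 * scale - np.abs(y[:n] - start.location).max()) * (
            1e4 - np.abs(y[n:]).max()
        )

    runaway.terminal = True

    y0 = np.concatenate([start.location, np.zeros(n * n)])
    sol = solve_ivp(
        rhs, (0.0, t_end), y0, method="RK45", rtol=1e-6, atol=1e-9, events=runaway
    )
    if sol.status == 1:  # runaway event: restart the polish from the fixed point
        mu = start.location.copy()
        sigma = np.eye(n)
    else:
        mu = sol.y[:n, -1]
        sigma = 0.5 * (sol.y[n:, -1].reshape(n, n) + sol.y[n:, -1].reshape(n, n).T)

    # polish: alternate Lyapunov solve for Sigma and Newton solve for mu
    delta = np.inf
    for _ in range(100):
        J = jac(mu)
        sigma_new = linalg.solve_continuous_lyapunov(J, -2.0 * np.eye(n))
        sigma_new = 0.5 * (sigma_new + sigma_new.T)
        res = optimize.root(
            lambda m: mean_rhs(m, sigma_new), mu, jac=lambda m: jac(m), tol=1e-14
        )
        mu_new = res.x if res.success else mu
        delta = max(np.abs(mu_new - mu).max(), np.abs(sigma_new - sigma).max())
        mu, sigma = mu_new, sigma_new
        if delta < 1e-12:
            break
    if not delta < 1e-8:
        raise RuntimeError(
            "moment closure did not reach a steady state (last update "
            f"{delta:.2e}): the component is marginally stable or eps is too "
            "large for the Gaussian regime"
        )

    if np.linalg.eigvalsh(sigma).min() <= 0:
        raise RuntimeError(
            "moment closure lost positive definiteness: the start is not "
            "attracting or eps is too large for the Gaussian regime"
        )
    return GaussianComponent(mu=mu, sigma=sigma, basin=0)


# ---------------------------------------------------------------------------
# component rates
# ---------------------------------------------------------------------------


def component_rate(
    model: DifferentiationModel,
    component: GaussianComponent,
    epsilon: Optional[float] = None,
    n_nodes: int = 8,
    mc_samples: int = 1 << 15,
    seed: int = 0,
) -> float:
    """Gaussian expectation R_k = E[R(X)], X ~ N(mu, eps Sigma).

    Tensor Gauss-Hermite cubature for dim <= 5 (exact for polynomial rates up
    to degree 2*n_nodes - 1, which covers the quartic example rates), plain
    Monte Carlo with a fixed seed above that.
    """
    eps = model.epsilon if epsilon is None else float(epsilon)
    n = model.dim
    cov = eps * component.sigma
    L = np.linalg.cholesky(cov)
    if n <= 5:
        nodes, wts = np.polynomial.hermite.hermgauss(n_nodes)
        grids = np.meshgrid(*([nodes] * n), indexing="ij")
        Z = np.stack([g.ravel() for g in grids], axis=-1)  # (m^n, n)
        W = np.ones(Z.shape[0])
        for g in np.meshgrid(*([wts] * n), indexing="ij"):
            W *= g.ravel() / np.sqrt(np.pi)
        X = component.mu + np.sqrt(2.0) * Z @ L.T
        vals = np.asarray(model.rate(X), dtype=float)
        if not np.all(np.isfinite(vals)):
            raise RuntimeError("rate cubature hit non-finite values")
        return float(W @ vals)
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((mc_samples, n))
    X = component.mu + Z @ L.T
    vals = np.asarray(model.rate(X), dtype=float)
    return float(vals.mean())


# ---------------------------------------------------------------------------
# mixture weights
# ---------------------------------------------------------------------------


def estimate_rho0(
    model: DifferentiationModel,
    fixed_points: Sequence[FixedPoint],
    n_particles: int = 50000,
    T: Optional[float] = None,
    dt: Optional[float] = None,
    seed: int = 20220617,
    check_convergence: bool = True,
) -> np.ndarray:
    """Basin-occupancy weights rho0 by unweighted trajectory simulation.

    Uniform initial law on the domain; the ending time doubles until the
    occupancy drift between T and 2T falls below three Monte-Carlo standard
    errors (metastable hopping is exponentially slow at small eps, so the
    fractions settle on the O(1) relaxation timescale).
    """
    from . import fk_sim

    stable = [fp for fp in fixed_points if fp.stability == "stable"]
    if not stable:
        raise ValueError("need at least one stable fixed point")
    if len(stable) == 1:
        return np.array([1.0])
    if T is None:
        T = 10.0
    ens = fk_sim.simulate_ensemble(
        model, n_particles, T, dt=dt, seed=seed, use_rate=False
    )
    occ = fk_sim.basin_occupancy(ens, stable, model)
    rho = occ["rho0"]
    if check_convergence:
        se = np.sqrt(np.maximum(rho * (1 - rho), 1e-12) / n_particles)
        for _ in range(2):
            ens2 = fk_sim.simulate_ensemble(
                model, n_particles, 2 * T, dt=dt, seed=seed, use_rate=False
            )
            rho2 = fk_sim.basin_occupancy(ens2, stable, model)["rho0"]
            if np.all(np.abs(rho2 - rho) <= 3.0 * se + 1e-12):
                rho = rho2
                break
            logger.info("basin occupancy still drifting; doubling T to %.1f", 2 * T)
            T *= 2
            rho = rho2
    rho = np.maximum(rho, 1e-12)
    return rho / rho.sum()


def residence_weights(
    rho0: np.ndarray, rates: np.ndarray, exit_rates: np.ndarray
) -> np.ndarray:
    """Proliferation-corrected weights at fixed exit rates.

    Each basin's occupancy is inflated by the expected weight accumulated
    over one residence (exponential with rate q_k under birth-death rate
    R_k):  w_k = rho0_k q_k / (q_k - R_k),  normalized.  Requires q_k > R_k.
    Monotone: raising one R_k (others fixed) never lowers that component's
    normalized weight.
    """
    rho0 = np.asarray(rho0, dtype=float).ravel()
    rates = np.asarray(rates, dtype=float).ravel()
    exit_rates = np.asarray(exit_rates, dtype=float).ravel()
    if np.any(exit_rates <= rates):
        raise ValueError("exit rates must exceed the basin rates (q_k > R_k)")
    w = rho0 * exit_rates / (exit_rates - rates)
    return w / w.sum()


def estimate_rhoU(
    rho0: np.ndarray,
    rates: np.ndarray,
    exit_rate_scale: Optional[float] = None,
) -> tuple[np.ndarray, RateSummary]:
    """Proliferation-corrected mixture weights rhoU from rho0 and R_k.

    Closure: q_k = c / rho0_k with a single constant c.  Primary path: c > 0
    solves the steady balance sum_k rhoU_k(c) R_k = 0 (bracketed bisection;
    admissible iff the rates change sign appropriately).  If no admissible c
    exists, c falls back to ``exit_rate_scale`` (default max|R_k| + 1, made
    admissible) with a prominent warning, and the rates are recentred by a
    growth rate lambda chosen so the balance holds for R - lambda.
    """
    rho0 = np.asarray(rho0, dtype=float).ravel()
    rates = np.asarray(rates, dtype=float).ravel()
    if rho0.size != rates.size:
        raise ValueError("rho0 and rates must have equal length")
    if np.any(rho0 <= 0) or abs(rho0.sum() - 1.0) > 1e-8:
        raise ValueError("rho0 must be positive and sum to 1")
    K = rho0.size

    def weights_for(c: float, r: np.ndarray) -> np.ndarray:
        # q_k = c / rho0_k under the closure 1/q_k ~ rho0_k
        return residence_weights(rho0, r, c / rho0)

    span = float(np.ptp(rates))
    if span < 1e-14:
        lam = float(rates[0]) if K else 0.0
        c = exit_rate_scale if exit_rate_scale else 1.0
        summary = RateSummary(
            component_rates=rates,
            exit_rates=np.full(K, c) / rho0,
            closure_constant=float(c),
            growth_rate=lam,
        )
        return rho0.copy(), summary

    cmin = float(np.max(rho0 * rates))  # admissibility: c > cmin keeps q_k > R_k

    def balance(c: float) -> float:
        return float(weights_for(c, rates) @ rates)

    c_root = None
    mean0 = float(rho0 @ rates)
    if cmin > 0 and mean0 < 0:
        # balance -> +inf as c -> cmin+, -> mean0 < 0 as c -> inf: root exists
        a = cmin * (1.0 + 1e-10) + 1e-300
        b = max(2.0 * cmin, cmin + 1.0)
        for _ in range(200):
            if balance(b) < 0:
                break
            b *= 2.0
        else:
            b = None
        if b is not None:
            c_root = optimize.brentq(balance, a, b, xtol=1e-14, rtol=1e-14)

    if c_root is not None:
        rhoU = weights_for(c_root, rates)
        lam = float(rhoU @ rates)  # ~0 by construction
        summary = RateSummary(
            component_rates=rates,
            exit_rates=c_root / rho0,
            closure_constant=c_root,
            growth_rate=lam,
        )
        return rhoU, summary

    # fallback: explicit exit-rate scale, recentre the rates by lambda
    c = exit_rate_scale if exit_rate_scale is not None else float(np.abs(rates).max()) + 1.0
    logger.warning(
        "no admissible closure constant balances the raw rates; using exit-rate "
        "scale c = %.4g and recentring the rates by a growth rate", c
    )

    def balance_lam(lam: float) -> float:
        r = rates - lam
        cm = float(np.max(rho0 * r))
        cc = max(c, 2.0 * cm if cm > 0 else c)
        w = weights_for(cc, r)
        return float(w @ r)

    lo, hi = float(rates.min()), float(rates.max())
    lam = optimize.brentq(balance_lam, lo, hi, xtol=1e-14)
    r = rates - lam
    cm = float(np.max(rho0 * r))
    cc = max(c, 2.0 * cm if cm > 0 else c)
    rhoU = weights_for(cc, r)
    summary = RateSummary(
        component_rates=rates,
        exit_rates=cc / rho0,
        closure_constant=cc,
        growth_rate=lam,
        fallback=True,
    )
    return rhoU, summary


def assemble_mixture(
    components: Sequence[GaussianComponent],
    weights: Sequence[float],
    kind: str,
    epsilon: float,
) -> GaussianMixture:
    """Evaluable mixture density sum_k w_k N(x; mu_k, eps Sigma_k)."""
    return GaussianMixture(components, weights, epsilon=epsilon, kind=kind)


def evolve_weights(
    Q: np.ndarray,
    rates: np.ndarray,
    rho_init: np.ndarray,
    T: float,
    n_out: int = 50,
) -> dict:
    """Integrate the upscaled weight dynamics for a known rate matrix Q:

        d rhoU/dt = Q^T rhoU + diag(R) rhoU,    d rho0/dt = Q^T rho0.

    Q must be a generator (rows sum to zero, off-diagonals >= 0).  The rhoU
    trajectory is renormalized on output and the implied growth logged.
    Returns dict with times, rho0, rhoU (normalized), rhoU_total.
    """
    Q = np.asarray(Q, dtype=float)
    rates = np.asarray(rates, dtype=float).ravel()
    rho_init = np.asarray(rho_init, dtype=float).ravel()
    K = rho_init.size
    if Q.shape != (K, K):
        raise ValueError("Q must be K x K")
    if np.abs(Q.sum(axis=1)).max() > 1e-10:
        raise ValueError("Q rows must sum to zero (generator matrix)")
    offdiag = Q - np.diag(np.diag(Q))
    if offdiag.min() < -1e-12:
        raise ValueError("Q off-diagonals must be nonnegative (generator matrix)")
    times = np.linspace(0.0, T, n_out)
    A0 = Q.T
    AU = Q.T + np.diag(rates)
    rho0_traj = np.stack([linalg.expm(A0 * t) @ rho_init for t in times])
    rhoU_raw = np.stack([linalg.expm(AU * t) @ rho_init for t in times])
    total = rhoU_raw.sum(axis=1)
    rhoU_traj = rhoU_raw / total[:, None]
    if T > 0 and total[-1] > 0:
        logger.debug(
            "weight dynamics growth rate ~ %.6g", np.log(total[-1] / total[0]) / T
        )
    return {
        "times": times,
        "rho0": rho0_traj,
        "rhoU": rhoU_traj,
        "rhoU_total": total,
    }


# ---------------------------------------------------------------------------
# mixture IO
# ---------------------------------------------------------------------------


def save_mixture(mix: GaussianMixture, path, model_name: str = "") -> None:
    doc = {
        "kind": mix.kind,
        "epsilon": mix.epsilon,
        "model": model_name,
        "components": [
            {
                "mu": c.mu.tolist(),
                "sigma": c.sigma.tolist(),
                "weight": float(w),
                "basin": int(c.basin),
            }
            for c, w in zip(mix.components, mix.weights)
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_mixture(path) -> GaussianMixture:
    with open(path) as fh:
        doc = json.load(fh)
    comps = [
        GaussianComponent(
            mu=np.asarray(c["mu"]), sigma=np.asarray(c["sigma"]), basin=c.get("basin", 0)
        )
        for c in doc["components"]
    ]
    weights = [c["weight"] for c in doc["components"]]
    return GaussianMixture(comps, weights, epsilon=doc["epsilon"], kind=doc["kind"])
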