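"""Weighted single-cell simulation (Feynman-Kac representation).

Each cell follows the diffusion  dX = b(X) dt + sqrt(2 eps) dW  and carries a
multiplicative weight obeying  d rho = R(X) rho dt  with rho(0) = 1, so the
weighted empirical measure  E[rho_t delta(x - X_t)]  solves the generalized
Fokker-Planck equation with the birth-death term: proliferating regions
(R > 0) inflate their cells' weights, dying regions deflate them, without any
branching of trajectories.

Positions are advanced by Euler-Maruyama; weights by the exact per-step
exponential  rho <- rho exp(R(X) dt),  which keeps them positive and is exact
for R piecewise-constant along a step.  Optional systematic resampling keeps
the effective sample size bounded away from zero on long runs; it preserves
the total weight exactly and is disabled by default to match the plain
ensemble averages used for basin-occupancy estimation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .fpe2d import Grid2D, GridField
from .models import DifferentiationModel

logger = logging.getLogger(__name__)

__all__ = [
    "WeightedEnsemble",
    "simulate_ensemble",
    "density_estimate",
    "basin_occupancy",
    "flow_to_attractor",
    "default_dt",
    "save_ensemble",
    "load_ensemble",
]


@dataclass
class WeightedEnsemble:
    """Particle positions with Feynman-Kac weights at a common time."""

    positions: np.ndarray  # (N, n)
    weights: np.ndarray  # (N,)
    time: float
    seed: int
    model_name: str = ""
    resampled_count: int = 0
    reflected_count: int = 0

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if self.weights.shape[0] != self.positions.shape[0]:
            raise ValueError("weights/positions length mismatch")
        if np.any(self.weights <= 0):
            raise ValueError("Feynman-Kac weights must stay positive")

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    def effective_sample_size(self) -> float:
        w = self.weights
        return float(w.sum() ** 2 / (w**2).sum())


def default_dt(model: DifferentiationModel, n_probe: int = 256, seed: int = 0) -> float:
    """Step size 0.01 * min(1, 1/max|J|) with the Jacobian norm probed on a
    random sample of domain points."""
    from .models import numeric_derivatives

    rng = np.random.default_rng(seed)
    pts = model.domain.sample_uniform(rng, n_probe)
    der = numeric_derivatives(model)
    jmax = 0.0
    for x in pts[:: max(1, n_probe // 64)]:
        J = np.asarray(der.jacobian(x), dtype=float)
        jmax = max(jmax, float(np.abs(J).max()))
    return 0.01 * min(1.0, 1.0 / max(jmax, 1e-12))


def _systematic_resample(rng, positions, weights):
    n = weights.shape[0]
    total = weights.sum()
    cum = np.cumsum(weights) / total
    u = (rng.random() + np.arange(n)) / n
    idx = np.searchsorted(cum, u)
    new_w = np.full(n, total / n)
    return positions[idx].copy(), new_w


def simulate_ensemble(
    model: DifferentiationModel,
    n_particles: int,
    T: float,
    dt: Optional[float] = None,
    init: Optional[Callable[[np.random.Generator, int], np.ndarray]] = None,
    seed: int = 0,
    resample_threshold: Optional[float] = None,
    use_rate: bool = True,
) -> WeightedEnsemble:
    """Simulate N weighted cells up to time T.

    ``init(rng, n) -> (n, dim)`` samples the initial law (default: uniform on
    the model domain, matching the basin-occupancy estimators).  Particles
    are reflected at an absorbing box twice the model domain (occurrences
    are counted; vanishingly rare at eps = 0.01).  ``resample_threshold`` in
    (0, 1] triggers systematic resampling when ESS/N drops below it; None
    disables resampling.
    """
    if n_particles < 1:
        raise ValueError("need at least one particle")
    if dt is None:
        dt = default_dt(model)
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed)
    if init is None:
        x = model.domain.sample_uniform(rng, n_particles)
    else:
        x = np.asarray(init(rng, n_particles), dtype=float)
        if x.shape != (n_particles, model.dim):
            raise ValueError("init sampler returned wrong shape")
    w = np.ones(n_particles)
    box = model.domain.scaled(2.0)
    lo = np.asarray(box.lower)
    hi = np.asarray(box.upper)
    span = hi - lo
    sig = np.sqrt(2.0 * model.epsilon * dt)
    n_steps = int(round(T / dt))
    resampled = 0
    reflected = 0
    warned = False
    t = 0.0
    for _ in range(n_steps):
        if use_rate:
            r = np.asarray(model.rate(x), dtype=float)
            if not warned and np.abs(r).max() * dt > 0.5:
                logger.warning(
                    "max |R| dt = %.2f > 0.5: weight update accuracy degrades",
                    np.abs(r).max() * dt,
                )
                warned = True
            w = w * np.exp(r * dt)
        b = np.asarray(model.drift(x), dtype=float)
        x = x + b * dt + sig * rng.standard_normal(x.shape)
        out = (x < lo) | (x > hi)
        if out.any():
            reflected += int(out.any(axis=1).sum())
            # reflect into the absorbing box (triangular fold)
            y = np.mod(x - lo, 2.0 * span)
            x = np.where(y > span, 2.0 * span - y, y) + lo
        t += dt
        if resample_threshold is not None:
            ess = w.sum() ** 2 / (w**2).sum()
            if ess / n_particles < resample_threshold:
                x, w = _systematic_resample(rng, x, w)
                resampled += 1
    return WeightedEnsemble(
        positions=x,
        weights=w,
        time=t,
        seed=seed,
        model_name=model.name,
        resampled_count=resampled,
        reflected_count=reflected,
    )


def density_estimate(
    ensemble: WeightedEnsemble,
    grid: Grid2D,
    smooth_sigma: Optional[float] = None,
) -> GridField:
    """Weighted histogram of the ensemble on the grid, normalized to unit
    mass; ``smooth_sigma`` (physical units) applies a Gaussian kernel.

    The pre-normalization total weight (the growing population size relative
    to the initial one) is reported in ``meta['total_weight']``.
    """
    if ensemble.n_particles == 0:
        raise ValueError("empty ensemble")
    x = ensemble.positions
    if x.shape[1] != 2:
        raise ValueError("density_estimate requires a 2-D ensemble")
    xe = np.linspace(grid.bounds.lower[0], grid.bounds.upper[0], grid.nx + 1)
    ye = np.linspace(grid.bounds.lower[1], grid.bounds.upper[1], grid.ny + 1)
    H, _, _ = np.histogram2d(x[:, 0], x[:, 1], bins=[xe, ye], weights=ensemble.weights)
    vals = H.T  # (ny, nx), y-outer
    if vals.sum() == 0:
        raise ValueError("all particles fell outside the grid")
    if smooth_sigma is not None and smooth_sigma > 0:
        from scipy.ndimage import gaussian_filter

        vals = gaussian_filter(
            vals, sigma=(smooth_sigma / grid.hy, smooth_sigma / grid.hx)
        )
    mean_w = float(ensemble.weights.mean())
    out = GridField(grid, vals, kind="density").normalize()
    out.meta.update(
        total_weight=mean_w, time=ensemble.time, model=ensemble.model_name
    )
    return out


def flow_to_attractor(
    model: DifferentiationModel,
    positions: np.ndarray,
    attractors: np.ndarray,
    time_cap: float = 100.0,
    dt: Optional[float] = None,
    capture_radius: Optional[float] = None,
) -> tuple[np.ndarray, int]:
    """Assign each state to the attractor its noiseless trajectory reaches.

    Batch RK4 integration of dx/dt = b(x); a state is assigned once it comes
    within ``capture_radius`` of an attractor.  States not converged within
    ``time_cap`` are assigned to the nearest attractor and counted.
    Returns (labels, n_unconverged).
    """
    att = np.atleast_2d(np.asarray(attractors, dtype=float))
    x = np.atleast_2d(np.asarray(positions, dtype=float)).copy()
    n = x.shape[0]
    if dt is None:
        dt = min(0.05, default_dt(model) * 5.0)
    if capture_radius is None:
        capture_radius = 0.03 * float(model.domain.extent.max())
    labels = -np.ones(n, dtype=int)
    active = np.ones(n, dtype=bool)

    def rk4_step(y):
        k1 = np.asarray(model.drift(y))
        k2 = np.asarray(model.drift(y + 0.5 * dt * k1))
        k3 = np.asarray(model.drift(y + 0.5 * dt * k2))
        k4 = np.asarray(model.drift(y + dt * k3))
        return y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)

    n_steps = int(np.ceil(time_cap / dt))
    check_every = 5
    for step in range(n_steps):
        if not active.any():
            break
        x[active] = rk4_step(x[active])
        if step % check_every == 0 or step == n_steps - 1:
            d = np.linalg.norm(x[active, None, :] - att[None, :, :], axis=-1)
            hit = d.min(axis=1) < capture_radius
            if hit.any():
                act_idx = np.flatnonzero(active)
                labels[act_idx[hit]] = d[hit].argmin(axis=1)
                active[act_idx[hit]] = False
    n_unconverged = int(active.sum())
    if n_unconverged:
        d = np.linalg.norm(x[active, None, :] - att[None, :, :], axis=-1)
        labels[active] = d.argmin(axis=1)
        logger.info(
            "%d states did not converge within the time cap; assigned nearest",
            n_unconverged,
        )
    return labels, n_unconverged


def basin_occupancy(
    ensemble: WeightedEnsemble,
    attractors: Sequence,
    model: DifferentiationModel,
    time_cap: float = 100.0,
) -> dict:
    """Per-basin occupancy fractions of a weighted ensemble.

    ``rho0`` are the unweighted trajectory fractions (the mixture weights of
    the no-proliferation steady density); ``rhoU`` the weight-weighted
    fractions (the proliferation-corrected mixture weights).  Both sum to 1.
    """
    att = np.atleast_2d(
        np.asarray(
            [a.location if hasattr(a, "location") else a for a in attractors],
            dtype=float,
        )
    )
    labels, n_unconv = flow_to_attractor(
        model, ensemble.positions, att, time_cap=time_cap
    )
    K = att.shape[0]
    counts = np.bincount(labels, minlength=K).astype(float)
    wsums = np.bincount(labels, weights=ensemble.weights, minlength=K)
    rho0 = counts / counts.sum()
    rhoU = wsums / wsums.sum()
    return {
        "rho0": rho0,
        "rhoU": rhoU,
        "labels": labels,
        "unconverged": n_unconv,
    }


# ---------------------------------------------------------------------------
# snapshot IO
# ---------------------------------------------------------------------------


def save_ensemble(ensemble: WeightedEnsemble, path) -> None:
    """TSV snapshot (x1..xn, weight) plus JSON sidecar (time, seed, model)."""
    path = str(path)
    data = np.column_stack([ensemble.positions, ensemble.weights])
    header = "\t".join(
        [f"x{i+1}" for i in range(ensemble.positions.shape[1])] + ["weight"]
    )
    np.savetxt(path, data, delimiter="\t", fmt="%.17g", header=header)
    with open(path + ".json", "w") as fh:
        json.dump(
            {
                "time": ensemble.time,
                "seed": ensemble.seed,
                "model": ensemble.model_name,
                "resampled_count": ensemble.resampled_count,
                "reflected_count": ensemble.reflected_count,
            },
            fh,
            indent=1,
        )


def load_ensemble(path) -> WeightedEnsemble:
    path = str(path)
    data = np.loadtxt(path, delimiter="\t")
    data = np.atleast_2d(data)
    with open(path + ".json") as fh:
        sidecar = json.load(fh)
    return WeightedEnsemble(
        positions=data[:, :-1],
        weights=data[:, -1],
        time=float(sidecar["time"]),
        seed=int(sidecar["seed"]),
        model_name=sidecar.get("model", ""),
        resampled_count=int(sidecar.get("resampled_count", 0)),
        reflected_count=int(sidecar.get("reflected_count", 0)),
    )
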