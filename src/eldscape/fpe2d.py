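"""Generalized Fokker-Planck solver on rectangular 2-D grids.

The population density p(x, t) obeys

    dp/dt = -div(b p) + eps * Laplacian(p) + R(x) p,

with a net birth-death rate R.  The drift-diffusion part is discretized with
an exponential-fitting (Scharfetter-Gummel) finite-volume scheme on a
cell-centered uniform grid with zero-total-flux (reflecting) boundaries.
The scheme is the standard positivity-preserving, oscillation-free choice
for convection-dominated operators at mesh size h > eps: fluxes across each
cell face are fitted to the local 1-D drift-diffusion equilibrium, giving an
M-matrix whose column sums vanish to machine precision (exact discrete mass
conservation for R = 0).

Two steady densities are computed: ``steady_p0`` (R set to zero; the null
vector of the drift-diffusion operator A) and ``steady_pU`` (the principal
eigenfunction of A + diag(R), whose eigenvalue is the net population growth
rate lambda).  Because eigenvectors are invariant under the shift
R -> R - lambda, the normalized P_U automatically satisfies the steady
balance  integral (R - lambda) P_U dx = 0  to the eigen-residual.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from .models import Box, DifferentiationModel

logger = logging.getLogger(__name__)

__all__ = [
    "Grid2D",
    "GridField",
    "SteadySolution",
    "build_grid",
    "discretize_operator",
    "steady_p0",
    "steady_pU",
    "transient_solve",
    "save_field",
    "load_field",
]


@dataclass(frozen=True)
class Grid2D:
    """Cell-centered uniform grid: nx*ny cells over a 2-D box.

    Node (cell-center) coordinates lie strictly inside the box; flat field
    arrays are row-major with y as the outer index (``values[jy, ix]``).
    """

    nx: int
    ny: int
    bounds: Box

    def __post_init__(self):
        if self.nx < 16 or self.ny < 16:
            raise ValueError("grid needs at least 16 cells per axis")
        if self.bounds.dim != 2:
            raise ValueError("Grid2D requires a 2-D domain")

    @property
    def hx(self) -> float:
        return (self.bounds.upper[0] - self.bounds.lower[0]) / self.nx

    @property
    def hy(self) -> float:
        return (self.bounds.upper[1] - self.bounds.lower[1]) / self.ny

    @property
    def cell_area(self) -> float:
        return self.hx * self.hy

    @property
    def x(self) -> np.ndarray:
        return self.bounds.lower[0] + (np.arange(self.nx) + 0.5) * self.hx

    @property
    def y(self) -> np.ndarray:
        return self.bounds.lower[1] + (np.arange(self.ny) + 0.5) * self.hy

    @property
    def shape(self) -> tuple:
        return (self.ny, self.nx)

    @property
    def size(self) -> int:
        return self.nx * self.ny

    def meshgrid(self) -> tuple:
        return np.meshgrid(self.x, self.y, indexing="xy")

    def nodes(self) -> np.ndarray:
        X, Y = self.meshgrid()
        return np.stack([X.ravel(), Y.ravel()], axis=-1)


@dataclass
class GridField:
    """A scalar field sampled at the grid nodes.

    ``kind`` tags the field as a probability density (1/area units), an
    energy (same units as eps), or a residual.  Densities carry unit mass
    after :meth:`normalize`.  ``mask`` (optional) marks nodes where the
    value is trustworthy (used by energy fields derived from logs of small
    densities).
    """

    grid: Grid2D
    values: np.ndarray
    kind: str = "density"
    mask: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("field shape does not match grid shape")
        if self.kind not in ("density", "energy", "residual"):
            raise ValueError(f"unknown field kind {self.kind!r}")

    def mass(self) -> float:
        return float(self.values.sum() * self.grid.cell_area)

    def normalize(self) -> "GridField":
        m = self.mass()
        if m <= 0:
            raise ValueError("cannot normalize a field with nonpositive mass")
        self.values = self.values / m
        return self

    def copy(self) -> "GridField":
        return GridField(
            self.grid,
            self.values.copy(),
            self.kind,
            None if self.mask is None else self.mask.copy(),
            dict(self.meta),
        )


@dataclass
class SteadySolution:
    """A steady density with its growth rate and solver diagnostics."""

    density: GridField
    growth_rate: float
    residual_norm: float
    iterations: int


def build_grid(model: DifferentiationModel, nx: int = 201, ny: int = 201) -> Grid2D:
    """Cell-centered uniform grid over the model domain."""
    if model.dim != 2:
        raise ValueError("fpe2d handles two-dimensional models only")
    return Grid2D(nx=nx, ny=ny, bounds=model.domain)


def _bernoulli(z: np.ndarray) -> np.ndarray:
    """B(z) = z / (exp(z) - 1), evaluated stably for all float z."""
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    small = np.abs(z) < 1e-8
    out[small] = 1.0 - 0.5 * z[small]
    zb = np.clip(z[~small], -700.0, 700.0)
    out[~small] = zb / np.expm1(zb)
    # for z << -700, B(z) ~ -z
    very_neg = z < -700.0
    out[very_neg] = -z[very_neg]
    return out


def discretize_operator(model: DifferentiationModel, grid: Grid2D) -> sparse.csr_matrix:
    """Sparse generator A of the drift-diffusion semigroup: dp/dt = A p.

    Scharfetter-Gummel fluxes with reflecting boundaries; columns of A sum
    to zero (discrete conservation) and off-diagonals are nonnegative
    (M-matrix sign pattern), which guarantees positivity of the solution and
    rules out the numerical oscillations of centered schemes at cell Peclet
    numbers above 1.
    """
    eps = model.epsilon
    nx, ny, hx, hy = grid.nx, grid.ny, grid.hx, grid.hy
    xc, yc = grid.x, grid.y

    def idx(jy, ix):
        return jy * nx + ix

    rows, cols, vals = [], [], []

    # vertical faces between (jy, ix) and (jy, ix+1)
    xf = model.domain.lower[0] + np.arange(1, nx) * hx  # interior face abscissae
    Xf, Yf = np.meshgrid(xf, yc, indexing="xy")
    pts = np.stack([Xf.ravel(), Yf.ravel()], axis=-1)
    v = np.asarray(model.drift(pts), dtype=float)[:, 0]
    w = v * hx / eps
    Bm = _bernoulli(-w) * eps / hx**2  # multiplies p_left
    Bp = _bernoulli(w) * eps / hx**2  # multiplies p_right
    IX, JY = np.meshgrid(np.arange(nx - 1), np.arange(ny), indexing="xy")
    left = idx(JY.ravel(), IX.ravel())
    right = left + 1
    # flux J = Bm p_L - Bp p_R (scaled); dp_L/dt -= J, dp_R/dt += J
    rows += [left, left, right, right]
    cols += [left, right, left, right]
    vals += [-Bm, Bp, Bm, -Bp]

    # horizontal faces between (jy, ix) and (jy+1, ix)
    yf = model.domain.lower[1] + np.arange(1, ny) * hy
    Xf, Yf = np.meshgrid(xc, yf, indexing="xy")
    pts = np.stack([Xf.ravel(), Yf.ravel()], axis=-1)
    v = np.asarray(model.drift(pts), dtype=float)[:, 1]
    w = v * hy / eps
    Bm = _bernoulli(-w) * eps / hy**2
    Bp = _bernoulli(w) * eps / hy**2
    IX, JY = np.meshgrid(np.arange(nx), np.arange(ny - 1), indexing="xy")
    low = idx(JY.ravel(), IX.ravel())
    high = low + nx
    rows += [low, low, high, high]
    cols += [low, high, low, high]
    vals += [-Bm, Bp, Bm, -Bp]

    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    A = sparse.coo_matrix((vals, (rows, cols)), shape=(grid.size, grid.size)).tocsr()

    offdiag = A - sparse.diags(A.diagonal())
    if offdiag.nnz and offdiag.data.min() < -1e-14:
        # cannot happen for SG fluxes; kept as a positivity trip-wire
        logger.warning(
            "discrete operator lost the M-matrix sign pattern "
            "(min off-diagonal %.3e); positivity is not guaranteed",
            offdiag.data.min(),
        )
    return A


# ---------------------------------------------------------------------------
# steady-state eigen-solves
# ---------------------------------------------------------------------------


def _rate_on_grid(model: DifferentiationModel, grid: Grid2D) -> np.ndarray:
    return np.asarray(model.rate(grid.nodes()), dtype=float)


def _inverse_iteration(M, sigma, v0, tol, max_iter=200):
    """Inverse/Rayleigh-quotient iteration for the eigenpair nearest sigma."""
    n = M.shape[0]
    I = sparse.identity(n, format="csc")
    v = v0 / np.linalg.norm(v0)
    lam = sigma
    iterations = 0
    for outer in range(8):
        lu = splu((M - sigma * I).tocsc())
        for _ in range(max_iter // 8 + 5):
            iterations += 1
            w = lu.solve(v)
            nw = np.linalg.norm(w)
            if not np.isfinite(nw) or nw == 0:
                break
            v = w / nw
            Mv = M @ v
            lam = float(v @ Mv)
            res = np.linalg.norm(Mv - lam * v)
            scale = np.linalg.norm(Mv) + abs(lam) + 1.0
            if res < tol * scale:
                return v, lam, res / scale, iterations
        # Rayleigh update (offset avoids an exactly singular factorization)
        sigma = lam + 1e-10 * (1.0 + abs(lam))
    Mv = M @ v
    res = np.linalg.norm(Mv - lam * v) / (np.linalg.norm(Mv) + abs(lam) + 1.0)
    return v, lam, res, iterations


def _null_vector_direct(A, v0):
    """Exact (direct) null vector of the conservative operator A.

    One row of A p = 0 is redundant (columns sum to zero); replacing it with
    a pin p_r = 1 at a high-density node gives a nonsingular sparse system
    whose solution is the null vector up to scale.  Unlike inverse iteration
    this resolves the relative weights of metastable basins, whose eigenvalue
    splitting (~exp(-dF/eps)) is far below any iteration tolerance.
    """
    n = A.shape[0]
    # locate a high-density node with a few smoothing solves
    lu = splu((A - 1e-9 * sparse.identity(n, format="csc")).tocsc())
    v = v0.copy()
    for _ in range(3):
        v = lu.solve(v)
        v /= np.linalg.norm(v)
    pin = int(np.argmax(np.abs(v)))
    A_mod = A.tolil(copy=True)
    A_mod.rows[pin] = [pin]
    A_mod.data[pin] = [1.0]
    rhs = np.zeros(n)
    rhs[pin] = 1.0
    p = splu(A_mod.tocsc()).solve(rhs)
    if p.sum() < 0:
        p = -p
    Ap = A @ p
    res = np.linalg.norm(Ap) / (np.linalg.norm(A @ np.abs(p)) + np.linalg.norm(p))
    return p, 0.0, float(res), 1


def _growth_estimate(M, R_pos_max, v0, n_steps=300, rtol=1e-4):
    """Rough principal-eigenvalue estimate by renormalized implicit Euler."""
    n = M.shape[0]
    dt = 0.25 / max(1.0, R_pos_max)
    I = sparse.identity(n, format="csc")
    lu = splu((I - dt * M).tocsc())
    p = v0 / v0.sum()
    lam_prev = np.inf
    lam = 0.0
    for k in range(n_steps):
        q = lu.solve(p)
        g = q.sum()  # mass growth factor per implicit step
        lam = (1.0 - 1.0 / g) / dt
        p = q / g
        if k > 30 and abs(lam - lam_prev) < rtol * (1.0 + abs(lam)):
            break
        lam_prev = lam
    return lam, p


def _steady_solve(
    model: DifferentiationModel,
    grid: Grid2D,
    rate_values: np.ndarray,
    tol: float = 1e-13,
) -> SteadySolution:
    """Principal eigenpair of A + diag(R).  Constant R (including R = 0) is
    handled by the exact diagonal-shift identity so the density is bitwise
    the R = 0 solution."""
    A = discretize_operator(model, grid)
    Rv = np.asarray(rate_values, dtype=float).ravel()
    if Rv.shape != (grid.size,):
        raise ValueError("rate values must match the grid size")

    shift = 0.0
    if np.ptp(Rv) < 1e-14:
        shift = float(Rv[0]) if Rv.size else 0.0
        Rv = np.zeros_like(Rv)

    n = grid.size
    v0 = np.full(n, 1.0 / n)

    if not np.any(Rv):
        # Null vector of A (eigenvalue exactly 0 by conservation).  Iterative
        # eigen-solvers cannot separate the metastable near-null modes (their
        # eigenvalues are exponentially small in 1/eps), so the basin weights
        # must come from a direct solve: pin one high-density node, solve the
        # remaining exactly-consistent system, then normalize.
        v, lam, res, iters = _null_vector_direct(A, v0)
        lam_report = shift  # growth rate 0 by construction (+ constant shift)
    else:
        M = (A + sparse.diags(Rv)).tocsr()
        lam_est, p_est = _growth_estimate(M, max(float(Rv.max()), 0.0), v0)
        sigma = lam_est + max(1e-6, 0.02 * (1.0 + abs(lam_est)))
        v, lam, res, iters = _inverse_iteration(M, sigma, p_est, tol)
        lam_report = lam + shift

    if v.sum() < 0:
        v = -v
    neg = v.min()
    if neg < -1e-8 * v.max():
        raise RuntimeError(
            f"eigenfunction is not Perron-positive (min/max = {neg / v.max():.2e}); "
            "the leading eigenvalue may be complex or defective"
        )
    v = np.clip(v, 0.0, None)
    dens = GridField(grid, v.reshape(grid.shape), kind="density").normalize()
    dens.meta.update(model=model.name, epsilon=model.epsilon, growth_rate=lam_report)
    if res > 1e-8:
        logger.warning("steady solve residual %.2e exceeds 1e-8", res)
    return SteadySolution(
        density=dens, growth_rate=lam_report, residual_norm=res, iterations=iters
    )


def steady_p0(model: DifferentiationModel, grid: Grid2D, tol: float = 1e-13) -> SteadySolution:
    """Steady density with the birth-death rate switched off (R = 0)."""
    return _steady_solve(model, grid, np.zeros(grid.size), tol=tol)


def steady_pU(model: DifferentiationModel, grid: Grid2D, tol: float = 1e-13) -> SteadySolution:
    """Steady density with the model's R: normalized principal eigenfunction
    of A + diag(R); ``growth_rate`` is the principal eigenvalue lambda."""
    return _steady_solve(model, grid, _rate_on_grid(model, grid), tol=tol)


def transient_solve(
    model: DifferentiationModel,
    grid: Grid2D,
    p_init: GridField,
    T: float,
    dt: float,
    renormalize: bool = False,
    use_rate: bool = True,
) -> GridField:
    """Implicit-Euler time stepping of dp/dt = (A + diag(R)) p up to time T.

    With ``renormalize`` the density is rescaled to unit mass each step and
    the running growth-rate estimate is logged.  Negative values beyond
    -1e-12 abort (they would indicate a scheme violation; the SG M-matrix
    makes implicit Euler positivity-preserving).
    """
    if p_init.grid is not grid and p_init.grid.shape != grid.shape:
        raise ValueError("initial density lives on a different grid")
    A = discretize_operator(model, grid)
    if use_rate:
        Rv = _rate_on_grid(model, grid)
        M = (A + sparse.diags(Rv)).tocsc()
    else:
        M = A.tocsc()
    n_steps = int(round(T / dt)) if T > 0 else 0
    if n_steps == 0:
        return p_init.copy()
    I = sparse.identity(grid.size, format="csc")
    lu = splu((I - dt * M).tocsc())
    p = p_init.values.ravel().copy()
    area = grid.cell_area
    for k in range(n_steps):
        p = lu.solve(p)
        if p.min() < -1e-12 * max(p.max(), 1.0):
            raise RuntimeError("transient solve produced negative density")
        if renormalize:
            m = p.sum() * area
            lam_hat = (1.0 - 1.0 / m) / dt if m > 0 else np.nan
            logger.debug("step %d: running growth-rate estimate %.6g", k, lam_hat)
            p /= m
    out = GridField(grid, p.reshape(grid.shape), kind="density")
    out.meta.update(model=model.name, epsilon=model.epsilon, time=T)
    return out


# ---------------------------------------------------------------------------
# TSV + JSON sidecar export
# ---------------------------------------------------------------------------


def save_field(fieldobj: GridField, path) -> None:
    """Write a field as a TSV matrix (row-major, y-outer) plus a JSON sidecar
    carrying the domain bounds, grid shape, eps and any scalar metadata."""
    path = str(path)
    np.savetxt(path, fieldobj.values, delimiter="\t", fmt="%.17g")
    sidecar = {
        "kind": fieldobj.kind,
        "shape": list(fieldobj.grid.shape),
        "bounds": {
            "lower": list(fieldobj.grid.bounds.lower),
            "upper": list(fieldobj.grid.bounds.upper),
        },
        "meta": {
            k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
            for k, v in fieldobj.meta.items()
            if isinstance(v, (int, float, str, np.floating))
        },
    }
    with open(path + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def load_field(path) -> GridField:
    path = str(path)
    values = np.loadtxt(path, delimiter="\t")
    with open(path + ".json") as fh:
        sidecar = json.load(fh)
    ny, nx = sidecar["shape"]
    grid = Grid2D(
        nx=nx,
        ny=ny,
        bounds=Box(tuple(sidecar["bounds"]["lower"]), tuple(sidecar["bounds"]["upper"])),
    )
    fieldobj = GridField(grid, values, kind=sidecar["kind"])
    fieldobj.meta.update(sidecar.get("meta", {}))
    return fieldobj
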