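"""Construction of the cell-type landscape U, the pluripotency landscape V
and the curl component f from a pair of steady densities.

Definitions (all energies in units of eps):

    U(x) = -eps log P_U(x)            cell-type landscape; local minima are
                                      metastable states, i.e. cell types
    V(x) = -eps log(P_0(x)/P_U(x))    pluripotency landscape; -grad V points
                                      along the differentiation direction
    f(x) = b(x) + grad U + grad V     curl component (non-gradient remainder)

so that the drift decomposes as b = -grad U - grad V + f.  The curl flux
J = f P_0 is divergence-free at the continuous steady state; the residual of
that identity, the steady-balance integral of (R - lambda) P_U, and an
orthogonality statistic between f and grad V are exposed as diagnostics.

Logs are only meaningful where the densities are resolved: energy fields
carry a mask (density above 1e-12 of its maximum) and all diagnostics are
restricted to the masked interior with a one-cell boundary ring excluded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import splu
from skimage.morphology import h_minima

from .fpe2d import Grid2D, GridField, save_field
from .models import DifferentiationModel

__all__ = [
    "DecompositionResult",
    "potential_U",
    "potential_V",
    "curl_component",
    "check_balance",
    "check_divergence_free",
    "solve_pba_V",
    "orthogonality_diagnostic",
    "count_minima",
]

_DENSITY_FLOOR = 1e-300
_MASK_RELATIVE = 1e-12


def _support_mask(p: np.ndarray) -> np.ndarray:
    return p > _MASK_RELATIVE * p.max()


def potential_U(P_U: GridField, epsilon: float) -> GridField:
    """Cell-type landscape U = -eps log P_U, shifted so its minimum is 0.

    The density is floored at 1e-300 so U is finite everywhere; the mask
    marks nodes where P_U exceeds 1e-12 of its maximum (values outside are
    reported but not trusted).
    """
    p = P_U.values
    mask = _support_mask(p)
    U = -epsilon * np.log(np.maximum(p, _DENSITY_FLOOR))
    U = U - U[mask].min()
    out = GridField(P_U.grid, U, kind="energy", mask=mask)
    out.meta.update(P_U.meta)
    return out


def potential_V(P_0: GridField, P_U: GridField, epsilon: float) -> GridField:
    """Pluripotency landscape V = -eps log(P_0/P_U), mean-zero over the
    jointly unmasked region.

    V is defined only up to the two density normalizations, hence the gauge;
    when P_0 and P_U are the same array (R = 0 reduction) V is identically
    zero.
    """
    if P_0.grid.shape != P_U.grid.shape:
        raise ValueError("densities live on different grids")
    p0, pu = P_0.values, P_U.values
    mask = _support_mask(p0) & _support_mask(pu)
    V = -epsilon * (
        np.log(np.maximum(p0, _DENSITY_FLOOR)) - np.log(np.maximum(pu, _DENSITY_FLOOR))
    )
    V = V - V[mask].mean()
    out = GridField(P_0.grid, V, kind="energy", mask=mask)
    return out


def _gradient(values: np.ndarray, grid: Grid2D) -> np.ndarray:
    """Central-difference gradient, shape (ny, nx, 2) ordered (d/dx, d/dy)."""
    gy, gx = np.gradient(values, grid.hy, grid.hx)
    return np.stack([gx, gy], axis=-1)


def _interior_mask(grid: Grid2D, *masks: Optional[np.ndarray]) -> np.ndarray:
    """Interior nodes (one-cell ring excluded) where all masks hold, eroded
    by one cell so central differences never straddle a masked node."""
    m = np.ones(grid.shape, dtype=bool)
    m[0, :] = m[-1, :] = m[:, 0] = m[:, -1] = False
    for extra in masks:
        if extra is not None:
            m &= ndimage.binary_erosion(extra, structure=np.ones((3, 3)))
    return m


def curl_component(
    model: DifferentiationModel, U: GridField, V: GridField
) -> tuple[np.ndarray, np.ndarray]:
    """Curl component f = b + grad U + grad V at the grid nodes.

    Returns ``(f, valid)`` where ``f`` has shape (ny, nx, 2) and ``valid``
    marks the interior nodes (masked region eroded by one cell, boundary
    ring excluded) on which f is meaningful -- outside the density support
    the floored logs make the gradients vacuous.
    """
    grid = U.grid
    b = np.asarray(model.drift(grid.nodes()), dtype=float).reshape(grid.shape + (2,))
    f = b + _gradient(U.values, grid) + _gradient(V.values, grid)
    valid = _interior_mask(grid, U.mask, V.mask)
    return f, valid


def check_balance(
    P_U: GridField, rate: Callable[[np.ndarray], np.ndarray], growth_rate: float
) -> float:
    """Steady-balance residual: grid quadrature of (R - lambda) P_U."""
    grid = P_U.grid
    R = np.asarray(rate(grid.nodes()), dtype=float).reshape(grid.shape)
    return float(((R - growth_rate) * P_U.values).sum() * grid.cell_area)


def check_divergence_free(
    f: np.ndarray,
    P_0: GridField,
    valid: Optional[np.ndarray] = None,
    drift: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, float]:
    """Divergence residual of the curl flux J = f P_0.

    Returns the raw central-difference divergence field and a scalar
    summary: the maximum interior |div J| normalized by the flux scale
    max (||f|| + ||b||) P_0 / h.  Including the drift flux in the scale
    keeps the statistic meaningful in the gradient limit, where f itself is
    discretization noise and a curl-flux-only normalization would compare
    noise against noise.  ``drift`` is b sampled on the grid (shape
    (ny, nx, 2)); omit it to fall back to the curl-flux scale alone.
    """
    grid = P_0.grid
    J = f * P_0.values[..., None]
    dJx = np.gradient(J[..., 0], grid.hx, axis=1)
    dJy = np.gradient(J[..., 1], grid.hy, axis=0)
    div = dJx + dJy
    region = _interior_mask(grid) if valid is None else valid
    if not region.any():
        return div, 0.0
    fluxnorm = np.linalg.norm(f, axis=-1)
    if drift is not None:
        fluxnorm = fluxnorm + np.linalg.norm(drift, axis=-1)
    fluxnorm = fluxnorm * P_0.values
    scale = fluxnorm[region].max() / min(grid.hx, grid.hy)
    summary = float(np.abs(div[region]).max() / scale) if scale > 0 else 0.0
    return div, summary


def orthogonality_diagnostic(
    f: np.ndarray,
    V: GridField,
    P_0: GridField,
    valid: Optional[np.ndarray] = None,
    drift_scale: Optional[float] = None,
) -> float:
    """P_0-weighted mean of |f . grad V| normalized by the weighted means of
    ||f|| and ||grad V||; near 0 means the drift's curl part does no work
    against the pluripotency gradient (the regime where the elliptic
    equation of :func:`solve_pba_V` is exact).

    The normalization is scale-invariant in f, so when f sits at the
    discretization-noise level -- gradient drift, or R = 0 -- the ratio is
    vacuous; the statistic is then 0 by the zero-field convention.
    ``drift_scale`` is max ||b|| over the diagnostic region: f below 2% of
    it is treated as the zero field (the same scale class as the gradient
    reduction check)."""
    grid = P_0.grid
    gV = _gradient(V.values, grid)
    region = _interior_mask(grid, V.mask) if valid is None else valid
    w = P_0.values[region]
    wsum = w.sum()
    if wsum <= 0:
        return 0.0
    dot = np.abs(np.einsum("...i,...i", f, gV))[region]
    fn = np.linalg.norm(f, axis=-1)[region]
    gn = np.linalg.norm(gV, axis=-1)[region]
    if drift_scale is not None and fn.max() < 0.02 * drift_scale:
        return 0.0
    mean_f = (w * fn).sum() / wsum
    mean_g = (w * gn).sum() / wsum
    if mean_f == 0.0 or mean_g == 0.0:
        return 0.0
    return float((w * dot).sum() / wsum / (mean_f * mean_g))


def solve_pba_V(
    p_ss: GridField,
    rate: Callable[[np.ndarray], np.ndarray],
    grid: Grid2D,
    growth_rate: Optional[float] = None,
) -> GridField:
    """Potential V from the elliptic balance equation

        grad(log p_ss) . grad V + Laplacian V = -(R - lambda),

    i.e. div(p_ss grad V) = -(R - lambda) p_ss, with zero-Neumann boundary
    and mean-zero gauge.  This is the construction used by population-
    balance approaches when only the steady density is known; it agrees with
    the log-ratio V for gradient drifts but is not valid for general
    non-gradient systems (unless f is orthogonal to grad V).

    The rate is recentred by lambda = <R>_{p_ss} (recomputed by quadrature on
    the solve region) so the Neumann problem is solvable.  The solve is
    restricted to the region where p_ss exceeds 1e-10 of its maximum (largest
    connected component); outside, V is NaN.
    """
    p = p_ss.values
    mask = p > 1e-10 * p.max()
    labels, nlab = ndimage.label(mask, structure=np.ones((3, 3)))
    if nlab > 1:
        sizes = ndimage.sum(mask, labels, index=np.arange(1, nlab + 1))
        mask = labels == (1 + int(np.argmax(sizes)))

    ny, nx = grid.shape
    ids = -np.ones(grid.shape, dtype=int)
    ids[mask] = np.arange(int(mask.sum()))
    m = int(mask.sum())
    if m < 9:
        raise ValueError("density support too small for the elliptic solve")

    R = np.asarray(rate(grid.nodes()), dtype=float).reshape(grid.shape)
    lam = float((R[mask] * p[mask]).sum() / p[mask].sum())

    rows, cols, vals = [], [], []

    def add_faces(shift, h):
        a = mask & np.roll(mask, -1, axis=shift)
        if shift == 0:
            a[-1, :] = False
        else:
            a[:, -1] = False
        i_idx = ids[a]
        j_idx = ids[np.roll(a, 1, axis=shift)]
        pa = p[a]
        pb = p[np.roll(a, 1, axis=shift)]
        w = np.sqrt(pa * pb) / h**2  # geometric mean tames exp-small ratios
        rows.extend([i_idx, i_idx, j_idx, j_idx])
        cols.extend([i_idx, j_idx, i_idx, j_idx])
        vals.extend([-w, w, w, -w])

    add_faces(0, grid.hy)
    add_faces(1, grid.hx)
    L = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(m, m),
    ).tocsc()

    rhs = -(R[mask] - lam) * p[mask]
    # gauge: pin the highest-density node, then shift to mean zero
    pin = int(ids[np.unravel_index(np.argmax(np.where(mask, p, -np.inf)), p.shape)])
    L = L.tolil()
    L.rows[pin] = [pin]
    L.data[pin] = [1.0]
    rhs = rhs.copy()
    rhs[pin] = 0.0
    sol = splu(L.tocsc()).solve(rhs)
    sol -= sol.mean()

    V = np.full(grid.shape, np.nan)
    V[mask] = sol
    out = GridField(grid, V, kind="energy", mask=mask)
    out.meta["growth_rate"] = lam
    return out


def count_minima(
    U: GridField, prominence: Optional[float] = None, epsilon: Optional[float] = None
) -> list[dict]:
    """Interior local minima of an energy field, prominence-filtered.

    A node qualifies when it is strictly below its 8 neighbors, lies in the
    unmasked interior, and survives an h-minima (prominence) filter: basins
    shallower than ``prominence`` relative to their lowest escape level are
    discarded.  Default prominence is 0.5 eps -- features below the thermal
    energy scale are noise.  Minima closer than 3 grid cells are merged.

    Returns a list of dicts with keys ``index`` (jy, ix), ``location`` (x, y)
    and ``value``.
    """
    if prominence is None:
        eps = epsilon if epsilon is not None else U.meta.get("epsilon")
        if eps is None:
            raise ValueError("provide prominence or epsilon")
        prominence = 0.5 * float(eps)
    grid = U.grid
    vals = U.values.copy()
    mask = U.mask if U.mask is not None else np.ones(grid.shape, dtype=bool)
    fill = vals[mask].max() + 10.0 * (prominence + 1.0)
    vals[~mask] = fill

    # strict 8-neighbor local minima (footprint excludes the center node)
    footprint = np.ones((3, 3), dtype=bool)
    footprint[1, 1] = False
    neigh_min = ndimage.minimum_filter(
        vals, footprint=footprint, mode="constant", cval=np.inf
    )
    strict = (vals < neigh_min) & mask

    # prominence filter via the h-minima transform
    deep = h_minima(vals, prominence) > 0
    cand = strict & deep
    cand[0, :] = cand[-1, :] = cand[:, 0] = cand[:, -1] = False

    idx = np.argwhere(cand)
    if idx.size == 0:
        return []
    order = np.argsort(vals[cand])
    idx = idx[order]
    kept: list[np.ndarray] = []
    for ij in idx:
        if all(np.abs(ij - k).max() > 3 for k in kept):
            kept.append(ij)
    out = []
    for jy, ix in kept:
        out.append(
            {
                "index": (int(jy), int(ix)),
                "location": (float(grid.x[ix]), float(grid.y[jy])),
                "value": float(U.values[jy, ix]),
            }
        )
    out.sort(key=lambda d: d["value"])
    return out


# ---------------------------------------------------------------------------
# Results container (statsmodels-style)
# ---------------------------------------------------------------------------


@dataclass
class DecompositionResult:
    """Bundled landscapes, curl component, growth rate and diagnostics.

    Produced by :class:`eldscape.EnergyLandscape.fit`.  ``U`` and ``V`` are
    :class:`GridField` energies (2-D routes) and ``f`` the curl component on
    the grid; for mean-field fits in dimension > 2 the grid attributes are
    None and the mixture objects carry the landscapes (use :meth:`energy_U`
    / :meth:`energy_V` to evaluate at arbitrary points).
    """

    model: DifferentiationModel
    method: str
    growth_rate: float
    U: Optional[GridField] = None
    V: Optional[GridField] = None
    f: Optional[np.ndarray] = None
    f_valid: Optional[np.ndarray] = None
    P0: Optional[GridField] = None
    PU: Optional[GridField] = None
    minima: list = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)
    mixtures: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def energy_U(self, x: np.ndarray) -> np.ndarray:
        """Evaluate U at points (mixture-backed; mean-field fits only)."""
        mix = self.mixtures.get("PU")
        if mix is None:
            raise ValueError("pointwise evaluation requires a mean-field fit")
        return -self.model.epsilon * mix.logpdf(x)

    def energy_V(self, x: np.ndarray) -> np.ndarray:
        mixU = self.mixtures.get("PU")
        mix0 = self.mixtures.get("P0")
        if mixU is None or mix0 is None:
            raise ValueError("pointwise evaluation requires a mean-field fit")
        return -self.model.epsilon * (mix0.logpdf(x) - mixU.logpdf(x))

    @property
    def n_cell_types(self) -> int:
        return len(self.minima)

    def summary(self) -> str:
        lines = []
        lines.append("Energy Landscape Decomposition Results")
        lines.append("=" * 54)
        lines.append(f"{'model':<28}{self.model.name}")
        lines.append(f"{'method':<28}{self.method}")
        lines.append(f"{'dimension':<28}{self.model.dim}")
        lines.append(f"{'noise amplitude eps':<28}{self.model.epsilon:g}")
        lines.append(f"{'growth rate lambda':<28}{self.growth_rate:.6g}")
        lines.append(f"{'metastable states (U)':<28}{self.n_cell_types}")
        for i, mnm in enumerate(self.minima):
            loc = ", ".join(f"{c:.4f}" for c in mnm["location"])
            lines.append(f"  type {i + 1:<22}({loc})  U = {mnm['value']:.4f}")
        if self.diagnostics:
            lines.append("-" * 54)
            lines.append("diagnostics")
            for k, v in self.diagnostics.items():
                if isinstance(v, (int, float, np.floating)):
                    lines.append(f"  {k:<26}{v:.3e}")
        lines.append("=" * 54)
        return "\n".join(lines)

    def export(self, outdir) -> None:
        """Write TSV grids for U, V, |f| and the f components plus a JSON
        diagnostics block into ``outdir``."""
        import os

        os.makedirs(outdir, exist_ok=True)
        if self.U is not None:
            save_field(self.U, os.path.join(outdir, "U.tsv"))
        if self.V is not None:
            save_field(self.V, os.path.join(outdir, "V.tsv"))
        if self.f is not None and self.U is not None:
            grid = self.U.grid
            for name, arr in (
                ("f_norm", np.linalg.norm(self.f, axis=-1)),
                ("f_x", self.f[..., 0]),
                ("f_y", self.f[..., 1]),
            ):
                save_field(
                    GridField(grid, arr, kind="residual"),
                    os.path.join(outdir, f"{name}.tsv"),
                )
        if self.P0 is not None:
            save_field(self.P0, os.path.join(outdir, "P0.tsv"))
        if self.PU is not None:
            save_field(self.PU, os.path.join(outdir, "PU.tsv"))
        blob = {
            "model": self.model.name,
            "method": self.method,
            "epsilon": self.model.epsilon,
            "growth_rate": self.growth_rate,
            "n_cell_types": self.n_cell_types,
            "minima": self.minima,
            "diagnostics": {
                k: float(v)
                for k, v in self.diagnostics.items()
                if isinstance(v, (int, float, np.floating))
            },
        }
        with open(os.path.join(outdir, "diagnostics.json"), "w") as fh:
            json.dump(blob, fh, indent=1)

    def plot_U(self, ax=None, kind: str = "surface"):
        from .plotting import plot_energy

        return plot_energy(self.U, ax=ax, kind=kind, label="U")

    def plot_V(self, ax=None, kind: str = "contour"):
        from .plotting import plot_energy

        return plot_energy(self.V, ax=ax, kind=kind, label="V")
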