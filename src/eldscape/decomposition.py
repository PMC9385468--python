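"""Model/Results facade: fit an energy-landscape decomposition to a model.

:class:`EnergyLandscape` is the entry point, in the spirit of a statsmodels
model object: construct it from a :class:`~eldscape.models.DifferentiationModel`
(or a built-in name / config path), call :meth:`fit`, and inspect the
returned :class:`~eldscape.landscape.DecompositionResult` (``summary()``,
``minima``, ``diagnostics``, exports, plots).

Two fitting routes:

* ``method='pde'`` (dim == 2): both steady densities from the grid solver,
  then U, V, f and the full diagnostics block.
* ``method='mfa'`` (any dim): fixed-point census, Gaussian moment closure,
  basin occupancies by simulation, the exit-rate weight correction, and
  mixture-backed landscapes (also rendered on a grid in 2-D).
"""

from __future__ import annotations

import logging
from typing import Optional, Union

import numpy as np

from . import fpe2d, landscape, mfa
from .models import DifferentiationModel, get_model, load_config

logger = logging.getLogger(__name__)

__all__ = ["EnergyLandscape"]


def _resolve_model(model) -> DifferentiationModel:
    if isinstance(model, DifferentiationModel):
        return model
    if isinstance(model, str):
        import os

        if os.path.exists(model):
            return load_config(model)
        return get_model(model)
    raise TypeError("model must be a DifferentiationModel, built-in name or config path")


class EnergyLandscape:
    """Energy-landscape decomposition of a differentiation model.

    Parameters
    ----------
    model : DifferentiationModel or str
        The (b, R, eps) model; a built-in name (``example1``/``example2``) or
        a YAML config path is also accepted.
    method : {'pde', 'mfa'}
        Grid solve of the generalized Fokker-Planck equation (2-D only) or
        the Gaussian mean-field approximation (any dimension).
    grid_shape : (nx, ny)
        Grid resolution for the PDE route and for rendering mean-field
        landscapes of 2-D models.
    n_particles, T : simulation size for the basin-occupancy estimate
        (mean-field route).
    seed : int
        Seed for every stochastic ingredient (occupancy simulation).

    Examples
    --------
    >>> from eldscape import EnergyLandscape
    >>> res = EnergyLandscape("example1", grid_shape=(101, 101)).fit()
    >>> res.n_cell_types
    3
    """

    def __init__(
        self,
        model: Union[DifferentiationModel, str],
        method: str = "pde",
        grid_shape: tuple = (201, 201),
        n_particles: int = 50000,
        T: Optional[float] = None,
        dt: Optional[float] = None,
        seed: int = 0,
        exit_rate_scale: Optional[float] = None,
        check_convergence: bool = True,
    ):
        self.model = _resolve_model(model)
        if method not in ("pde", "mfa"):
            raise ValueError("method must be 'pde' or 'mfa'")
        if method == "pde" and self.model.dim != 2:
            raise ValueError("the PDE route requires a 2-D model; use method='mfa'")
        self.method = method
        self.grid_shape = tuple(grid_shape)
        self.n_particles = int(n_particles)
        self.T = T
        self.dt = dt
        self.seed = int(seed)
        self.exit_rate_scale = exit_rate_scale
        self.check_convergence = bool(check_convergence)

    def fit(self) -> landscape.DecompositionResult:
        if self.method == "pde":
            return self._fit_pde()
        return self._fit_mfa()

    # ------------------------------------------------------------------ pde

    def _fit_pde(self) -> landscape.DecompositionResult:
        model = self.model
        grid = fpe2d.build_grid(model, *self.grid_shape)
        sol0 = fpe2d.steady_p0(model, grid)
        solU = fpe2d.steady_pU(model, grid)
        return self._assemble_grid_result(
            model, sol0.density, solU.density, solU.growth_rate,
            extra_diag={
                "p0_residual": sol0.residual_norm,
                "pU_residual": solU.residual_norm,
            },
        )

    def _assemble_grid_result(
        self, model, P0, PU, growth_rate, extra_diag=None, method=None, mixtures=None
    ) -> landscape.DecompositionResult:
        eps = model.epsilon
        U = landscape.potential_U(PU, eps)
        U.meta.setdefault("epsilon", eps)
        V = landscape.potential_V(P0, PU, eps)
        f, valid = landscape.curl_component(model, U, V)
        balance = landscape.check_balance(PU, model.rate, growth_rate)
        b = np.asarray(model.drift(U.grid.nodes()), dtype=float).reshape(
            U.grid.shape + (2,)
        )
        _, div_res = landscape.check_divergence_free(f, P0, valid, drift=b)
        bnorm = np.linalg.norm(b, axis=-1)
        drift_scale = float(bnorm[valid].max()) if valid.any() else 0.0
        ortho = landscape.orthogonality_diagnostic(
            f, V, P0, valid, drift_scale=drift_scale
        )
        fnorm = np.linalg.norm(f, axis=-1)
        f_ratio = (
            float(fnorm[valid].max() / bnorm[valid].max())
            if valid.any() and bnorm[valid].max() > 0
            else 0.0
        )
        minima = landscape.count_minima(U, epsilon=eps)
        diagnostics = {
            "balance_residual": balance,
            "divergence_residual": div_res,
            "orthogonality": ortho,
            "f_to_drift_ratio": f_ratio,
            "sup_V": float(np.abs(V.values[V.mask]).max()) if V.mask.any() else 0.0,
        }
        if extra_diag:
            diagnostics.update(extra_diag)
        return landscape.DecompositionResult(
            model=model,
            method=method or self.method,
            growth_rate=float(growth_rate),
            U=U,
            V=V,
            f=f,
            f_valid=valid,
            P0=P0,
            PU=PU,
            minima=minima,
            diagnostics=diagnostics,
            mixtures=mixtures or {},
        )

    # ------------------------------------------------------------------ mfa

    def _fit_mfa(self) -> landscape.DecompositionResult:
        model = self.model
        eps = model.epsilon
        fps = mfa.find_fixed_points(model, seed=self.seed)
        stable = [fp for fp in fps if fp.stability == "stable"]
        components = []
        for k, fp in enumerate(stable):
            comp = mfa.moment_odes(model, fp)
            comp.basin = k
            components.append(comp)
        rates = np.array([mfa.component_rate(model, c) for c in components])

        if len(stable) == 1:
            # the trajectory-fraction route is vacuous for a single basin;
            # use the single component with the trajectory-averaged weight
            rho0 = np.array([1.0])
            rhoU = np.array([1.0])
            summary = mfa.RateSummary(
                component_rates=rates,
                exit_rates=np.array([abs(rates[0]) + 1.0]),
                closure_constant=abs(rates[0]) + 1.0,
                growth_rate=float(rates[0]),
            )
        else:
            rho0 = mfa.estimate_rho0(
                model,
                stable,
                n_particles=self.n_particles,
                T=self.T,
                dt=self.dt,
                seed=self.seed if self.seed else 20220617,
                check_convergence=self.check_convergence,
            )
            rhoU, summary = mfa.estimate_rhoU(
                rho0, rates, exit_rate_scale=self.exit_rate_scale
            )

        mix0 = mfa.assemble_mixture(components, rho0, "P0", eps)
        mixU = mfa.assemble_mixture(components, rhoU, "PU", eps)
        mixtures = {"P0": mix0, "PU": mixU}
        growth = summary.growth_rate

        if model.dim == 2:
            grid = fpe2d.build_grid(model, *self.grid_shape)
            nodes = grid.nodes()
            # densities from log-space evaluation (exp-underflow is benign)
            P0 = fpe2d.GridField(
                grid, np.exp(mix0.logpdf(nodes)).reshape(grid.shape), kind="density"
            ).normalize()
            PU = fpe2d.GridField(
                grid, np.exp(mixU.logpdf(nodes)).reshape(grid.shape), kind="density"
            ).normalize()
            result = self._assemble_grid_result(
                model, P0, PU, growth, method="mfa", mixtures=mixtures
            )
        else:
            mix_balance = float(rhoU @ (rates - growth))
            result = landscape.DecompositionResult(
                model=model,
                method="mfa",
                growth_rate=growth,
                minima=[
                    {
                        "index": None,
                        "location": tuple(float(v) for v in c.mu),
                        "value": float(-eps * mixU.logpdf(c.mu)),
                    }
                    for c in components
                ],
                diagnostics={"balance_residual": mix_balance},
                mixtures=mixtures,
            )
            ref = min(m["value"] for m in result.minima)
            for m in result.minima:
                m["value"] -= ref
        result.extras.update(
            fixed_points=fps,
            rho0=rho0,
            rhoU=rhoU,
            rate_summary=summary,
        )
        result.diagnostics["mixture_balance"] = float(
            rhoU @ (rates - summary.growth_rate)
        )
        return result
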