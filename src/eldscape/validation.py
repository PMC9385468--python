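"""Built-in consistency checks surfaced by ``eldscape validate``.

Each check exercises a reduction limit or an independent oracle:

* Ornstein-Uhlenbeck stationary density against the closed-form Gaussian;
* Boltzmann form of the no-proliferation steady density for gradient drift;
* V = 0 and P_U = P_0 when R = 0;
* curl component ~ 0 for gradient drift;
* steady balance of (R - lambda) against P_U;
* divergence-free curl flux;
* exactness of the moment closure on linear drift (Lyapunov solution).
"""

from __future__ import annotations

import numpy as np

from . import fpe2d, landscape, mfa
from .decomposition import EnergyLandscape
from .models import Box, DifferentiationModel, make_example1


def _ou_model(eps=0.01):
    return DifferentiationModel(
        name="ou",
        dim=2,
        drift=lambda x: -np.asarray(x, dtype=float),
        rate=lambda x: np.zeros(np.asarray(x).shape[:-1]),
        epsilon=eps,
        domain=Box((-1.0, -1.0), (1.0, 1.0)),
        jacobian=lambda x: -np.eye(2),
        hessian=lambda x: np.zeros((2, 2, 2)),
    )


def run_validation(grid: int = 101, perturb_epsilon: bool = False) -> dict:
    """Return {check name: (passed, value, detail)}.

    ``perturb_epsilon`` deliberately mismatches eps in the Boltzmann check
    (negative control: the check must then fail).
    """
    report = {}

    # --- OU stationary density vs closed form -----------------------------
    ou = _ou_model()
    g = fpe2d.build_grid(ou, 201, 201)
    p = fpe2d.steady_p0(ou, g).density
    X, Y = g.meshgrid()
    exact = np.exp(-(X**2 + Y**2) / (2 * ou.epsilon)) / (2 * np.pi * ou.epsilon)
    err = np.abs(p.values - exact).max() / exact.max()
    report["ou_gaussian_sup_relerr"] = (err < 0.02, err, "(< 0.02)")

    # --- gradient model: Boltzmann form and reductions --------------------
    ex1 = make_example1()
    res = EnergyLandscape(ex1, grid_shape=(grid, grid)).fit()
    F = ex1.metadata["potential"](res.U.grid.nodes()).reshape(res.U.grid.shape)
    eps_check = ex1.epsilon * (2.5 if perturb_epsilon else 1.0)
    U0 = landscape.potential_U(res.P0, eps_check)
    region = res.P0.values > 1e-6 * res.P0.values.max()
    diff = (U0.values - F)[region]
    boltz = np.abs(diff - diff.mean()).max()
    report["boltzmann_sup_err"] = (boltz < 0.05, boltz, "(< 0.05)")

    report["curl_to_drift_ratio"] = (
        res.diagnostics["f_to_drift_ratio"] < 0.05,
        res.diagnostics["f_to_drift_ratio"],
        "(< 0.05, gradient drift)",
    )
    report["balance_residual"] = (
        abs(res.diagnostics["balance_residual"]) < 1e-6,
        abs(res.diagnostics["balance_residual"]),
        f"(< 1e-6; lambda = {res.growth_rate:.6g})",
    )
    report["divergence_residual"] = (
        res.diagnostics["divergence_residual"] < 0.05,
        res.diagnostics["divergence_residual"],
        "(< 0.05)",
    )

    # --- R = 0 reduction ---------------------------------------------------
    r0 = EnergyLandscape(ex1.zero_rate(), grid_shape=(grid, grid)).fit()
    supV = r0.diagnostics["sup_V"]
    report["sup_V_at_R0"] = (supV < 1e-10, supV, "(< 1e-10)")

    # --- moment closure exact on linear drift ------------------------------
    fp = mfa.FixedPoint(np.zeros(2), "stable", np.array([-1.0, -1.0]))
    comp = mfa.moment_odes(ou, fp)
    lyap_err = np.abs(comp.sigma - np.eye(2)).max()
    report["lyapunov_exactness"] = (lyap_err < 1e-8, lyap_err, "(< 1e-8)")

    return report
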