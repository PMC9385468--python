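"""Differentiation-dynamics model abstraction.

A differentiation model is the triple (b, R, eps): a drift field ``b(x)``
encoding gene-gene interactions, a net birth-death rate ``R(x)`` (positive
where cells proliferate, negative where they die), and a noise amplitude
``eps``.  Cell state ``x`` lives in an axis-aligned box in expression-level
units.  Two classic benchmark systems are registered here:

* ``make_example1`` -- a two-dimensional gradient drift b = -grad F with a
  triple-well potential F (one stem-like well, two differentiated wells) and
  a quartic birth-death rate that makes the stem state proliferate.
* ``make_example2`` -- the two-gene mutual-inhibition / self-activation
  toggle switch with Hill kinetics (non-gradient), with a tunable rate
  amplitude r controlling how strongly proliferation focuses on the
  co-expressed progenitor state.

Arbitrary n-gene Hill networks are built with :func:`make_hill_network`,
and model definitions round-trip through YAML config files.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "Box",
    "PolynomialRate",
    "HillTerm",
    "DifferentiationModel",
    "DriftDerivatives",
    "make_example1",
    "make_example2",
    "make_hill_network",
    "numeric_derivatives",
    "load_config",
    "save_config",
    "get_model",
]


@dataclass(frozen=True)
class Box:
    """Axis-aligned domain box with strictly positive extent per axis."""

    lower: tuple
    upper: tuple

    def __post_init__(self):
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        if lo.shape != hi.shape or lo.ndim != 1:
            raise ValueError("lower/upper must be 1-D and of equal length")
        if not np.all(hi > lo):
            raise ValueError("domain must have strictly positive extent on every axis")
        object.__setattr__(self, "lower", tuple(float(v) for v in lo))
        object.__setattr__(self, "upper", tuple(float(v) for v in hi))

    @property
    def dim(self) -> int:
        return len(self.lower)

    @property
    def extent(self) -> np.ndarray:
        return np.asarray(self.upper) - np.asarray(self.lower)

    def contains(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        lo = np.asarray(self.lower)
        hi = np.asarray(self.upper)
        return np.all((x >= lo) & (x <= hi), axis=-1)

    def sample_uniform(self, rng: np.random.Generator, n: int) -> np.ndarray:
        lo = np.asarray(self.lower)
        hi = np.asarray(self.upper)
        return rng.uniform(lo, hi, size=(n, self.dim))

    def scaled(self, factor: float) -> "Box":
        """Box with the same center and extents multiplied by ``factor``."""
        lo = np.asarray(self.lower)
        hi = np.asarray(self.upper)
        c = 0.5 * (lo + hi)
        half = 0.5 * (hi - lo) * factor
        return Box(tuple(c - half), tuple(c + half))


class PolynomialRate:
    """Net birth-death rate as a sum of monomials ``coeff * prod x_i**p_i``.

    The printed example rates are low-order polynomials; keeping them in
    monomial form makes config round trips loss-free and Gaussian
    expectations exactly integrable by cubature.
    """

    def __init__(self, terms: Sequence[tuple], dim: int):
        self.dim = int(dim)
        self.terms = []
        for coeff, powers in terms:
            powers = tuple(int(p) for p in powers)
            if len(powers) != self.dim:
                raise ValueError("monomial power tuple length must equal dim")
            self.terms.append((float(coeff), powers))

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.zeros(x.shape[:-1], dtype=float)
        for coeff, powers in self.terms:
            term = np.full(x.shape[:-1], coeff, dtype=float)
            for i, p in enumerate(powers):
                if p:
                    term = term * x[..., i] ** p
            out += term
        return out

    def to_dict(self) -> dict:
        return {
            "dim": self.dim,
            "terms": [{"coeff": c, "powers": list(p)} for c, p in self.terms],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PolynomialRate":
        return cls([(t["coeff"], tuple(t["powers"])) for t in d["terms"]], d["dim"])


def _zero_rate(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return np.zeros(x.shape[:-1], dtype=float)


@dataclass(frozen=True)
class HillTerm:
    """One regulatory edge: gene ``source`` acts on gene ``target``.

    ``kind`` is ``activation`` (alpha * x^s / (S^s + x^s)) or ``inhibition``
    (beta * S^s / (S^s + x^s)); ``amplitude`` is the maximal production rate,
    ``threshold`` the half-saturation constant S and ``hill`` the Hill
    coefficient s.
    """

    target: int
    source: int
    kind: str
    amplitude: float
    threshold: float
    hill: float

    def __post_init__(self):
        if self.kind not in ("activation", "inhibition"):
            raise ValueError(f"unknown interaction type: {self.kind!r}")
        if self.threshold <= 0:
            raise ValueError("Hill threshold must be positive")
        if self.hill <= 0:
            raise ValueError("Hill coefficient must be positive")


@dataclass
class DifferentiationModel:
    """The pair (b, R) with noise amplitude and domain metadata.

    ``drift`` and ``rate`` are vectorized callables accepting arrays of shape
    (..., dim).  ``jacobian``/``hessian`` are optional analytic derivative
    callables (a single point -> (n, n) resp. (n, n, n)); absent ones are
    filled in by finite differences through :func:`numeric_derivatives`.
    """

    name: str
    dim: int
    drift: Callable[[np.ndarray], np.ndarray]
    rate: Callable[[np.ndarray], np.ndarray]
    epsilon: float
    domain: Box
    jacobian: Optional[Callable[[np.ndarray], np.ndarray]] = None
    hessian: Optional[Callable[[np.ndarray], np.ndarray]] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.domain.dim != self.dim:
            raise ValueError("domain dimension does not match model dimension")
        # finiteness of b and R on the closed domain (spot check on a coarse lattice)
        probe = self._probe_points()
        b = np.asarray(self.drift(probe), dtype=float)
        r = np.asarray(self.rate(probe), dtype=float)
        if not (np.all(np.isfinite(b)) and np.all(np.isfinite(r))):
            raise ValueError("drift/rate must be finite on the domain")

    def _probe_points(self, per_axis: int = 3) -> np.ndarray:
        axes = [
            np.linspace(self.domain.lower[i], self.domain.upper[i], per_axis)
            for i in range(self.dim)
        ]
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=-1)

    def with_rate(
        self, rate: Callable[[np.ndarray], np.ndarray], name_suffix: str = ""
    ) -> "DifferentiationModel":
        """Copy of the model with the birth-death rate replaced."""
        meta = dict(self.metadata)
        meta.pop("rate_poly", None)
        if isinstance(rate, PolynomialRate):
            meta["rate_poly"] = rate
        return DifferentiationModel(
            name=self.name + name_suffix,
            dim=self.dim,
            drift=self.drift,
            rate=rate,
            epsilon=self.epsilon,
            domain=self.domain,
            jacobian=self.jacobian,
            hessian=self.hessian,
            metadata=meta,
        )

    def zero_rate(self) -> "DifferentiationModel":
        return self.with_rate(_zero_rate, name_suffix="_R0")


@dataclass
class DriftDerivatives:
    """Jacobian and Hessian of the drift (analytic where available)."""

    jacobian: Callable[[np.ndarray], np.ndarray]
    hessian: Callable[[np.ndarray], np.ndarray]
    h_fd: float
    analytic_jacobian: bool = False
    analytic_hessian: bool = False


# ---------------------------------------------------------------------------
# Example 1: triple-well gradient drift
# ---------------------------------------------------------------------------


def _example1_potential(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    x1, x2 = x[..., 0], x[..., 1]
    return (x1**2 / 2.0 + x2 / 2.0) ** 2 + (x2**2 - 1.0) ** 2 / 2.0


def _example1_drift(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    x1, x2 = x[..., 0], x[..., 1]
    g = x1**2 / 2.0 + x2 / 2.0
    b1 = -2.0 * g * x1
    b2 = -g - 2.0 * x2 * (x2**2 - 1.0)
    return np.stack([b1, b2], axis=-1)


def _example1_jacobian(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    x1, x2 = x[..., 0], x[..., 1]
    j11 = -3.0 * x1**2 - x2
    j12 = -x1 * np.ones_like(x2)
    j21 = -x1 * np.ones_like(x2)
    j22 = -0.5 - 6.0 * x2**2 + 2.0
    return np.stack(
        [np.stack([j11, j12], axis=-1), np.stack([j21, j22], axis=-1)], axis=-2
    )


def _example1_hessian(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    x1, x2 = float(x[..., 0]), float(x[..., 1])
    H = np.zeros((2, 2, 2))
    # second derivatives of b1 = -x1^3 - x1 x2
    H[0, 0, 0] = -6.0 * x1
    H[0, 0, 1] = H[0, 1, 0] = -1.0
    # second derivatives of b2 = -(x1^2/2 + x2/2) - 2 x2^3 + 2 x2
    H[1, 0, 0] = -1.0
    H[1, 1, 1] = -12.0 * x2
    return H


def example1_rate_poly() -> PolynomialRate:
    # 0.3[(x1^2-1)^2 + (x2+1)^2 - 1] expanded into monomials
    return PolynomialRate(
        [
            (0.3, (4, 0)),
            (-0.6, (2, 0)),
            (0.3, (0, 2)),
            (0.6, (0, 1)),
            (0.3, (0, 0)),
        ],
        dim=2,
    )


def make_example1() -> DifferentiationModel:
    """Triple-well gradient benchmark: stem state proliferates, wings die.

    b = -grad F with F(x) = (x1^2/2 + x2/2)^2 + (x2^2-1)^2/2; stable states
    at (0, sqrt(3)/2) (stem, type A) and (+-1, -1) (differentiated, B and C);
    R(x) = 0.3[(x1^2-1)^2 + (x2+1)^2 - 1]; eps = 0.01.
    """
    rate = example1_rate_poly()
    return DifferentiationModel(
        name="example1",
        dim=2,
        drift=_example1_drift,
        rate=rate,
        epsilon=0.01,
        domain=Box((-2.5, -2.5), (2.5, 2.5)),
        jacobian=_example1_jacobian,
        hessian=_example1_hessian,
        metadata={
            "potential": _example1_potential,
            "gradient_system": True,
            "rate_poly": rate,
            "stable_points": [
                (0.0, math.sqrt(3.0) / 2.0),
                (-1.0, -1.0),
                (1.0, -1.0),
            ],
        },
    )


# ---------------------------------------------------------------------------
# Example 2 and generic Hill networks
# ---------------------------------------------------------------------------


def _hill_drift_factory(dim, terms, degradation):
    deg = np.asarray(degradation, dtype=float)

    def drift(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = -deg * x
        for t in terms:
            xs = x[..., t.source]
            Ss = t.threshold**t.hill
            xp = np.abs(xs) ** t.hill  # Hill kinetics defined for x >= 0
            if t.kind == "activation":
                contrib = t.amplitude * xp / (Ss + xp)
            else:
                contrib = t.amplitude * Ss / (Ss + xp)
            out[..., t.target] = out[..., t.target] + contrib
        return out

    return drift


def _hill_jacobian_factory(dim, terms, degradation):
    deg = np.asarray(degradation, dtype=float)

    def jacobian(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        J = np.zeros(x.shape[:-1] + (dim, dim))
        idx = np.arange(dim)
        J[..., idx, idx] = -deg
        for t in terms:
            xs = np.abs(x[..., t.source])
            Ss = t.threshold**t.hill
            xp = xs**t.hill
            denom = (Ss + xp) ** 2
            with np.errstate(divide="ignore", invalid="ignore"):
                d = t.hill * Ss * np.where(xs > 0, xs ** (t.hill - 1.0), 0.0) / denom
            if t.kind == "activation":
                J[..., t.target, t.source] += t.amplitude * d
            else:
                J[..., t.target, t.source] -= t.amplitude * d
        return J

    return jacobian


def make_hill_network(
    spec: dict,
    epsilon: float = 0.01,
    domain: Optional[Box] = None,
    name: str = "hill_network",
) -> DifferentiationModel:
    """Build an n-gene Hill-kinetics model from a network description.

    ``spec`` maps:
      - ``genes``: int (count) or list of names;
      - ``degradation``: per-gene linear decay rates k_i;
      - ``terms``: list of dicts with keys target, source, type
        (activation|inhibition), amplitude, threshold, hill;
      - optional ``rate``: PolynomialRate dict ({"dim", "terms"}).

    The drift of gene i is the sum of its activated Hill terms
    alpha x^s/(S^s + x^s) and inhibited terms beta S^s/(S^s + x^s) minus
    k_i x_i.
    """
    genes = spec["genes"]
    if isinstance(genes, int):
        dim = genes
        gene_names = [f"x{i+1}" for i in range(dim)]
    else:
        gene_names = list(genes)
        dim = len(gene_names)
    degradation = list(spec.get("degradation", [1.0] * dim))
    if len(degradation) != dim:
        raise ValueError("degradation list length must equal gene count")

    terms = []
    for t in spec.get("terms", []):
        terms.append(
            HillTerm(
                target=int(t["target"]),
                source=int(t["source"]),
                kind=str(t.get("type", t.get("kind"))),
                amplitude=float(t["amplitude"]),
                threshold=float(t["threshold"]),
                hill=float(t["hill"]),
            )
        )
    for t in terms:
        if not (0 <= t.target < dim and 0 <= t.source < dim):
            raise ValueError("Hill term references an unknown gene index")

    if domain is None:
        # dissipative bound: x_i <= (sum of production amplitudes)/k_i
        hi = []
        for i in range(dim):
            amp = sum(t.amplitude for t in terms if t.target == i)
            hi.append(max(1.5 * amp / degradation[i], 1.0))
        domain = Box(tuple(0.0 for _ in range(dim)), tuple(hi))

    if "rate" in spec and spec["rate"] is not None:
        rate = PolynomialRate.from_dict(spec["rate"])
        if rate.dim != dim:
            raise ValueError("rate polynomial dimension does not match gene count")
    else:
        rate = _zero_rate

    meta = {
        "hill_spec": {
            "genes": gene_names,
            "degradation": [float(k) for k in degradation],
            "terms": [
                {
                    "target": t.target,
                    "source": t.source,
                    "type": t.kind,
                    "amplitude": t.amplitude,
                    "threshold": t.threshold,
                    "hill": t.hill,
                }
                for t in terms
            ],
        }
    }
    if isinstance(rate, PolynomialRate):
        meta["rate_poly"] = rate

    return DifferentiationModel(
        name=name,
        dim=dim,
        drift=_hill_drift_factory(dim, terms, degradation),
        rate=rate,
        epsilon=epsilon,
        domain=domain,
        jacobian=_hill_jacobian_factory(dim, terms, degradation),
        hessian=None,
        metadata=meta,
    )


def example2_hill_spec(r: float = 0.0) -> dict:
    """Network description of the two-gene toggle (self-activation + mutual
    inhibition), parameters alpha = 0.3, beta = 0.5, s = 4, k = 1, S = 0.5."""
    spec = {
        "genes": ["x1", "x2"],
        "degradation": [1.0, 1.0],
        "terms": [
            {"target": 0, "source": 0, "type": "activation", "amplitude": 0.3,
             "threshold": 0.5, "hill": 4},
            {"target": 0, "source": 1, "type": "inhibition", "amplitude": 0.5,
             "threshold": 0.5, "hill": 4},
            {"target": 1, "source": 1, "type": "activation", "amplitude": 0.3,
             "threshold": 0.5, "hill": 4},
            {"target": 1, "source": 0, "type": "inhibition", "amplitude": 0.5,
             "threshold": 0.5, "hill": 4},
        ],
    }
    if r:
        spec["rate"] = example2_rate_poly(r).to_dict()
    return spec


def example2_rate_poly(r: float) -> PolynomialRate:
    # -r[(x1-1)^2 + (x2-1)^2 - 0.5] expanded into monomials
    return PolynomialRate(
        [
            (-r, (2, 0)),
            (2.0 * r, (1, 0)),
            (-r, (0, 2)),
            (2.0 * r, (0, 1)),
            (-1.5 * r, (0, 0)),
        ],
        dim=2,
    )


def make_example2(r: float = 0.0) -> DifferentiationModel:
    """Two-gene fate-decision toggle switch with tunable rate amplitude r.

    Drift per Hill kinetics with alpha1 = alpha2 = 0.3, beta1 = beta2 = 0.5,
    s = 4, k1 = k2 = 1, S = 0.5; R(x) = -r[(x1-1)^2 + (x2-1)^2 - 0.5];
    eps = 0.01; domain [0, 3]^2.
    """
    if r < 0:
        raise ValueError("rate amplitude r must be nonnegative")
    model = make_hill_network(
        example2_hill_spec(),
        epsilon=0.01,
        domain=Box((0.0, 0.0), (3.0, 3.0)),
        name="example2",
    )
    rate = example2_rate_poly(r)
    model = model.with_rate(rate)
    model.name = "example2"
    model.metadata["r"] = float(r)
    return model


# ---------------------------------------------------------------------------
# Derivatives
# ---------------------------------------------------------------------------


def numeric_derivatives(
    model: DifferentiationModel, h_fd: Optional[float] = None
) -> DriftDerivatives:
    """Jacobian/Hessian of the drift; analytic forms substituted when the
    model provides them, central finite differences otherwise.

    Default step: 1e-5 times the mean domain extent.  Evaluations falling
    outside the domain are clamped to the boundary and logged once.
    """
    if h_fd is None:
        h_fd = 1e-5 * float(np.mean(model.domain.extent))
    if h_fd <= 0:
        raise ValueError("finite-difference step must be positive")
    n = model.dim
    lo = np.asarray(model.domain.lower)
    hi = np.asarray(model.domain.upper)
    clamp_logged = [False]

    def _eval(x):
        # stencils may poke slightly outside the domain; clamp only when the
        # drift actually fails there (Hill/polynomial drifts are entire)
        x = np.asarray(x, dtype=float)
        b = np.asarray(model.drift(x), dtype=float)
        if not np.all(np.isfinite(b)):
            if not clamp_logged[0]:
                logger.warning(
                    "finite-difference stencil clamped to the domain boundary"
                )
                clamp_logged[0] = True
            b = np.asarray(model.drift(np.clip(x, lo, hi)), dtype=float)
        return b

    def fd_jacobian(x):
        x = np.asarray(x, dtype=float)
        J = np.empty((n, n))
        for j in range(n):
            e = np.zeros(n)
            e[j] = h_fd
            J[:, j] = (_eval(x + e) - _eval(x - e)) / (2.0 * h_fd)
        return J

    def fd_hessian(x):
        x = np.asarray(x, dtype=float)
        H = np.empty((n, n, n))
        b0 = _eval(x)
        for j in range(n):
            ej = np.zeros(n)
            ej[j] = h_fd
            H[:, j, j] = (_eval(x + ej) - 2.0 * b0 + _eval(x - ej)) / h_fd**2
            for l in range(j + 1, n):
                el = np.zeros(n)
                el[l] = h_fd
                mixed = (
                    _eval(x + ej + el)
                    - _eval(x + ej - el)
                    - _eval(x - ej + el)
                    + _eval(x - ej - el)
                ) / (4.0 * h_fd**2)
                H[:, j, l] = mixed
                H[:, l, j] = mixed
        return H

    jac = model.jacobian if model.jacobian is not None else fd_jacobian
    hess = model.hessian if model.hessian is not None else fd_hessian
    return DriftDerivatives(
        jacobian=jac,
        hessian=hess,
        h_fd=h_fd,
        analytic_jacobian=model.jacobian is not None,
        analytic_hessian=model.hessian is not None,
    )


# ---------------------------------------------------------------------------
# Config round trip
# ---------------------------------------------------------------------------

_BUILTINS = {"example1": make_example1, "example2": make_example2}


def get_model(name: str, **kwargs) -> DifferentiationModel:
    """Look up a built-in model by name (``example1`` or ``example2``)."""
    try:
        factory = _BUILTINS[name]
    except KeyError:
        raise KeyError(
            f"unknown built-in model {name!r}; available: {sorted(_BUILTINS)}"
        ) from None
    return factory(**kwargs)


def save_config(model: DifferentiationModel, path) -> None:
    """Write a YAML config describing the model.

    Built-in models are referenced by name; Hill-network models are written
    in full (genes, degradation, interaction terms, rate polynomial).
    """
    doc: dict = {
        "noise": {"epsilon": float(model.epsilon)},
        "domain": {
            "lower": list(model.domain.lower),
            "upper": list(model.domain.upper),
        },
    }
    if model.name in _BUILTINS or model.name.startswith("example2"):
        doc["model"] = {"name": "example2" if "example2" in model.name else model.name}
        if "r" in model.metadata:
            doc["model"]["r"] = float(model.metadata["r"])
    elif "hill_spec" in model.metadata:
        doc["model"] = {"name": model.name, "kind": "hill"}
        doc["model"].update(model.metadata["hill_spec"])
    else:
        raise ValueError(
            "only built-in and Hill-network models can be written to config"
        )
    poly = model.metadata.get("rate_poly")
    if isinstance(poly, PolynomialRate):
        doc["rate"] = poly.to_dict()
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_config(path) -> DifferentiationModel:
    """Read a model from a YAML config written by :func:`save_config` (or by
    hand, same schema)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    mspec = doc.get("model", {})
    name = mspec.get("name", "custom")
    eps = float(doc.get("noise", {}).get("epsilon", 0.01))
    domain = None
    if "domain" in doc:
        domain = Box(tuple(doc["domain"]["lower"]), tuple(doc["domain"]["upper"]))

    if name in _BUILTINS:
        kwargs = {}
        if name == "example2" and "r" in mspec:
            kwargs["r"] = float(mspec["r"])
        model = _BUILTINS[name](**kwargs)
        if abs(eps - model.epsilon) > 0:
            model.epsilon = eps
        if domain is not None:
            model.domain = domain
        if "rate" in doc:
            model = model.with_rate(PolynomialRate.from_dict(doc["rate"]))
            model.name = name
        return model

    if mspec.get("kind") == "hill" or "terms" in mspec:
        spec = {
            "genes": mspec.get("genes"),
            "degradation": mspec.get("degradation"),
            "terms": mspec.get("terms", []),
        }
        if "rate" in doc:
            spec["rate"] = doc["rate"]
        return make_hill_network(spec, epsilon=eps, domain=domain, name=name)

    raise ValueError(f"config does not describe a recognizable model: {path}")
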