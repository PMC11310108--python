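"""Hyperboloid-model primitives.

The d-dimensional hyperbolic space is modelled as the upper sheet of the
hyperboloid H^d = {u in R^{d+1} : <u,u> = -1, u0 > 0}, where <.,.> is the
Lorentz inner product.  All operations are written against ``autograd.numpy``
so that gradients flow through distances into downstream tree decoding.

Points are stored in ambient (d+1)-coordinates but optimised in the d
unconstrained tangent coordinates (z1..zd); :func:`project_to_hyperboloid`
restores the constrained first coordinate exactly by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import autograd.numpy as anp
import numpy as np

__all__ = [
    "Curvature",
    "EmbeddingLocations",
    "DistanceMatrix",
    "lorentz_inner",
    "hyperbolic_distance",
    "project_to_hyperboloid",
    "pairwise_distances",
]

#: arcosh argument floor; -<u,v> can dip below 1 by floating-point error for
#: near-coincident points and d/dx arcosh diverges at 1.
ACOSH_EPS = 1e-9

#: hyperboloid-constraint tolerance used by validators
HYPERBOLOID_TOL = 1e-8

#: default embedding dimension
DEFAULT_DIM = 3


class Curvature:
    """Strictly negative curvature, parametrised as kappa = -exp(c).

    The unconstrained log-parameter ``c`` is what optimisers touch, so the
    curvature stays negative at every point of an optimisation trajectory.
    """

    __slots__ = ("log_neg",)

    def __init__(self, kappa: float = -1.0):
        kappa = float(kappa)
        if not kappa < 0:
            raise ValueError(f"curvature must be strictly negative, got {kappa}")
        self.log_neg = float(np.log(-kappa))

    @classmethod
    def from_log(cls, log_neg: float) -> "Curvature":
        out = cls(-1.0)
        out.log_neg = float(log_neg)
        return out

    @property
    def kappa(self) -> float:
        return -float(np.exp(self.log_neg))

    def __repr__(self) -> str:  # pragma: no cover
        return f"Curvature(kappa={self.kappa:g})"


def _kappa_value(kappa):
    """Accept a Curvature, a plain negative float, or an autograd box."""
    if isinstance(kappa, Curvature):
        return kappa.kappa
    return kappa


def _coords(u):
    """Accept a HyperboloidPoint-like object or a raw coordinate array."""
    return getattr(u, "coords", u)


@dataclass
class EmbeddingLocations:
    """n taxa embedded on H^d: an (n, d+1) array of ambient coordinates.

    Row order is the taxon order and is stable across all operations.
    """

    points: np.ndarray
    taxon_labels: list = field(default_factory=list)

    def __post_init__(self):
        self.points = as_array(self.points) if _is_box(self.points) else np.asarray(self.points, dtype=float)
        if not self.taxon_labels:
            self.taxon_labels = [f"t{i}" for i in range(self.n)]
        if len(self.taxon_labels) != self.n:
            raise ValueError("one label per embedded point required")
        if len(set(self.taxon_labels)) != self.n:
            raise ValueError("taxon labels must be unique")
        if self.n < 3:
            raise ValueError("need at least 3 taxa")

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def dim(self) -> int:
        return self.points.shape[1] - 1

    @property
    def tangent(self) -> np.ndarray:
        """The unconstrained tangent coordinates (drop the u0 column)."""
        return self.points[:, 1:]

    def validate(self, tol: float = HYPERBOLOID_TOL) -> None:
        sp = lorentz_inner(self.points, self.points)
        if np.any(np.abs(np.asarray(sp) + 1.0) > tol):
            raise ValueError("points violate the hyperboloid constraint <u,u> = -1")
        if np.any(np.asarray(self.points)[:, 0] < 1.0 - tol):
            raise ValueError("points must lie on the upper sheet (u0 >= 1)")


def _is_box(x) -> bool:
    return type(x).__module__.startswith("autograd")


def as_array(x):
    """np.asarray that passes autograd boxes through untouched.

    ``autograd.numpy.asarray`` has no VJP, so coercion must skip traced
    values.
    """
    return x if _is_box(x) else np.asarray(x, dtype=float)


@dataclass
class DistanceMatrix:
    """Symmetric, zero-diagonal, non-negative pairwise taxon distances."""

    values: np.ndarray
    labels: list = field(default_factory=list)

    def __post_init__(self):
        if not _is_box(self.values):
            self.values = np.asarray(self.values, dtype=float)
        if not self.labels:
            self.labels = [f"t{i}" for i in range(self.n)]
        if len(self.labels) != self.n:
            raise ValueError("one label per row required")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def validate(self, tol: float = 1e-8) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if np.any(np.abs(v - v.T) > tol):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(v)) > tol):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(v < -tol):
            raise ValueError("distances must be non-negative")


def lorentz_inner(u, v):
    """Lorentz inner product <u,v> = -u0*v0 + sum_{i>=1} ui*vi.

    Accepts vectors of equal length >= 2 or (n, d+1) arrays (row-wise).
    """
    u, v = _coords(u), _coords(v)
    u = as_array(u)
    v = as_array(v)
    if u.shape[-1] != v.shape[-1]:
        raise ValueError(f"dimension mismatch: {u.shape[-1]} vs {v.shape[-1]}")
    if u.shape[-1] < 2:
        raise ValueError("points need at least 2 ambient coordinates")
    return -u[..., 0] * v[..., 0] + anp.sum(u[..., 1:] * v[..., 1:], axis=-1)


def hyperbolic_distance(u, v, kappa=-1.0):
    """Distance on H^d at curvature kappa < 0:

        d_kappa(u, v) = arcosh(-<u,v>) / sqrt(-kappa)

    The arcosh argument is clamped to 1 + 1e-9 from below, so near-coincident
    points return a tiny distance instead of a NaN and the derivative stays
    finite.
    """
    k = _kappa_value(kappa)
    arg = -lorentz_inner(u, v)
    arg = anp.maximum(arg, 1.0 + ACOSH_EPS)
    return anp.arccosh(arg) / anp.sqrt(-k)


def project_to_hyperboloid(z):
    """Lift tangent coordinates z in R^d onto H^d.

    The first ambient coordinate becomes sqrt(1 + |z|^2); the remaining d
    coordinates are z itself, so <out,out> = -1 holds exactly.  Accepts a
    single vector or an (n, d) array.
    """
    z = as_array(z)
    if not _is_box(z) and not np.all(np.isfinite(z)):
        raise ValueError("tangent coordinates must be finite")
    z0 = anp.sqrt(1.0 + anp.sum(z * z, axis=-1, keepdims=True))
    return anp.concatenate([z0, z], axis=-1)


def pairwise_distances(locs, kappa=-1.0):
    """All-pairs hyperbolic distances of an embedding.

    Returns a :class:`DistanceMatrix` when given :class:`EmbeddingLocations`,
    or a raw (n, n) array when given a raw (n, d+1) coordinate array (the
    differentiable fast path used inside the optimisers).
    """
    raw = not isinstance(locs, EmbeddingLocations)
    X = locs if raw else locs.points
    X = as_array(X)
    n = X.shape[0]
    k = _kappa_value(kappa)
    # Lorentz Gram matrix: G_ij = <x_i, x_j>
    G = -anp.outer(X[:, 0], X[:, 0]) + X[:, 1:] @ X[:, 1:].T
    arg = anp.maximum(-G, 1.0 + ACOSH_EPS)
    off = 1.0 - np.eye(n)
    D = anp.arccosh(arg) / anp.sqrt(-k) * off  # exact zeros on the diagonal
    if raw:
        return D
    return DistanceMatrix(values=D, labels=list(locs.taxon_labels))
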