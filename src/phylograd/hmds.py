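"""Hyperbolic multidimensional scaling: embed a distance matrix into H^d.

Used to initialise the maximum-likelihood and variational engines from a
starting tree's tip-tip distances.  The embedding minimises the (unweighted
squared-error) stress

    stress(z) = sum_{i<j} (d_kappa(z_i, z_j) - D_ij)^2

over tangent coordinates, combining a spectral initialisation — the
hyperbolic analogue of classical MDS, reading time-like and space-like
directions off an eigendecomposition of cosh(sqrt(-kappa) D) — with Adam
refinement of the stress through autograd.  Embedding a metric this way is
approximate: a tree encoded as distances need not decode back to exactly the
same tree.
"""

from __future__ import annotations

import autograd.numpy as anp
import numpy as np
from autograd import value_and_grad
from autograd.tracer import getval
from scipy.optimize import minimize

from .geometry import (
    Curvature,
    DistanceMatrix,
    EmbeddingLocations,
    as_array,
    pairwise_distances,
    project_to_hyperboloid,
)

__all__ = ["embed_distances", "embedding_stress"]


def embedding_stress(locs, D, kappa=-1.0):
    """Sum of squared differences between embedded and target distances.

    Non-negative; zero iff the embedding reproduces D exactly.  Accepts
    :class:`EmbeddingLocations`/raw coordinates and
    :class:`DistanceMatrix`/raw matrices.
    """
    X = locs.points if isinstance(locs, EmbeddingLocations) else locs
    Dv = as_array(D.values if isinstance(D, DistanceMatrix) else D)
    n = Dv.shape[0]
    if X.shape[0] != n:
        raise ValueError("embedding and distance matrix disagree on n")
    E = pairwise_distances(X, kappa)
    E = E.values if isinstance(E, DistanceMatrix) else E
    iu = np.triu_indices(n, k=1)
    diff = E[iu] - Dv[iu]
    return anp.sum(diff * diff)


def _spectral_tangent_init(D: np.ndarray, dim: int, kappa: float) -> np.ndarray:
    """Hyperbolic analogue of classical-MDS initialisation.

    On an exact hyperbolic configuration, cosh(sqrt(-kappa) D) equals the
    negated Lorentz Gram matrix, whose space-like part is carried by the most
    negative eigenvalues.  The eigenvectors of the `dim` most negative
    eigenvalues of -A, scaled by sqrt(|lambda|), give spatial coordinates
    that are then re-projected exactly onto the hyperboloid.
    """
    A = np.cosh(np.sqrt(-kappa) * D)
    lamA, VA = np.linalg.eigh(A)
    order = np.argsort(lamA)  # most negative first
    Z = np.zeros((D.shape[0], dim))
    for j in range(min(dim, D.shape[0])):
        lj = lamA[order[j]]
        if lj < 0:
            Z[:, j] = np.sqrt(-lj) * VA[:, order[j]]
    return Z


def embed_distances(
    D,
    dim: int = 3,
    kappa=-1.0,
    max_iter: int = 800,
    seed: int = 0,
    restarts: int = 4,
    callback=None,
) -> EmbeddingLocations:
    """Embed a tip-tip distance matrix on H^dim at the given curvature.

    Runs L-BFGS on the stress from the spectral initialisation plus
    ``restarts - 1`` seeded perturbations of it, and returns the lowest-stress
    solution, so the final stress never exceeds the initial one.
    Deterministic given the seed.  ``callback(stress)`` is invoked once per
    optimiser iteration of each restart.
    """
    labels = list(D.labels) if isinstance(D, DistanceMatrix) else None
    Dv = np.asarray(getval(D.values if isinstance(D, DistanceMatrix) else D), dtype=float)
    n = Dv.shape[0]
    if n < 3:
        raise ValueError("need at least 3 taxa to embed")
    if dim < 2:
        raise ValueError("embedding dimension must be >= 2")
    k = kappa.kappa if isinstance(kappa, Curvature) else float(kappa)

    rng = np.random.default_rng(seed)
    Z0 = _spectral_tangent_init(Dv, dim, k)
    if not np.all(np.isfinite(Z0)) or np.allclose(Z0, 0.0):
        Z0 = rng.normal(scale=1e-2, size=(n, dim))

    def stress_of(zflat):
        X = project_to_hyperboloid(zflat.reshape(n, dim))
        return embedding_stress(X, Dv, k)

    vg = value_and_grad(stress_of)
    scale = 0.3 * (np.abs(Z0).std() + 1e-3)
    best = None
    for r in range(max(1, restarts)):
        if r == 0:
            # tiny jitter breaks exact symmetries (e.g. equidistant configurations)
            z = (Z0 + rng.normal(scale=1e-6 * (1.0 + np.abs(Z0).max()), size=Z0.shape)).flatten()
        else:
            z = (Z0 + rng.normal(scale=scale, size=Z0.shape)).flatten()
        cb = None if callback is None else (lambda zk: callback(float(getval(stress_of(zk)))))
        res = minimize(vg, z, jac=True, method="L-BFGS-B",
                       options=dict(maxiter=max_iter), callback=cb)
        cand = (float(res.fun), res.x)
        start = (float(getval(stress_of(z))), z)
        if cand[0] > start[0]:  # line-search pathology guard
            cand = start
        if best is None or cand[0] < best[0]:
            best = cand
    X = np.asarray(getval(project_to_hyperboloid(best[1].reshape(n, dim))))
    return EmbeddingLocations(points=X, taxon_labels=labels or [f"t{i}" for i in range(n)])
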