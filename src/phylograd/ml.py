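"""Maximum-likelihood inference over the embedding space.

The optimisation target is the composite map

    tangent coords --project--> H^d points --d_kappa--> distance matrix
                  --soft-NJ--> tree --pruning--> log-likelihood,

differentiable end to end, maximised by Adam over the n*d tangent
coordinates, the (log-parametrised, always-negative) curvature, and the GTR
parameters (through softmax simplex reparametrisations).  The learning rate
follows the (t+1)^(-1/2) decay schedule.  The tree reported is the one
decoded at the best objective seen, not the last epoch, because soft
decoding can wobble late in a run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import autograd.numpy as anp
import numpy as np
from autograd import value_and_grad
from autograd.tracer import getval
from scipy.optimize import minimize

from .geometry import Curvature, DistanceMatrix, pairwise_distances, project_to_hyperboloid
from .hmds import embed_distances
from .models import Alignment, SubstitutionModel, log_likelihood
from .simulate import tree_path_distances
from .soft_nj import DEFAULT_ETA, PhyloTree, soft_nj_decode

__all__ = [
    "OptimizerConfig",
    "TraceRecord",
    "composite_objective",
    "maximize_likelihood",
    "refine_branch_lengths",
    "jc69_corrected_distances",
]


@dataclass
class OptimizerConfig:
    """Gradient-ascent settings shared by the ML and VI engines.

    The learning rate at epoch t is learning_rate * (t+1)^(-lr_decay_exponent).
    """

    epochs: int = 2000
    learning_rate: float = 0.1
    lr_decay_exponent: float = 0.5
    eta: float = DEFAULT_ETA
    seed: int = 0
    init_curvature: float = -100.0
    dim: int = 3
    optimize_curvature: bool = True

    def __post_init__(self):
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if not self.eta > 0:
            raise ValueError("temperature eta must be > 0")
        if not self.init_curvature < 0:
            raise ValueError("curvature must be negative")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


@dataclass
class TraceRecord:
    """Per-epoch objective, curvature, and gradient norm."""

    objective: list = field(default_factory=list)
    curvature: list = field(default_factory=list)
    grad_norm: list = field(default_factory=list)

    def append(self, obj: float, kappa: float, gnorm: float) -> None:
        self.objective.append(float(obj))
        self.curvature.append(float(kappa))
        self.grad_norm.append(float(gnorm))

    def __len__(self) -> int:
        return len(self.objective)


def _softmax(x):
    e = anp.exp(x - anp.max(x))
    return e / anp.sum(e)


def jc69_corrected_distances(aln: Alignment, max_distance: float = 5.0) -> DistanceMatrix:
    """JC69-corrected pairwise distances, d = -(3/4) ln(1 - 4 p / 3).

    The observed proportion of differing sites p is computed over positions
    where both sequences are unambiguous; saturated pairs are capped at
    ``max_distance`` substitutions per site.
    """
    n = aln.n_taxa
    pats = aln.patterns
    cnt = aln.pattern_counts
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = pats[:, i], pats[:, j]
            ok = (a < 4) & (b < 4)
            tot = float(np.sum(cnt[ok]))
            if tot == 0:
                d = max_distance
            else:
                p = float(np.sum(cnt[ok & (a != b)])) / tot
                if p >= 0.75 - 1e-9:
                    d = max_distance
                else:
                    d = min(-0.75 * np.log(1.0 - 4.0 * p / 3.0), max_distance)
            D[i, j] = D[j, i] = d
    return DistanceMatrix(values=D, labels=list(aln.taxa))


def composite_objective(tangent_coords, curvature, model: SubstitutionModel, aln: Alignment, eta: float = DEFAULT_ETA):
    """Log-likelihood of the tree decoded from embedded tangent coordinates.

    Differentiable w.r.t. the coordinates, the curvature (Curvature, float or
    autograd scalar), and the model parameters.  Taxon i of the alignment is
    the i-th embedded point.
    """
    kappa = curvature.kappa if isinstance(curvature, Curvature) else curvature
    X = project_to_hyperboloid(tangent_coords)
    D = pairwise_distances(X, kappa)
    tree = soft_nj_decode(D, eta, labels=list(aln.taxa))
    return log_likelihood(tree, aln, model)


def _model_from_params(kind: str, rate_logits, freq_logits) -> SubstitutionModel:
    if kind == "JC69":
        return SubstitutionModel.jc69()
    return SubstitutionModel.gtr(_softmax(rate_logits), _softmax(freq_logits))


def maximize_likelihood(
    aln: Alignment,
    start_tree: PhyloTree | None = None,
    config: OptimizerConfig | None = None,
    model: SubstitutionModel | None = None,
) -> tuple[PhyloTree, SubstitutionModel, TraceRecord]:
    """Gradient-ascent maximum likelihood over embedding space.

    The embedding is initialised from the start tree's tip-tip path distances
    (or, when no tree is given, from the JC69-corrected alignment distances
    decoded by cold neighbour joining).  Coordinates, curvature, and GTR
    parameters are optimised jointly for ``config.epochs`` epochs; the tree
    decoded at the best objective is returned.  Deterministic given the seed.
    """
    cfg = config or OptimizerConfig()
    model = model or SubstitutionModel.jc69()
    if aln.n_taxa < 4:
        raise ValueError("need at least 4 taxa for embedding-space ML")
    if start_tree is not None:
        if set(start_tree.taxon_labels) != set(aln.taxa):
            raise ValueError("start tree tips and alignment taxa must match")
        D0 = tree_path_distances(start_tree)
        # re-order rows to alignment taxon order
        perm = [D0.labels.index(t) for t in aln.taxa]
        D0 = DistanceMatrix(values=np.asarray(D0.values)[np.ix_(perm, perm)], labels=list(aln.taxa))
    else:
        D0 = jc69_corrected_distances(aln)
    locs = embed_distances(D0, dim=cfg.dim, kappa=cfg.init_curvature, seed=cfg.seed)
    n, d = aln.n_taxa, cfg.dim
    kind = model.kind

    z0 = np.asarray(locs.tangent).flatten()
    c0 = np.array([np.log(-cfg.init_curvature)])
    extra = np.zeros(10) if kind == "GTR" else np.zeros(0)
    params = np.concatenate([z0, c0, extra])

    def unpack(p):
        z = p[: n * d].reshape(n, d)
        c = p[n * d]
        rl = p[n * d + 1 : n * d + 7] if kind == "GTR" else None
        fl = p[n * d + 7 :] if kind == "GTR" else None
        return z, c, rl, fl

    def objective(p):
        z, c, rl, fl = unpack(p)
        kappa = -anp.exp(c) if cfg.optimize_curvature else cfg.init_curvature
        m = _model_from_params(kind, rl, fl)
        return composite_objective(z, kappa, m, aln, cfg.eta)

    vg = value_and_grad(objective)
    trace = TraceRecord()
    best_obj, best_p = -np.inf, params.copy()
    m1 = np.zeros_like(params)
    m2 = np.zeros_like(params)
    b1, b2, eps = 0.9, 0.999, 1e-8
    for t in range(cfg.epochs):
        val, g = vg(params)
        val = float(getval(val))
        g = np.asarray(getval(g))
        if not np.isfinite(val):
            raise FloatingPointError(f"objective diverged (non-finite) at epoch {t}")
        if val > best_obj:
            best_obj, best_p = val, params.copy()
        z, c, _, _ = unpack(params)
        trace.append(val, -np.exp(float(c)), float(np.linalg.norm(g)))
        lr = cfg.learning_rate * (t + 1) ** (-cfg.lr_decay_exponent)
        m1 = b1 * m1 + (1 - b1) * g
        m2 = b2 * m2 + (1 - b2) * g * g
        mh = m1 / (1 - b1 ** (t + 1))
        vh = m2 / (1 - b2 ** (t + 1))
        params = params + lr * mh / (np.sqrt(vh) + eps)  # ascent

    z, c, rl, fl = unpack(best_p)
    kappa = -np.exp(float(c)) if cfg.optimize_curvature else cfg.init_curvature
    fitted = _model_from_params(kind, None if rl is None else np.asarray(rl), None if fl is None else np.asarray(fl))
    if kind == "GTR":
        fitted = SubstitutionModel.gtr(np.asarray(getval(fitted.rates)), np.asarray(getval(fitted.freqs)))
    X = project_to_hyperboloid(z)
    tree = soft_nj_decode(pairwise_distances(X, kappa), cfg.eta, labels=list(aln.taxa))
    tree = tree.with_lengths(tree.lengths_value())
    return tree, fitted, trace


def refine_branch_lengths(tree: PhyloTree, aln: Alignment, model: SubstitutionModel, max_iter: int = 200) -> PhyloTree:
    """Re-optimise branch lengths on a fixed topology by L-BFGS.

    Lengths are optimised in log space (so they stay positive); the input
    tree is returned unchanged if no improvement is found, so the output
    log-likelihood is never worse than the input's.
    """
    bl0 = np.maximum(tree.lengths_value(), 1e-8)
    ll0 = float(getval(log_likelihood(tree, aln, model)))

    def neg_ll(logbl):
        return -log_likelihood(tree.with_lengths(anp.exp(logbl)), aln, model)

    res = minimize(value_and_grad(neg_ll), np.log(bl0), jac=True, method="L-BFGS-B",
                   options=dict(maxiter=max_iter))
    if np.isfinite(res.fun) and -res.fun > ll0:
        return tree.with_lengths(np.exp(res.x))
    return tree
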