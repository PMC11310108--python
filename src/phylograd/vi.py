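"""Variational Bayesian phylogenetics over hyperbolic embeddings.

Each taxon gets a K-component mixture of diagonal (mean-field) multivariate
normals in the tangent space of the hyperboloid origin; a draw is projected
onto H^d, turned into pairwise distances at a fixed curvature, and decoded by
soft-NJ into a tree.  The variational parameters (mixture logits, means, log
scales) are optimised by stochastic gradient ascent on the stratified
importance-weighted (SIWAE) bound

    L = E[ log (1/M) sum_m sum_k alpha_k p(T,D) / q_k(T) ],

with one fresh reparametrised draw from each component k per inner sample m.
K = 1, M = 1 reduces to the usual one-sample ELBO estimator.

Because sampling changes dimensionality (n*d tangent coordinates -> 2n-3
branch lengths), the density of a decoded tree needs the generalized-Jacobian
volume factor det(J J^T)^(1/2), where J is the Jacobian of the
tangent-to-branch-lengths map at the draw, assembled by automatic
differentiation:

    log q(T) = log q_tangent(z) - (1/2) log det(J J^T).

The marginal likelihood is estimated by importance sampling from the fitted
mixture, log p(D) ~ log (1/N) sum_i p(D|T_i) p(T_i) / q(T_i), computed in
log space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import autograd.numpy as anp
import numpy as np
from autograd import jacobian, value_and_grad
from autograd.scipy.special import logsumexp
from autograd.tracer import getval

from .geometry import Curvature, EmbeddingLocations, pairwise_distances, project_to_hyperboloid
from .hmds import embed_distances
from .ml import OptimizerConfig, TraceRecord, jc69_corrected_distances, _softmax
from .models import (
    Alignment,
    SubstitutionModel,
    log_likelihood,
    log_prior_exp_branches,
    log_prior_gamma_dirichlet,
    log_prior_gtr,
)
from .simulate import tree_path_distances
from .soft_nj import DEFAULT_ETA, PhyloTree, soft_nj_decode

__all__ = [
    "VariationalParams",
    "TreeSample",
    "init_variational",
    "sample_tree",
    "siwae_objective",
    "fit_variational",
    "estimate_marginal_likelihood",
    "importance_log_evidence",
    "log_joint",
]

#: default coefficient of variation for the initial scales: sigma is the
#: smallest tip-tip distance divided by this
DEFAULT_CV = 20.0

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class VariationalParams:
    """Mixture-of-projected-normals distribution over trees.

    ``mixture_logits`` (K,) map to weights via softmax; ``means`` and
    ``log_scales`` are (K, n, d) per-component, per-taxon tangent-space
    parameters.
    """

    mixture_logits: np.ndarray
    means: np.ndarray
    log_scales: np.ndarray
    taxon_labels: list = field(default_factory=list)

    def __post_init__(self):
        self.mixture_logits = np.asarray(getval(self.mixture_logits), dtype=float) \
            if not _boxed(self.mixture_logits) else self.mixture_logits
        if np.ndim(getval(self.means)) != 3:
            raise ValueError("means must be (K, n, d)")
        if np.shape(getval(self.means)) != np.shape(getval(self.log_scales)):
            raise ValueError("means and log_scales must have matching shapes")
        if not self.taxon_labels:
            self.taxon_labels = [f"t{i}" for i in range(self.n_taxa)]

    @property
    def K(self) -> int:
        return np.shape(getval(self.means))[0]

    @property
    def n_taxa(self) -> int:
        return np.shape(getval(self.means))[1]

    @property
    def dim(self) -> int:
        return np.shape(getval(self.means))[2]

    @property
    def weights(self):
        return _softmax(self.mixture_logits)

    # --- flat parameter vector interface for optimisers -------------------
    def pack(self) -> np.ndarray:
        return np.concatenate([
            np.asarray(getval(self.mixture_logits)).ravel(),
            np.asarray(getval(self.means)).ravel(),
            np.asarray(getval(self.log_scales)).ravel(),
        ])

    def unpack_like(self, flat):
        K, n, d = self.K, self.n_taxa, self.dim
        logits = flat[:K]
        means = flat[K : K + K * n * d].reshape(K, n, d)
        log_scales = flat[K + K * n * d :].reshape(K, n, d)
        return logits, means, log_scales

    def replaced(self, flat) -> "VariationalParams":
        logits, means, log_scales = self.unpack_like(np.asarray(getval(flat)))
        return VariationalParams(logits, means, log_scales, list(self.taxon_labels))


def _boxed(x) -> bool:
    return type(x).__module__.startswith("autograd")


@dataclass
class TreeSample:
    """One tree drawn from the variational distribution.

    ``log_q`` is the Jacobian-corrected mixture density of the draw in tree
    space; ``log_joint`` = log p(D|T) + log p(T) (+ log p(M)) when the sample
    was taken with a model attached, else None.
    """

    tree: PhyloTree
    log_q: float
    log_joint: float | None = None


def init_variational(
    locs: EmbeddingLocations,
    K: int,
    cv: float = DEFAULT_CV,
    kappa=-1.0,
    jitter: float = 0.0,
    seed: int = 0,
) -> VariationalParams:
    """Centre a K-component mixture on an embedding.

    Every component mean starts at the tangent coordinates of ``locs`` (plus
    an optional seeded jitter of ``jitter * sigma`` per component so
    components are not exactly degenerate); all scales start at
    sigma = (smallest tip-tip distance) / cv, with the global minimum taken
    over the embedded pairwise distances; weights start equal at 1/K.
    """
    if K < 1:
        raise ValueError("need at least one mixture component")
    if not cv > 0:
        raise ValueError("coefficient of variation must be positive")
    k = kappa.kappa if isinstance(kappa, Curvature) else float(kappa)
    D = np.asarray(getval(pairwise_distances(locs, k).values))
    n = locs.n
    iu = np.triu_indices(n, 1)
    sigma = float(np.min(D[iu])) / cv
    if sigma <= 0:
        sigma = 1e-3 / cv
    z = np.asarray(getval(locs.tangent))
    rng = np.random.default_rng(seed)
    means = np.stack([z + jitter * sigma * rng.standard_normal(z.shape) for _ in range(K)])
    log_scales = np.full((K, n, z.shape[1]), np.log(sigma))
    return VariationalParams(np.zeros(K), means, log_scales, list(locs.taxon_labels))


def log_joint(tree: PhyloTree, aln: Alignment, model: SubstitutionModel, prior: str = "gamma_dirichlet", exp_rate: float = 10.0):
    """log p(T, D) = log p(D|T,M) + log p(T) + log p(M)."""
    ll = log_likelihood(tree, aln, model)
    if prior == "gamma_dirichlet":
        lp = log_prior_gamma_dirichlet(tree)
    elif prior == "exp10":
        lp = log_prior_exp_branches(tree, rate=exp_rate)
    else:
        raise ValueError(f"unknown prior {prior!r}")
    return ll + lp + log_prior_gtr(model)


def _decode_fn(params: VariationalParams, kappa: float, eta: float):
    n, d = params.n_taxa, params.dim
    labels = list(params.taxon_labels)

    def decode(zflat):
        X = project_to_hyperboloid(zflat.reshape(n, d))
        D = pairwise_distances(X, kappa)
        return soft_nj_decode(D, eta, labels=labels)

    return decode


def _log_gram_det(decode, zflat):
    """(1/2) log det(J J^T) for the tangent->branch-lengths map at zflat."""
    J = jacobian(lambda z: decode(z).branch_lengths)(zflat)
    G = J @ J.T
    sign, ld = anp.linalg.slogdet(G)
    sv = float(getval(sign))
    lv = float(getval(ld))
    if sv <= 0 or not np.isfinite(lv):
        raise FloatingPointError("singular generalized-Jacobian Gram matrix (degenerate configuration)")
    return 0.5 * ld


def _normal_logpdf_sum(z, mean, log_scale):
    """Sum of independent normal log-densities (diagonal covariance)."""
    var = anp.exp(2.0 * log_scale)
    return anp.sum(-0.5 * _LOG2PI - log_scale - 0.5 * (z - mean) ** 2 / var)


def _mixture_log_density(z, logits, means, log_scales):
    K = np.shape(getval(means))[0]
    logw = logits - logsumexp(logits)
    comps = [logw[k] + _normal_logpdf_sum(z, means[k].ravel(), log_scales[k].ravel()) for k in range(K)]
    return logsumexp(anp.stack(comps))


def sample_tree(
    params: VariationalParams,
    eta: float = DEFAULT_ETA,
    kappa=-1.0,
    seed: int | np.random.Generator = 0,
    aln: Alignment | None = None,
    model: SubstitutionModel | None = None,
    prior: str = "gamma_dirichlet",
    include_jacobian: bool = True,
) -> TreeSample:
    """Draw one tree from the variational mixture.

    Draws a component from the mixture weights, a tangent vector from its
    diagonal normal, projects it onto the hyperboloid, and decodes by
    soft-NJ.  ``log_q`` is the full mixture density of the draw corrected by
    the generalized-Jacobian factor.  With ``aln`` and ``model`` given,
    ``log_joint`` is filled in too.  Deterministic given the seed.
    """
    k = kappa.kappa if isinstance(kappa, Curvature) else float(kappa)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w = np.asarray(getval(params.weights))
    comp = int(rng.choice(params.K, p=w))
    mu = np.asarray(getval(params.means))[comp]
    sd = np.exp(np.asarray(getval(params.log_scales))[comp])
    z = (mu + sd * rng.standard_normal(mu.shape)).flatten()
    decode = _decode_fn(params, k, eta)
    tree = decode(z)
    tree = tree.with_lengths(tree.lengths_value())
    lq = _mixture_log_density(z, params.mixture_logits,
                              np.asarray(getval(params.means)),
                              np.asarray(getval(params.log_scales)))
    lq = float(getval(lq))
    if include_jacobian:
        lq = lq - float(getval(_log_gram_det(decode, z)))
    lj = None
    if aln is not None and model is not None:
        lj = float(getval(log_joint(tree, aln, model, prior)))
    return TreeSample(tree=tree, log_q=lq, log_joint=lj)


def _siwae_from_flat(flat, template: VariationalParams, aln, model, M, eps, kappa, eta, prior, include_jacobian):
    """SIWAE value as a differentiable function of the flat parameter vector.

    ``eps`` is an (M, K, n, d) block of standard-normal reparametrisation
    noise, one fresh draw per (inner sample, component) pair.
    """
    K, n, d = template.K, template.n_taxa, template.dim
    logits = flat[:K]
    means = flat[K : K + K * n * d].reshape(K, n, d)
    log_scales = flat[K + K * n * d :].reshape(K, n, d)
    logw = logits - logsumexp(logits)
    decode = _decode_fn(template, kappa, eta)
    terms = []
    for m in range(M):
        for k in range(K):
            z = (means[k] + anp.exp(log_scales[k]) * eps[m, k]).flatten()
            tree = decode(z)
            lq = _normal_logpdf_sum(z, means[k].ravel(), log_scales[k].ravel())
            if include_jacobian:
                J = jacobian(lambda zz: decode(zz).branch_lengths)(z)
                G = J @ J.T
                _, ld = anp.linalg.slogdet(G)
                lq = lq - 0.5 * ld
            lj = log_joint(tree, aln, model, prior)
            terms.append(logw[k] + lj - lq)
    return logsumexp(anp.stack(terms)) - anp.log(M)


def siwae_objective(
    params: VariationalParams,
    aln: Alignment,
    model: SubstitutionModel,
    M: int = 1,
    seed: int | np.random.Generator = 0,
    kappa=-1.0,
    eta: float = DEFAULT_ETA,
    prior: str = "gamma_dirichlet",
    include_jacobian: bool = True,
):
    """One stochastic evaluation of the SIWAE bound.

    Stratified: each of the M inner samples takes one fresh draw from every
    component, weighted by its mixture weight.  Reparametrised, hence
    differentiable w.r.t. the variational parameters.
    """
    if M < 1:
        raise ValueError("need at least one importance sample")
    k = kappa.kappa if isinstance(kappa, Curvature) else float(kappa)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eps = rng.standard_normal((M, params.K, params.n_taxa, params.dim))
    flat = params.pack()
    return _siwae_from_flat(flat, params, aln, model, M, eps, k, eta, prior, include_jacobian)


def fit_variational(
    aln: Alignment,
    start_tree: PhyloTree | None = None,
    config: OptimizerConfig | None = None,
    K: int = 3,
    M: int = 1,
    model: SubstitutionModel | None = None,
    prior: str = "gamma_dirichlet",
    cv: float = DEFAULT_CV,
    jitter: float = 0.1,
    include_jacobian: bool = True,
) -> tuple[VariationalParams, TraceRecord]:
    """Stochastic gradient ascent on the SIWAE bound.

    The mixture is initialised from a hyperbolic embedding of the start
    tree's tip-tip distances (or of the NJ distances of the alignment); the
    curvature stays fixed at its initial value throughout.  Deterministic
    given ``config.seed``.
    """
    cfg = config or OptimizerConfig()
    model = model or SubstitutionModel.jc69()
    if aln.n_taxa < 4:
        raise ValueError("need at least 4 taxa")
    if start_tree is not None:
        if set(start_tree.taxon_labels) != set(aln.taxa):
            raise ValueError("start tree tips and alignment taxa must match")
        D0 = tree_path_distances(start_tree)
        perm = [D0.labels.index(t) for t in aln.taxa]
        from .geometry import DistanceMatrix

        D0 = DistanceMatrix(values=np.asarray(D0.values)[np.ix_(perm, perm)], labels=list(aln.taxa))
    else:
        D0 = jc69_corrected_distances(aln)
    locs = embed_distances(D0, dim=cfg.dim, kappa=cfg.init_curvature, seed=cfg.seed)
    params = init_variational(locs, K, cv=cv, kappa=cfg.init_curvature, jitter=jitter, seed=cfg.seed)

    rng = np.random.default_rng(cfg.seed)
    flat = params.pack()
    vg = value_and_grad(
        lambda f, eps: _siwae_from_flat(f, params, aln, model, M, eps, cfg.init_curvature, cfg.eta, prior, include_jacobian)
    )
    trace = TraceRecord()
    m1 = np.zeros_like(flat)
    m2 = np.zeros_like(flat)
    b1, b2, epsu = 0.9, 0.999, 1e-8
    for t in range(cfg.epochs):
        eps = rng.standard_normal((M, K, params.n_taxa, params.dim))
        try:
            val, g = vg(flat, eps)
        except np.linalg.LinAlgError as exc:
            raise FloatingPointError(f"SIWAE diverged (singular Jacobian Gram) at epoch {t}") from exc
        val = float(getval(val))
        g = np.asarray(getval(g))
        if not np.isfinite(val) or not np.all(np.isfinite(g)):
            raise FloatingPointError(f"SIWAE diverged (non-finite) at epoch {t}")
        trace.append(val, cfg.init_curvature, float(np.linalg.norm(g)))
        lr = cfg.learning_rate * (t + 1) ** (-cfg.lr_decay_exponent)
        m1 = b1 * m1 + (1 - b1) * g
        m2 = b2 * m2 + (1 - b2) * g * g
        mh = m1 / (1 - b1 ** (t + 1))
        vh = m2 / (1 - b2 ** (t + 1))
        flat = flat + lr * mh / (np.sqrt(vh) + epsu)
    return params.replaced(flat), trace


def importance_log_evidence(log_joints, log_qs) -> tuple[float, float]:
    """log of the importance-sampling average and its MC standard error.

    Computes log((1/N) sum exp(log_joint - log_q)) stably; the standard
    error of the log-estimate follows from the delta method on the
    normalised weights.
    """
    lw = np.asarray(log_joints, dtype=float) - np.asarray(log_qs, dtype=float)
    N = lw.size
    mx = np.max(lw)
    w = np.exp(lw - mx)
    est = mx + np.log(np.mean(w))
    se = float(np.std(w, ddof=1) / (np.mean(w) * np.sqrt(N))) if N > 1 else np.inf
    return float(est), se


def estimate_marginal_likelihood(
    params: VariationalParams,
    aln: Alignment,
    model: SubstitutionModel,
    N: int = 1000,
    seed: int = 0,
    kappa=-1.0,
    eta: float = DEFAULT_ETA,
    prior: str = "exp10",
    include_jacobian: bool = True,
    return_se: bool = False,
):
    """Variational importance-sampling estimate of log p(D).

    Draws N trees from the fitted mixture and averages p(D|T) p(T) / q(T) in
    log space.  Invariant to the order of the samples.
    """
    if N < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    ljs, lqs = [], []
    for _ in range(N):
        s = sample_tree(params, eta=eta, kappa=kappa, seed=rng, aln=aln, model=model,
                        prior=prior, include_jacobian=include_jacobian)
        ljs.append(s.log_joint)
        lqs.append(s.log_q)
    est, se = importance_log_evidence(ljs, lqs)
    return (est, se) if return_se else est
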