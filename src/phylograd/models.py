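"""Substitution models, the pruning likelihood, and prior densities.

Supports JC69 (closed-form transition probabilities) and GTR (six
exchangeabilities on the 6-simplex, four equilibrium frequencies on the
4-simplex; matrix exponential via symmetrised eigendecomposition).  Rate
matrices are normalised to one expected substitution per site per unit branch
length, so JC69 is exactly GTR at uniform parameters.

The log-likelihood is computed by Felsenstein pruning over compressed site
patterns with per-node rescaling, and is differentiable with respect to
branch lengths and GTR parameters through autograd.

Priors: the Gamma-Dirichlet prior on branch lengths (Gamma over the total
tree length, flat Dirichlet over branch proportions), an alternative
uniform-topology + i.i.d. exponential branch prior, and flat Dirichlets on
the GTR simplices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import autograd.numpy as anp
import numpy as np
from autograd.scipy.special import gammaln
from autograd.tracer import getval

from .geometry import as_array
from .soft_nj import PhyloTree

__all__ = [
    "Alignment",
    "SubstitutionModel",
    "transition_probs",
    "log_likelihood",
    "log_prior_gamma_dirichlet",
    "log_prior_exp_branches",
    "log_prior_gtr",
    "NUCLEOTIDES",
]

NUCLEOTIDES = "ACGT"
_MISSING_CODE = 4
# alphabet: canonical bases, RNA U -> T, and gap/unknown treated as missing
_CHAR_CODES = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "-": 4, "?": 4, "N": 4}

#: GTR exchangeability order
RATE_ORDER = ("AC", "AG", "AT", "CG", "CT", "GT")
_RATE_INDEX = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]


@dataclass
class Alignment:
    """A multiple sequence alignment with compressed site patterns.

    ``patterns`` is an (n_patterns, n_taxa) integer matrix of state codes
    (0..3 = ACGT, 4 = missing) holding the unique alignment columns, and
    ``pattern_counts`` their multiplicities (summing to the alignment length).
    """

    taxa: list
    sequences: list
    patterns: np.ndarray = field(init=False, repr=False)
    pattern_counts: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if len(self.taxa) != len(self.sequences):
            raise ValueError("one sequence per taxon required")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels in alignment")
        if len(self.sequences) == 0:
            raise ValueError("empty alignment")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            bad = next(t for t, s in zip(self.taxa, self.sequences) if len(s) != len(self.sequences[0]))
            raise ValueError(f"sequences have unequal lengths (e.g. record '{bad}')")
        codes = np.empty((len(self.sequences), len(self.sequences[0])), dtype=np.int8)
        for i, seq in enumerate(self.sequences):
            for j, ch in enumerate(seq.upper()):
                try:
                    codes[i, j] = _CHAR_CODES[ch]
                except KeyError:
                    raise ValueError(
                        f"unsupported character {ch!r} in sequence '{self.taxa[i]}'"
                    ) from None
        cols, counts = np.unique(codes.T, axis=0, return_counts=True)
        self.patterns = cols
        self.pattern_counts = counts

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0])

    def tip_partials(self) -> np.ndarray:
        """(n_taxa, n_patterns, 4) conditional likelihoods at the tips.

        Observed states are indicators; missing data is a vector of ones.
        """
        n_pat = self.patterns.shape[0]
        out = np.zeros((self.n_taxa, n_pat, 4))
        for i in range(self.n_taxa):
            col = self.patterns[:, i]
            obs = col < 4
            out[i, obs, col[obs]] = 1.0
            out[i, ~obs, :] = 1.0
        return out


def _simplex_ok(x, size, tol=1e-6):
    x = np.asarray(getval(x), dtype=float)
    return x.shape == (size,) and np.all(x >= -tol) and abs(float(np.sum(x)) - 1.0) <= tol


@dataclass
class SubstitutionModel:
    """JC69 or GTR nucleotide substitution model.

    ``rates`` are the six exchangeabilities (order AC, AG, AT, CG, CT, GT) on
    the simplex; ``freqs`` the equilibrium base frequencies (ACGT order) on
    the simplex.  JC69 pins rates = 1/6 and freqs = 1/4.
    """

    kind: str = "JC69"
    rates: np.ndarray = None
    freqs: np.ndarray = None

    def __post_init__(self):
        self.kind = self.kind.upper()
        if self.kind not in ("JC69", "GTR"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.kind == "JC69":
            if self.rates is None:
                self.rates = np.full(6, 1.0 / 6.0)
            if self.freqs is None:
                self.freqs = np.full(4, 0.25)
        else:
            if self.rates is None:
                self.rates = np.full(6, 1.0 / 6.0)
            if self.freqs is None:
                self.freqs = np.full(4, 0.25)
        self.rates = as_array(self.rates)
        self.freqs = as_array(self.freqs)
        if not _simplex_ok(self.rates, 6):
            raise ValueError("rates must be a 6-vector on the simplex")
        if not _simplex_ok(self.freqs, 4):
            raise ValueError("freqs must be a 4-vector on the simplex")

    @classmethod
    def jc69(cls) -> "SubstitutionModel":
        return cls(kind="JC69")

    @classmethod
    def gtr(cls, rates, freqs) -> "SubstitutionModel":
        return cls(kind="GTR", rates=rates, freqs=freqs)


def _gtr_eigensystem(model: SubstitutionModel):
    """Eigendecomposition of the normalised reversible rate matrix.

    Returns (lam, B, Binv, pi) with Q = B diag(lam) Binv, built from the
    symmetric similarity transform diag(sqrt(pi)) Q diag(1/sqrt(pi)) so the
    decomposition is stable and differentiable.
    """
    pi = model.freqs
    # symmetric exchangeability matrix
    sym = anp.zeros((4, 4))
    for (i, j), r in zip(_RATE_INDEX, [model.rates[k] for k in range(6)]):
        e = np.zeros((4, 4))
        e[i, j] = e[j, i] = 1.0
        sym = sym + r * e
    Q = sym * pi[None, :]
    Q = Q - anp.diag(anp.sum(Q, axis=1))
    # normalise to one expected substitution per unit time
    mu = -anp.sum(pi * anp.diag(Q))
    Q = Q / mu
    sq = anp.sqrt(pi)
    S = (sq[:, None] * Q) / sq[None, :]
    S = 0.5 * (S + S.T)  # enforce exact symmetry for eigh
    lam, V = anp.linalg.eigh(S)
    B = V / sq[:, None]
    Binv = V.T * sq[None, :]
    return lam, B, Binv, pi


def transition_probs(model: SubstitutionModel, t):
    """4x4 transition probability matrix P(t) = exp(Q t).

    JC69 uses the closed form; GTR exponentiates the normalised rate matrix.
    Branch length t is in expected substitutions per site and must be >= 0.
    """
    tv = float(getval(t))
    if tv < 0:
        raise ValueError(f"branch length must be non-negative, got {tv}")
    if model.kind == "JC69":
        e = anp.exp(-4.0 * t / 3.0)
        eye = np.eye(4)
        return (0.25 + 0.75 * e) * eye + (0.25 - 0.25 * e) * (1.0 - eye)
    lam, B, Binv, _ = _gtr_eigensystem(model)
    return (B * anp.exp(lam * t)[None, :]) @ Binv


def _rooted_traversal(tree: PhyloTree, root: int | None = None):
    """Post-order list of (node, [(child, edge_index), ...]) from a root node."""
    adj = tree.adjacency()
    if root is None:
        root = tree.n_nodes - 1  # last internal node
    stack = [(root, -1)]
    visit = []
    while stack:
        v, parent = stack.pop()
        children = [(w, e) for (w, e) in adj[v] if w != parent]
        visit.append((v, children))
        for w, _ in children:
            stack.append((w, v))
    visit.reverse()  # children before parents
    return root, visit


def log_likelihood(tree: PhyloTree, aln: Alignment, model: SubstitutionModel, root: int | None = None):
    """Felsenstein-pruning log-likelihood log p(D | T, M).

    Site patterns are compressed; partial likelihood vectors are rescaled by
    their per-pattern maximum at every internal node so alignments of
    thousands of sites do not underflow.  For a reversible model the value is
    invariant to the (arbitrary) root placement used for pruning.
    """
    if set(tree.taxon_labels) != set(aln.taxa):
        raise ValueError("tree tips and alignment taxa must match as a set")
    # map tree tip index -> alignment row
    aln_index = {t: i for i, t in enumerate(aln.taxa)}
    tips = aln.tip_partials()
    root, visit = _rooted_traversal(tree, root)
    n_pat = aln.patterns.shape[0]
    partial = {}
    log_scale = 0.0
    lam = B = Binv = None
    if model.kind == "GTR":
        lam, B, Binv, _ = _gtr_eigensystem(model)
    for v, children in visit:
        if not children:  # tip
            partial[v] = tips[aln_index[tree.taxon_labels[v]]]
            continue
        acc = 1.0
        for w, e in children:
            t = tree.branch_lengths[e]
            if model.kind == "JC69":
                ex = anp.exp(-4.0 * t / 3.0)
                eye = np.eye(4)
                P = (0.25 + 0.75 * ex) * eye + (0.25 - 0.25 * ex) * (1.0 - eye)
            else:
                P = (B * anp.exp(lam * t)[None, :]) @ Binv
            acc = acc * (partial[w] @ P.T)
        mx = anp.max(acc, axis=1)
        partial[v] = acc / mx[:, None]
        log_scale = log_scale + anp.log(mx)
    site_l = partial[root] @ model.freqs
    return anp.sum((anp.log(site_l) + log_scale) * aln.pattern_counts)


def _log_gamma_pdf(x, shape, rate):
    return shape * anp.log(rate) + (shape - 1.0) * anp.log(x) - rate * x - gammaln(shape)


def log_prior_gamma_dirichlet(tree: PhyloTree, shape: float = 1.0, rate: float = 0.1):
    """Gamma-Dirichlet branch-length prior.

    A Gamma(shape, rate) density on the total tree length TL, a flat
    Dirichlet on the branch proportions, and the Jacobian -(B-1) log TL of
    the (TL, proportions) -> branch-lengths change of variables.  Returns
    -inf for any zero-length branch.
    """
    bl = tree.branch_lengths
    if np.any(tree.lengths_value() <= 0):
        return -np.inf
    B = tree.n_edges
    total = anp.sum(bl)
    log_gamma = _log_gamma_pdf(total, shape, rate)
    log_dirichlet = gammaln(float(B))  # log (B-1)! ; flat Dirichlet, proportions drop out
    log_jacobian = -(B - 1.0) * anp.log(total)
    return log_gamma + log_dirichlet + log_jacobian


def _log_num_unrooted_topologies(n: int) -> float:
    """log (2n-5)!! — the number of unrooted bifurcating topologies on n tips."""
    return float(sum(np.log(k) for k in range(3, 2 * n - 4, 2))) if n > 3 else 0.0


def log_prior_exp_branches(tree: PhyloTree, rate: float = 10.0, include_topology: bool = True):
    """Uniform-topology, i.i.d. Exponential(rate) branch-length prior."""
    bl = tree.branch_lengths
    B = tree.n_edges
    out = B * anp.log(rate) - rate * anp.sum(bl)
    if include_topology:
        out = out - _log_num_unrooted_topologies(tree.n_tips)
    return out


def log_prior_gtr(model: SubstitutionModel):
    """Flat Dirichlet priors on the GTR simplices: log 5! + log 3!.

    JC69 has no free parameters, so its prior constant is dropped (0).
    """
    if model.kind == "JC69":
        return 0.0
    if not _simplex_ok(model.rates, 6) or not _simplex_ok(model.freqs, 4):
        raise ValueError("GTR parameters must lie on their simplices")
    return float(np.log(120.0) + np.log(6.0))
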