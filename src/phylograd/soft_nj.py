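"""Differentiable neighbour joining (soft-NJ).

Classical neighbour joining repeatedly joins the pair of active nodes that
minimises the Studier–Keppler Q-criterion; the argmin makes the map from a
distance matrix to branch lengths piecewise and non-differentiable.  Soft-NJ
replaces the argmin with a temperature-controlled soft-sort selection: the
joined pair is chosen by a pair of weight vectors (numerically one-hot at cold
temperature), and every quantity derived from the selection — joined distance,
row sums, branch lengths, and the agglomerated distance row — is computed as a
weighted combination over all active nodes.  Gradients therefore flow from the
input distances into every branch length of the decoded tree, while at
temperature eta <= 1e-5 the output coincides with classical NJ up to the
branch-length floor.

Bookkeeping (which global node ids merged) is taken from the hard argmax of
the soft weights; values stay soft.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import autograd.numpy as anp
import numpy as np
from autograd.tracer import getval

from .geometry import DistanceMatrix, as_array

__all__ = [
    "SoftSelection",
    "PhyloTree",
    "soft_sort_permutation",
    "soft_argmin",
    "nj_q_matrix",
    "soft_nj_decode",
    "DEFAULT_ETA",
    "BRANCH_LENGTH_FLOOR",
]

#: default soft-sort temperature; cold enough that soft-NJ is numerically hard
DEFAULT_ETA = 1e-5

#: smallest branch length emitted by the decoder (classical NJ can go negative;
#: the likelihood and the branch-length priors require positive lengths)
BRANCH_LENGTH_FLOOR = 1e-6

#: sharpness of the smooth branch-length floor; chosen so the deviation from a
#: hard max never exceeds log(2)/BETA ~ 7e-7
_FLOOR_BETA = 1e6

#: large finite diagonal sentinel for Q matrices (IEEE infinities poison
#: softmax gradients)
Q_DIAGONAL_SENTINEL = 1e10

#: floor for the tie-break indicator between the two soft-sort passes.  At
#: cold temperature the indicator spans from 1 down to subnormal magnitudes,
#: and second derivatives of |g_i - g_j| at subnormal arguments underflow to
#: 0/0.  Entries this small are guaranteed losers; clamping them to a shared
#: constant keeps all second-order quantities in the normal range.
_TIE_INDICATOR_FLOOR = 1e-12


@dataclass
class SoftSelection:
    """Soft one-hot row/column weights selecting a pair of active nodes."""

    row_weights: np.ndarray
    col_weights: np.ndarray

    def hard_indices(self) -> tuple[int, int]:
        """Argmax bookkeeping indices (row, col), guaranteed distinct."""
        wr = np.asarray(getval(self.row_weights))
        wc = np.asarray(getval(self.col_weights))
        i = int(np.argmax(wr))
        wc_masked = wc.copy()
        wc_masked[i] = -np.inf
        j = int(np.argmax(wc_masked))
        return (i, j) if i < j else (j, i)


@dataclass
class PhyloTree:
    """Unrooted bifurcating tree over n labelled tips.

    Nodes are integers: tips 0..n-1 (in ``taxon_labels`` order), internal
    nodes n..2n-3.  ``edges[e]`` is an unordered node pair carrying branch
    length ``branch_lengths[e]``; a valid tree has 2n-3 edges and n-2 internal
    nodes of degree three.  ``branch_lengths`` may be an autograd box so that
    decoded trees stay differentiable end to end.
    """

    n_tips: int
    taxon_labels: list
    edges: list = field(default_factory=list)
    branch_lengths: np.ndarray = None

    def __post_init__(self):
        if self.branch_lengths is not None and isinstance(self.branch_lengths, (list, tuple)):
            self.branch_lengths = np.asarray(self.branch_lengths, dtype=float)

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_tips - 2

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> dict:
        """node -> list of (neighbour, edge_index)."""
        adj = {v: [] for v in range(self.n_nodes)}
        for e, (a, b) in enumerate(self.edges):
            adj[a].append((b, e))
            adj[b].append((a, e))
        return adj

    def total_length(self):
        return anp.sum(self.branch_lengths)

    def lengths_value(self) -> np.ndarray:
        """Branch lengths as a plain float array (autograd boxes unwrapped)."""
        return np.asarray(getval(self.branch_lengths), dtype=float)

    def with_lengths(self, lengths) -> "PhyloTree":
        return PhyloTree(self.n_tips, list(self.taxon_labels), list(self.edges), lengths)

    def validate(self) -> None:
        n = self.n_tips
        if n < 3:
            raise ValueError("a phylogenetic tree needs at least 3 tips")
        if self.n_edges != 2 * n - 3:
            raise ValueError(f"expected {2 * n - 3} edges, found {self.n_edges}")
        deg = np.zeros(self.n_nodes, dtype=int)
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        if not np.all(deg[:n] == 1):
            raise ValueError("every tip must have degree 1")
        if not np.all(deg[n:] == 3):
            raise ValueError("every internal node must have degree 3")
        bl = self.lengths_value()
        if bl.shape != (self.n_edges,):
            raise ValueError("one branch length per edge required")
        if not np.all(np.isfinite(bl)):
            raise ValueError("branch lengths must be finite")
        if np.any(bl < 0):
            raise ValueError("branch lengths must be non-negative")


def smooth_branch_floor(x, floor: float = BRANCH_LENGTH_FLOOR):
    """Differentiable max(x, floor) via a sharp softplus.

    |smooth - hard| <= log(2)/_FLOOR_BETA < 1e-6 everywhere, and is exactly 0
    in double precision once x - floor > ~7.5e-4.
    """
    t = (x - floor) * _FLOOR_BETA
    sp = (anp.maximum(t, 0.0) + anp.log1p(anp.exp(-anp.abs(t)))) / _FLOOR_BETA
    return floor + sp


def soft_sort_permutation(x, eta: float):
    """Relaxed descending-sort permutation matrix of a vector.

    P = softmax(-|sort(x) 1^T - 1 x^T| / eta), row-stochastic.  Row i softly
    selects the i-th largest entry of x, so ``P[0]`` is a soft argmax and
    ``P[-1]`` a soft argmin.  Ties in x are ordered first-occurrence-first
    (stable sort).  As eta -> 0 with distinct entries, P converges to the hard
    sorting permutation.
    """
    if not eta > 0:
        raise ValueError(f"temperature eta must be > 0, got {eta}")
    x = as_array(x)
    xv = np.asarray(getval(x), dtype=float)
    if not np.all(np.isfinite(xv)):
        raise ValueError("soft-sort input must be finite")
    order = np.argsort(-xv, kind="stable")  # descending, first occurrence wins
    s = x[order]
    scores = -anp.abs(s[:, None] - x[None, :]) / eta
    scores = scores - anp.max(scores, axis=1, keepdims=True)
    e = anp.exp(scores)
    return e / anp.sum(e, axis=1, keepdims=True)


def _reverse_cumsum(p):
    return anp.cumsum(p[::-1])[::-1]


def soft_argmin(Q, eta: float) -> SoftSelection:
    """Differentiable argmin over the strict upper triangle of a matrix.

    Two soft-sort passes: the first yields a soft indicator of the minimal
    entries of the flattened (row-major) upper triangle; the second breaks
    ties by re-sorting the indicator weighted with its reversed cumulative
    sum, so that at cold temperature the FIRST minimal entry in flattened
    order is selected.  Returns row/column weight vectors over the m active
    nodes, each summing to one and fully differentiable w.r.t. Q.
    """
    Q = as_array(Q)
    m = Q.shape[0]
    if Q.ndim != 2 or Q.shape[1] != m:
        raise ValueError("Q must be square")
    if m < 2:
        raise ValueError("soft_argmin needs at least 2 active nodes")
    rows, cols = np.triu_indices(m, k=1)
    q = Q[rows, cols]
    p = soft_sort_permutation(q, eta)[-1]  # soft indicator of min(q)
    g = anp.maximum(p * _reverse_cumsum(p), _TIE_INDICATOR_FLOOR)
    f = soft_sort_permutation(g, eta)[0]  # soft argmax of g
    # scatter the flat pair weights back onto row/col node weights
    R = np.zeros((m, len(q)))
    C = np.zeros((m, len(q)))
    R[rows, np.arange(len(q))] = 1.0
    C[cols, np.arange(len(q))] = 1.0
    return SoftSelection(row_weights=R @ f, col_weights=C @ f)


def nj_q_matrix(D):
    """Studier–Keppler join criterion over m active nodes:

        Q_ij = (m - 2) D_ij - sum_k D_ik - sum_k D_jk   (i != j)

    The diagonal is set to a large finite sentinel so it never wins a soft
    selection.
    """
    D = as_array(D.values if isinstance(D, DistanceMatrix) else D)
    m = D.shape[0]
    if m < 3:
        raise ValueError("Q matrix needs at least 3 active nodes")
    S = anp.sum(D, axis=1)
    Q = (m - 2) * D - S[:, None] - S[None, :]
    off = 1.0 - np.eye(m)
    return Q * off + Q_DIAGONAL_SENTINEL * np.eye(m)


def soft_nj_decode(D, eta: float = DEFAULT_ETA, labels=None) -> PhyloTree:
    """Decode a distance matrix into an unrooted bifurcating tree.

    Agglomerates with soft selections (see module docstring): branch lengths
    follow Saitou–Nei,

        l_i = D_ij / 2 + (S_i - S_j) / (2 (m - 2)),    l_j = D_ij - l_i,

    and the merged node's distances are D_uk = (D_ik + D_jk - D_ij) / 2, all
    evaluated through the soft weights.  Negative lengths are lifted to a
    smooth floor of 1e-6.  Every branch length is a differentiable function
    of D.
    """
    if isinstance(D, DistanceMatrix):
        labels = labels or list(D.labels)
        D = D.values
    D = as_array(D)
    n = D.shape[0]
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    if not np.all(np.isfinite(np.asarray(getval(D), dtype=float))):
        raise ValueError("distance matrix must be finite")
    labels = list(labels) if labels is not None else [f"t{i}" for i in range(n)]

    active = list(range(n))  # global node ids of the current rows
    next_internal = n
    edges: list[tuple[int, int]] = []
    blens: list = []
    Dcur = D
    m = n
    while m > 3:
        sel = soft_argmin(nj_q_matrix(Dcur), eta)
        wr, wc = sel.row_weights, sel.col_weights
        i, j = sel.hard_indices()
        ones = np.ones(m)
        d_ij = wr @ Dcur @ wc
        Si = wr @ Dcur @ ones
        Sj = wc @ Dcur @ ones
        li = 0.5 * d_ij + (Si - Sj) / (2.0 * (m - 2))
        lj = d_ij - li
        u = next_internal
        next_internal += 1
        edges.append((active[i], u))
        blens.append(smooth_branch_floor(li))
        edges.append((active[j], u))
        blens.append(smooth_branch_floor(lj))
        r = 0.5 * (wr @ Dcur + wc @ Dcur - d_ij)
        keep = [k for k in range(m) if k not in (i, j)]
        Dsub = Dcur[np.ix_(keep, keep)]
        rk = r[np.asarray(keep)]
        top = anp.concatenate([Dsub, rk[:, None]], axis=1)
        bottom = anp.concatenate([rk, anp.zeros(1)])[None, :]
        Dcur = anp.concatenate([top, bottom], axis=0)
        active = [active[k] for k in keep] + [u]
        m -= 1

    # terminal 3-star: three-point formulas around the last internal node
    a, b, c = active
    v = next_internal
    Dab, Dac, Dbc = Dcur[0, 1], Dcur[0, 2], Dcur[1, 2]
    edges.append((a, v))
    blens.append(smooth_branch_floor(0.5 * (Dab + Dac - Dbc)))
    edges.append((b, v))
    blens.append(smooth_branch_floor(0.5 * (Dab + Dbc - Dac)))
    edges.append((c, v))
    blens.append(smooth_branch_floor(0.5 * (Dac + Dbc - Dab)))

    return PhyloTree(
        n_tips=n,
        taxon_labels=labels,
        edges=edges,
        branch_lengths=anp.stack(blens) if blens else np.zeros(0),
    )
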