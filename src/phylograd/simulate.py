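"""Synthetic trees and alignments for offline, fully reproducible testing.

Random unrooted bifurcating topologies are drawn uniformly by sequential
random addition (each new tip subdivides a uniformly chosen existing edge),
matching a uniform prior over unrooted topologies.  Branch lengths are i.i.d.
exponential; the default rate of 10 gives a mean branch length of 0.1
substitutions per site, a typical scale for the alignments this package
targets.  Alignments are evolved site-independently under the chosen
substitution model by sampling a root state from the equilibrium frequencies
and propagating states along branches with the model's transition
probabilities.
"""

from __future__ import annotations

import numpy as np
from autograd.tracer import getval

from .geometry import DistanceMatrix
from .models import NUCLEOTIDES, Alignment, SubstitutionModel, transition_probs
from .soft_nj import PhyloTree

__all__ = ["simulate_tree", "tree_path_distances", "simulate_alignment", "DEFAULT_BRANCH_RATE"]

#: default exponential rate for branch lengths (mean 0.1 subst/site)
DEFAULT_BRANCH_RATE = 10.0


def simulate_tree(
    n: int,
    branch_rate: float = DEFAULT_BRANCH_RATE,
    seed: int | np.random.Generator = 0,
    labels=None,
) -> PhyloTree:
    """Random unrooted bifurcating tree on n >= 3 tips.

    Topology is uniform over unrooted topologies; branch lengths are i.i.d.
    Exponential(branch_rate).  Deterministic given the seed.
    """
    if n < 3:
        raise ValueError("need at least 3 taxa to build an unrooted tree")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = list(labels) if labels is not None else [f"t{i}" for i in range(n)]
    if len(labels) != n:
        raise ValueError("need one label per tip")
    # start from the 3-tip star around internal node `n`
    edges = [(0, n), (1, n), (2, n)]
    next_internal = n + 1
    for tip in range(3, n):
        e = int(rng.integers(len(edges)))
        a, b = edges[e]
        u = next_internal
        next_internal += 1
        edges[e] = (a, u)
        edges.append((b, u))
        edges.append((tip, u))
    lengths = rng.exponential(1.0 / branch_rate, size=len(edges))
    tree = PhyloTree(n_tips=n, taxon_labels=labels, edges=edges, branch_lengths=lengths)
    tree.validate()
    return tree


def tree_path_distances(tree: PhyloTree) -> DistanceMatrix:
    """Tip-tip path-length (patristic) distance matrix of a tree.

    The result is an additive metric: it satisfies the four-point condition
    exactly, and classical NJ on it recovers the generating tree.
    """
    n = tree.n_tips
    adj = tree.adjacency()
    bl = tree.lengths_value()
    D = np.zeros((n, n))
    for src in range(n):
        dist = {src: 0.0}
        stack = [(src, -1)]
        while stack:
            v, parent = stack.pop()
            for w, e in adj[v]:
                if w == parent:
                    continue
                dist[w] = dist[v] + bl[e]
                stack.append((w, v))
        for dst in range(n):
            D[src, dst] = dist[dst]
    D = 0.5 * (D + D.T)
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(values=D, labels=list(tree.taxon_labels))


def simulate_alignment(
    tree: PhyloTree,
    model: SubstitutionModel,
    L: int,
    seed: int | np.random.Generator = 0,
) -> Alignment:
    """Evolve an L-site alignment along a tree under a substitution model."""
    if L < 1:
        raise ValueError("alignment length must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = tree.n_tips
    adj = tree.adjacency()
    bl = tree.lengths_value()
    freqs = np.asarray(getval(model.freqs), dtype=float)
    root = tree.n_nodes - 1
    states = {root: rng.choice(4, size=L, p=freqs)}
    stack = [(root, -1)]
    while stack:
        v, parent = stack.pop()
        for w, e in adj[v]:
            if w == parent:
                continue
            P = np.asarray(getval(transition_probs(model, bl[e])), dtype=float)
            cum = np.cumsum(P, axis=1)
            u = rng.random(L)
            states[w] = (u[:, None] > cum[states[v]]).sum(axis=1)
            stack.append((w, v))
    seqs = ["".join(NUCLEOTIDES[c] for c in states[i]) for i in range(n)]
    return Alignment(taxa=list(tree.taxon_labels), sequences=seqs)
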