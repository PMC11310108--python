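"""Shared fixtures and independent reference implementations (oracles).

The oracles here are deliberately written without reusing package internals:
classical neighbour joining with hard argmin, brute-force likelihood by
exhaustive internal-state summation, and split-set comparison. They pin the
behaviour of the differentiable implementations.
"""

from __future__ import annotations

import numpy as np
import pytest

from phylograd import Alignment, PhyloTree, SubstitutionModel, simulate_alignment, simulate_tree


# --------------------------------------------------------------------------
# classical (hard) neighbour joining — independent oracle
# --------------------------------------------------------------------------

def classical_nj(D: np.ndarray, labels=None):
    """Reference NJ: hard argmin, Studier-Keppler Q, Saitou-Nei lengths.

    Ties broken by the first minimal entry in flattened row-major
    upper-triangle order. Returns a PhyloTree (without the package's smooth
    branch floor; negative lengths clamped hard at 1e-6 to match contract).
    """
    D = np.asarray(D, dtype=float).copy()
    n = D.shape[0]
    labels = list(labels) if labels is not None else [f"t{i}" for i in range(n)]
    active = list(range(n))
    next_internal = n
    edges, blens = [], []
    m = n
    while m > 3:
        S = D.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - S[i] - S[j]
                if best is None or q < best[0]:  # strict: first tie wins
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (S[i] - S[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        u = next_internal
        next_internal += 1
        edges.append((active[i], u))
        blens.append(max(li, 1e-6))
        edges.append((active[j], u))
        blens.append(max(lj, 1e-6))
        r = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        newD = np.zeros((m - 1, m - 1))
        newD[:-1, :-1] = D[np.ix_(keep, keep)]
        newD[:-1, -1] = newD[-1, :-1] = r[keep]
        D = newD
        active = [active[k] for k in keep] + [u]
        m -= 1
    a, b, c = active
    v = next_internal
    Dab, Dac, Dbc = D[0, 1], D[0, 2], D[1, 2]
    edges += [(a, v), (b, v), (c, v)]
    blens += [max(0.5 * (Dab + Dac - Dbc), 1e-6),
              max(0.5 * (Dab + Dbc - Dac), 1e-6),
              max(0.5 * (Dac + Dbc - Dab), 1e-6)]
    return PhyloTree(n_tips=n, taxon_labels=labels, edges=edges, branch_lengths=np.asarray(blens))


# --------------------------------------------------------------------------
# split sets and RF distance — independent of dendropy
# --------------------------------------------------------------------------

def tree_splits(tree: PhyloTree) -> set:
    """Non-trivial bipartitions as frozensets of tip labels (smaller side)."""
    n = tree.n_tips
    adj = tree.adjacency()
    out = set()
    for a, b in tree.edges:
        # collect tips reachable from `a` without crossing edge (a, b)
        seen_tips = set()
        visited = {a}
        stack = [(a, b)]
        while stack:
            v, block = stack.pop()
            if v < n:
                seen_tips.add(v)
            for w, _ in adj[v]:
                if w == block or w in visited:
                    continue
                visited.add(w)
                stack.append((w, -1))
        if 1 < len(seen_tips) < n - 1:
            side = frozenset(tree.taxon_labels[t] for t in seen_tips)
            other = frozenset(tree.taxon_labels[t] for t in range(n)) - side
            out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return out


def rf_oracle(t1: PhyloTree, t2: PhyloTree) -> int:
    s1, s2 = tree_splits(t1), tree_splits(t2)
    return len(s1 ^ s2)


# --------------------------------------------------------------------------
# brute-force likelihood by exhaustive internal-state summation
# --------------------------------------------------------------------------

def brute_force_log_likelihood(tree: PhyloTree, aln: Alignment, model: SubstitutionModel) -> float:
    """Sum over all 4^(n_internal) internal-state assignments.

    Edges are oriented away from the root so P[parent, child] is used,
    which is correct for any (also non-reversible) stationary model.
    Missing tip states (code 4) are marginalised by dropping the tip's
    edge factor (the transition row sums to one).
    """
    from itertools import product

    from phylograd import transition_probs

    n = tree.n_tips
    n_int = tree.n_nodes - n
    aln_row = {t: i for i, t in enumerate(aln.taxa)}
    bl = tree.lengths_value()
    root = tree.n_nodes - 1
    # orient edges parent -> child from the root
    adj = tree.adjacency()
    oriented = []  # (parent, child, P-matrix)
    stack = [(root, -1)]
    while stack:
        v, parent = stack.pop()
        for w, e in adj[v]:
            if w == parent:
                continue
            oriented.append((v, w, np.asarray(transition_probs(model, float(bl[e])))))
            stack.append((w, v))
    freqs = np.asarray(model.freqs, dtype=float)
    total = 0.0
    for p_idx in range(aln.patterns.shape[0]):
        site_like = 0.0
        for assign in product(range(4), repeat=n_int):
            state = {}
            for tip in range(n):
                state[tip] = int(aln.patterns[p_idx, aln_row[tree.taxon_labels[tip]]])
            for k in range(n_int):
                state[n + k] = assign[k]
            term = freqs[state[root]]
            for a, b, P in oriented:
                sa, sb = state[a], state[b]
                if sb == 4:  # missing tip: row of P sums to 1
                    continue
                term *= P[sa, sb]
            site_like += term
        total += float(aln.pattern_counts[p_idx]) * np.log(site_like)
    return total


# --------------------------------------------------------------------------
# shared fixtures
# --------------------------------------------------------------------------

@pytest.fixture(scope="session")
def jc69():
    return SubstitutionModel.jc69()


@pytest.fixture(scope="session")
def small_tree():
    return simulate_tree(6, seed=11)


@pytest.fixture(scope="session")
def small_alignment(small_tree, jc69):
    return simulate_alignment(small_tree, jc69, 300, seed=11)
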