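# Methods

This document describes the mathematics implemented by phylograd: the
hyperboloid geometry, the differentiable soft neighbour-joining decoder, the
phylogenetic likelihood, the maximum-likelihood optimiser, and the
variational-Bayes machinery.

## 1. Hyperboloid geometry

Work in the hyperboloid (Lorentz) model of `d`-dimensional hyperbolic space.
With the Lorentz inner product

\[ \langle u, v \rangle_L = -u_0 v_0 + \sum_{i=1}^d u_i v_i , \]

the model with curvature \(\kappa = -1\) is
\(\mathbb{H}^d = \{ x : \langle x, x\rangle_L = -1,\; x_0 > 0 \}\).
A point is parametrised by its *spatial* (tangent) coordinates
\(z \in \mathbb{R}^d\) and projected onto the sheet by
\(x = (\sqrt{1 + \lVert z\rVert^2},\, z)\); this keeps all optimisation
unconstrained. The geodesic distance at curvature \(\kappa < 0\) is

\[ d_\kappa(u, v) = \frac{\operatorname{arcosh}(-\langle u, v\rangle_L)}{\sqrt{-\kappa}} . \]

The arcosh argument is clamped from below at \(1 + 10^{-9}\) so the distance
and its gradient stay finite when points coincide numerically. Curvature is
parametrised as \(\kappa = -e^{c}\) with \(c\) unconstrained, so gradient
steps can never cross zero. Hyperbolic space is a natural host for trees:
volume grows exponentially with radius, matching the exponential growth of
the number of leaves, so additive tree metrics embed with low distortion at
strongly negative curvature.

## 2. Embedding (hyperbolic MDS)

`embed_distances` places \(n\) taxa on the hyperboloid by minimising the
squared stress

\[ \sigma(Z) = \sum_{i<j} \big( d_\kappa(x_i, x_j) - \delta_{ij} \big)^2 \]

over tangent coordinates \(Z\), where \(\delta\) is the target distance
matrix (for example patristic distances of a starting tree, or
JC69-corrected sequence distances). Optimisation uses scipy's L-BFGS on the
autograd gradient, from a seeded random initialisation scaled to the data.

## 3. Soft neighbour joining

Classical neighbour joining repeatedly *selects* the pair minimising the
Studier–Keppler criterion

\[ Q_{ij} = (m - 2) D_{ij} - S_i - S_j, \qquad S_i = \sum_k D_{ik}, \]

merges it with Saitou–Nei branch lengths

\[ \ell_i = \tfrac{1}{2} D_{ij} + \frac{S_i - S_j}{2(m-2)}, \qquad
   \ell_j = D_{ij} - \ell_i , \]

and reduces the matrix with \(D_{uk} = \tfrac12 (D_{ik} + D_{jk} - D_{ij})\).
The argmin is not differentiable, so it is replaced by a *soft selection*:
a temperature-\(\eta\) relaxation built from two soft-sort passes. A soft
descending sort of a vector \(x\) is the row-stochastic matrix

\[ P = \operatorname{softmax}_{\text{rows}}\!\big( -| \operatorname{sort}(x) \mathbf{1}^\top - \mathbf{1} x^\top | / \eta \big), \]

and the first-minimum indicator is obtained by a second pass that breaks
ties in favour of the first flattened upper-triangle entry (the indicator is
floored at \(10^{-12}\) so second-order derivatives remain finite at very
cold temperatures). The soft selection weights every candidate pair; all
subsequent quantities — branch lengths, reduced matrices — are convex
combinations under these weights, hence smooth in \(D\). As
\(\eta \to 0\) the decoder converges to classical neighbour joining; at the
default \(\eta = 10^{-5}\) they agree to well below \(10^{-6}\) in every
branch length on non-degenerate inputs. Negative branch lengths are lifted
to a smooth floor at \(10^{-6}\) via a sharp softplus.

## 4. Likelihood

Felsenstein pruning with site-pattern compression and per-node rescaling
computes \(\log p(Y \mid \tau, \ell, \theta)\). JC69 transition
probabilities use the closed form; GTR builds the reversible rate matrix
from six exchangeabilities and four equilibrium frequencies, symmetrises it
with \(\Pi^{1/2}\), diagonalises, and normalises to one expected
substitution per site. GTR at uniform parameters reproduces JC69 exactly.
Missing characters (`-`, `?`, `N`, ambiguity codes) get all-ones partials.

Two priors are provided for Bayesian runs: a Gamma–Dirichlet prior (gamma on
the total tree length, flat Dirichlet on branch proportions) and an
exponential(10) i.i.d. branch prior with a uniform prior over unrooted
topologies.

## 5. Maximum likelihood

The composite objective is the map

\[ Z \;\mapsto\; \text{project} \;\mapsto\; \text{pairwise } d_\kappa
   \;\mapsto\; \text{soft NJ} \;\mapsto\; \log\text{-likelihood} , \]

differentiable end to end. `maximize_likelihood` starts from a
user-supplied or NJ tree, embeds it, and runs Adam with learning rate
\(\text{lr}\,(t+1)^{-1/2}\) over tangent coordinates and the curvature
parameter, tracking the best decoded tree seen. An optional final
`refine_branch_lengths` step runs L-BFGS-B on the branch lengths of the
fixed best topology.

## 6. Variational Bayes

The approximating family is a mixture of \(K\) diagonal Gaussians over
tangent coordinates (`boosts`). A draw \(z \sim q_k\) is decoded to a tree
through the same projection–distance–soft-NJ map \(f\). Because \(f\) maps
\(\mathbb{R}^{nd}\) to the \((2n-3)\)-dimensional branch-length space, the
density of the decoded tree uses the generalised change of variables

\[ \log q(\ell) = \log q(z) - \tfrac12 \log \det\! \big( J f(z)\, Jf(z)^\top \big) . \]

Training maximises a stratified importance-weighted bound: with \(M\)
draws per component,

\[ \mathcal{L} = \mathbb{E} \Big[ \log \tfrac{1}{M} \sum_{m=1}^M \sum_{k=1}^K
   w_k \exp\{ \log p(Y, \ell_{mk}) - \log q(\ell_{mk}) \} \Big], \]

reparametrised through \(\epsilon \sim \mathcal{N}(0, I)\) so the gradient
flows into means, log-scales and mixture logits. This bound is
non-decreasing in \(K\) in expectation, which is the practical payoff of
boosting. The marginal likelihood is estimated by importance sampling with
the trained mixture as proposal,
\(\hat p(Y) = \frac{1}{N} \sum_s \exp\{\log p(Y, \ell_s) - \log q(\ell_s)\}\),
with a delta-method standard error on the log scale.

## 7. Numerical safeguards

- arcosh argument clamp \(1 + 10^{-9}\); curvature \(\kappa = -e^c\).
- Soft-sort tie-break indicator floored at \(10^{-12}\) (second-order
  stability at cold \(\eta\)).
- Finite sentinel \(10^{10}\) on the Q-matrix diagonal instead of
  \(\infty\) (keeps autograd's VJPs NaN-free).
- Smooth branch-length floor \(10^{-6}\) (softplus, \(\beta = 10^6\)).
- Pruning rescales partial likelihoods per node and accumulates logs.
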