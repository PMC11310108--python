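# phylograd

Differentiable phylogenetic inference via hyperbolic embeddings.

Taxa are embedded as points on a hyperboloid (constant negative curvature).
Pairwise hyperbolic distances are decoded into an unrooted bifurcating tree
by a *soft* neighbour-joining pass in which every discrete selection is
replaced by a temperature-controlled soft permutation, so branch lengths —
and hence the phylogenetic likelihood — are differentiable functions of the
embedding coordinates. Gradients flow end to end with reverse-mode automatic
differentiation (autograd), enabling:

- **Maximum likelihood** by gradient ascent over embedding locations and
  curvature (`maximize_likelihood`), with optional exact branch-length
  refinement on the final topology (`refine_branch_lengths`).
- **Variational Bayes** with a boosted mixture-of-Gaussians approximation in
  embedding space, trained on a stratified importance-weighted objective
  (`fit_variational`), posterior tree sampling (`sample_tree`) and an
  importance-sampling marginal-likelihood estimate
  (`estimate_marginal_likelihood`).

## Quick start (Python)

```python
import phylograd as pg

model = pg.SubstitutionModel.jc69()
true_tree = pg.simulate_tree(8, seed=1)
aln = pg.simulate_alignment(true_tree, model, 1000, seed=1)

# maximum likelihood from a distance-based start
cfg = pg.OptimizerConfig(epochs=500, seed=1)
best, fitted_model, trace = pg.maximize_likelihood(aln, config=cfg, model=model)
print(pg.tree_to_newick(best))

# variational Bayes
params, vtrace = pg.fit_variational(aln, config=cfg, K=3, model=model)
draw = pg.sample_tree(params, kappa=cfg.init_curvature, seed=0)
```

## Quick start (CLI)

```bash
phylograd simulate --n-taxa 8 --sites 1000 --seed 1 --out-dir sim
phylograd ml sim/alignment.fasta --epochs 500 --seed 1 --out-dir run_ml
phylograd vi sim/alignment.fasta --epochs 200 --boosts 3 --seed 1 --out-dir run_vi
phylograd embed sim/true_tree.nwk --out-dir run_embed
```

Each command writes a `config.json` recording the exact invocation, so runs
are reproducible from their output directory alone.

## Package layout

| Module | Contents |
| --- | --- |
| `phylograd.geometry` | hyperboloid model, Lorentz products, distances, curvature |
| `phylograd.hmds` | hyperbolic multidimensional scaling (embedding trees/distances) |
| `phylograd.soft_nj` | soft permutations, soft neighbour joining, `PhyloTree` |
| `phylograd.models` | alignments, JC69/GTR, pruning likelihood, priors |
| `phylograd.ml` | composite objective and gradient-ascent maximum likelihood |
| `phylograd.vi` | variational mixtures, stratified importance-weighted bound, evidence |
| `phylograd.simulate` | tree and alignment simulation fixtures |
| `phylograd.io` / `phylograd.cli` | FASTA/NEXUS/Newick I/O and the `phylograd` CLI |

See `docs/methods.md` for the underlying mathematics.

## Testing

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end criteria (soft/hard NJ
equivalence, gradient correctness, likelihood oracles, geometry invariants,
round trips, ML recovery, VI sanity against a Metropolis–Hastings reference,
the boosting trend, and the evidence estimator); the other files are unit and
property tests. `scripts/acceptance.py --seed 0 --out results/acceptance.json`
runs a seeded end-to-end sweep and writes the main computed quantities.
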