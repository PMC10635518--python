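# pitmatch

Population-wise matching and labeling of **sulcal graphs** — the graphs
whose nodes are sulcal basins of a cortical hemisphere (each node carrying
the 3D coordinates of its sulcal pit on a common registration sphere) and
whose edges connect spatially adjacent basins (weighted by the
great-circle arc length between pits).  Matching these graphs across a
population of subjects is what makes basin-level group statistics
possible; the difficulty is the massive inter-individual variability in
how the cortex folds.

The package provides the full experimental stack for studying this
problem without any imaging data:

- a **simulator** for biologically plausible populations of artificial
  sulcal graphs with ground-truth correspondences: a max–min-spaced
  reference configuration on the sphere, von Mises–Fisher perturbation of
  each node (concentration κ, larger = less noise), beta-binomial counts
  of suppressed and outlier nodes, convex-hull triangulation edges with a
  fraction p removed;
- **pairwise matching** as a quadratic assignment problem,
  max J(X) = tr(Ψᵀ X) + Σ K_E X X over permutations, with Gaussian-kernel
  node/edge affinities (median-heuristic bandwidths), solved by
  multi-start Frank–Wolfe ascent with Hungarian rounding and 2-opt polish;
- four **multi-graph synchronization** methods that refine the bulk matrix
  of all pairwise matchings toward cycle consistency
  (X_ik = X_ij X_jk): spectral synchronization anchored to a reference
  graph (`msync`), independent spectral rounding (`matcheig`), nuclear-norm
  low-rank recovery with partial matching (`mals`, threshold t = 0.5), and
  affinity-blind consistency sweeps (`cao`);
- **evaluation**: precision/recall/F1 against ground truth, per-node and
  per-graph cycle consistency, label propagation from the largest graph,
  cluster centroids and silhouettes, and per-cluster two-sample t-tests on
  node attributes between subject groups.

## Worked example

```python
from pitmatch import (SimulationConfig, generate_population, pad_population,
                      estimate_bandwidths, all_pairs, FWConfig, run_method,
                      match_counts, propagate_labels)

cfg = SimulationConfig(n_graphs=8, n_ref=30, kappa=400.0,
                       mu_pert=4.0, sigma_pert=2.5, p=0.10,
                       trials=1000, seed=7)
pop, truth, refs = generate_population(cfg)
padded = pad_population(pop)

bw = estimate_bandwidths(padded)
pairwise = all_pairs(padded, bw, FWConfig(restarts=2))
refined, meta = run_method("mals", padded, pairwise, bw)

for name, bulk in [("pairwise", pairwise), ("mals", refined)]:
    s = match_counts(bulk, truth, padded)
    print(f"{name:9s} P={s.precision:.3f} R={s.recall:.3f} F1={s.f1:.3f}")
```

prints

```
pairwise  P=0.619 R=0.769 F1=0.686
mals      P=0.669 R=0.826 F1=0.739
```

i.e. on this small noisy population the pairwise matcher recovers most
true correspondences but also forces every node into a match, costing
precision; the low-rank refinement pools consistency evidence across all
eight graphs, pruning inconsistent matches and recovering missed ones
(F1 rises from 0.69 to 0.74).  `propagate_labels(refined, padded)` then
turns the matching into per-subject cluster labels for group statistics.

The same pipeline is available from the shell:

```
pitmatch simulate --n-graphs 8 --n-ref 30 --kappa 400 --mu-pert 4 \
         --sigma-pert 2.5 --trials 1000 --seed 7 --out pop/
pitmatch match --method pairwise --pop pop/ --out pairwise.mtx
pitmatch match --method mals --pop pop/ --init pairwise.mtx --out mals.mtx
pitmatch evaluate --bulk mals.mtx --pop pop/ --report metrics.json
pitmatch label --bulk mals.mtx --pop pop/ --out labels.csv
pitmatch benchmark --kappas 1000,200 --replicates 1 --n-graphs 6 \
         --n-ref 15 --trials 50 --seed 1 --out bench.csv
```

See `docs/methods.md` for the model details, parameter meanings, tuned
defaults, and the limitations of the synthetic benchmark.

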