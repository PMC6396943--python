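# allostate

Toolkit for dissecting protein allostery from molecular-dynamics
ensembles by combining **Markov state models (MSM)**, **one-vs-one
random-forest feature importance**, **machine-learning community
partitioning of residues**, and **transition path theory (TPT)**.

The motivating systems are photosensory LOV-domain proteins such as the
fungal circadian photoreceptor Vivid, where formation of a single
cysteinyl–flavin covalent bond ("bonded" vs "non-bonded" condition)
tilts the conformational free-energy surface and drives a large
N-terminal rearrangement. The package answers, quantitatively: which
metastable states exist, how the bond changes the kinetics between
them, which residue-pair geometries distinguish the states, which
residue *groups* move collectively, and along which state sequences
the dark→light transition actually flows.

## The methods in brief

- **Featurization.** Frames are described by all N(N−1)/2 pairwise Cα
  distances (translation/rotation invariant) and projected onto 2D-RMSD
  collective variables — RMSD to a dark and a light reference after
  Kabsch superposition, RMSD = √(Σᵢ‖rᵢ⁰ − U rᵢ‖²/N).
- **MSM.** k-means microstates on the CV plane; sliding-window
  transition counts at lag τ restricted to the largest strongly
  connected count graph; reversible maximum-likelihood transition
  matrix T (detailed balance πᵢTᵢⱼ = πⱼTⱼᵢ); stationary distribution π
  from the eigenvalue-1 left eigenvector; implied timescales
  tᵢ = −τ/ln λᵢ; crisp PCCA-style spectral lumping into macrostates;
  Chapman–Kolmogorov and within-microstate dispersion diagnostics;
  condition-split macrostate matrices.
- **Importance.** One random forest per unordered macrostate pair
  (M(M−1)/2 forests), each trained only on its two states' frames.
  Per-pair importance is normalized Gini impurity decrease; the overall
  importance is the average over pairs; cumulative coverage reports how
  few features carry a given fraction of the distinguishing signal.
- **ML communities.** Residues form a graph weighted by feature
  importance Eᵢⱼ. The partition objective T = Σₗ Σ_{i<j∈Cₗ} Eᵢⱼ (edge
  weight *inside* communities) is minimized by a Kernighan–Lin-style
  local search — single-node insertions (ΔT = Ex_{i,Cₖ} − Inᵢ) and
  cross-community swaps (ΔT = Ex_{i,Cₖ} + Ex_{j,Cₘ} − Inᵢ − Inⱼ −
  2Eᵢⱼ), best move first, strict descent, many random restarts — so
  that the state-discriminating signal lies *between* communities. An
  elbow criterion over the community count selects the partition.
- **TPT.** Forward committors q⁺ solve −qᵢ + Σ_{k∈I} Tᵢₖqₖ = −Σ_{k∈B}
  Tᵢₖ with q⁺ = 0 on the source set A and 1 on the target set B;
  q⁻ = 1 − q⁺ for reversible chains; effective flux
  fᵢⱼ = πᵢq⁻ᵢTᵢⱼq⁺ⱼ; net flux fᵢⱼ⁺ = max(0, fᵢⱼ − fⱼᵢ); total flux
  F = Σ_{i∈A,j∉A} πᵢTᵢⱼq⁺ⱼ; pathways by iterative widest-path
  (maximum-bottleneck) extraction, aggregated into channels with flux-
  proportional probabilities.
- **Synthetic ground truth.** A seeded generator emulates the study
  design (12 trajectories of 1 μs saved every 100 ps → 120,000 frames;
  148 residues → 10,878 features): a hidden metastable Markov chain
  with condition-dependent transition matrices drives rigid
  displacements of planted residue communities on an ideal helical Cα
  trace, plus Gaussian noise — so every stage can be validated against
  a known answer.

## Worked example

```python
import numpy as np
from allostate import synthetic, geometry, msm, ml_importance as mli, community as comm, tpt

# synthetic two-condition study: 20 residues, 4 macrostates, 4 x 2000 frames
spec = synthetic.SyntheticSpec.test_scale(seed=3)
ens, truth = synthetic.generate(spec, seed=3)

cv = geometry.rmsd2d(ens, spec.macrostate_structure(0),
                     spec.macrostate_structure(spec.n_macrostates - 1))
micro = msm.cluster_microstates(cv, k=30, seed=1)
counts, active = msm.count_and_trim(micro.labels_per_trajectory(), lag=1, n_states=30)
model = msm.estimate_T(counts, active, lag_frames=1)
print("leading eigenvalue:", float(np.max(np.abs(model.eigenvalues()))))
print("detailed-balance error:", msm.detailed_balance_error(model))

macro = msm.pcca(model, 4, seed=0)
feats = geometry.pairwise_distances(ens)
data = mli.LabeledFeatures(features=feats,
                           labels=macro.map_labels(micro.labels, model.active_set))
ovo, table = mli.train_ovo(data, mli.ClassifierSpec(n_trees=100, seed=5))
print("pairwise classifiers:", ovo.n_classifiers)
print("features for 90% importance:",
      mli.cumulative_coverage(table.overall, 0.9), "of", feats.n_features)

graph = comm.build_graph(table.overall, feats.pair_map, n_residues=20)
part = comm.kl_search(graph, 3, restarts=100, seed=2)
total = graph.total_weight
print(f"among-community importance: {100 * (1 - part.objective / total):.3f}%")

mT, _ = msm.condition_macro_T(micro.labels_per_trajectory(), ens.condition_tags,
                              macro, model.active_set, lag=1, condition="bonded")
net = tpt.analyze(tpt.TPTProblem(T=mT, pi=msm.stationary_distribution(mT),
                                 A={0}, B={3}))
print(net.channel_table().head(1).to_string(index=False))
```

Output:

```
leading eigenvalue: 0.9999999999999991
detailed-balance error: 2.688821387764051e-17
pairwise classifiers: 6
features for 90% importance: 76 of 190
among-community importance: 100.000%
    channel  flux_per_tau  probability_pct
State 1-3-4      0.005505            100.0
```

Reading the numbers: the reversible transition-matrix estimate has the
unit Perron eigenvalue and satisfies detailed balance to machine
precision; 4 macrostates give 4·3/2 = 6 pairwise forests; 76 of the 190
pair distances carry 90% of the state-discriminating signal; the
recovered 3-community partition leaves essentially all importance
*between* communities (the planted groups move rigidly, so
within-community distances carry no signal); and on the bonded-condition
macrostate chain the entire dark→light flux runs through a single
channel, state 1 → 3 → 4, with probability 100%.

The same pipeline runs from the shell:

```bash
allostate synth --test-scale --out data/ --seed 11
allostate run --config run.yaml --out results/
```

## Layout

- `src/allostate/geometry.py` — structures, Kabsch RMSD/RMSF, pair
  distances, 2D-RMSD CVs
- `src/allostate/msm.py` — microstates, reversible estimation, PCCA,
  validation
- `src/allostate/ml_importance.py` — classifiers, one-vs-one forests,
  importance tables
- `src/allostate/community.py` — importance graphs, Kernighan–Lin
  partitioning, accumulation tables
- `src/allostate/tpt.py` — committors, fluxes, pathway decomposition
- `src/allostate/synthetic.py` — ground-truthed trajectory generator
- `src/allostate/pipeline.py`, `cli.py` — orchestration and CLI
- `docs/methods.md` — models, assumptions, numerical choices
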