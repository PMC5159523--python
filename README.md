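# g4fret

Single-molecule FRET analysis of multi-pathway G-quadruplex (G4) folding —
from raw donor/acceptor intensity trajectories to conformational states,
dwell-time kinetics, a rate-derived free-energy landscape, and
structure-based FRET predictions.

## The scientific problem

The human telomeric overhang `AGGG(TTAGGG)3` folds, in K⁺-containing
solution, into several competing G-quadruplex topologies (chair, 2-tetrad
basket, hybrid 1, hybrid 2). In surface-immobilized smFRET recordings
(200 ms frames, 600 s movies, alternating laser excitation) each conformer
appears as a distinct transfer-efficiency level, and the molecule hops
among them through the unfolded state. This package implements the full
analysis chain needed to turn such recordings into a quantitative folding
model:

1. **Trace corrections** — background subtraction, donor leakage
   *D* = 0.13, acceptor direct excitation *A* = 0.05, and
   *E* = F_A / (F_A + γF_D) with γ = 1.2; dual-label selection via the
   direct-excitation (AA) channel and single-step photobleach truncation.
2. **State inference** — Gaussian hidden-Markov models fitted by
   variational-Bayes EM with conjugate priors; the number of states is
   selected by the evidence lower bound (ELBO), and Viterbi decoding gives
   the idealized state path.
3. **Kinetics** — dwell segmentation with the "> 2 frames" filter and
   censoring rules (dwells cut by bleaching/blinking/recording end never
   enter fits); maximum-likelihood single- and two-component exponential
   fits with left-truncation and finite-window corrections; transition
   density plots and per-origin transition probabilities.
4. **Energetics** — the two-state relations ΔG_U = ln(k_F/k_U) and
   ΔG‡ = ln(k₀/k) (thermal units, k_BT at 298 K; attempt frequency
   k₀ = 10⁶ s⁻¹ by default) assemble the one-dimensional free-energy
   landscape with exact thermodynamic-cycle closure.
5. **Ensemble histograms** — per-frame FRET histograms over time windows,
   fitted globally with Gaussian peaks sharing positions/widths across
   windows (free per-window areas) to follow population redistribution.
6. **Accessible-volume (AV) FRET prediction** — grid flood-fill dye clouds
   around attachment atoms on PDB structures/ensembles, quality-threshold
   RMSD frame clustering, and E = 1/(1 + (R/R₀)⁶) under four
   frame-averaging approaches.

Because no public smFRET data accession exists for this system, the
package ships a first-class synthetic movie generator: a continuous-time
Markov chain over the five-state scheme (with the 80/20 chair/basket
first-fold branching of the cation-jump experiment) rendered into noisy
three-channel camera traces whose forward model is the exact inverse of
the correction chain.

## Worked example

```python
import numpy as np
from g4fret import (build_default_model, simulate_dataset, analyze_trace,
                    classify_first_fold, build_landscape)

model = build_default_model()          # U + chair/basket/hybrid2/hybrid1
data = simulate_dataset(model, n_molecules=5, seed=7)

trace, sidecar = data[1]
res = analyze_trace(trace, seed=0, molecule=1)
print(np.round(res.fit.means, 2), res.canonical)
print("first folded state:", classify_first_fold(res))

scape = build_landscape(model.k_fold, model.k_unfold, k0=1e6)
print(scape.to_frame().round(2).to_string(index=False))
```

prints (seed 7):

```
[0.3  0.56 0.73 0.88] ['U', 'basket', 'hybrid', 'chair']
first folded state: chair
  state  dG_U_kBT  dGf_barrier_kBT  dGu_barrier_kBT    k0_s-1
  chair      0.34            15.38            15.71 1000000.0
 basket     -0.61            15.48            14.87 1000000.0
hybrid2     -0.46            15.48            15.02 1000000.0
hybrid1      0.29            17.73            18.02 1000000.0
```

The four emission levels recover the conformer E values (0.30 unfolded,
0.57 2-tetrad basket, 0.73 hybrids, 0.88 chair); this molecule folds first
into the chair, the kinetically preferred first state. The landscape shows
folding barriers of ~15 k_BT against stabilities of well under 1 k_BT —
kinetic partitioning among marginally stable conformers — with hybrid 1
carrying the highest unfolding barrier (~18 k_BT), which makes it the
long-lived sink that dominates at equilibrium.

The `examples/` directory has one short narrative script per capability
(simulation, HMM inference, dwell kinetics, energetics, time-resolved
histograms, AV prediction); each prints the numbers it computes and what
they mean.

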