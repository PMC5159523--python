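"""Infer conformational states from one trace with the vb-HMM.

Simulates a single molecule, applies the intensity corrections
(background, donor leakage D = 0.13, direct excitation A = 0.05,
gamma = 1.2), truncates at the first photobleach, and fits Gaussian
hidden-Markov models of increasing size by variational-Bayes EM; the
number of states is selected by the evidence lower bound (ELBO).
"""

import numpy as np

from g4fret import analyze_trace, build_default_model, simulate_dataset

model = build_default_model()
trace, sidecar = simulate_dataset(model, 1, seed=12)[0]

res = analyze_trace(trace, seed=0, molecule=0)
traj, fit = res.trajectory, res.fit

print(f"Trace: {len(trace)} frames; analysis window (pre-bleach): "
      f"{traj.window_end} frames; dual-labeled: {traj.dual_labeled}")
print(f"\nSelected K = {fit.n_states} states (ELBO {fit.elbo:.1f}, "
      f"{fit.n_iter} iterations):")
for mean, sd, w, label in zip(fit.means, fit.sds, fit.state_weights, res.canonical):
    print(f"  E = {mean:.3f} +- {sd:.3f}  occupancy {w:.2f}  -> {label}")

true_states = sorted({s for s, _, _ in sidecar["sojourns"]})
print(f"\nGround-truth states visited: {true_states}")
print("Viterbi path (first 40 frames):", fit.path[:40])
print("\nEach state's mean E reports on the donor-acceptor distance of one "
      "G4 conformer; the two hybrids share E = 0.73 and are separated later "
      "by dwell time, not by level.")
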