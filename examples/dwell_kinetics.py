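"""Dwell-time kinetics: from state paths to rate constants.

Simulates 150 molecules (600 s movies, 200 ms frames), extracts dwell
segments with the two-frame filter and censoring rules, and recovers
every folding/unfolding rate constant of the star scheme, including the
two-component fit that separates the short-lived hybrid 2 from the
long-lived hybrid 1 at the shared E = 0.73 level.
"""

import numpy as np

from g4fret import CameraParams, build_default_model, recover_star_rates, simulate_state_path
from g4fret.pipeline import ground_truth_dwells

model = build_default_model()
camera = CameraParams()
rng = np.random.default_rng(5)

dwells = []
for i in range(150):
    path = simulate_state_path(model, camera.movie_length, seed=rng)
    dwells += ground_truth_dwells(model, path, camera, molecule=i)
print(f"{len(dwells)} dwells from 150 molecules "
      f"({sum(not d.censored for d in dwells)} uncensored)")

res = recover_star_rates(dwells, n_bootstrap=200, seed=1)
print(f"\nU escape rate: {res['U'].rates[0]:.3f}/s "
      f"(CI {res['U'].ci[0][0]:.3f}-{res['U'].ci[0][1]:.3f})")
print(f"hybrid two-component fit: k_fast = {res['hybrid'].rates[0]:.3f}/s, "
      f"k_slow = {res['hybrid'].rates[1]:.4f}/s "
      f"(separation {res['hybrid'].rates[0]/res['hybrid'].rates[1]:.0f}x)")

print(f"\n{'state':9s} {'k_F fit':>8s} {'k_F true':>9s} {'k_U fit':>8s} {'k_U true':>9s}")
for s in ("chair", "basket", "hybrid2", "hybrid1"):
    print(f"{s:9s} {res['k_fold'][s]:8.3f} {model.k_fold[s]:9.3f} "
          f"{res['k_unfold'][s]:8.4f} {model.k_unfold[s]:9.4f}")
print("\nRates are per-second; every estimate should land within ~15% of "
      "the generating value at this sample size.")
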