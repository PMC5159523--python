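"""Time-resolved population histograms after the K+ jump.

Simulates an ensemble of molecules folding from the unfolded state,
builds per-frame FRET histograms in successive time windows, and fits
them globally with four Gaussian components sharing positions and widths;
the per-window amplitudes show the population shifting from the
kinetically favored chair (E = 0.88) toward the thermodynamically stable
hybrid level (E = 0.73).
"""

import numpy as np

from g4fret import (
    PhotophysicsParams,
    build_default_model,
    build_histogram,
    global_gaussian_fit,
    process_trace,
    simulate_dataset,
)

model = build_default_model()
# long observation, slow bleaching, to cover the relaxation
phys = PhotophysicsParams(donor_bleach_rate=0.002, acceptor_bleach_rate=0.002)
data = simulate_dataset(model, 80, phys=phys, seed=3)
trajs = [process_trace(trace) for trace, _ in data]

windows = [(0.0, 30.0), (30.0, 120.0), (120.0, 600.0)]
hists = [build_histogram(trajs, w) for w in windows]
fit = global_gaussian_fit(hists, 4)

print("Shared peak positions:", np.round(fit.means, 3))
print("Shared peak widths:   ", np.round(fit.sds, 3))
print(f"\n{'window (s)':>12s}  " + "  ".join(f"E={m:.2f}" for m in fit.means))
for w, weights in zip(windows, fit.weights()):
    print(f"{str(w):>12s}  " + "  ".join(f"{x:6.2f}" for x in weights))
print("\nEach row gives the fraction of frames in each conformer peak for "
      "one time window; the U (E=0.30) population drains while the folded "
      "levels fill in as the ensemble relaxes after the cation jump.")
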