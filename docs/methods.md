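# Methods

This note documents the models, estimators and numerical choices behind
`g4fret`, what the synthetic data generator does and does not emulate, and
the design decisions taken where the analysis was genuinely open.

## Kinetic model and synthetic data

The folding dynamics are modeled as a continuous-time Markov chain over
one unfolded state (U, E = 0.30) and four folded conformers: chair
(E = 0.88), 2-tetrad basket (E = 0.57) and the two hybrids sharing
E = 0.73. The default topology is a star — conformers interconvert only
through U; direct folded→folded edges are supported but default to zero.
Default rate constants (s⁻¹):

| conformer | k_F  | k_U   |
|-----------|------|-------|
| chair     | 0.21 | 0.15  |
| basket    | 0.19 | 0.35  |
| hybrid 2  | 0.19 | 0.30  |
| hybrid 1  | 0.02 | 0.015 |

Hybrid 1 is the long-lived state: both its rates are an order of magnitude
below hybrid 2's, so the two hybrids are distinguishable only by dwell
time, never by FRET level. The *first* folding event of a cation-jump
trajectory branches 80% chair / 20% basket; this is a separate model
feature (`first_fold_branching`) because the observed first-fold split is
not reproducible from the steady-state rates alone (rate-proportional
branching would give the chair only ~34%). Subsequent events branch
proportionally to rates.

Note an internal tension of these defaults: with k_F = 0.02, hybrid 1's
equilibrium stability ln(0.02/0.015) = 0.29 k_BT sits 0.05 k_BT *below*
the chair's ln(0.21/0.15) = 0.34 k_BT, while the ~3 k_BT hybrid-1
stability quoted in the energetics module corresponds to a ~0.2 s⁻¹
folding rate. We keep the slow hybrid-1 folding rate because it is what
produces the characteristic late, rare entry into the long-lived state;
the energetics closed forms take their rates as explicit arguments and are
not tied to the generator.

**Trace rendering.** Paths are realized by the Gillespie algorithm and
rendered at 200 ms frames over 600 s movies. Per frame the apparent E is
the occupancy-weighted mean of the state E levels over the integration
window (so mid-frame transitions produce intermediate "blur" values, as on
a real camera). Ideal signals hold F_A + γF_D at a configured total
(default 200 counts/frame, an invented count level — the study does not
constrain it); the observed donor-excitation acceptor channel adds donor
leakage 0.13·F_D and direct excitation 0.05·AA; each channel receives
Gaussian shot noise with variance equal to its mean (a Poisson flag is
available; the Gaussian approximation is excellent at ≥ 50 counts) plus
Gaussian background (default 20 ± 5 counts, also invented and flagged as
configuration). Each dye bleaches once, at an exponential time (defaults
0.008 s⁻¹ donor, 0.010 s⁻¹ acceptor — chosen to give the ~1 min usable
traces typical of this kind of recording); after acceptor bleaching the
donor recovers to full brightness, after donor bleaching both
donor-excitation channels fall to background. One master seed spawns
independent per-molecule streams.

The generator deliberately omits EMCCD gain statistics, spectral crosstalk
beyond the two scalar factors, triplet photophysics beyond optional
two-state blinking, intensity drift, and multi-molecule spots. Passing
tests on this synthetic data therefore validate the estimators under
idealized single-molecule conditions; they do not certify robustness to
instrument-specific artifacts.

## Trace processing

Corrections follow the standard ALEX chain: F_D = DD − bg; F_A = DA − bg −
D·F_D − A·(AA − bg); E = F_A/(F_A + γF_D) with the single average factors
D = 0.13, A = 0.05, γ = 1.2 applied to all traces. E is *not* clamped to
[0, 1]: shot noise legitimately produces out-of-range values, and clamping
would bias the Gaussian emission fits.

Bleach detection is a single change-point search: candidate frames compare
5-frame means immediately before/after; a step must drop by ≥ 5 background
sds, land at background, and stay there to the end of the trace (a
recovery would indicate blinking). Donor bleaching is sought on DD + DA
(which collapses to background regardless of FRET state), acceptor
bleaching on AA. Ties break to the earliest frame. On default synthetic
data the detected frame is within ±1 of truth in > 95% of molecules. The
analysis window always ends at the first detected bleach.

Dual-label selection requires the initial AA mean and the initial DD + DA
mean to exceed background by 5 background sds.

## State inference (vb-HMM)

Each E trajectory is fitted per molecule with a K-state Gaussian-emission
HMM by variational-Bayes EM under conjugate priors: symmetric Dirichlet
(concentration 1) on the initial distribution and each transition row, and
Normal–Gamma on each emission (mean, precision). The emission mean prior
centers on the trace mean with 0.25 pseudo-observations; the precision
prior has shape 2 with its rate matched to a *successive-difference* noise
estimate, median(Δx²)/(2·0.4549) — using the total trace variance instead
(which includes between-state variance) measurably biases model selection
toward merged states.

The E step runs scaled forward–backward with the expected log parameters
(numba-compiled kernels; the time recursion is inherently sequential); the
M step updates the posterior hyperparameters; the ELBO is the forward log
normalizer minus the Dirichlet and Normal–Gamma KL terms and is
non-decreasing by construction (asserted per iteration in the tests).
Convergence: relative ELBO change < 1e-6, at most 500 iterations.
Initialization per restart: centers drawn from random data points and
refined by ten 1D k-means sweeps, soft assignment, sticky (0.9 diagonal)
transition counts; restarts default to 10 for single fits (the pipeline
uses 3 per K to keep many-molecule runs fast; sizes are stated with each
analysis). Model selection fits K = 1..K_max (default 6; 5 in the
pipeline) and keeps the highest ELBO; states with < 0.5 frames of
responsibility are flagged empty. States are reported sorted by mean, and
Viterbi decoding under the expected-log parameters gives the state path.

Fitted levels map to conformer classes by nearest canonical center
{0.30, 0.57, 0.73, 0.88} with a 0.08 maximum distance; unassignable levels
are flagged and their dwells excluded.

## Dwell-time kinetics

Contiguous runs of one state become dwells; dwells lasting ≤ 2 frames are
discarded (HMM-artifact guard), and dwells touching the window boundaries
are censored and never enter rate fits. Transition records come only from
uncensored dwells with a known following state; preceding/following states
refer to adjacent *retained* dwells.

Rate fitting is maximum likelihood on raw dwell durations, not
least-squares on binned histograms — the two agree asymptotically, and the
MLE composes cleanly with the two truncation corrections:

* **Left truncation.** Discretization rounds a dwell to its nearest frame
  count, so the "> 2 frames" filter truncates the continuous durations at
  ≈ 2.5 frames (0.5 s); the single-exponential MLE becomes
  k = n/Σ(t − t_min). Using t_min = 2 frames instead leaves a −3…−6%
  bias (both choices are available; the pipeline uses 2.5 frames).
* **Right truncation.** A dwell starting late in a finite recording is
  observed uncensored only if it ends before the window does; excluding
  censored dwells therefore biases long-lived states short (≈ −10% for
  the 67 s hybrid-1 dwell in a 600 s movie). Supplying per-dwell windows
  conditions the likelihood on the dwell being uncensored and removes the
  bias without ever fitting censored durations.

Two-component fits (the hybrid level) run a plain exponential-mixture EM
for initialization and then maximize the conditional likelihood (Nelder–
Mead on logit-weight/log-rates), reporting k_fast > k_slow and *source*
weights (corrected for the differential retention of slow vs fast dwells).
Confidence intervals are percentile bootstrap (default 500 resamples).

Star-scheme rate recovery: the U escape rate comes from the truncated MLE
of U dwells; per-conformer folding rates split it by the U→conformer
branching probabilities (competing exponentials), with the observed
branching counts reweighted by each destination's inverse retention
probability exp(+k_U·t_min) — the filter removes short destination dwells
and would otherwise undercount transitions into fast-unfolding conformers
by up to ~12%. The hybrid folding flux is split between hybrid 2 and
hybrid 1 by the two-component source weights. On 300 molecules × 600 s all
eight default rates are recovered within 5% (tolerance 15% in the tests).

Direct folded→folded transition records are tabulated (they arise from
unfolded dwells shorter than the filter) but excluded from rate fits.
Transition density plots use 50 × 50 bins over E ∈ [0, 1], normalized to
unit mass.

**First-fold classification.** A real-time folding event is a U→folded
transition. In a cation-jump recording the molecule starts unfolded by
experimental design, so classification assumes an initial unfolded
condition (the pre-fold U dwell is shorter than one frame in ~20% of
molecules and would otherwise go unseen); the first folded Viterbi segment
of ≥ 2 frames gives the label. This threshold is deliberately weaker than
the kinetics filter: only the state identity is needed, not an unbiased
duration. The 80/20 figure is a two-way split between the only two
kinetically accessible first states, so the reported chair percentage is
taken over chair/basket-first molecules; rare 'hybrid'-first labels are
detection artifacts (a missed sub-frame first dwell followed by a
rate-branched later event, or camera blur at the transition frame) and are
tabulated but excluded from the split.

## Energetics

ΔG_U = ln(k_F/k_U) and ΔG‡ = ln(k₀/k) in k_BT at 298 K. The attempt
frequency k₀ = 10⁶ s⁻¹ is configuration, not inference: it reproduces a
~15 k_BT folding barrier from a ~0.2 s⁻¹ folding rate and is printed in
every output. The unfolding barrier is assembled as ΔG‡_F + ΔG_U so the
thermodynamic cycle closes to machine precision. k₀ shifts barriers only,
never stabilities.

## Ensemble histograms

Histograms count every pre-bleach frame (one count per frame, no
per-molecule averaging), bin width 0.02 over E ∈ [−0.1, 1.1]. The global
fit is weighted least squares (Poisson √counts weights) over all windows
simultaneously with shared means and widths, per-window non-negative
amplitudes parameterized by area (in count units), means bounded within
±0.08 of the four conformer initializers to prevent component swapping,
and widths bounded in [0.01, 0.25].

## Accessible-volume FRET prediction

A grid point belongs to a dye's accessible volume if (i) a linker path of
length ≤ L and clearance ≥ w/2 from every atom (van der Waals radii:
H 1.2, C 1.7, N 1.55, O 1.52, P/S 1.8 Å) connects it to the attachment
atom, and (ii) a sphere of the dye radius there overlaps no atom. With
three radii (AV3 flag) a point is allowed if any radius fits. Defaults for
Cy3/Cy5 — L = 20 Å, w = 4.5 Å, R_dye = 8 Å — are configuration (measured
dye dimensions are not available) and are carried in `DyeParameters`.
R₀ defaults to 56 Å, the physically sensible value for this dye pair.

Path length is Dijkstra over a gcd-reduced 5×5×5 lattice move set with
Euclidean edge weights (worst-case metric overestimate ~3%, versus ~11%
for the plain 26-neighbour lattice), plus a straight-line shortcut for any
point whose direct segment to the attachment is unobstructed — without
these two measures the unobstructed cloud volume falls several percent
below the true linker ball. The attachment atom itself is not an obstacle.
A buried attachment yields an explicit empty cloud. Grid spacing defaults
to 1 Å; halving it changes the unobstructed benchmark volume by < 1%.

The Monte-Carlo rejection oracle used in the tests samples the linker ball
uniformly and rejects dye-sphere clashes; it cannot see path
connectivity, so the 5% grid/oracle agreement is asserted on obstacle
configurations where connectivity is negligible (obstacles in the 6.5–8 Å
mid-shell, mutually ≥ 9 Å apart). Behind large or paired obstacles the
grid correctly excludes points whose shortest linker path exceeds L while
the oracle counts them; that disagreement is the linker physics, not an
error.

Frame clustering is quality-threshold RMSD clustering (default cutoff 8 Å,
10 clusters) after rigid superposition on a selection (e.g. the G-quartet
nucleobases). Ensemble efficiencies are reported under four averaging
approaches — E of the mean distance, mean per-frame E, cluster-population
weighted distance, and the top-cluster representative — plus their
average; the specific four variants are this package's reconstruction of
common practice, selectable individually.

## Problem sizes and determinism

The validation suite uses 200 molecules for the first-fold benchmark, 300
molecules × 600 s for rate recovery, 15 × 1500-frame traces for the HMM
benchmark, and 10 randomized obstacle sets (2·10⁵ Monte-Carlo samples
each) for the AV oracle — sizes at which every sampling error is several
times smaller than the asserted tolerances. All randomness flows through
explicit seeds; per-molecule streams are spawned from a master seed, so
every number in the README and the acceptance output is reproducible.

## Known limitations

* Per-trajectory HMM fitting (no information sharing across molecules);
  no sticky/hierarchical variants, photon-by-photon inference, or drift
  correction.
* γ, D, A are configuration, not estimated from data; no stoichiometry
  analysis.
* The hybrid-1/hybrid-2 decomposition assumes exactly two lifetime
  components at the shared level.
* Energetics assume a single shared attempt frequency; no temperature
  dependence or friction modeling.
* The AV model is geometric: isotropic κ², mean-position distances, no
  dye photophysics or dye-surface interactions.
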