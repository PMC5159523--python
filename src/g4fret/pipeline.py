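"""End-to-end analysis: raw traces -> states -> dwells -> rates -> energetics.

Convenience layer that chains the module operations the way the full
experiment analysis does: intensity corrections and bleach truncation,
vb-HMM state inference with ELBO model selection, canonical conformer
assignment of the emission levels, dwell extraction with the two-frame
filter and censoring rules, and rate-constant recovery for the
star-topology folding scheme (unfolded exchanging with every conformer).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .correction import CorrectionFactors, FretTrajectory, process_trace
from .hmm import HmmFit, HmmPriors, select_model
from .kinetics import (
    DwellSegment,
    RateEstimate,
    assign_canonical_states,
    extract_dwells,
    fit_exponential,
    records_from_dwells,
    transition_probabilities,
)

__all__ = [
    "TraceAnalysis",
    "analyze_trace",
    "classify_first_fold",
    "first_fold_fractions",
    "canonical_dwells",
    "ground_truth_dwells",
    "recover_star_rates",
]

FOLDED_CLASSES = ("basket", "hybrid", "chair")


@dataclass
class TraceAnalysis:
    """Everything inferred from one molecule."""

    trajectory: FretTrajectory
    fit: HmmFit | None
    canonical: list[str | None]          # conformer class per HMM state
    dwells: list[DwellSegment]
    molecule: int | None = None


def analyze_trace(
    raw: pd.DataFrame,
    factors: CorrectionFactors = CorrectionFactors(),
    k_max: int = 5,
    restarts: int = 3,
    min_dwell_frames: int = 2,
    priors: HmmPriors = HmmPriors(),
    seed: int | np.random.Generator | None = None,
    molecule: int | None = None,
) -> TraceAnalysis:
    """Corrections -> bleach window -> vb-HMM -> canonical dwell extraction.

    Molecules that are not dual-labeled, or whose analysis window is too
    short for inference (< 10 frames), return with ``fit=None``.
    """
    traj = process_trace(raw, factors)
    e = traj.e_window
    if not traj.dual_labeled or e.size < 10 or not np.all(np.isfinite(e)):
        return TraceAnalysis(traj, None, [], [], molecule)
    fit = select_model(e, k_max=k_max, restarts=restarts, seed=seed, priors=priors)
    canonical = assign_canonical_states(fit.means)
    dwells = extract_dwells(
        fit.path, e, traj.time_s[1] - traj.time_s[0],
        min_frames=min_dwell_frames, molecule=molecule,
    )
    return TraceAnalysis(traj, fit, canonical, dwells, molecule)


def classify_first_fold(
    analysis: TraceAnalysis,
    min_frames: int = 2,
    assume_initial_unfolded: bool = True,
) -> str | None:
    """Conformer class of the first folded state visited in real time.

    A real-time folding event is an unfolded -> folded transition, so a
    folded segment only counts once the molecule is known to be unfolded.
    In a cation-jump recording the molecule starts unfolded by
    experimental design (``assume_initial_unfolded=True``, the default);
    this matters because the pre-fold unfolded dwell is often shorter
    than a frame and would otherwise go unseen.  For equilibrium
    recordings set it to False, which requires an explicit
    unfolded-assigned segment first.

    The first folded segment must last at least ``min_frames`` frames to
    guard against single-frame classification artefacts; the threshold is
    deliberately weaker than the kinetics dwell filter because only the
    state identity is needed here, not an unbiased duration.  A candidate
    of at most two frames whose emission level lies strictly between the
    flanking segments' levels is skipped as camera blur: a frame spanning
    a transition reads an occupancy-weighted intermediate efficiency by
    construction.  Returns None when no real-time folding is seen.
    """
    if analysis.fit is None:
        return None
    fit = analysis.fit
    path = fit.path
    change = np.flatnonzero(path[1:] != path[:-1]) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [len(path)]))
    seen_unfolded = assume_initial_unfolded
    for i, (s0, s1) in enumerate(zip(starts, stops)):
        label = analysis.canonical[path[s0]]
        if label == "U":
            seen_unfolded = True
            continue
        if s1 - s0 < min_frames:
            continue
        if s1 - s0 <= 2:
            level = fit.means[path[s0]]
            prev = fit.means[path[starts[i - 1]]] if i > 0 else 0.30
            nxt = fit.means[path[starts[i + 1]]] if i < len(starts) - 1 else prev
            if min(prev, nxt) < level < max(prev, nxt):
                continue  # camera blur at a transition, not a state visit
        if seen_unfolded and label in FOLDED_CLASSES:
            return label
    return None


def first_fold_fractions(labels: list[str | None]) -> dict[str, float]:
    """Fraction of each first-folded conformer among folding molecules."""
    folded = [x for x in labels if x is not None]
    if not folded:
        raise ValueError("no molecule shows real-time folding")
    return {c: folded.count(c) / len(folded) for c in FOLDED_CLASSES}


def canonical_dwells(analyses: list[TraceAnalysis]) -> list[DwellSegment]:
    """Pool dwells over molecules, relabeled by conformer class.

    Dwells of unassignable emission levels are dropped; preceding and
    following states are relabeled alongside.
    """
    out: list[DwellSegment] = []
    for a in analyses:
        if a.fit is None:
            continue

        def relabel(s):
            return None if s is None else a.canonical[s]

        for d in a.dwells:
            label = relabel(d.state)
            if label is None:
                continue
            out.append(
                DwellSegment(
                    state=label,
                    e_mean=d.e_mean,
                    duration=d.duration,
                    n_frames=d.n_frames,
                    censored=d.censored,
                    preceding=relabel(d.preceding),
                    following=relabel(d.following),
                    entry_time=d.entry_time,
                    window=d.window,
                    molecule=d.molecule,
                )
            )
    return out


def ground_truth_dwells(
    model,
    path,
    camera,
    min_dwell_frames: int = 2,
    molecule: int | None = None,
) -> list[DwellSegment]:
    """Dwells from a ground-truth state path discretized to the frame grid.

    Applies the same majority-occupancy discretization, conformer-class
    relabeling and dwell-filtering rules as the inference pipeline, so
    the dwell/rate estimators can be benchmarked in isolation from the
    photophysics and the HMM.
    """
    from .kinetics import assign_canonical_states
    from .simulate import discretize_path

    n, dt = camera.n_frames, camera.frame_interval
    idx = discretize_path(path, n, dt, model.states)
    canonical = assign_canonical_states(np.asarray(model.e_centers))
    labels = np.array([canonical[i] for i in idx], dtype=object)
    e = np.asarray(model.e_centers)[idx]
    return extract_dwells(labels, e, dt, min_frames=min_dwell_frames,
                          molecule=molecule)


def recover_star_rates(
    dwells: list[DwellSegment],
    frame_interval: float = 0.2,
    min_dwell_frames: int = 2,
    n_bootstrap: int = 0,
    seed: int | np.random.Generator | None = None,
) -> dict[str, RateEstimate | dict[str, float]]:
    """Folding/unfolding rate constants of the star scheme from pooled dwells.

    * The total escape rate out of the unfolded state comes from the
      truncated single-exponential MLE of uncensored U dwells; individual
      folding rates split it by the observed U -> conformer transition
      probabilities (competing exponentials).
    * Unfolding rates of chair and 2-tetrad basket come from
      single-exponential fits of their dwells.
    * Hybrid dwells (shared E 0.73) mix a short-lived (hybrid 2) and a
      long-lived (hybrid 1) population and are fitted with a
      two-component exponential; the fast/slow rates are the two hybrid
      unfolding rates and the source weights split the hybrid folding
      flux between them.

    All fits use the left-truncated likelihood (two-frame filter) and the
    finite-recording window correction.  Censored dwells never enter fits.
    Returns per-group RateEstimates plus assembled ``k_fold``/``k_unfold``
    dictionaries keyed by conformer (hybrid rates labeled hybrid1/hybrid2).

    Two discretization corrections are applied.  First, a dwell's frame
    count is its true duration rounded to the nearest frame, so the
    "longer than ``min_dwell_frames`` frames" filter truncates the
    continuous durations at (min_dwell_frames + 1/2) frames; that value
    is used as the truncation point of the likelihood.  Second, the
    filter removes short *destination* dwells and with them the
    transitions into them, undercounting transitions into short-lived
    conformers; the observed branching counts are reweighted by the
    inverse retention probability exp(+k_U * t_min) of each destination
    (using its own fitted unfolding rate) before normalization.
    """
    t_min = (min_dwell_frames + 0.5) * frame_interval
    rng = np.random.default_rng(seed)

    def group(state):
        sel = [d for d in dwells if d.state == state and not d.censored]
        t = np.array([d.duration for d in sel])
        w = np.array([d.window for d in sel])
        return t, w

    out: dict = {}
    t_u, w_u = group("U")
    est_u = fit_exponential(t_u, 1, t_min, w_u, label="U escape",
                            n_bootstrap=n_bootstrap, seed=rng)
    out["U"] = est_u

    records = records_from_dwells(dwells)
    u_counts = (
        transition_probabilities([r for r in records if r.from_state == "U"])
        .loc["U"]
    )

    k_fold: dict[str, float] = {}
    k_unfold: dict[str, float] = {}
    for state in ("chair", "basket"):
        t_s, w_s = group(state)
        est = fit_exponential(t_s, 1, t_min, w_s, label=f"{state} unfolding",
                              n_bootstrap=n_bootstrap, seed=rng)
        out[state] = est
        k_unfold[state] = est.rates[0]

    t_h, w_h = group("hybrid")
    est_h = fit_exponential(t_h, 2, t_min, w_h, label="hybrid unfolding",
                            n_bootstrap=n_bootstrap, seed=rng)
    out["hybrid"] = est_h
    k_unfold["hybrid2"], k_unfold["hybrid1"] = est_h.rates

    # inverse-retention reweighting of the branching probabilities
    retention = {
        "chair": np.exp(-k_unfold["chair"] * t_min),
        "basket": np.exp(-k_unfold["basket"] * t_min),
        "hybrid": est_h.weights[0] * np.exp(-k_unfold["hybrid2"] * t_min)
        + est_h.weights[1] * np.exp(-k_unfold["hybrid1"] * t_min),
    }
    branching = {
        s: float(u_counts.get(s, 0.0)) / retention[s] for s in retention
    }
    total = sum(branching.values())
    branching = {s: p / total for s, p in branching.items()}

    k_fold["chair"] = est_u.rates[0] * branching["chair"]
    k_fold["basket"] = est_u.rates[0] * branching["basket"]
    k_hyb_total = est_u.rates[0] * branching["hybrid"]
    k_fold["hybrid2"] = k_hyb_total * est_h.weights[0]
    k_fold["hybrid1"] = k_hyb_total * est_h.weights[1]
    out["branching"] = branching

    out["k_fold"] = k_fold
    out["k_unfold"] = k_unfold
    return out
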