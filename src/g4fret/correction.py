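"""Raw three-channel traces -> corrected FRET-efficiency trajectories.

Implements the standard ALEX intensity correction chain: background
subtraction, donor leakage into the acceptor channel (D), acceptor direct
excitation (A), and the gamma factor for unequal donor/acceptor brightness
and detection efficiency,

    F_D = DD - bg_DD
    F_A = DA - bg_DA - D*F_D - A*(AA - bg_AA)
    E   = F_A / (F_A + gamma * F_D)

plus the molecule-selection and bleach-truncation rules: only dual-labeled
molecules (AA signal above background) are analyzed, and only frames prior
to the first single-step photobleaching event enter the analysis window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CorrectionFactors",
    "FretTrajectory",
    "correct_intensities",
    "compute_fret",
    "detect_bleach",
    "select_dual_labeled",
    "process_trace",
]


@dataclass(frozen=True)
class CorrectionFactors:
    """Single average correction factors applied to every trace.

    Defaults are the experimentally determined values: donor leakage
    D = 0.13, acceptor direct excitation A = 0.05, gamma = 1.2.
    """

    donor_leakage: float = 0.13
    direct_excitation: float = 0.05
    gamma: float = 1.2
    bg_mean: tuple[float, float, float] = (20.0, 20.0, 20.0)  # DD, DA, AA
    bg_sd: float = 5.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.donor_leakage < 1.0 and 0.0 <= self.direct_excitation < 1.0):
            raise ValueError("leakage and direct excitation must be in [0, 1)")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")


@dataclass
class FretTrajectory:
    """Corrected per-frame E with the analysis window and selection flags."""

    e: np.ndarray                 # corrected E, unclamped; NaN where undefined
    time_s: np.ndarray
    window_end: int               # exclusive end of the pre-bleach window
    dual_labeled: bool
    donor_bleach_frame: int | None = None
    acceptor_bleach_frame: int | None = None

    @property
    def e_window(self) -> np.ndarray:
        """E restricted to the pre-bleach analysis window."""
        return self.e[: self.window_end]


def correct_intensities(
    raw: pd.DataFrame, factors: CorrectionFactors
) -> tuple[np.ndarray, np.ndarray]:
    """Background/leakage/direct-excitation corrected (F_D, F_A) per frame.

    Negative corrected intensities are legitimate noise and are kept.
    """
    bg_dd, bg_da, bg_aa = factors.bg_mean
    f_d = raw["DD"].to_numpy(float) - bg_dd
    f_a = (
        raw["DA"].to_numpy(float)
        - bg_da
        - factors.donor_leakage * f_d
        - factors.direct_excitation * (raw["AA"].to_numpy(float) - bg_aa)
    )
    return f_d, f_a


def compute_fret(f_d: np.ndarray, f_a: np.ndarray, gamma: float) -> np.ndarray:
    """E = F_A / (F_A + gamma*F_D), unclamped; NaN where the denominator is 0.

    E is deliberately not clipped to [0, 1]: shot noise legitimately
    produces out-of-range values that histograms and the HMM must see.
    """
    denom = f_a + gamma * np.asarray(f_d, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(denom != 0, np.asarray(f_a, float) / denom, np.nan)
    return e


def _step_change_point(
    x: np.ndarray,
    bg_level: float,
    bg_sd: float,
    window: int = 5,
    threshold_sigma: float = 5.0,
) -> int | None:
    """Largest single-step mean drop to background level; None if no step.

    Candidate frames compare the ``window``-frame means immediately before
    and after; a candidate must drop by at least ``threshold_sigma *
    bg_sd``, land near background, and stay near background to the end of
    the trace (a recovery would indicate blinking, not bleaching).  Ties
    break to the earliest frame.
    """
    n = x.size
    if n < 2 * window:
        return None
    cum = np.concatenate(([0.0], np.cumsum(x)))
    f = np.arange(window, n - window + 1)
    pre = (cum[f] - cum[f - window]) / window
    post = (cum[f + window] - cum[f]) / window
    tail = (cum[-1] - cum[f]) / (n - f)
    drop = pre - post
    thresh = threshold_sigma * bg_sd
    ok = (drop >= thresh) & (np.abs(post - bg_level) <= thresh) \
        & (np.abs(tail - bg_level) <= thresh)
    if not ok.any():
        return None
    cand = np.where(ok)[0]
    best = cand[np.argmax(drop[cand])]
    # earliest tie within numerical equality
    ties = cand[np.isclose(drop[cand], drop[best])]
    return int(f[ties.min()])


def detect_bleach(
    raw: pd.DataFrame,
    factors: CorrectionFactors = CorrectionFactors(),
    window: int = 5,
    threshold_sigma: float = 5.0,
) -> tuple[int | None, int | None]:
    """Single-step photobleach frames for (donor, acceptor); None if absent.

    Donor bleaching is sought on the total donor-excitation signal DD + DA
    (which collapses to background when the donor dies regardless of FRET
    state), acceptor bleaching on the direct-excitation AA channel.
    """
    if len(raw) < 10:
        raise ValueError("trace too short for bleach detection")
    bg_dd, bg_da, bg_aa = factors.bg_mean
    donor_total = raw["DD"].to_numpy(float) + raw["DA"].to_numpy(float)
    donor = _step_change_point(
        donor_total, bg_dd + bg_da, factors.bg_sd * np.sqrt(2.0),
        window, threshold_sigma,
    )
    acceptor = _step_change_point(
        raw["AA"].to_numpy(float), bg_aa, factors.bg_sd, window, threshold_sigma
    )
    return donor, acceptor


def select_dual_labeled(
    traces: list[pd.DataFrame],
    factors: CorrectionFactors = CorrectionFactors(),
    n_initial: int = 10,
    threshold_sigma: float = 5.0,
) -> list[bool]:
    """Flag molecules carrying both an active donor and acceptor.

    A molecule passes if its initial AA mean exceeds background by
    ``threshold_sigma`` background sds (active acceptor under direct
    excitation) and its initial DD + DA total does likewise (active donor).
    """
    bg_dd, bg_da, bg_aa = factors.bg_mean
    keep = []
    for raw in traces:
        aa0 = raw["AA"].to_numpy(float)[:n_initial].mean()
        d0 = (raw["DD"] + raw["DA"]).to_numpy(float)[:n_initial].mean()
        keep.append(
            bool(
                aa0 > bg_aa + threshold_sigma * factors.bg_sd
                and d0 > bg_dd + bg_da + threshold_sigma * factors.bg_sd * np.sqrt(2.0)
            )
        )
    return keep


def process_trace(
    raw: pd.DataFrame,
    factors: CorrectionFactors = CorrectionFactors(),
) -> FretTrajectory:
    """Full per-molecule chain: corrections, E, bleach window, selection."""
    f_d, f_a = correct_intensities(raw, factors)
    e = compute_fret(f_d, f_a, factors.gamma)
    donor, acceptor = detect_bleach(raw, factors)
    bleaches = [b for b in (donor, acceptor) if b is not None]
    window_end = min(bleaches) if bleaches else len(raw)
    dual = select_dual_labeled([raw], factors)[0]
    return FretTrajectory(
        e=e,
        time_s=raw["time_s"].to_numpy(float),
        window_end=window_end,
        dual_labeled=dual,
        donor_bleach_frame=donor,
        acceptor_bleach_frame=acceptor,
    )
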