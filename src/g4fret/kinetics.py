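"""Dwell-time kinetics: from idealized state paths to rate constants.

Contiguous runs of one inferred state become dwell segments.  Following
the analysis rules of the experiment, dwells lasting no more than two
frames are discarded (HMM artefact guard), and dwells cut by blinking,
photobleaching or the ends of the recording are censored and never enter
rate fits.  Surviving dwell durations are fitted by maximum likelihood
with single- or two-component exponential models.

Two truncation effects are handled explicitly in the likelihood:

* the two-frame minimum-dwell filter left-truncates the observable
  durations at ``t_min``; the single-exponential MLE then reduces to the
  shifted closed form k = n / sum(t - t_min);
* a finite recording right-truncates: a dwell starting late in the trace
  is observed (uncensored) only if it ends before the window does.
  Supplying per-dwell observation windows conditions the likelihood on
  the dwell being uncensored, which removes the survivor bias that
  otherwise shortens long-lived states (the hybrid-1 dwell time is
  comparable to the movie length, so this matters).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar

from .model import CANONICAL_E

__all__ = [
    "DwellSegment",
    "TransitionRecord",
    "RateEstimate",
    "TransitionDensity",
    "extract_dwells",
    "assign_canonical_states",
    "records_from_dwells",
    "transition_density",
    "transition_probabilities",
    "fit_exponential",
    "dwell_vs_E_scatter",
    "dwell_table",
]


@dataclass(frozen=True)
class DwellSegment:
    """One continuous residence in an inferred state."""

    state: int | str
    e_mean: float
    duration: float            # s, multiple of the frame interval
    n_frames: int
    censored: bool             # cut by blink/bleach/recording boundary
    preceding: int | str | None
    following: int | str | None
    entry_time: float          # s, dwell start within the trace
    window: float              # s, maximum observable duration from entry
    molecule: int | None = None


@dataclass(frozen=True)
class TransitionRecord:
    from_state: int | str
    to_state: int | str
    e_before: float
    e_after: float
    dwell_before: float        # s, duration of the dwell preceding the jump


@dataclass(frozen=True)
class RateEstimate:
    """Exponential rate fit for one transition group."""

    label: str
    n_components: int
    rates: tuple[float, ...]       # descending: k_fast first
    weights: tuple[float, ...]     # source mixture weights, sum to 1
    n: int
    ci: tuple[tuple[float, float], ...] | None   # bootstrap CI per rate
    t_min: float

    def __post_init__(self) -> None:
        if any(k <= 0 for k in self.rates):
            raise ValueError("rates must be > 0")
        if self.n_components == 2 and not np.isclose(sum(self.weights), 1.0):
            raise ValueError("mixture weights must sum to 1")


@dataclass(frozen=True)
class TransitionDensity:
    """Normalized 2D histogram of (E before, E after) over all transitions."""

    hist: np.ndarray
    edges: np.ndarray

    def __post_init__(self) -> None:
        if not np.isclose(self.hist.sum(), 1.0):
            raise ValueError("transition density must be normalized")


def extract_dwells(
    path: np.ndarray,
    e: np.ndarray,
    frame_interval: float,
    min_frames: int = 2,
    window_end: int | None = None,
    molecule: int | None = None,
) -> list[DwellSegment]:
    """Segment an idealized state path into retained dwell segments.

    ``path`` holds per-frame state labels (ints or strings); ``e`` the
    corrected efficiency per frame.  Only frames before ``window_end``
    (first bleach) are used.  Dwells of at most ``min_frames`` frames are
    discarded; dwells touching the window boundaries are censored.
    Preceding/following states refer to the adjacent *retained* dwells
    (removed short dwells are treated as artefacts).
    """
    path = np.asarray(path)
    e = np.asarray(e, float)
    end = len(path) if window_end is None else window_end
    path, e = path[:end], e[:end]
    if len(path) == 0:
        return []

    # run-length segmentation
    change = np.flatnonzero(path[1:] != path[:-1]) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [len(path)]))

    kept = [
        (int(s0), int(s1))
        for s0, s1 in zip(starts, stops)
        if (s1 - s0) > min_frames
    ]
    dwells: list[DwellSegment] = []
    for i, (s0, s1) in enumerate(kept):
        state = path[s0]
        state = state.item() if hasattr(state, "item") else state
        censored = s0 == 0 or s1 == len(path)
        prev_state = path[kept[i - 1][0]] if i > 0 else None
        next_state = path[kept[i + 1][0]] if i < len(kept) - 1 else None
        dwells.append(
            DwellSegment(
                state=state,
                e_mean=float(e[s0:s1].mean()),
                duration=(s1 - s0) * frame_interval,
                n_frames=s1 - s0,
                censored=bool(censored),
                preceding=None if prev_state is None else
                    (prev_state.item() if hasattr(prev_state, "item") else prev_state),
                following=None if (censored or next_state is None) else
                    (next_state.item() if hasattr(next_state, "item") else next_state),
                entry_time=s0 * frame_interval,
                window=(len(path) - s0) * frame_interval,
                molecule=molecule,
            )
        )
    return dwells


def assign_canonical_states(
    levels: np.ndarray,
    centers: dict[str, float] = CANONICAL_E,
    max_distance: float = 0.08,
) -> list[str | None]:
    """Nearest-center assignment of HMM emission levels to conformer classes.

    Levels farther than ``max_distance`` from every canonical center (U
    0.30, 2-tetrad basket 0.57, hybrid 0.73, chair 0.88) are returned as
    ``None`` and their dwells are excluded downstream.
    """
    labels, cvals = list(centers), np.array(list(centers.values()))
    out: list[str | None] = []
    for level in np.asarray(levels, float):
        if not -0.2 < level < 1.2:
            out.append(None)
            continue
        d = np.abs(cvals - level)
        j = int(d.argmin())
        out.append(labels[j] if d[j] <= max_distance else None)
    return out


def records_from_dwells(dwells: list[DwellSegment]) -> list[TransitionRecord]:
    """Transition records from uncensored dwells with a known destination."""
    by_mol: dict = {}
    for d in dwells:
        by_mol.setdefault(d.molecule, []).append(d)
    records = []
    for mol_dwells in by_mol.values():
        mol_dwells.sort(key=lambda d: d.entry_time)
        for i, d in enumerate(mol_dwells):
            if d.censored or d.following is None or d.following == d.state:
                continue
            nxt = mol_dwells[i + 1] if i + 1 < len(mol_dwells) else None
            records.append(
                TransitionRecord(
                    from_state=d.state,
                    to_state=d.following,
                    e_before=d.e_mean,
                    e_after=nxt.e_mean if nxt is not None else float("nan"),
                    dwell_before=d.duration,
                )
            )
    return records


def transition_density(
    records: list[TransitionRecord],
    bins: int = 50,
    e_range: tuple[float, float] = (0.0, 1.0),
) -> TransitionDensity:
    """Probability-normalized TDP over (E before, E after)."""
    if not records:
        raise ValueError("no transition records")
    eb = np.array([r.e_before for r in records])
    ea = np.array([r.e_after for r in records])
    ok = np.isfinite(eb) & np.isfinite(ea)
    hist, edges, _ = np.histogram2d(eb[ok], ea[ok], bins=bins, range=(e_range, e_range))
    total = hist.sum()
    if total == 0:
        raise ValueError("no records inside the E range")
    return TransitionDensity(hist=hist / total, edges=edges)


def transition_probabilities(records: list[TransitionRecord]) -> pd.DataFrame:
    """Per-origin transition probability table; rows sum to 1."""
    if not records:
        raise ValueError("no transition records")
    df = pd.DataFrame(
        [(r.from_state, r.to_state) for r in records], columns=["from", "to"]
    )
    counts = df.groupby(["from", "to"]).size().unstack(fill_value=0)
    return counts.div(counts.sum(axis=1), axis=0)


def _single_exp_mle(t: np.ndarray, t_min: float, windows: np.ndarray | None) -> float:
    if windows is None:
        return t.size / float(np.sum(t - t_min))
    tau = windows - t_min

    def nll(log_k: float) -> float:
        k = np.exp(log_k)
        with np.errstate(over="ignore"):
            surv = -np.log1p(-np.exp(-k * tau))
        return -(np.log(k) * t.size - k * np.sum(t - t_min) + np.sum(surv))

    k0 = t.size / float(np.sum(t - t_min))
    res = minimize_scalar(
        nll, bounds=(np.log(k0) - 5, np.log(k0) + 5), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(np.exp(res.x))


def _double_exp_em(u: np.ndarray, n_iter: int = 500, tol: float = 1e-10):
    """Plain two-component exponential mixture EM on shifted durations."""
    med = np.median(u)
    k = np.array([1.0 / max(np.mean(u[u <= med]), 1e-9),
                  1.0 / max(np.mean(u[u > med]), 1e-9)])
    w = np.array([0.5, 0.5])
    prev = -np.inf
    for _ in range(n_iter):
        log_p = np.log(w) + np.log(k) - np.outer(u, k)
        m = log_p.max(axis=1, keepdims=True)
        p = np.exp(log_p - m)
        ll = float(np.sum(m.ravel() + np.log(p.sum(axis=1))))
        r = p / p.sum(axis=1, keepdims=True)
        w = r.mean(axis=0)
        k = r.sum(axis=0) / (r * u[:, None]).sum(axis=0)
        if abs(ll - prev) < tol * max(abs(ll), 1.0):
            break
        prev = ll
    return w, k


def _double_exp_mle(
    t: np.ndarray, t_min: float, windows: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    """Source weights and rates of a two-exponential mixture, by conditional ML.

    The likelihood conditions each dwell on being retained (> t_min) and
    uncensored (< its window), so the returned weights are those of the
    underlying dwell population, not of the truncated sample.
    """
    u = t - t_min
    w_em, k_em = _double_exp_em(u)
    # survival correction: observed-by-retention weights -> source weights
    w_src = w_em * np.exp(np.clip(k_em * t_min, None, 500))
    w_src /= w_src.sum()
    w_src = np.clip(w_src, 1e-6, 1 - 1e-6)

    def nll(theta: np.ndarray) -> float:
        w1 = 1.0 / (1.0 + np.exp(-theta[0]))
        k1, k2 = np.exp(theta[1]), np.exp(theta[2])
        num = np.logaddexp(
            np.log(w1) + np.log(k1) - k1 * t,
            np.log1p(-w1) + np.log(k2) - k2 * t,
        )
        # P(dwell observed): retained (> t_min) and, if a window is given,
        # uncensored (< window)
        with np.errstate(over="ignore", under="ignore"):
            if windows is None:
                obs = w1 * np.exp(-k1 * t_min) + (1 - w1) * np.exp(-k2 * t_min)
                denom = t.size * np.log(max(obs, 1e-300))
            else:
                obs = (
                    w1 * (np.exp(-k1 * t_min) - np.exp(-k1 * windows))
                    + (1 - w1) * (np.exp(-k2 * t_min) - np.exp(-k2 * windows))
                )
                denom = float(np.sum(np.log(np.clip(obs, 1e-300, None))))
        return -(num.sum() - denom)

    theta0 = np.array([np.log(w_src[0] / (1 - w_src[0])),
                       np.log(k_em[0]), np.log(k_em[1])])
    res = minimize(nll, theta0, method="Nelder-Mead",
                   options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
    w1 = 1.0 / (1.0 + np.exp(-res.x[0]))
    k = np.exp(res.x[1:3])
    w = np.array([w1, 1.0 - w1])
    order = np.argsort(k)[::-1]
    return w[order], k[order]


def fit_exponential(
    durations: np.ndarray,
    n_components: int = 1,
    t_min: float = 0.0,
    windows: np.ndarray | None = None,
    label: str = "",
    n_bootstrap: int = 500,
    seed: int | np.random.Generator | None = None,
) -> RateEstimate:
    """Maximum-likelihood exponential fit of uncensored dwell durations.

    Parameters
    ----------
    durations:
        Uncensored dwell times (s); all must exceed ``t_min``.
    n_components:
        1 for a single exponential (k = n / sum(t - t_min)), 2 for a
        two-component mixture fitted by EM plus conditional-likelihood
        refinement; reported with k_fast first.
    t_min:
        Left-truncation point of the minimum-dwell filter (s).
    windows:
        Optional per-dwell maximum observable duration (s); conditions the
        likelihood on the dwell being uncensored (finite-recording
        correction).
    n_bootstrap:
        Bootstrap resamples for the rate confidence intervals (95%);
        0 disables.
    """
    t = np.asarray(durations, float)
    if t.size == 0 or np.any(t <= 0):
        raise ValueError("durations must be positive and non-empty")
    if np.any(t < t_min):
        raise ValueError("durations below the truncation point t_min")
    if windows is not None:
        windows = np.asarray(windows, float)
        if windows.shape != t.shape or np.any(windows < t):
            raise ValueError("windows must match durations and bound them")
    min_n = 10 if n_components == 1 else 50
    if t.size < min_n:
        raise ValueError(
            f"{t.size} dwells: need >= {min_n} for a {n_components}-component fit"
        )

    def _fit(tt, ww):
        if n_components == 1:
            return (np.array([_single_exp_mle(tt, t_min, ww)]), np.array([1.0]))
        w, k = _double_exp_mle(tt, t_min, ww)
        return k, w

    rates, weights = _fit(t, windows)
    ci = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        samples = np.empty((n_bootstrap, n_components))
        for i in range(n_bootstrap):
            idx = rng.integers(0, t.size, t.size)
            try:
                k_b, _ = _fit(t[idx], None if windows is None else windows[idx])
                samples[i] = np.sort(k_b)[::-1]
            except (ValueError, FloatingPointError):
                samples[i] = np.nan
        lo = np.nanpercentile(samples, 2.5, axis=0)
        hi = np.nanpercentile(samples, 97.5, axis=0)
        ci = tuple((float(a), float(b)) for a, b in zip(lo, hi))

    return RateEstimate(
        label=label,
        n_components=n_components,
        rates=tuple(float(k) for k in rates),
        weights=tuple(float(w) for w in weights),
        n=t.size,
        ci=ci,
        t_min=t_min,
    )


def dwell_vs_E_scatter(dwells: list[DwellSegment]) -> pd.DataFrame:
    """One row per retained dwell: (E, duration); the state-grouping QC plot."""
    return pd.DataFrame(
        {
            "E": [d.e_mean for d in dwells],
            "duration_s": [d.duration for d in dwells],
            "state": [d.state for d in dwells],
            "censored": [d.censored for d in dwells],
        }
    )


def dwell_table(dwells: list[DwellSegment]) -> pd.DataFrame:
    """Full dwell table (molecule, state, E_mean, duration_s, censored, from, to)."""
    return pd.DataFrame(
        {
            "molecule": [d.molecule for d in dwells],
            "state": [d.state for d in dwells],
            "E_mean": [d.e_mean for d in dwells],
            "duration_s": [d.duration for d in dwells],
            "censored": [d.censored for d in dwells],
            "from": [d.preceding for d in dwells],
            "to": [d.following for d in dwells],
        }
    )
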