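"""Synthetic smFRET movie generator.

Realizes the kinetic scheme as a continuous-time Markov chain (Gillespie
algorithm) and renders the resulting state path into three-channel
camera-frame intensity traces (DD: donor-excitation donor, DA:
donor-excitation acceptor, AA: acceptor-excitation acceptor) with shot
noise, background, donor leakage, acceptor direct excitation, an unequal
detection factor gamma and single-step photobleaching — i.e. the exact
forward model whose inversion is the trace-processing correction chain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import KineticModel

__all__ = [
    "StatePath",
    "CameraParams",
    "PhotophysicsParams",
    "simulate_state_path",
    "discretize_path",
    "render_trace",
    "simulate_molecule",
    "simulate_dataset",
    "write_trace",
    "read_trace",
]


@dataclass(frozen=True)
class StatePath:
    """Ordered sojourns of one molecule: (label, entry time s, exit time s)."""

    sojourns: tuple[tuple[str, float, float], ...]
    duration: float

    def __post_init__(self) -> None:
        t = 0.0
        for label, t0, t1 in self.sojourns:
            if not np.isclose(t0, t):
                raise ValueError("sojourns must be contiguous and start at 0")
            if t1 <= t0:
                raise ValueError("sojourn duration must be > 0")
            t = t1
        if self.sojourns and not np.isclose(t, self.duration):
            raise ValueError("sojourns must cover the full duration")

    def state_at(self, time: float) -> str:
        for label, t0, t1 in self.sojourns:
            if t0 <= time < t1:
                return label
        return self.sojourns[-1][0]


@dataclass(frozen=True)
class CameraParams:
    """EMCCD frame acquisition parameters.

    Defaults emulate the experiment: 200 ms integration per frame, 600 s
    movies.  Total signal and background levels are generator configuration
    (microscope count levels are not constrained by the study).
    """

    frame_interval: float = 0.2  # s
    movie_length: float = 600.0  # s
    total_signal: float = 200.0  # counts/frame; F_A + gamma*F_D is held here
    acceptor_total: float = 200.0  # counts/frame in AA when acceptor alive
    bg_mean: tuple[float, float, float] = (20.0, 20.0, 20.0)  # DD, DA, AA
    bg_sd: tuple[float, float, float] = (5.0, 5.0, 5.0)
    shot_noise: bool = True
    poisson: bool = False  # exact Poisson shot noise instead of Gaussian

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame interval must be > 0")
        n = self.movie_length / self.frame_interval
        if self.movie_length <= 0 or not np.isclose(n, round(n)):
            raise ValueError("movie length must be a positive multiple of the frame interval")

    @property
    def n_frames(self) -> int:
        return int(round(self.movie_length / self.frame_interval))


@dataclass(frozen=True)
class PhotophysicsParams:
    """Dye bleaching/blinking rates (1/s); defaults give ~1 min traces."""

    donor_bleach_rate: float = 0.008
    acceptor_bleach_rate: float = 0.010
    blink_on_rate: float = 0.0
    blink_off_rate: float = 0.0

    def __post_init__(self) -> None:
        for k in (self.donor_bleach_rate, self.acceptor_bleach_rate,
                  self.blink_on_rate, self.blink_off_rate):
            if k < 0:
                raise ValueError("photophysics rates must be >= 0")


def simulate_state_path(
    model: KineticModel,
    duration: float,
    initial_state: str | None = None,
    seed: int | np.random.Generator | None = None,
) -> StatePath:
    """Gillespie realization of the kinetic scheme.

    Sojourn times are exponential with the state's total exit rate.  The
    first unfolded -> folded jump draws its destination from the model's
    first-fold branching; all later jumps branch proportionally to rates.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(seed)
    initial = model.unfolded if initial_state is None else initial_state
    if initial not in model.states:
        raise ValueError(f"unknown initial state {initial!r}")

    folded = list(model.folded_states)
    exit_rates: dict[str, float] = {}
    dests: dict[str, tuple[list[str], np.ndarray]] = {}
    k_f = np.array([model.k_fold[s] for s in folded])
    exit_rates[model.unfolded] = float(k_f.sum())
    if k_f.sum() > 0:
        dests[model.unfolded] = (folded, k_f / k_f.sum())
    for s in folded:
        targets = [model.unfolded]
        rates = [model.k_unfold[s]]
        for (a, b), k in model.k_direct.items():
            if a == s and k > 0:
                targets.append(b)
                rates.append(k)
        r = np.array(rates)
        exit_rates[s] = float(r.sum())
        if r.sum() > 0:
            dests[s] = (targets, r / r.sum())

    sojourns: list[tuple[str, float, float]] = []
    t, state = 0.0, initial
    folded_yet = False
    while t < duration:
        rate = exit_rates[state]
        dt = rng.exponential(1.0 / rate) if rate > 0 else np.inf
        t_exit = min(t + dt, duration)
        sojourns.append((state, t, t_exit))
        if t + dt >= duration:
            break
        if state == model.unfolded and not folded_yet:
            probs = model.branching_vector()
            state = folded[rng.choice(len(folded), p=probs)]
            folded_yet = True
        else:
            targets, probs = dests[state]
            state = targets[rng.choice(len(targets), p=probs)]
        t = t_exit
    return StatePath(sojourns=tuple(sojourns), duration=duration)


def _frame_occupancy(path: StatePath, n_frames: int, dt: float,
                     states: tuple[str, ...]) -> np.ndarray:
    """(n_frames, n_states) fraction of each frame spent in each state."""
    occ = np.zeros((n_frames, len(states)))
    idx = {s: i for i, s in enumerate(states)}
    for label, t0, t1 in path.sojourns:
        j = idx[label]
        f0 = int(np.floor(t0 / dt))
        f1 = min(int(np.ceil(t1 / dt)), n_frames)
        for f in range(f0, f1):
            lo, hi = f * dt, (f + 1) * dt
            overlap = min(t1, hi) - max(t0, lo)
            if overlap > 0:
                occ[f, j] += overlap / dt
    return occ


def discretize_path(path: StatePath, n_frames: int, dt: float,
                    states: tuple[str, ...]) -> np.ndarray:
    """Majority-occupancy state index per camera frame."""
    occ = _frame_occupancy(path, n_frames, dt, states)
    return occ.argmax(axis=1)


def render_trace(
    path: StatePath,
    model: KineticModel,
    camera: CameraParams = CameraParams(),
    phys: PhotophysicsParams = PhotophysicsParams(),
    factors=None,
    seed: int | np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Render a state path into a three-channel intensity trace.

    Per frame the apparent transfer efficiency is the occupancy-weighted
    mean of the state E levels over the integration window.  Ideal signals
    keep F_A + gamma*F_D at the configured total; the observed DA channel
    adds donor leakage D*F_D and direct excitation A*AA; channel-specific
    Gaussian (or Poisson) shot noise with variance equal to the mean signal
    and Gaussian background are then applied.  Dye bleach times are drawn
    once per molecule: after acceptor bleach the acceptor channels go dark
    and the donor recovers to full brightness; after donor bleach both
    donor-excitation channels drop to background.

    Returns the trace table (frame, time_s, DD, DA, AA) and a ground-truth
    sidecar dict (state path, bleach times, apparent E per frame).
    """
    from .correction import CorrectionFactors  # avoid import cycle

    if factors is None:
        factors = CorrectionFactors(
            donor_leakage=0.13, direct_excitation=0.05, gamma=1.2,
            bg_mean=camera.bg_mean,
        )
    if path.duration < camera.movie_length - 1e-9:
        raise ValueError("state path shorter than the movie")
    rng = np.random.default_rng(seed)
    n, dt = camera.n_frames, camera.frame_interval
    e_levels = np.asarray(model.e_centers)
    occ = _frame_occupancy(path, n, dt, model.states)
    e_app = occ @ e_levels

    t_donor = rng.exponential(1.0 / phys.donor_bleach_rate) \
        if phys.donor_bleach_rate > 0 else np.inf
    t_acceptor = rng.exponential(1.0 / phys.acceptor_bleach_rate) \
        if phys.acceptor_bleach_rate > 0 else np.inf

    edges = np.arange(n + 1) * dt
    frac_d = np.clip((t_donor - edges[:-1]) / dt, 0.0, 1.0)      # donor alive
    frac_a = np.clip((t_acceptor - edges[:-1]) / dt, 0.0, 1.0)   # acceptor alive
    frac_both = np.minimum(frac_d, frac_a)
    frac_donly = frac_d - frac_both  # donor alive, acceptor bleached

    blink_dark = np.zeros(n, dtype=bool)
    if phys.blink_off_rate > 0 and phys.blink_on_rate > 0:
        # simple two-state acceptor blinking, frame-resolution
        t, on = 0.0, True
        while t < camera.movie_length:
            rate = phys.blink_off_rate if on else phys.blink_on_rate
            t2 = t + rng.exponential(1.0 / rate)
            if not on:
                f0, f1 = int(t / dt), min(int(np.ceil(t2 / dt)), n)
                blink_dark[f0:f1] = True
            t, on = t2, not on
        frac_a = np.where(blink_dark, 0.0, frac_a)
        frac_both = np.minimum(frac_d, frac_a)
        frac_donly = frac_d - frac_both

    total, gamma = camera.total_signal, factors.gamma
    dd_ideal = frac_both * (1.0 - e_app) * total / gamma + frac_donly * total / gamma
    da_fret = frac_both * e_app * total
    aa_ideal = frac_a * camera.acceptor_total
    da_ideal = da_fret + factors.donor_leakage * dd_ideal \
        + factors.direct_excitation * aa_ideal

    channels = []
    for ideal, bg_m, bg_s in zip(
        (dd_ideal, da_ideal, aa_ideal), camera.bg_mean, camera.bg_sd
    ):
        x = ideal.copy()
        if camera.shot_noise:
            if camera.poisson:
                x = rng.poisson(np.clip(x, 0.0, None)).astype(float)
            else:
                x = x + rng.normal(0.0, np.sqrt(np.clip(x, 0.0, None)))
        x = x + (rng.normal(bg_m, bg_s, size=n) if bg_s > 0 else bg_m)
        channels.append(x)

    trace = pd.DataFrame(
        {
            "frame": np.arange(n),
            "time_s": edges[:-1],
            "DD": channels[0],
            "DA": channels[1],
            "AA": channels[2],
        }
    )
    sidecar = {
        "sojourns": [[s, float(t0), float(t1)] for s, t0, t1 in path.sojourns],
        "donor_bleach_s": None if np.isinf(t_donor) else float(t_donor),
        "acceptor_bleach_s": None if np.isinf(t_acceptor) else float(t_acceptor),
        "e_apparent": e_app.tolist(),
        "frame_state": [model.states[i]
                        for i in discretize_path(path, n, dt, model.states)],
    }
    return trace, sidecar


def simulate_molecule(
    model: KineticModel,
    camera: CameraParams = CameraParams(),
    phys: PhotophysicsParams = PhotophysicsParams(),
    factors=None,
    initial_state: str | None = None,
    seed: int | np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate one molecule: state path plus rendered trace."""
    rng = np.random.default_rng(seed)
    path = simulate_state_path(model, camera.movie_length, initial_state, rng)
    return render_trace(path, model, camera, phys, factors, rng)


def simulate_dataset(
    model: KineticModel,
    n_molecules: int,
    camera: CameraParams = CameraParams(),
    phys: PhotophysicsParams = PhotophysicsParams(),
    factors=None,
    initial_state: str | None = None,
    seed: int = 0,
) -> list[tuple[pd.DataFrame, dict]]:
    """Simulate a dataset with per-molecule streams spawned from one seed."""
    streams = np.random.SeedSequence(seed).spawn(n_molecules)
    out = []
    for i, ss in enumerate(streams):
        trace, sidecar = simulate_molecule(
            model, camera, phys, factors, initial_state, np.random.default_rng(ss)
        )
        sidecar["molecule"] = i
        out.append((trace, sidecar))
    return out


def write_trace(trace: pd.DataFrame, path: str | Path,
                sidecar: dict | None = None) -> None:
    """Write trace TSV (frame, time_s, DD, DA, AA) plus JSON sidecar."""
    path = Path(path)
    trace.to_csv(path, sep="\t", index=False, float_format="%.4f")
    if sidecar is not None:
        path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_trace(path: str | Path) -> tuple[pd.DataFrame, dict | None]:
    path = Path(path)
    trace = pd.read_csv(path, sep="\t")
    sidecar_path = path.with_suffix(".json")
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else None
    return trace, sidecar
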