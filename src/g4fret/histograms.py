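"""Population FRET histograms and global shared-parameter Gaussian fits.

Histograms count every pre-bleach frame of every molecule (one count per
frame, no per-molecule averaging).  A time series of histograms — e.g.
successive windows after the K+ jump — is fitted globally with a mixture
of Gaussian peaks whose positions and widths are shared across all
histograms while the per-histogram amplitudes (areas) are free; the
amplitude trajectories then report how the conformer populations
redistribute over time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .correction import FretTrajectory

__all__ = ["EfficiencyHistogram", "GaussianMixFit", "build_histogram",
           "global_gaussian_fit"]

DEFAULT_E_RANGE = (-0.1, 1.1)
DEFAULT_BIN_WIDTH = 0.02


@dataclass(frozen=True)
class EfficiencyHistogram:
    """Per-frame E histogram for one time window."""

    counts: np.ndarray
    edges: np.ndarray
    window: tuple[float, float] | None
    n_molecules: int

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])


@dataclass(frozen=True)
class GaussianMixFit:
    """Global Gaussian-mixture fit: shared means/sds, per-histogram areas."""

    means: np.ndarray              # shared across histograms
    sds: np.ndarray                # shared
    amplitudes: np.ndarray         # (n_histograms, n_components) areas, >= 0
    residual_norm: float
    success: bool

    def weights(self) -> np.ndarray:
        """Per-histogram component fractions (areas normalized per row)."""
        total = self.amplitudes.sum(axis=1, keepdims=True)
        return self.amplitudes / np.where(total > 0, total, 1.0)

    def model_counts(self, hist: EfficiencyHistogram, row: int) -> np.ndarray:
        return _mixture(hist.centers, self.means, self.sds,
                        self.amplitudes[row]) * hist.bin_width


def build_histogram(
    trajectories: list[FretTrajectory],
    window: tuple[float, float] | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
    e_range: tuple[float, float] = DEFAULT_E_RANGE,
) -> EfficiencyHistogram:
    """Histogram of all pre-bleach frames whose times fall in ``window``.

    Every frame yields one count; frames at or past a molecule's first
    bleaching event contribute nothing.
    """
    edges = np.arange(e_range[0], e_range[1] + bin_width / 2, bin_width)
    values = []
    n_mol = 0
    for traj in trajectories:
        e = traj.e_window
        t = traj.time_s[: traj.window_end]
        if window is not None:
            mask = (t >= window[0]) & (t < window[1])
            e = e[mask]
        e = e[np.isfinite(e)]
        if e.size:
            n_mol += 1
            values.append(e)
    if not values:
        raise ValueError("no trajectory frames intersect the window")
    counts, _ = np.histogram(np.concatenate(values), bins=edges)
    return EfficiencyHistogram(
        counts=counts.astype(float), edges=edges, window=window, n_molecules=n_mol
    )


def _mixture(x, means, sds, areas):
    z = (x[:, None] - means) / sds
    return (areas / (sds * np.sqrt(2 * np.pi)) * np.exp(-0.5 * z**2)).sum(axis=1)


def global_gaussian_fit(
    histograms: list[EfficiencyHistogram],
    n_components: int = 4,
    init_means: np.ndarray | None = None,
    mean_bound: float = 0.08,
    init_sd: float = 0.06,
    sd_bounds: tuple[float, float] = (0.01, 0.25),
) -> GaussianMixFit:
    """Weighted least-squares global fit over all histograms simultaneously.

    Peak positions and widths are shared; per-histogram areas are free and
    constrained non-negative.  Counts are weighted by sqrt(counts)
    (Poisson).  ``init_means`` defaults to the four conformer levels
    {0.30, 0.57, 0.73, 0.88}; means are bounded within ``mean_bound`` of
    their initializers to prevent component swapping.
    """
    if n_components < 1:
        raise ValueError("need at least one component")
    if init_means is None:
        init_means = np.array([0.30, 0.57, 0.73, 0.88])[:n_components] \
            if n_components <= 4 else np.linspace(0.2, 0.9, n_components)
    init_means = np.asarray(init_means, float)
    if init_means.size != n_components:
        raise ValueError("init_means length must equal n_components")
    edges0 = histograms[0].edges
    for h in histograms:
        if h.edges.shape != edges0.shape or not np.allclose(h.edges, edges0):
            raise ValueError("histograms must share bin edges")

    n_h = len(histograms)
    areas0 = np.array(
        [np.full(n_components, max(h.counts.sum(), 1.0) * h.bin_width / n_components)
         for h in histograms]
    )

    def unpack(p):
        means = p[:n_components]
        sds = p[n_components: 2 * n_components]
        areas = p[2 * n_components:].reshape(n_h, n_components)
        return means, sds, areas

    def residuals(p):
        means, sds, areas = unpack(p)
        out = []
        for i, h in enumerate(histograms):
            model = _mixture(h.centers, means, sds, areas[i]) * h.bin_width
            w = np.sqrt(np.maximum(h.counts, 1.0))
            out.append((model - h.counts) / w)
        return np.concatenate(out)

    x0 = np.concatenate([init_means, np.full(n_components, init_sd), areas0.ravel()])
    lb = np.concatenate([
        init_means - mean_bound,
        np.full(n_components, sd_bounds[0]),
        np.zeros(n_h * n_components),
    ])
    ub = np.concatenate([
        init_means + mean_bound,
        np.full(n_components, sd_bounds[1]),
        np.full(n_h * n_components, np.inf),
    ])
    res = least_squares(residuals, x0, bounds=(lb, ub), max_nfev=20000)
    means, sds, areas = unpack(res.x)
    return GaussianMixFit(
        means=means, sds=sds, amplitudes=areas,
        residual_norm=float(np.linalg.norm(res.fun)), success=bool(res.success),
    )
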