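"""Rate constants -> one-dimensional free-energy landscape.

Standard two-state transition-state relations in thermal units (k_BT at
298 K), with the unfolded state as the zero of energy:

    stability    dG_U    = ln(k_F / k_U)      (positive = folded favored)
    barriers     dG++    = ln(k0 / k)

where k0 is the attempt frequency.  The default k0 = 1e6 1/s reproduces
the ~15 k_BT folding barriers implied by the observed ~0.2 1/s folding
rates; it is configuration, not an inferred quantity, and is reported in
every output.  The thermodynamic cycle dG++_F - dG++_U = -dG_U closes
exactly by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = ["EnergyLandscape", "stability", "barrier", "build_landscape",
           "DEFAULT_ATTEMPT_FREQUENCY"]

DEFAULT_ATTEMPT_FREQUENCY = 1e6  # 1/s


def stability(k_f: float, k_u: float) -> float:
    """Unfolding free energy dG_U = ln(k_F/k_U) in k_BT; > 0 = folded favored."""
    if k_f <= 0 or k_u <= 0:
        raise ValueError("rates must be > 0")
    return math.log(k_f / k_u)


def barrier(k: float, k0: float = DEFAULT_ATTEMPT_FREQUENCY) -> float:
    """Activation free energy dG++ = ln(k0/k) in k_BT; requires 0 < k <= k0.

    k = k0 is the barrierless limit and returns exactly 0.
    """
    if k <= 0:
        raise ValueError("rate must be > 0")
    if k > k0:
        raise ValueError(f"rate {k} > attempt frequency {k0}: no barrier")
    return math.log(k0 / k)


@dataclass(frozen=True)
class EnergyLandscape:
    """Per-conformer stabilities and barriers (k_BT), unfolded state at 0."""

    states: tuple[str, ...]
    dg_u: tuple[float, ...]            # stability of each folded state
    dg_fold_barrier: tuple[float, ...]
    dg_unfold_barrier: tuple[float, ...]
    attempt_frequency: float

    def __post_init__(self) -> None:
        for f, u, s in zip(self.dg_fold_barrier, self.dg_unfold_barrier, self.dg_u):
            if not math.isclose(f - u, -s, rel_tol=0, abs_tol=1e-12):
                raise ValueError("thermodynamic cycle does not close")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "state": self.states,
                "dG_U_kBT": self.dg_u,
                "dGf_barrier_kBT": self.dg_fold_barrier,
                "dGu_barrier_kBT": self.dg_unfold_barrier,
                "k0_s-1": self.attempt_frequency,
            }
        )

    def most_stable(self) -> str:
        """Folded state with the lowest free energy (largest dG_U)."""
        return self.states[self.dg_u.index(max(self.dg_u))]

    def plot(self, ax=None):
        """Horizontal-level sketch of the landscape: states and barrier."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        ax.hlines(0.0, 0.0, 0.8, color="k", lw=2)
        ax.annotate("U", (0.4, 0.1), ha="center")
        top = max(self.dg_fold_barrier)
        ax.hlines(top, 1.0, 1.8, color="gray", ls="--", lw=1.5)
        ax.annotate(r"$\Delta G^{\ddag}$", (1.4, top + 0.1), ha="center")
        for i, s in enumerate(self.states):
            x0 = 2.0 + i
            ax.hlines(-self.dg_u[i], x0, x0 + 0.8, lw=2)
            ax.annotate(s, (x0 + 0.4, -self.dg_u[i] + 0.1), ha="center")
        ax.set_ylabel(r"free energy ($k_BT$)")
        ax.set_xticks([])
        return ax


def build_landscape(
    k_fold: dict[str, float],
    k_unfold: dict[str, float],
    k0: float = DEFAULT_ATTEMPT_FREQUENCY,
) -> EnergyLandscape:
    """Landscape from per-conformer rate constants; cycle closes exactly."""
    if set(k_fold) != set(k_unfold):
        raise ValueError("every folded state needs both k_F and k_U")
    states = tuple(k_fold)
    dg_f = tuple(barrier(k_fold[s], k0) for s in states)
    # unfolding barrier derived through the cycle so closure is exact
    dg_u = tuple(stability(k_fold[s], k_unfold[s]) for s in states)
    dg_ub = tuple(f + s for f, s in zip(dg_f, dg_u))
    return EnergyLandscape(
        states=states,
        dg_u=dg_u,
        dg_fold_barrier=dg_f,
        dg_unfold_barrier=dg_ub,
        attempt_frequency=k0,
    )
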