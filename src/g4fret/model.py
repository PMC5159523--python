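"""Continuous-time kinetic models of G-quadruplex conformational dynamics.

The human telomeric overhang interconverts between an unfolded state and
several folded G-quadruplex conformers (chair, 2-tetrad basket, hybrid 1,
hybrid 2).  Folding proceeds almost exclusively through the unfolded state,
so the default kinetic scheme is a star: U <-> F_i with per-conformer
folding (k_F) and unfolding (k_U) rate constants.  Each conformer carries a
characteristic FRET efficiency level; the two hybrid conformers share a
level and are distinguished by lifetime only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.sparse.csgraph import connected_components

__all__ = [
    "KineticModel",
    "build_default_model",
    "stationary_distribution",
    "rate_matrix",
]

#: canonical FRET-efficiency centers of the four resolvable levels
CANONICAL_E = {"U": 0.30, "basket": 0.57, "hybrid": 0.73, "chair": 0.88}


@dataclass(frozen=True)
class KineticModel:
    """Star-topology (plus optional direct edges) kinetic scheme.

    Parameters
    ----------
    states:
        State labels; ``states[0]`` is the unfolded state, the rest are
        folded conformers.
    e_centers:
        Mean FRET efficiency of each state, same order as ``states``.
    k_fold:
        Rate constants (1/s) for unfolded -> folded, keyed by folded label.
    k_unfold:
        Rate constants (1/s) for folded -> unfolded, keyed by folded label.
    k_direct:
        Optional direct folded -> folded rate constants keyed by
        ``(from_label, to_label)``; default none.
    first_fold_branching:
        Probability of each folded conformer being the destination of the
        *first* folding event of a trajectory.  The cation-jump experiments
        show a first-fold split that is not reproducible from the
        steady-state rates alone, so it is a separate model feature.
        ``None`` means branch proportionally to ``k_fold``.
    """

    states: tuple[str, ...]
    e_centers: tuple[float, ...]
    k_fold: Mapping[str, float]
    k_unfold: Mapping[str, float]
    k_direct: Mapping[tuple[str, str], float] = field(default_factory=dict)
    first_fold_branching: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if len(self.states) < 2:
            raise ValueError("need one unfolded plus at least one folded state")
        if len(self.e_centers) != len(self.states):
            raise ValueError("e_centers must match states")
        for e in self.e_centers:
            if not 0.0 <= e <= 1.0:
                raise ValueError(f"E center {e} outside [0, 1]")
        folded = set(self.folded_states)
        for mapping, name in ((self.k_fold, "k_fold"), (self.k_unfold, "k_unfold")):
            if set(mapping) != folded:
                raise ValueError(f"{name} must be keyed by every folded state")
            for k in mapping.values():
                if k < 0:
                    raise ValueError(f"negative rate in {name}")
        for (a, b), k in self.k_direct.items():
            if a not in folded or b not in folded or a == b:
                raise ValueError(f"bad direct edge ({a}, {b})")
            if k < 0:
                raise ValueError("negative direct rate")
        if self.first_fold_branching is not None:
            if set(self.first_fold_branching) - folded:
                raise ValueError("branching keys must be folded states")
            total = sum(self.first_fold_branching.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"first_fold_branching sums to {total}, not 1")

    @property
    def unfolded(self) -> str:
        return self.states[0]

    @property
    def folded_states(self) -> tuple[str, ...]:
        return self.states[1:]

    @property
    def n_states(self) -> int:
        return len(self.states)

    def index(self, label: str) -> int:
        return self.states.index(label)

    def e_of(self, label: str) -> float:
        return self.e_centers[self.index(label)]

    def branching_vector(self) -> np.ndarray:
        """First-fold destination probabilities over the folded states."""
        if self.first_fold_branching is None:
            k = np.array([self.k_fold[s] for s in self.folded_states])
            if k.sum() == 0:
                raise ValueError("all folding rates zero: no first fold exists")
            return k / k.sum()
        return np.array(
            [self.first_fold_branching.get(s, 0.0) for s in self.folded_states]
        )


def build_default_model() -> KineticModel:
    """Five-state scheme for telomeric G4 folding in 25 mM K+.

    Unfolded (E 0.30) exchanges with four conformers: chair (E 0.88),
    2-tetrad basket (E 0.57) and the two hybrids sharing E 0.73.  Hybrid 1
    is the long-lived thermodynamic sink — its dwell time is an order of
    magnitude longer than the other conformers' — while chair, basket and
    hybrid 2 are rapidly formed, short-lived states.  The first folding
    event after the K+ jump lands in the chair with 80% probability and the
    2-tetrad basket otherwise.
    """
    return KineticModel(
        states=("U", "chair", "basket", "hybrid2", "hybrid1"),
        e_centers=(0.30, 0.88, 0.57, 0.73, 0.73),
        k_fold={"chair": 0.21, "basket": 0.19, "hybrid2": 0.19, "hybrid1": 0.02},
        k_unfold={"chair": 0.15, "basket": 0.35, "hybrid2": 0.30, "hybrid1": 0.015},
        first_fold_branching={"chair": 0.8, "basket": 0.2},
    )


def rate_matrix(model: KineticModel) -> np.ndarray:
    """Generator matrix Q (1/s); rows sum to zero, Q[i, j] = rate i -> j."""
    n = model.n_states
    q = np.zeros((n, n))
    for s in model.folded_states:
        j = model.index(s)
        q[0, j] = model.k_fold[s]
        q[j, 0] = model.k_unfold[s]
    for (a, b), k in model.k_direct.items():
        q[model.index(a), model.index(b)] += k
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def stationary_distribution(model: KineticModel) -> dict[str, float]:
    """Exact stationary distribution pi of the generator: pi Q = 0, sum pi = 1.

    The first-fold branching is a transient feature and is ignored here.
    Raises ``ValueError`` if the rate graph is not irreducible.
    """
    q = rate_matrix(model)
    adj = (q > 0).astype(int)
    n_comp, _ = connected_components(adj, directed=True, connection="strong")
    if n_comp != 1:
        raise ValueError("rate matrix is reducible; stationary distribution not unique")
    # solve pi Q = 0 with the normalization row appended
    a = np.vstack([q.T, np.ones(model.n_states)])
    b = np.zeros(model.n_states + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    return dict(zip(model.states, pi))
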