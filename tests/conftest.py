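import numpy as np
import pytest

import biotite.structure as struc

from g4fret import CameraParams, KineticModel, build_default_model

TRUE_K_FOLD = {"chair": 0.21, "basket": 0.19, "hybrid2": 0.19, "hybrid1": 0.02}
TRUE_K_UNFOLD = {"chair": 0.15, "basket": 0.35, "hybrid2": 0.30, "hybrid1": 0.015}
CANONICAL_LEVELS = np.array([0.30, 0.57, 0.73, 0.88])


@pytest.fixture(scope="session")
def default_model() -> KineticModel:
    return build_default_model()


@pytest.fixture
def two_state_model() -> KineticModel:
    return KineticModel(
        states=("U", "F"),
        e_centers=(0.3, 0.8),
        k_fold={"F": 1.0},
        k_unfold={"F": 1.0},
    )


@pytest.fixture
def quiet_camera() -> CameraParams:
    """Noise-free, background-free camera for exactness tests."""
    return CameraParams(
        movie_length=60.0,
        bg_mean=(0.0, 0.0, 0.0),
        bg_sd=(0.0, 0.0, 0.0),
        shot_noise=False,
    )


def make_atoms(coords, elements=None) -> struc.AtomArray:
    """Minimal synthetic AtomArray for geometry tests."""
    coords = np.asarray(coords, float)
    n = len(coords)
    arr = struc.AtomArray(n)
    arr.coord = coords
    arr.element = np.array(elements if elements is not None else ["C"] * n)
    arr.atom_name = np.array([f"X{i}" for i in range(n)])
    arr.res_id = np.arange(1, n + 1)
    arr.res_name = np.array(["LIG"] * n)
    arr.chain_id = np.array(["A"] * n)
    return arr


def make_stack(frame_coords, elements=None) -> struc.AtomArrayStack:
    """AtomArrayStack from (n_frames, n_atoms, 3) coordinates."""
    frame_coords = np.asarray(frame_coords, float)
    n_frames, n_atoms, _ = frame_coords.shape
    stack = struc.AtomArrayStack(n_frames, n_atoms)
    stack.coord = frame_coords
    stack.element = np.array(elements if elements is not None else ["C"] * n_atoms)
    stack.atom_name = np.array([f"X{i}" for i in range(n_atoms)])
    stack.res_id = np.arange(1, n_atoms + 1)
    stack.res_name = np.array(["LIG"] * n_atoms)
    stack.chain_id = np.array(["A"] * n_atoms)
    return stack
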