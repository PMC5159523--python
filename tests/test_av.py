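"""Accessible-volume geometry, clustering and structure-based FRET."""

import numpy as np
import pytest

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from g4fret import (
    DyeParameters,
    cluster_frames,
    compute_av,
    fret_from_distance,
    predict_fret,
    read_structure,
    select_atom,
)

from conftest import make_atoms, make_stack

SMALL_DYE = DyeParameters(linker_length=10.0, linker_width=3.0, dye_radii=(3.0,))
BALL_VOLUME = 4.0 / 3.0 * np.pi * 10.0**3


def mc_rejection_volume(rng, obstacles, linker_length, exclusion, n=200_000):
    """Independent Monte-Carlo oracle: uniform sampling in the linker ball,
    rejecting points whose dye sphere overlaps an obstacle atom."""
    pts = rng.normal(size=(n, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    pts *= rng.uniform(0.0, 1.0, (n, 1)) ** (1 / 3) * linker_length
    ball = 4.0 / 3.0 * np.pi * linker_length**3
    if len(obstacles) == 0:
        return ball
    d = np.linalg.norm(pts[:, None, :] - obstacles[None, :, :], axis=2).min(axis=1)
    return ball * (d >= exclusion).mean()


def separated_obstacles(rng, n_obstacles):
    """Obstacle atoms placed where linker-connectivity effects are negligible:
    mid-shell distances from the attachment, mutually well separated."""
    obs = []
    while len(obs) < n_obstacles:
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        p = u * rng.uniform(6.5, 8.0)
        if all(np.linalg.norm(p - q) >= 9.0 for q in obs):
            obs.append(p)
    return np.array(obs)


class TestReadStructure:
    def test_minimal_pdb_round_trip(self, tmp_path):
        atoms = make_atoms([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0], [0.0, 2.5, 1.0]],
                           ["C", "N", "O"])
        f = tmp_path / "mini.pdb"
        pdb = PDBFile()
        pdb.set_structure(atoms)
        pdb.write(str(f))
        stack = read_structure(f)
        assert stack.stack_depth() == 1
        assert stack.array_length() == 3
        assert np.allclose(stack[0].coord, atoms.coord, atol=1e-3)

    def test_multi_model_gives_frames(self, tmp_path):
        stack = make_stack(np.zeros((2, 3, 3)) + np.arange(3)[None, :, None])
        f = tmp_path / "two.pdb"
        pdb = PDBFile()
        pdb.set_structure(stack)
        pdb.write(str(f))
        back = read_structure(f)
        assert back.stack_depth() == 2

    def test_select_atom_unique(self):
        atoms = make_atoms([[0, 0, 0], [1, 0, 0]])
        assert select_atom(atoms, atom_name="X1") == 1
        with pytest.raises(ValueError, match="matches 2"):
            select_atom(atoms, chain_id="A")


class TestComputeAV:
    def test_unobstructed_volume_matches_ball(self):
        atoms = make_atoms([[0.0, 0.0, 0.0]])
        cloud = compute_av(atoms, 0, SMALL_DYE, grid_spacing=1.0)
        assert cloud.volume == pytest.approx(BALL_VOLUME, rel=0.05)
        assert np.allclose(cloud.mean_position, 0.0, atol=1e-9)

    def test_cloud_within_linker_ball(self):
        rng = np.random.default_rng(0)
        obs = rng.uniform(-8, 8, (4, 3))
        atoms = make_atoms(np.vstack([[0, 0, 0], obs]))
        cloud = compute_av(atoms, 0, SMALL_DYE, grid_spacing=1.0)
        r = np.linalg.norm(cloud.points - cloud.attachment_point, axis=1)
        assert np.all(r <= SMALL_DYE.linker_length + 1e-9)

    def test_buried_attachment_empty_cloud(self):
        cage = [[d * 2.2, 0, 0] for d in (-1, 1)] + \
               [[0, d * 2.2, 0] for d in (-1, 1)] + \
               [[0, 0, d * 2.2] for d in (-1, 1)] + \
               [[i * 1.6, j * 1.6, k * 1.6]
                for i in (-1, 1) for j in (-1, 1) for k in (-1, 1)]
        atoms = make_atoms(np.vstack([[0.0, 0.0, 0.0], cage]))
        cloud = compute_av(atoms, 0, SMALL_DYE, grid_spacing=1.0)
        assert cloud.is_empty
        assert cloud.volume == 0.0
        assert cloud.mean_position is None

    def test_obstacle_monotonicity(self):
        """Adding an obstacle atom never increases the cloud volume."""
        rng = np.random.default_rng(1)
        base_obs = separated_obstacles(rng, 2)
        atoms = make_atoms(np.vstack([[0, 0, 0], base_obs]))
        v_base = compute_av(atoms, 0, SMALL_DYE, 1.0).volume
        for _ in range(4):
            extra = rng.uniform(-9, 9, (1, 3))
            more = make_atoms(np.vstack([[0, 0, 0], base_obs, extra]))
            assert compute_av(more, 0, SMALL_DYE, 1.0).volume <= v_base + 1e-9

    def test_matches_monte_carlo_oracle(self):
        """Grid volume within 5% of rejection sampling on random obstacles."""
        rng = np.random.default_rng(2)
        for _ in range(4):
            obs = separated_obstacles(rng, rng.integers(2, 5))
            atoms = make_atoms(np.vstack([[0, 0, 0], obs]))
            cloud = compute_av(atoms, 0, SMALL_DYE, 1.0)
            oracle = mc_rejection_volume(rng, obs, 10.0, 1.70 + 3.0)
            assert cloud.volume == pytest.approx(oracle, rel=0.05)

    def test_grid_refinement_converges(self):
        atoms = make_atoms([[0.0, 0.0, 0.0]])
        v1 = compute_av(atoms, 0, SMALL_DYE, grid_spacing=1.0).volume
        v2 = compute_av(atoms, 0, SMALL_DYE, grid_spacing=0.5).volume
        assert abs(v2 / v1 - 1) < 0.03

    def test_spacing_validation(self):
        atoms = make_atoms([[0.0, 0.0, 0.0]])
        with pytest.raises(ValueError, match="grid spacing"):
            compute_av(atoms, 0, SMALL_DYE, grid_spacing=5.0)


class TestForsterRelation:
    def test_half_efficiency_at_r0(self):
        assert fret_from_distance(56.0, 56.0) == 0.5

    def test_double_distance(self):
        assert fret_from_distance(2.0, 1.0) == pytest.approx(1 / 65)

    def test_strictly_decreasing(self):
        r = np.linspace(10, 120, 50)
        e = fret_from_distance(r, 56.0)
        assert np.all(np.diff(e) < 0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fret_from_distance(-1.0, 56.0)
        with pytest.raises(ValueError):
            fret_from_distance(10.0, 0.0)


class TestClusterFrames:
    def test_identical_frames_one_cluster(self):
        coords = np.tile(np.array([[0, 0, 0], [3, 0, 0], [0, 3, 0.0]]), (5, 1, 1))
        stack = make_stack(coords)
        assignments, reps = cluster_frames(stack, cutoff=8.0, n_clusters=10)
        assert len(reps) == 1
        assert np.all(assignments == 0)

    def test_two_separated_conformers_split_exactly(self):
        a = np.array([[0, 0, 0], [3, 0, 0], [0, 3, 0.0]])
        b = a + np.array([0, 0, 30.0])  # RMSD >> cutoff after superposition?
        # make conformer B a genuinely different shape, not a rigid copy
        b = np.array([[0, 0, 0], [30, 0, 0], [0, 30, 0.0]])
        coords = np.array([a, b, a, b, a])
        stack = make_stack(coords)
        assignments, reps = cluster_frames(stack, cutoff=8.0, n_clusters=10)
        assert len(reps) == 2
        assert len(set(assignments[[0, 2, 4]])) == 1
        assert len(set(assignments[[1, 3]])) == 1
        assert assignments[0] != assignments[1]

    def test_three_basin_populations_match_weights(self):
        """Cluster populations on a noisy 3-basin ensemble match the
        generating weights within 5%."""
        rng = np.random.default_rng(3)
        basins = [
            np.array([[0, 0, 0], [5, 0, 0], [0, 5, 0.0]]),
            np.array([[0, 0, 0], [25, 0, 0], [0, 25, 0.0]]),
            np.array([[0, 0, 0], [50, 0, 0], [0, 0, 50.0]]),
        ]
        weights = np.array([0.5, 0.3, 0.2])
        n = 200
        labels = rng.choice(3, size=n, p=weights)
        coords = np.array([basins[l] + rng.normal(0, 0.5, (3, 3)) for l in labels])
        stack = make_stack(coords)
        assignments, reps = cluster_frames(stack, cutoff=8.0, n_clusters=10)
        pops = np.array([(assignments == c).sum() for c in range(len(reps))]) / n
        drawn = np.array([(labels == l).mean() for l in range(3)])
        assert np.allclose(np.sort(pops[:3]), np.sort(drawn), atol=0.05)


class TestPredictFret:
    def _two_point_stack(self, separations):
        coords = np.array(
            [[[0.0, 0, 0], [s, 0, 0]] for s in separations]
        )
        return make_stack(coords)

    def test_single_frame_approaches_agree(self):
        stack = self._two_point_stack([56.0])
        pred = predict_fret(stack, 0, 1, SMALL_DYE, SMALL_DYE, r0=56.0,
                            n_clusters=2)
        assert pred.e_by_approach[1] == pred.e_by_approach[2]
        assert pred.e_by_approach[1] == pred.e_by_approach[4]

    def test_separation_at_r0_gives_half(self):
        """Symmetric unobstructed clouds put the mean dye positions on the
        attachment atoms, so R = R0 yields E = 0.5 for every approach."""
        stack = self._two_point_stack([56.0, 56.0])
        pred = predict_fret(stack, 0, 1, SMALL_DYE, SMALL_DYE, r0=56.0,
                            n_clusters=2)
        for e in pred.e_by_approach.values():
            assert e == pytest.approx(0.5, abs=1e-6)
        assert pred.e_av == pytest.approx(0.5, abs=1e-6)

    def test_two_conformer_population_weighting(self):
        """Approach 3 equals the closed-form population-weighted efficiency."""
        separations = [50.0] * 3 + [70.0] * 1
        stack = self._two_point_stack(separations)
        pred = predict_fret(stack, 0, 1, SMALL_DYE, SMALL_DYE, r0=56.0,
                            cluster_cutoff=5.0, n_clusters=4)
        r_weighted = 0.75 * 50.0 + 0.25 * 70.0
        assert pred.e_by_approach[3] == pytest.approx(
            fret_from_distance(r_weighted, 56.0), abs=1e-6
        )
        assert pred.e_by_approach[4] == pytest.approx(
            fret_from_distance(50.0, 56.0), abs=1e-6
        )

    def test_convexity_inequality_on_bimodal_ensemble(self):
        """Mean-of-E exceeds E-of-mean when E is convex over the distances."""
        stack = self._two_point_stack([70.0, 90.0, 70.0, 90.0])
        pred = predict_fret(stack, 0, 1, SMALL_DYE, SMALL_DYE, r0=56.0,
                            n_clusters=2)
        assert pred.e_by_approach[2] >= pred.e_by_approach[1]
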