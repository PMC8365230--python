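import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from ribomech.deviation import (
    DegenerateFitError,
    angle_of_deviation,
    apply_transform,
    local_rmsd,
    per_residue_deviation,
    superpose,
)
from ribomech.structures import map_chains

from conftest import cg, helix_coords
from oracles import quaternion_superpose_rmsd


def rigid(coords, angle_deg=30.0, axis=(0, 0, 1.0), shift=(1.0, 2.0, 3.0)):
    r = Rotation.from_rotvec(np.radians(angle_deg) * np.asarray(axis)).as_matrix()
    return coords @ r.T + np.asarray(shift)


class TestSuperpose:
    def test_identity(self, helix30):
        m = map_chains(helix30, helix30)
        r, t, rmsd = superpose(helix30, helix30, m)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(r, np.eye(3), atol=1e-8)

    def test_exact_rigid_motion_recovered(self, helix30):
        b = cg(rigid(helix30.coords), name="moved")
        m = map_chains(helix30, b)
        r, t, rmsd = superpose(helix30, b, m)
        assert rmsd == pytest.approx(0.0, abs=1e-8)
        angle = np.degrees(np.arccos(np.clip((np.trace(r) - 1) / 2, -1, 1)))
        assert angle == pytest.approx(30.0, abs=1e-6)
        np.testing.assert_allclose(
            apply_transform(b.coords, r, t), helix30.coords, atol=1e-8
        )
        assert np.linalg.det(r) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_quaternion_oracle_on_noisy_clouds(self, seed):
        rng = np.random.default_rng(seed)
        xa = rng.uniform(-20, 20, size=(50, 3))
        xb = rigid(xa, angle_deg=rng.uniform(0, 180)) + rng.normal(0, 1.0, (50, 3))
        a, b = cg(xa), cg(xb)
        m = map_chains(a, b)
        _, _, rmsd = superpose(a, b, m)
        assert rmsd == pytest.approx(quaternion_superpose_rmsd(xa, xb), abs=1e-8)

    def test_degenerate_inputs_rejected(self):
        line = cg(np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)]))
        m = map_chains(line, line)
        with pytest.raises(DegenerateFitError):
            superpose(line, line, m)
        two = cg(np.array([[0.0, 0, 0], [3.8, 0, 0]]))
        m2 = map_chains(two, two)
        with pytest.raises(DegenerateFitError):
            superpose(two, two, m2)

    def test_rmsd_symmetric(self, state_pair, state_pair_map):
        unbound, bound, _ = state_pair
        _, _, r_ab = superpose(unbound, bound, state_pair_map)
        m_ba = map_chains(bound, unbound)
        _, _, r_ba = superpose(bound, unbound, m_ba)
        assert r_ab == pytest.approx(r_ba, abs=1e-9)


class TestPerResidueDeviation:
    def test_identical_structures_flag_nothing(self, helix30):
        m = map_chains(helix30, helix30)
        recs, mean, sd = per_residue_deviation(helix30, helix30, m)
        assert mean == pytest.approx(0.0, abs=1e-10)
        assert sd == pytest.approx(0.0, abs=1e-10)
        assert not any(r.significant for r in recs)

    def test_single_outlier_flagged(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(-30, 30, size=(100, 3))
        moved = base.copy()
        moved += rng.normal(0, 0.1 / np.sqrt(3), size=moved.shape)  # ~0.1 Å each
        moved[42] = base[42] + np.array([10.0, 0, 0])
        a, b = cg(base), cg(moved)
        m = map_chains(a, b)
        recs, mean, sd = per_residue_deviation(a, b, m, fit_subset="all")
        flagged = [r.index_a for r in recs if r.significant]
        assert flagged == [42]
        # explicit check of the mean + 2·SD rule on the reported distribution
        dev = np.array([r.deviation for r in recs])
        assert set(flagged) == set(np.flatnonzero(dev > dev.mean() + 2 * dev.std()))

    def test_invariant_to_common_rigid_motion(self, state_pair, state_pair_map):
        unbound, bound, _ = state_pair
        recs, _, _ = per_residue_deviation(unbound, bound, state_pair_map)
        u2 = unbound.with_coords(rigid(unbound.coords, 55.0, (0, 1, 0), (5, -2, 9)))
        b2 = bound.with_coords(rigid(bound.coords, 55.0, (0, 1, 0), (5, -2, 9)))
        recs2, _, _ = per_residue_deviation(u2, b2, state_pair_map)
        np.testing.assert_allclose(
            [r.deviation for r in recs], [r.deviation for r in recs2], atol=1e-8
        )


class TestLocalRmsd:
    def test_rigid_chain_translation_modes(self):
        coords = np.vstack([helix_coords(20),
                            helix_coords(20) + np.array([30.0, 0, 0])])
        chains = ["A"] * 20 + ["B"] * 20
        a = cg(coords, chain_ids=chains)
        moved = coords.copy()
        moved[20:] += np.array([0.0, 5.0, 0.0])
        b = cg(moved, chain_ids=chains)
        m = map_chains(a, b)
        assert local_rmsd(a, b, m, "B", "fit-on-self") == pytest.approx(0.0, abs=1e-8)
        ref = a.chain_indices("A")
        assert local_rmsd(a, b, m, "B", "fit-on-reference",
                          reference_fit_subset=ref) == pytest.approx(5.0, abs=1e-8)

    def test_whole_structure_chain_equals_global(self, helix30):
        rng = np.random.default_rng(1)
        b = cg(helix30.coords + rng.normal(0, 0.5, helix30.coords.shape))
        m = map_chains(helix30, b)
        _, _, global_rmsd = superpose(helix30, b, m)
        assert local_rmsd(helix30, b, m, "A", "fit-on-self") == \
            pytest.approx(global_rmsd, abs=1e-10)

    def test_unknown_chain_errors(self, helix30):
        m = map_chains(helix30, helix30)
        with pytest.raises(Exception):
            local_rmsd(helix30, helix30, m, "Z")


class TestAngleOfDeviation:
    def _two_chain(self, rng=None):
        coords = np.vstack([helix_coords(30),
                            (rng.uniform(-10, 10, (40, 3)) if rng is not None
                             else helix_coords(40)) + np.array([40.0, 0, 0])])
        return cg(coords, chain_ids=["R"] * 30 + ["P"] * (len(coords) - 30))

    def test_planted_rotation_recovered_exactly(self):
        a = self._two_chain()
        coords = a.coords.copy()
        target = a.chain_indices("P")
        c = coords[target].mean(axis=0)
        r = Rotation.from_euler("z", np.radians(10.0)).as_matrix()
        coords[target] = (coords[target] - c) @ r.T + c
        b = a.with_coords(coords)
        m = map_chains(a, b)
        assert angle_of_deviation(a, b, m, ["R"], "P") == pytest.approx(10.0, abs=1e-6)
        assert angle_of_deviation(a, a, m, ["R"], "P") == pytest.approx(0.0, abs=1e-6)

    def test_invariant_to_rigid_motion_of_whole_complex_b(self):
        a = self._two_chain(np.random.default_rng(7))
        coords = a.coords.copy()
        target = a.chain_indices("P")
        c = coords[target].mean(axis=0)
        r = Rotation.from_euler("x", np.radians(17.0)).as_matrix()
        coords[target] = (coords[target] - c) @ r.T + c
        b = a.with_coords(coords)
        m = map_chains(a, b)
        ref = angle_of_deviation(a, b, m, ["R"], "P")
        b2 = b.with_coords(rigid(b.coords, 120.0, (1, 1, 0), (-30, 4, 12)))
        assert angle_of_deviation(a, b2, m, ["R"], "P") == pytest.approx(ref, abs=1e-7)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(angle=st.floats(min_value=1.0, max_value=179.0),
           seed=st.integers(min_value=0, max_value=10_000))
    def test_angle_in_valid_range_and_recovers_plant(self, angle, seed):
        rng = np.random.default_rng(seed)
        a = self._two_chain(rng)
        coords = a.coords.copy()
        target = a.chain_indices("P")
        c = coords[target].mean(axis=0)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        r = Rotation.from_rotvec(np.radians(angle) * axis).as_matrix()
        coords[target] = (coords[target] - c) @ r.T + c
        b = a.with_coords(coords)
        m = map_chains(a, b)
        got = angle_of_deviation(a, b, m, ["R"], "P")
        assert 0.0 <= got <= 180.0
        assert got == pytest.approx(angle, abs=1e-5)
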