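"""Geometric kernels against brute-force oracles; PDB round trip."""
import numpy as np
import pandas as pd
import pytest

from qsarscreen.exceptions import ParameterError
from qsarscreen.synthetic import gen_trajectory
from qsarscreen.trajectory import (
    HYDROPHOBIC_RESIDUES,
    Trajectory,
    contact_series,
    find_donors_acceptors,
    hbond_count,
    hydrophobic_contacts,
    kabsch_rmsd,
    read_pdb,
    rmsd_series,
    rmsf,
    write_pdb,
)


def _intermolecular_sets(traj):
    donors, acceptors = find_donors_acceptors(traj)
    is_lig = traj.atoms["is_ligand"].to_numpy()
    return donors[is_lig[donors]], acceptors[~is_lig[acceptors]]


def _hbond_oracle(traj, frame_index, donors, acceptors, d_max=4.0, angle_min=120.0):
    """Independent O(n²) enumeration with explicit geometry, pure python."""
    frame = traj.coords[frame_index]
    elements = traj.atoms["element"].tolist()
    count = 0
    for d in donors:
        hs = [
            i for i, e in enumerate(elements)
            if e == "H" and np.linalg.norm(frame[i] - frame[d]) <= 1.25
        ]
        for a in acceptors:
            if a == d:
                continue
            if np.linalg.norm(frame[a] - frame[d]) > d_max:
                continue
            for h in hs:
                v1, v2 = frame[d] - frame[h], frame[a] - frame[h]
                cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                if np.degrees(np.arccos(np.clip(cosang, -1, 1))) >= angle_min:
                    count += 1
                    break
    return count


class TestKabschRmsd:
    def test_identical_frames(self, rng):
        A = rng.normal(size=(12, 3))
        assert kabsch_rmsd(A, A)[0] == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self, rng):
        from scipy.spatial.transform import Rotation

        A = rng.normal(size=(10, 3))
        R = Rotation.from_euler("xyz", [90, 30, -45], degrees=True).as_matrix()
        B = A @ R.T + np.array([3.0, -2.0, 7.0])
        assert kabsch_rmsd(A, B)[0] == pytest.approx(0.0, abs=1e-9)

    def test_mismatched_shapes_rejected(self, rng):
        with pytest.raises(ParameterError):
            kabsch_rmsd(rng.normal(size=(5, 3)), rng.normal(size=(6, 3)))

    def test_cross_check_against_mdanalysis(self, rng):
        from MDAnalysis.analysis.rms import rmsd as mda_rmsd

        A = rng.normal(size=(15, 3))
        B = A + rng.normal(0, 0.4, size=(15, 3))
        mine = kabsch_rmsd(A, B)[0]
        ref = mda_rmsd(B, A, center=True, superposition=True)
        assert mine == pytest.approx(ref, abs=1e-6)


class TestRmsdSeries:
    def test_first_frame_zero_and_static_all_zero(self):
        t = gen_trajectory(5, [("d", "a", 3.0, 180.0)], jitter_sd=0.0)
        series = rmsd_series(t)
        np.testing.assert_allclose(series, 0.0, atol=1e-9)

    def test_drifting_ligand_grows_monotonically(self):
        t = gen_trajectory(10, jitter_sd=0.0, ligand_drift=0.5)
        lig = t.heavy(t.select(ligand=True))
        series = rmsd_series(t, lig)
        assert series[0] == pytest.approx(0.0, abs=1e-9)
        # ligand internal geometry is rigid; superposed RMSD stays 0 — measure
        # drift against the full complex instead
        all_series = rmsd_series(t)
        assert (np.diff(all_series) > -1e-9).all()
        assert all_series[-1] > all_series[1]

    def test_empty_selection_rejected(self):
        t = gen_trajectory(3)
        with pytest.raises(ParameterError):
            rmsd_series(t, np.array([], dtype=int))


class TestRmsf:
    @staticmethod
    def _lattice_trajectory(n_frames=200, jitter=0.5, seed=0):
        rng = np.random.default_rng(seed)
        # 20 fixed anchor atoms + one 2-atom residue jittered isotropically
        anchors = np.array([[4.0 * i, 10.0 * (i % 3), 3.0 * (i % 5)] for i in range(20)])
        mobile = np.array([[50.0, 0.0, 0.0], [51.5, 0.0, 0.0]])
        base = np.vstack([anchors, mobile])
        coords = np.repeat(base[None], n_frames, axis=0)
        coords[:, 20:, :] += rng.normal(0, jitter, size=(n_frames, 2, 3))
        atoms = pd.DataFrame(
            {
                "name": ["CA"] * 20 + ["CB", "CG"],
                "element": ["C"] * 22,
                "resname": ["GLY"] * 20 + ["LEU"] * 2,
                "resid": list(range(1, 21)) + [21, 21],
                "chain": ["A"] * 22,
                "is_ligand": [False] * 22,
            }
        )
        return Trajectory(coords=coords, atoms=atoms)

    def test_static_trajectory_zero(self):
        t = gen_trajectory(4, jitter_sd=0.0)
        assert (rmsf(t) < 1e-12).all()

    def test_isotropic_jitter_expectation(self):
        # per-atom RMSF of isotropic sd-σ noise is σ·√3
        t = self._lattice_trajectory(jitter=0.5)
        values = rmsf(t, align_selection=np.arange(20))
        assert values[("A", 21)] == pytest.approx(0.5 * np.sqrt(3), rel=0.10)
        assert values.drop(index=("A", 21)).max() < 0.05

    def test_frame_order_invariance(self):
        t = self._lattice_trajectory(n_frames=50)
        perm = np.random.default_rng(5).permutation(50)
        t_perm = Trajectory(coords=t.coords[perm], atoms=t.atoms)
        a = rmsf(t, reference=0)
        b = rmsf(t_perm, reference=int(np.argmin(perm)))
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-9)


class TestHbonds:
    @pytest.mark.parametrize(
        "distance,angle,expected",
        [(3.0, 180.0, 1), (4.5, 180.0, 0), (3.0, 90.0, 0), (4.0, 120.0, 1)],
    )
    def test_planted_geometry(self, distance, angle, expected):
        t = gen_trajectory(1, [("d", "a", distance, angle)], jitter_sd=0.0)
        donors, acceptors = _intermolecular_sets(t)
        assert hbond_count(t, 0, donors, acceptors) == expected

    def test_jittered_frames_match_enumeration_oracle(self):
        t = gen_trajectory(
            50,
            [("d1", "a1", 3.2, 170.0), ("d2", "a2", 3.9, 125.0), ("d3", "a3", 4.05, 150.0)],
            jitter_sd=0.05, seed=17,
        )
        donors, acceptors = _intermolecular_sets(t)
        for frame in range(t.n_frames):
            assert hbond_count(t, frame, donors, acceptors) == _hbond_oracle(
                t, frame, donors, acceptors
            )


class TestHydrophobicContacts:
    def test_isolated_ligand_zero(self):
        t = gen_trajectory(1, n_hydrophobic_far=3)
        assert hydrophobic_contacts(t, 0) == 0

    def test_residue_level_deduplication(self):
        # one LEU with two atoms inside 4 Å still counts once
        t = gen_trajectory(1, n_hydrophobic_near=1)
        assert hydrophobic_contacts(t, 0) == 1

    def test_matches_brute_force_oracle(self):
        t = gen_trajectory(10, n_hydrophobic_near=4, n_hydrophobic_far=3, jitter_sd=0.3, seed=3)
        for frame_index in range(t.n_frames):
            frame = t.coords[frame_index]
            lig = t.heavy(t.select(ligand=True))
            residues = set()
            for i in t.heavy(t.select(ligand=False)):
                if t.atoms.loc[i, "resname"] not in HYDROPHOBIC_RESIDUES:
                    continue
                for j in lig:
                    if np.linalg.norm(frame[i] - frame[j]) <= 4.0:
                        residues.add((t.atoms.loc[i, "chain"], t.atoms.loc[i, "resid"]))
                        break
            assert hydrophobic_contacts(t, frame_index) == len(residues)

    def test_atom_order_permutation_invariance(self):
        t = gen_trajectory(1, n_hydrophobic_near=2, n_hydrophobic_far=1)
        perm = np.random.default_rng(0).permutation(t.n_atoms)
        t_perm = Trajectory(
            coords=t.coords[:, perm, :], atoms=t.atoms.iloc[perm].reset_index(drop=True)
        )
        assert hydrophobic_contacts(t, 0) == hydrophobic_contacts(t_perm, 0)


class TestPdbRoundTrip:
    def test_write_read_preserves_geometry_and_metrics(self, tmp_path):
        t = gen_trajectory(5, [("d", "a", 3.0, 160.0)], jitter_sd=0.1,
                           n_hydrophobic_near=2, seed=9)
        path = tmp_path / "traj.pdb"
        write_pdb(t, path)
        back = read_pdb(path)
        assert back.n_frames == t.n_frames and back.n_atoms == t.n_atoms
        np.testing.assert_allclose(back.coords, t.coords, atol=1e-2)  # PDB precision
        a = contact_series(t)
        b = contact_series(back)
        pd.testing.assert_frame_equal(
            a[["n_hbonds", "n_hydrophobic"]], b[["n_hbonds", "n_hydrophobic"]]
        )
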