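"""Protein–ligand trajectory metrics.

Operates on multi-frame coordinate sets produced by molecular dynamics engines
(consumed as multi-model PDB; the simulations themselves are out of scope):
Kabsch-superposition RMSD, per-residue RMSF, hydrogen-bond counts under a
4.0 Å donor–acceptor / 120° D–H···A rule, and hydrophobic residue contacts
within 4.0 Å of the ligand.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ParameterError

#: residues counted as hydrophobic for contact analysis
HYDROPHOBIC_RESIDUES = frozenset(
    {"GLY", "ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "TRP"}
)

#: default geometric cut-offs
HBOND_DISTANCE_CUTOFF = 4.0  # Å, donor heavy atom to acceptor heavy atom
HBOND_ANGLE_CUTOFF = 120.0  # degrees, D-H...A angle at the hydrogen
CONTACT_CUTOFF = 4.0  # Å, heavy-atom distance for hydrophobic contacts

#: maximum distance at which a hydrogen is considered covalently bonded to a
#: heavy atom when no explicit bond table is available (PDB input)
_H_COVALENT_CUTOFF = 1.25  # Å


@dataclass
class Trajectory:
    """An in-memory trajectory: (n_frames, n_atoms, 3) coordinates in Å plus
    per-atom metadata (name, element, resname, resid, chain, is_ligand)."""

    coords: np.ndarray
    atoms: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ParameterError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise ParameterError("atom metadata does not match coordinate atom count")
        if not np.isfinite(self.coords).all():
            raise ParameterError("coordinates must be finite")
        required = {"name", "element", "resname", "resid", "chain", "is_ligand"}
        missing = required - set(self.atoms.columns)
        if missing:
            raise ParameterError(f"atom table missing columns: {sorted(missing)}")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def select(self, *, ligand: bool | None = None, elements=None, names=None) -> np.ndarray:
        """Return atom indices matching the given filters."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if ligand is not None:
            mask &= self.atoms["is_ligand"].to_numpy() == ligand
        if elements is not None:
            mask &= self.atoms["element"].isin(list(elements)).to_numpy()
        if names is not None:
            mask &= self.atoms["name"].isin(list(names)).to_numpy()
        return np.nonzero(mask)[0]

    def heavy(self, indices: np.ndarray | None = None) -> np.ndarray:
        """Heavy-atom (non-hydrogen) subset of ``indices`` (default: all)."""
        not_h = (self.atoms["element"] != "H").to_numpy()
        if indices is None:
            return np.nonzero(not_h)[0]
        indices = np.asarray(indices)
        return indices[not_h[indices]]


def write_pdb(traj: Trajectory, path) -> None:
    """Write a trajectory as a multi-model PDB via MDAnalysis."""
    import MDAnalysis as mda

    n_atoms = traj.n_atoms
    resids_raw = traj.atoms["resid"].to_numpy()
    # map (chain, resid) pairs to contiguous residue indices
    keys = list(zip(traj.atoms["chain"], resids_raw))
    uniq = list(dict.fromkeys(keys))
    residx = np.array([uniq.index(k) for k in keys])
    u = mda.Universe.empty(
        n_atoms, n_residues=len(uniq), atom_resindex=residx, trajectory=True
    )
    u.add_TopologyAttr("names", traj.atoms["name"].to_list())
    u.add_TopologyAttr("elements", traj.atoms["element"].to_list())
    u.add_TopologyAttr("resnames", [traj.atoms["resname"].iloc[keys.index(k)] for k in uniq])
    u.add_TopologyAttr("resids", [k[1] for k in uniq])
    u.add_TopologyAttr("chainIDs", traj.atoms["chain"].to_list())  # per atom
    u.add_TopologyAttr("segids", ["SYS"])
    with mda.Writer(str(path), n_atoms, multiframe=True) as w:
        for frame in traj.coords:
            u.atoms.positions = frame
            w.write(u.atoms)


def read_pdb(path, ligand_resnames=("LIG",)) -> Trajectory:
    """Read a multi-model PDB into a :class:`Trajectory` via MDAnalysis.

    Atoms whose residue name is in ``ligand_resnames`` are flagged as ligand.
    """
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        atoms = pd.DataFrame(
            {
                "name": u.atoms.names,
                "element": [e if e else g[0] for e, g in zip(
                    getattr(u.atoms, "elements", [""] * len(u.atoms)), u.atoms.names)],
                "resname": u.atoms.resnames,
                "resid": u.atoms.resids,
                "chain": getattr(u.atoms, "chainIDs", np.array(["A"] * len(u.atoms))),
                "is_ligand": [r in set(ligand_resnames) for r in u.atoms.resnames],
            }
        )
        coords = np.array([u.atoms.positions.copy() for _ in u.trajectory], dtype=float)
    return Trajectory(coords=coords, atoms=atoms)


# ---------------------------------------------------------------------------
# superposition and deviation metrics
# ---------------------------------------------------------------------------

def kabsch_rotation(ref: np.ndarray, mobile: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal rotation matrix (Kabsch, via SVD) superposing ``mobile`` onto
    ``ref`` after centering. Returns (R, ref_centroid, mobile_centroid)."""
    ref = np.asarray(ref, dtype=float)
    mobile = np.asarray(mobile, dtype=float)
    cr = ref.mean(axis=0)
    cm = mobile.mean(axis=0)
    H = (mobile - cm).T @ (ref - cr)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, cr, cm


def kabsch_rmsd(ref: np.ndarray, mobile: np.ndarray, selection=None) -> tuple[float, np.ndarray]:
    """Least-squares superposition RMSD between two frames.

    ``selection`` (atom indices) restricts both the superposition and the
    deviation measurement. Returns (rmsd in Å, the fully superposed mobile
    frame)."""
    ref = np.asarray(ref, dtype=float)
    mobile = np.asarray(mobile, dtype=float)
    if ref.shape != mobile.shape:
        raise ParameterError("reference and mobile frames have mismatched shapes")
    sel = np.arange(len(ref)) if selection is None else np.asarray(selection)
    if len(sel) < 3:
        raise ParameterError("superposition needs at least 3 atoms")
    R, cr, cm = kabsch_rotation(ref[sel], mobile[sel])
    superposed = (mobile - cm) @ R.T + cr
    diff = superposed[sel] - ref[sel]
    rmsd = float(np.sqrt((diff**2).sum(axis=1).mean()))
    return rmsd, superposed


def rmsd_series(traj: Trajectory, selection=None, reference: int = 0) -> np.ndarray:
    """Per-frame RMSD against a reference frame (default: the first frame),
    each frame optimally superposed before measuring."""
    if traj.n_frames < 1:
        raise ParameterError("trajectory has no frames")
    sel = np.arange(traj.n_atoms) if selection is None else np.asarray(selection)
    if len(sel) == 0:
        raise ParameterError("empty selection")
    ref = traj.coords[reference]
    return np.array([kabsch_rmsd(ref, frame, sel)[0] for frame in traj.coords])


def rmsf(
    traj: Trajectory,
    selection=None,
    align_selection=None,
    reference: int = 0,
) -> pd.Series:
    """Per-residue RMSF: atomic fluctuation about the time-mean position after
    superposing every frame onto the reference frame, averaged over each
    residue's atoms. Indexed by (chain, resid)."""
    sel = np.arange(traj.n_atoms) if selection is None else np.asarray(selection)
    align = sel if align_selection is None else np.asarray(align_selection)
    if traj.n_frames < 2:
        warnings.warn("RMSF of a single-frame trajectory is identically zero")
        zeros = np.zeros(len(sel))
        return _aggregate_by_residue(traj, sel, zeros)
    ref = traj.coords[reference]
    aligned = np.empty((traj.n_frames, len(sel), 3))
    for i, frame in enumerate(traj.coords):
        _, superposed = kabsch_rmsd(ref, frame, align)
        aligned[i] = superposed[sel]
    mean_pos = aligned.mean(axis=0)
    fluct = np.sqrt(((aligned - mean_pos) ** 2).sum(axis=2).mean(axis=0))
    return _aggregate_by_residue(traj, sel, fluct)


def _aggregate_by_residue(traj: Trajectory, sel: np.ndarray, per_atom: np.ndarray) -> pd.Series:
    df = pd.DataFrame(
        {
            "chain": traj.atoms["chain"].to_numpy()[sel],
            "resid": traj.atoms["resid"].to_numpy()[sel],
            "value": per_atom,
        }
    )
    out = df.groupby(["chain", "resid"], sort=True)["value"].mean()
    out.name = "rmsf"
    return out


# ---------------------------------------------------------------------------
# contact metrics
# ---------------------------------------------------------------------------

def _attached_hydrogens(traj: Trajectory, frame: np.ndarray, heavy_idx: int) -> np.ndarray:
    """Hydrogens within covalent range of a heavy atom (distance-inferred;
    PDB input carries no bond table)."""
    h_idx = traj.select(elements=["H"])
    if len(h_idx) == 0:
        return h_idx
    d = np.linalg.norm(frame[h_idx] - frame[heavy_idx], axis=1)
    return h_idx[d <= _H_COVALENT_CUTOFF]


def find_donors_acceptors(traj: Trajectory, frame_index: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Identify hydrogen-bond donors (N/O with an attached H) and acceptors
    (any N/O) from atom metadata and the given frame's geometry."""
    frame = traj.coords[frame_index]
    polar = traj.select(elements=["N", "O"])
    donors = np.array(
        [i for i in polar if len(_attached_hydrogens(traj, frame, i)) > 0], dtype=int
    )
    return donors, polar


def hbond_count(
    traj: Trajectory,
    frame_index: int,
    donors: np.ndarray,
    acceptors: np.ndarray,
    d_max: float = HBOND_DISTANCE_CUTOFF,
    angle_min: float = HBOND_ANGLE_CUTOFF,
) -> int:
    """Count donor–acceptor pairs hydrogen-bonded in one frame.

    A pair counts when the donor-heavy-atom → acceptor distance is ≤ ``d_max``
    and some hydrogen attached to the donor makes a D–H···A angle ≥
    ``angle_min``. Structures with no hydrogens fall back to the distance-only
    criterion (callers can detect this via :func:`has_hydrogens`)."""
    frame = traj.coords[frame_index]
    donors = np.asarray(donors, dtype=int)
    acceptors = np.asarray(acceptors, dtype=int)
    if len(donors) == 0 or len(acceptors) == 0:
        return 0
    distance_only = not has_hydrogens(traj)
    count = 0
    for d_idx in donors:
        hs = None if distance_only else _attached_hydrogens(traj, frame, d_idx)
        for a_idx in acceptors:
            if a_idx == d_idx:
                continue
            dist = np.linalg.norm(frame[a_idx] - frame[d_idx])
            if dist > d_max:
                continue
            if distance_only:
                count += 1
                continue
            for h_idx in hs:
                v1 = frame[d_idx] - frame[h_idx]
                v2 = frame[a_idx] - frame[h_idx]
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                if angle >= angle_min:
                    count += 1
                    break
    return count


def has_hydrogens(traj: Trajectory) -> bool:
    return bool((traj.atoms["element"] == "H").any())


def hydrophobic_contacts(
    traj: Trajectory,
    frame_index: int,
    d_max: float = CONTACT_CUTOFF,
    residue_set=HYDROPHOBIC_RESIDUES,
) -> int:
    """Number of DISTINCT hydrophobic residues with at least one heavy atom
    within ``d_max`` of any ligand heavy atom in the given frame."""
    frame = traj.coords[frame_index]
    lig = traj.heavy(traj.select(ligand=True))
    if len(lig) == 0:
        raise ParameterError("no ligand atoms flagged in the trajectory")
    rec = traj.heavy(traj.select(ligand=False))
    resnames = traj.atoms["resname"].to_numpy()
    rec = rec[np.isin(resnames[rec], list(residue_set))]
    if len(rec) == 0:
        return 0
    d = np.linalg.norm(frame[rec][:, None, :] - frame[lig][None, :, :], axis=2)
    close = rec[(d <= d_max).any(axis=1)]
    keys = set(
        zip(traj.atoms["chain"].to_numpy()[close], traj.atoms["resid"].to_numpy()[close])
    )
    return len(keys)


def contact_series(
    traj: Trajectory,
    d_max: float = HBOND_DISTANCE_CUTOFF,
    angle_min: float = HBOND_ANGLE_CUTOFF,
) -> pd.DataFrame:
    """Per-frame ligand RMSD, intermolecular H-bond count and hydrophobic
    residue contact count — the standard per-trajectory summary."""
    lig_heavy = traj.heavy(traj.select(ligand=True))
    rms = rmsd_series(traj, lig_heavy) if len(lig_heavy) >= 3 else np.zeros(traj.n_frames)
    donors, acceptors = find_donors_acceptors(traj)
    is_lig = traj.atoms["is_ligand"].to_numpy()
    d_lig, d_rec = donors[is_lig[donors]], donors[~is_lig[donors]]
    a_lig, a_rec = acceptors[is_lig[acceptors]], acceptors[~is_lig[acceptors]]
    rows = []
    for i in range(traj.n_frames):
        nhb = hbond_count(traj, i, d_lig, a_rec, d_max, angle_min) + hbond_count(
            traj, i, d_rec, a_lig, d_max, angle_min
        )
        nphob = hydrophobic_contacts(traj, i, d_max)
        rows.append((rms[i], nhb, nphob))
    return pd.DataFrame(rows, columns=["rmsd", "n_hbonds", "n_hydrophobic"])
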