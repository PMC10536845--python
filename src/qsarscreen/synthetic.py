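"""Synthetic input generators for every pipeline stage.

Each generator emulates the statistical structure its downstream consumer
assumes — a bioactivity library with a latent linear substructure→activity
map plus planted curation defects, 4PL dose-response plates with a known
IC50, qPCR Ct tables with known fold changes, and toy receptor–ligand
trajectories with planted hydrogen-bond geometries — and attaches its latent
ground truth in metadata so closed-loop recovery can be tested without any
external data.

The SMILES grammar is a fixed enumerable lattice: 10 two-attachment-point
aromatic scaffolds × 20 C7-alkyl substituents × 20 C8-alkyl substituents
(4000 distinct molecules). The scaffolds split into two groups of five
positional isomers (toluene-core vs methylnaphthalene-core), so molecular
weight and Crippen LogP are exactly two-point distributions over the base
library; the alkyl substituent sets were chosen to share one molecular
formula and one Crippen atom-type profile each, contributing zero spread.
This makes the ±1.5 SD property trim exactly separable: planted property
outliers are always beyond the cut while base compounds never are.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ParameterError, SchemaError
from .trajectory import Trajectory

# --- fragment grammar ------------------------------------------------------
# Scaffolds carry two attachment dummies [*:1]/[*:2]; assembly uses RDKit molzip.
# First five: toluene-core positional isomers (C7H6 in-compound).
# Last five: methylnaphthalene-core positional isomers (C11H8 in-compound).
SCAFFOLDS = (
    "Cc1cc([*:1])cc([*:2])c1",
    "Cc1ccc([*:1])c([*:2])c1",
    "Cc1ccc([*:2])c([*:1])c1",
    "Cc1c([*:1])cccc1[*:2]",
    "Cc1cc([*:1])ccc1[*:2]",
    "Cc1ccc2cc([*:1])c([*:2])cc2c1",
    "Cc1ccc2c([*:1])cc([*:2])cc2c1",
    "Cc1cc([*:1])c2ccc([*:2])cc2c1",
    "Cc1cc([*:1])c2cc([*:2])ccc2c1",
    "Cc1c([*:1])cc2ccc([*:2])cc2c1",
)

# 20 rooted C7H15 alkyl substituents; all share formula and Crippen atom-type
# counts, so they contribute no MW or LogP spread.
SUBSTITUENTS_A = (
    "C(C(C(C(C(C)(C)))))", "C(C(C(C(C)(C(C)))))", "C(C(C(C(C)(C)(C))))",
    "C(C(C(C(C))(C(C))))", "C(C(C(C)(C(C(C)))))", "C(C(C(C)(C)(C(C))))",
    "C(C(C(C))(C(C(C))))", "C(C(C)(C(C(C(C)))))", "C(C(C)(C(C))(C(C)))",
    "C(C(C)(C)(C(C(C))))", "C(C(C)(C))(C(C(C)))", "C(C(C))(C(C(C)(C)))",
    "C(C(C))(C(C)(C(C)))", "C(C(C))(C(C)(C)(C))", "C(C)(C(C(C(C)(C))))",
    "C(C)(C(C(C)(C(C))))", "C(C)(C(C(C)(C)(C)))", "C(C)(C(C(C))(C(C)))",
    "C(C)(C(C)(C(C(C))))", "C(C)(C(C)(C)(C(C)))",
)

# 20 rooted C8H17 alkyl substituents, same-formula / same-type-profile set.
SUBSTITUENTS_B = (
    "C(C(C(C(C)(C(C)(C)))))", "C(C(C(C(C))(C(C)(C))))", "C(C(C(C)(C(C(C)(C)))))",
    "C(C(C(C)(C(C)(C(C)))))", "C(C(C(C)(C(C)(C)(C))))", "C(C(C(C)(C)(C(C)(C))))",
    "C(C(C(C)(C))(C(C(C))))", "C(C(C(C))(C(C(C)(C))))", "C(C(C(C))(C(C)(C(C))))",
    "C(C(C(C))(C(C)(C)(C)))", "C(C(C)(C(C(C(C)(C)))))", "C(C(C)(C(C(C)(C(C)))))",
    "C(C(C)(C(C(C)(C)(C))))", "C(C(C)(C(C(C))(C(C))))", "C(C(C)(C(C)(C(C(C)))))",
    "C(C(C)(C(C)(C)(C(C))))", "C(C(C)(C(C))(C(C)(C)))", "C(C(C)(C)(C(C(C)(C))))",
    "C(C(C)(C)(C(C)(C(C))))", "C(C(C)(C)(C(C)(C)(C)))",
)

MAX_DISTINCT = len(SCAFFOLDS) * len(SUBSTITUENTS_A) * len(SUBSTITUENTS_B)

#: counter-ion fragments cycled through when planting salts
SALT_FRAGMENTS = ("[Na+]", "[Cl-]", "[K+]", "[Br-]")

_JOURNALS = (
    "J Synth Chem", "Bioact Lett", "Med Chem Rep", "Chem Biol Arch", "Drug Res Notes",
)


def _assemble(scaffold: str, sub_a: str, sub_b: str) -> str:
    from rdkit import Chem

    frag = Chem.MolFromSmiles(f"{scaffold}.[*:1]{sub_a}.[*:2]{sub_b}")
    return Chem.MolToSmiles(Chem.molzip(frag))


@dataclass(frozen=True)
class SyntheticLibrarySpec:
    """Parameters of the synthetic bioactivity library.

    ``noise_sd`` is in pIC50 units; the three fractions are of ``n_compounds``
    and must sum to at most 1 (planting targets are disjoint base rows).
    ``pic50_range`` bounds the latent base activities.
    """

    n_compounds: int
    seed: int = 42
    noise_sd: float = 0.3
    dup_fraction: float = 0.0
    salt_fraction: float = 0.0
    outlier_fraction: float = 0.0
    pic50_range: tuple[float, float] = (4.99, 9.93)

    def __post_init__(self):
        for name in ("dup_fraction", "salt_fraction", "outlier_fraction"):
            f = getattr(self, name)
            if not 0.0 <= f <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {f}")
        if self.dup_fraction + self.salt_fraction + self.outlier_fraction > 1.0 + 1e-12:
            raise ParameterError("dup/salt/outlier fractions must sum to at most 1")
        if self.n_compounds < 0:
            raise ParameterError("n_compounds must be non-negative")
        if self.n_compounds > MAX_DISTINCT:
            raise ParameterError(
                f"the fragment grammar yields at most {MAX_DISTINCT} distinct structures"
            )
        low, high = self.pic50_range
        if not low < high:
            raise ParameterError("pic50_range must satisfy low < high")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")


def _activity_coefficients(spec: SyntheticLibrarySpec) -> dict:
    """Latent linear substructure→pIC50 map.

    The scaffold-group term dominates (bimodal ±0.73·half-range) with small
    within-group and substituent terms, keeping the base activity distribution
    platykurtic enough that no base compound ever exceeds 1.5 SD from the mean."""
    low, high = spec.pic50_range
    center, half = (low + high) / 2.0, (high - low) / 2.0
    within = np.linspace(-0.08, 0.08, 5) * half
    coef_scaffold = np.concatenate([-0.73 * half + within, 0.73 * half + within])
    coef_a = np.linspace(-0.06, 0.06, len(SUBSTITUENTS_A)) * half
    coef_b = np.linspace(-0.06, 0.06, len(SUBSTITUENTS_B)) * half
    return {
        "intercept": center,
        "scaffold": coef_scaffold,
        "sub_a": coef_a,
        "sub_b": coef_b,
        "outlier_offset": 2.2 * half,
    }


def _lattice_index(i: int) -> tuple[int, int, int]:
    # mixed-radix enumeration covering all 4000 cells before any repeat
    return i % 10, (i // 10) % 20, (i // 200) % 20


def gen_bioactivity_library(spec: SyntheticLibrarySpec) -> pd.DataFrame:
    """Generate a raw bioactivity table with planted curation defects.

    Columns: compound_id, smiles, ic50_nM, year, journal, plus ground-truth
    columns (gt_pic50, gt_duplicate, gt_dup_of, gt_salt, gt_outlier).
    Planted duplicates are appended copies with a later year; planted salts
    carry a disconnected counter-ion fragment; planted outliers replace one
    substituent with an extreme fragment (MW, LogP) or carry an extreme
    activity (pIC50). The latent truth is stored in ``df.attrs['truth']``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_compounds
    coef = _activity_coefficients(spec)

    rows = []
    for i in range(n):
        j, a, b = _lattice_index(i)
        pic50 = (
            coef["intercept"]
            + coef["scaffold"][j]
            + coef["sub_a"][a]
            + coef["sub_b"][b]
        )
        rows.append(
            {
                "compound_id": f"SYN-{i:05d}",
                "scaffold_idx": j,
                "sub_a_idx": a,
                "sub_b_idx": b,
                "gt_pic50": pic50,
                "year": int(rng.integers(2005, 2021)),
                "journal": _JOURNALS[i % len(_JOURNALS)],
                "gt_duplicate": False,
                "gt_dup_of": "",
                "gt_salt": False,
                "gt_outlier": "",
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "compound_id", "scaffold_idx", "sub_a_idx", "sub_b_idx", "gt_pic50",
            "year", "journal", "gt_duplicate", "gt_dup_of", "gt_salt", "gt_outlier",
        ],
    )

    # choose disjoint planting targets among base rows
    n_dup = round(spec.dup_fraction * n)
    n_salt = round(spec.salt_fraction * n)
    n_out = round(spec.outlier_fraction * n)
    perm = rng.permutation(n)
    dup_targets = perm[:n_dup]
    salt_targets = perm[n_dup : n_dup + n_salt]
    out_targets = perm[n_dup + n_salt : n_dup + n_salt + n_out]

    # plant outliers: cycle pIC50 / MW / LogP kinds
    outlier_kinds = ["pic50_high", "pic50_low", "mw", "logp"]
    for r, idx in enumerate(out_targets):
        kind = outlier_kinds[r % len(outlier_kinds)]
        df.loc[idx, "gt_outlier"] = kind
        if kind == "pic50_high":
            df.loc[idx, "gt_pic50"] = coef["intercept"] + coef["outlier_offset"]
        elif kind == "pic50_low":
            df.loc[idx, "gt_pic50"] = coef["intercept"] - coef["outlier_offset"]

    # assemble SMILES (outlier kinds mw/logp swap the C8 substituent for an
    # extreme fragment: a long plain chain or a polyol of comparable mass)
    smiles = []
    for i in range(len(df)):
        j, a, b = df.loc[i, ["scaffold_idx", "sub_a_idx", "sub_b_idx"]]
        kind = df.loc[i, "gt_outlier"]
        if kind == "mw":
            sub_b = "C" * (18 + int(i) % 5)
        elif kind == "logp":
            sub_b = "C(C(O)C(O)C(O)CO)"
        else:
            sub_b = SUBSTITUENTS_B[b]
        smiles.append(_assemble(SCAFFOLDS[j], SUBSTITUENTS_A[a], sub_b))
    df["smiles"] = smiles

    # plant salts: append a disconnected counter-ion fragment
    for r, idx in enumerate(salt_targets):
        df.loc[idx, "gt_salt"] = True
        df.loc[idx, "smiles"] = (
            df.loc[idx, "smiles"] + "." + SALT_FRAGMENTS[r % len(SALT_FRAGMENTS)]
        )

    # add observation noise, then planted duplicate copies (later year)
    df["gt_pic50_observed"] = df["gt_pic50"] + rng.normal(0.0, spec.noise_sd, len(df))
    dup_rows = []
    for r, idx in enumerate(dup_targets):
        copy = df.loc[idx].copy()
        copy["compound_id"] = f"SYN-D{r:04d}"
        copy["year"] = int(copy["year"]) + 1 + int(rng.integers(0, 3))
        copy["gt_duplicate"] = True
        copy["gt_dup_of"] = df.loc[idx, "compound_id"]
        dup_rows.append(copy)
    if dup_rows:
        df = pd.concat([df, pd.DataFrame(dup_rows)], ignore_index=True)

    df["ic50_nM"] = 10.0 ** (9.0 - df["gt_pic50_observed"])
    df = df.drop(columns=["scaffold_idx", "sub_a_idx", "sub_b_idx", "gt_pic50_observed"])
    df = df[
        ["compound_id", "smiles", "ic50_nM", "year", "journal",
         "gt_pic50", "gt_duplicate", "gt_dup_of", "gt_salt", "gt_outlier"]
    ]
    df.attrs["truth"] = {
        "coefficients": {
            "intercept": coef["intercept"],
            "scaffold": coef["scaffold"].tolist(),
            "sub_a": coef["sub_a"].tolist(),
            "sub_b": coef["sub_b"].tolist(),
        },
        "spec": {
            "n_compounds": spec.n_compounds,
            "seed": spec.seed,
            "noise_sd": spec.noise_sd,
            "dup_fraction": spec.dup_fraction,
            "salt_fraction": spec.salt_fraction,
            "outlier_fraction": spec.outlier_fraction,
            "pic50_range": list(spec.pic50_range),
        },
    }
    return df


# ---------------------------------------------------------------------------
# dose-response plates
# ---------------------------------------------------------------------------

def default_dilution_series(start: float = 780.0, n_points: int = 11) -> np.ndarray:
    """1/2 serial dilution concentrations in μg/mL, highest first."""
    return start / (2.0 ** np.arange(n_points))


def four_pl(conc, ic50, hill=1.0, top=100.0, bottom=0.0):
    """Four-parameter logistic response (viability %, decreasing for hill>0)."""
    conc = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (
        1.0 + 10.0 ** (hill * (np.log10(conc) - math.log10(ic50)))
    )


def gen_dose_response(
    ic50: float,
    hill: float = 1.0,
    top: float = 100.0,
    bottom: float = 0.0,
    concs=None,
    noise_sd: float = 2.0,
    n_reps: int = 6,
    seed: int = 42,
) -> pd.DataFrame:
    """Simulate a two-wavelength plate read of a 4PL dose-response.

    Returns a plate table (well, conc, abs590, abs690, role) in which vehicle
    wells define 100% viability; ``noise_sd`` is in viability-% units. The
    generating parameters are stored in ``df.attrs['truth']``."""
    if concs is None:
        concs = default_dilution_series()
    concs = np.asarray(concs, dtype=float)
    if (concs <= 0).any():
        raise ParameterError("concentrations must be strictly positive")
    if n_reps < 1:
        raise ParameterError("n_reps must be at least 1")
    if ic50 <= 0:
        raise ParameterError("ic50 must be positive")
    rng = np.random.default_rng(seed)
    background = 0.05
    vehicle_signal = 1.0  # blank-corrected absorbance of untreated wells
    rows = []
    well = 0
    for _ in range(n_reps):
        rows.append((f"W{well:03d}", 0.0, background + vehicle_signal, background, "vehicle"))
        well += 1
    for c in concs:
        v = four_pl(c, ic50, hill, top, bottom)
        for _ in range(n_reps):
            noisy = v + rng.normal(0.0, noise_sd)
            rows.append(
                (f"W{well:03d}", c, background + vehicle_signal * noisy / 100.0, background, "treated")
            )
            well += 1
    df = pd.DataFrame(rows, columns=["well", "conc", "abs590", "abs690", "role"])
    df.attrs["truth"] = {
        "ic50": ic50, "hill": hill, "top": top, "bottom": bottom,
        "noise_sd": noise_sd, "n_reps": n_reps, "seed": seed,
    }
    return df


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

def gen_qpcr(
    fold_changes: dict[str, float],
    baseline_ct: float | dict[str, float] = 24.0,
    endo_genes: tuple[str, ...] = ("ACTB", "GAPDH"),
    endo_ct: tuple[float, ...] = (18.0, 19.0),
    n_reps: int = 3,
    ct_sd: float = 0.1,
    seed: int = 42,
) -> pd.DataFrame:
    """Simulate a Ct table (gene, group, replicate, ct) for treated vs control.

    Treated-group target Ct = baseline − log2(fold_change) + noise; endogenous
    control genes have identical expectation in both groups, so the downstream
    2^−ΔΔCt estimate converges to ``fold_changes`` as ``ct_sd`` → 0."""
    if n_reps < 2:
        raise ParameterError("n_reps must be at least 2")
    for g, f in fold_changes.items():
        if f <= 0:
            raise ParameterError(f"fold change for {g} must be positive, got {f}")
    if len(endo_genes) != len(endo_ct):
        raise SchemaError("endo_genes and endo_ct lengths differ")
    rng = np.random.default_rng(seed)
    rows = []
    for gene, fold in fold_changes.items():
        base = baseline_ct[gene] if isinstance(baseline_ct, dict) else baseline_ct
        for group, shift in (("control", 0.0), ("treated", -math.log2(fold))):
            for rep in range(1, n_reps + 1):
                rows.append((gene, group, rep, base + shift + rng.normal(0.0, ct_sd)))
    for gene, base in zip(endo_genes, endo_ct):
        for group in ("control", "treated"):
            for rep in range(1, n_reps + 1):
                rows.append((gene, group, rep, base + rng.normal(0.0, ct_sd)))
    df = pd.DataFrame(rows, columns=["gene", "group", "replicate", "ct"])
    df.attrs["truth"] = {
        "fold_changes": dict(fold_changes),
        "endo_genes": list(endo_genes),
        "ct_sd": ct_sd,
        "n_reps": n_reps,
        "seed": seed,
    }
    return df


# ---------------------------------------------------------------------------
# toy trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedHBond:
    """A donor–acceptor pair planted at an exact distance/angle geometry."""

    donor: str
    acceptor: str
    distance: float  # Å, donor heavy atom to acceptor heavy atom
    angle: float  # degrees, D-H...A angle at the hydrogen

    def __post_init__(self):
        if self.distance <= 0:
            raise ParameterError("planted H-bond distance must be positive")
        if not 0.0 < self.angle <= 180.0:
            raise ParameterError("planted H-bond angle must lie in (0, 180]")


def _hydrogen_position(d: float, angle_deg: float) -> np.ndarray:
    """Place H (|DH| = 1 Å) so the D–H···A angle equals ``angle_deg``, with
    D at the origin and A at (d, 0, 0); solved via the law of cosines."""
    c = math.cos(math.radians(angle_deg))
    disc = c * c - 1.0 + d * d
    if disc < 0:
        raise ParameterError(
            f"no hydrogen placement exists for distance {d} Å and angle {angle_deg}°"
        )
    t = c + math.sqrt(disc)  # |HA|
    x = (1.0 + d * d - t * t) / (2.0 * d)
    y = math.sqrt(max(0.0, 1.0 - x * x))
    return np.array([x, y, 0.0])


def gen_trajectory(
    n_frames: int,
    planted_hbonds=(),
    jitter_sd: float = 0.0,
    seed: int = 42,
    ligand_drift: float = 0.0,
    n_hydrophobic_near: int = 0,
    n_hydrophobic_far: int = 0,
) -> Trajectory:
    """Build a toy receptor–ligand trajectory with planted contact geometry.

    Each planted H-bond places a ligand N donor (with one H) and a receptor
    O acceptor at the requested distance/angle, isolated >6 Å from all other
    polar pairs. ``n_hydrophobic_near`` leucine residues sit within contact
    range of the ligand, ``n_hydrophobic_far`` far outside it. Gaussian jitter
    of ``jitter_sd`` Å is added per frame per coordinate; ``ligand_drift``
    translates the ligand by that many Å per frame along +x. The planted
    configuration is stored in ``traj.metadata['truth']``."""
    if n_frames < 1:
        raise ParameterError("n_frames must be at least 1")
    if jitter_sd < 0:
        raise ParameterError("jitter_sd must be non-negative")
    planted = [
        hb if isinstance(hb, PlantedHBond) else PlantedHBond(*hb) for hb in planted_hbonds
    ]
    rng = np.random.default_rng(seed)

    names, elements, resnames, resids, chains, is_ligand = [], [], [], [], [], []
    base = []

    def add_atom(name, element, resname, resid, chain, ligand, xyz):
        names.append(name)
        elements.append(element)
        resnames.append(resname)
        resids.append(resid)
        chains.append(chain)
        is_ligand.append(ligand)
        base.append(np.asarray(xyz, dtype=float))

    # receptor backbone: a rigid frame of glycine CA atoms well away from the
    # contact region, giving superposition something stable to hold on to
    resid = 1
    for k in range(8):
        add_atom("CA", "C", "GLY", resid, "A", False, (4.0 * k, -30.0, 0.0))
        resid += 1

    # planted donor/acceptor pairs, each isolated on its own x-offset
    for p, hb in enumerate(planted):
        origin = np.array([12.0 * p, 0.0, 0.0])
        add_atom(f"N{p}", "N", "LIG", 900, "L", True, origin)
        add_atom(f"H{p}", "H", "LIG", 900, "L", True, origin + _hydrogen_position(hb.distance, hb.angle))
        add_atom(f"O{p}", "O", "SER", resid, "A", False, origin + np.array([hb.distance, 0.0, 0.0]))
        resid += 1

    # ligand carbon core (guarantees ≥3 ligand heavy atoms for RMSD work)
    lig_origin = np.array([0.0, 8.0, 0.0])
    for k, off in enumerate([(0, 0, 0), (1.5, 0, 0), (0, 1.5, 0), (0, 0, 1.5)]):
        add_atom(f"C{k}", "C", "LIG", 900, "L", True, lig_origin + np.asarray(off, float))

    # hydrophobic residues: two heavy atoms each, near or far from the ligand
    for k in range(n_hydrophobic_near):
        pos = lig_origin + np.array([0.0, 3.0, 1.2 * k])
        add_atom("CB", "C", "LEU", resid, "A", False, pos)
        add_atom("CG", "C", "LEU", resid, "A", False, pos + np.array([0.0, 1.0, 0.0]))
        resid += 1
    for k in range(n_hydrophobic_far):
        pos = lig_origin + np.array([60.0 + 5.0 * k, 40.0, 0.0])
        add_atom("CB", "C", "LEU", resid, "A", False, pos)
        add_atom("CG", "C", "LEU", resid, "A", False, pos + np.array([0.0, 1.0, 0.0]))
        resid += 1

    base = np.stack(base)
    lig_mask = np.asarray(is_ligand)
    coords = np.empty((n_frames, len(base), 3))
    for f in range(n_frames):
        frame = base.copy()
        if ligand_drift:
            frame[lig_mask, 0] += ligand_drift * f
        if jitter_sd:
            frame += rng.normal(0.0, jitter_sd, frame.shape)
        coords[f] = frame

    atoms = pd.DataFrame(
        {
            "name": names,
            "element": elements,
            "resname": resnames,
            "resid": resids,
            "chain": chains,
            "is_ligand": is_ligand,
        }
    )
    return Trajectory(
        coords=coords,
        atoms=atoms,
        metadata={
            "truth": {
                "planted_hbonds": [
                    {"donor": hb.donor, "acceptor": hb.acceptor,
                     "distance": hb.distance, "angle": hb.angle}
                    for hb in planted
                ],
                "jitter_sd": jitter_sd,
                "ligand_drift": ligand_drift,
                "n_hydrophobic_near": n_hydrophobic_near,
                "n_hydrophobic_far": n_hydrophobic_far,
                "seed": seed,
            }
        },
    )
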