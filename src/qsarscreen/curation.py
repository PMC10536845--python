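"""Bioactivity dataset curation.

Turns a raw IC50 table into the modelling dataset through a fixed pipeline:
structure-level deduplication (latest publication year wins), counter-ion
("salt") stripping, the pIC50 transform, and a single-pass ±1.5 SD property
trim on molecular weight, Crippen LogP and pIC50.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataError, DomainError, SchemaError

#: bare single-atom counter-ions recognised by the desalting rule
COUNTER_ION_ELEMENTS = frozenset(
    {"Na", "K", "Li", "Cs", "Mg", "Ca", "Zn", "Fe", "Cu", "Mn", "Al",
     "F", "Cl", "Br", "I"}
)


def _rdkit():
    from rdkit import Chem
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.*")
    return Chem


@dataclass
class CurationReport:
    """Per-step accounting of the curation pipeline; counts are monotone
    non-increasing and removed-id lists reconcile with the count deltas."""

    n_input: int = 0
    n_after_dedup: int = 0
    n_after_desalt: int = 0
    n_after_trim: int = 0
    removed_ids: dict[str, list[str]] = field(default_factory=dict)
    modified_ids: dict[str, list[str]] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_input": self.n_input,
                "n_after_dedup": self.n_after_dedup,
                "n_after_desalt": self.n_after_desalt,
                "n_after_trim": self.n_after_trim,
                "removed_ids": self.removed_ids,
                "modified_ids": self.modified_ids,
                "notes": self.notes,
            },
            indent=2,
        )


def to_pic50(ic50_molar) -> float | np.ndarray:
    """pIC50 = −log10(IC50 in molar units)."""
    arr = np.asarray(ic50_molar, dtype=float)
    if (arr <= 0).any():
        raise DomainError("IC50 must be strictly positive to take −log10")
    out = -np.log10(arr)
    return float(out) if np.isscalar(ic50_molar) or out.ndim == 0 else out


def from_pic50(pic50) -> float | np.ndarray:
    """Inverse transform: molar IC50 = 10^(−pIC50)."""
    arr = np.asarray(pic50, dtype=float)
    out = 10.0 ** (-arr)
    return float(out) if np.isscalar(pic50) or out.ndim == 0 else out


def canonical_smiles(smiles: str) -> str | None:
    """RDKit canonical SMILES, or None when unparseable."""
    Chem = _rdkit()
    mol = Chem.MolFromSmiles(smiles)
    return None if mol is None else Chem.MolToSmiles(mol)


def read_bioactivity_csv(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parse a raw bioactivity CSV into (records, rejects).

    Requires columns compound_id, smiles, year and one of ic50_nM / ic50_uM.
    IC50 is converted to molar and pIC50 added. Rows with missing or
    unparseable SMILES, or non-positive IC50, are routed to the rejects table
    with a reason column instead of being silently dropped."""
    df = pd.read_csv(path, dtype={"compound_id": str, "smiles": str})
    required = ["compound_id", "smiles", "year"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")
    if "ic50_nM" in df.columns:
        ic50_molar = df["ic50_nM"].astype(float) * 1e-9
    elif "ic50_uM" in df.columns:
        ic50_molar = df["ic50_uM"].astype(float) * 1e-6
    else:
        raise SchemaError("missing mandatory column(s): ['ic50_nM' or 'ic50_uM']")
    df = df.copy()
    df["ic50_molar"] = ic50_molar

    reasons = pd.Series("", index=df.index)
    blank = df["smiles"].isna() | (df["smiles"].astype(str).str.strip() == "")
    reasons[blank] = "empty SMILES"
    bad_ic50 = ~blank & ~(df["ic50_molar"] > 0)
    reasons[bad_ic50] = "non-positive IC50"
    to_check = ~blank & ~bad_ic50
    canon = pd.Series(None, index=df.index, dtype=object)
    for i in df.index[to_check]:
        canon[i] = canonical_smiles(df.at[i, "smiles"])
    unparseable = to_check & canon.isna()
    reasons[unparseable] = "unparseable SMILES"

    rejects = df[reasons != ""].copy()
    rejects["reason"] = reasons[reasons != ""]
    records = df[reasons == ""].copy()
    records["canonical_smiles"] = canon[reasons == ""]
    records["pic50"] = to_pic50(records["ic50_molar"].to_numpy()) if len(records) else []
    records["year"] = records["year"].astype(int)
    return records.reset_index(drop=True), rejects.reset_index(drop=True)


def deduplicate(table: pd.DataFrame) -> tuple[pd.DataFrame, CurationReport]:
    """One record per canonical structure; the latest-year entry wins, ties
    broken by last file position."""
    if "year" not in table.columns or table["year"].isna().any():
        raise SchemaError("deduplication requires a year for every record")
    df = table.copy()
    if "canonical_smiles" not in df.columns:
        df["canonical_smiles"] = [canonical_smiles(s) for s in df["smiles"]]
    df["_pos"] = np.arange(len(df))
    keep_pos = (
        df.sort_values(["year", "_pos"], kind="stable")
        .groupby("canonical_smiles", sort=False)["_pos"]
        .last()
    )
    kept = df[df["_pos"].isin(set(keep_pos))].drop(columns="_pos")
    removed = df[~df["_pos"].isin(set(keep_pos))]
    report = CurationReport(
        n_input=len(df),
        n_after_dedup=len(kept),
        removed_ids={"dedup": removed["compound_id"].tolist()},
    )
    return kept.reset_index(drop=True), report


def strip_salts(table: pd.DataFrame) -> tuple[pd.DataFrame, CurationReport]:
    """Remove bare metal/halide counter-ion fragments from multi-fragment
    SMILES, keeping the largest organic fragment. Records reduced to no
    organic fragment are dropped; every modification is logged."""
    Chem = _rdkit()
    df = table.copy()
    modified, dropped_ids, keep_mask, new_smiles = [], [], [], []
    for i in df.index:
        smi = df.at[i, "smiles"]
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            keep_mask.append(True)
            new_smiles.append(smi)
            continue
        frags = Chem.GetMolFrags(mol, asMols=True)
        organic = [
            f for f in frags
            if not (f.GetNumAtoms() == 1
                    and f.GetAtomWithIdx(0).GetSymbol() in COUNTER_ION_ELEMENTS)
        ]
        if len(organic) == len(frags):
            keep_mask.append(True)
            new_smiles.append(smi)
            continue
        if not organic:
            keep_mask.append(False)
            new_smiles.append(smi)
            dropped_ids.append(df.at[i, "compound_id"])
            continue
        largest = max(organic, key=lambda f: f.GetNumAtoms())
        keep_mask.append(True)
        new_smiles.append(Chem.MolToSmiles(largest))
        modified.append(df.at[i, "compound_id"])
    df["smiles"] = new_smiles
    out = df[np.asarray(keep_mask)].copy()
    out["canonical_smiles"] = [canonical_smiles(s) for s in out["smiles"]]
    report = CurationReport(
        n_input=len(df),
        n_after_desalt=len(out),
        removed_ids={"desalt": dropped_ids},
        modified_ids={"desalt": modified},
    )
    return out.reset_index(drop=True), report


def compute_descriptors(table: pd.DataFrame) -> pd.DataFrame:
    """Add mw (g/mol) and logp (Crippen estimate) columns computed from the
    cleaned structures."""
    Chem = _rdkit()
    from rdkit.Chem import Crippen, Descriptors

    df = table.copy()
    mws, logps = [], []
    for smi in df["smiles"]:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise DataError(f"descriptor computation hit unparseable SMILES: {smi!r}")
        mws.append(Descriptors.MolWt(mol))
        logps.append(Crippen.MolLogP(mol))
    df["mw"] = mws
    df["logp"] = logps
    return df


def trim_outliers(
    table: pd.DataFrame, k_sd: float = 1.5, columns=("mw", "logp", "pic50")
) -> tuple[pd.DataFrame, CurationReport]:
    """Single-pass property trim: remove any record with a value outside
    mean ± k_sd·SD of its column, with means/SDs computed once on the input
    table (population SD). Zero-SD columns remove nothing."""
    df = table.copy()
    for c in columns:
        if c not in df.columns:
            raise SchemaError(f"trim_outliers requires column {c!r}")
    report = CurationReport(n_input=len(df))
    if len(df) < 3:
        warnings.warn("fewer than 3 records: property trim skipped")
        report.n_after_trim = len(df)
        report.removed_ids["trim"] = []
        report.notes.append("trim skipped: fewer than 3 records")
        return df, report
    mask = np.ones(len(df), dtype=bool)
    for c in columns:
        v = df[c].to_numpy(dtype=float)
        mu, sd = v.mean(), v.std()  # population SD, single pass
        if sd == 0 or not np.isfinite(sd):
            continue
        mask &= np.abs(v - mu) <= k_sd * sd
    out = df[mask]
    report.n_after_trim = len(out)
    report.removed_ids["trim"] = df.loc[~mask, "compound_id"].tolist()
    return out.reset_index(drop=True), report


def curate(
    table: pd.DataFrame, k_sd: float = 1.5
) -> tuple[pd.DataFrame, CurationReport]:
    """Full curation pipeline in the fixed order dedup → desalt → transform →
    trim, with a reconciled report."""
    report = CurationReport(n_input=len(table))
    deduped, r1 = deduplicate(table)
    report.n_after_dedup = len(deduped)
    report.removed_ids["dedup"] = r1.removed_ids["dedup"]
    desalted, r2 = strip_salts(deduped)
    report.n_after_desalt = len(desalted)
    report.removed_ids["desalt"] = r2.removed_ids["desalt"]
    report.modified_ids["desalt"] = r2.modified_ids["desalt"]
    if "pic50" not in desalted.columns:
        if "ic50_molar" in desalted.columns:
            molar = desalted["ic50_molar"].to_numpy(dtype=float)
        elif "ic50_nM" in desalted.columns:
            molar = desalted["ic50_nM"].to_numpy(dtype=float) * 1e-9
        elif "ic50_uM" in desalted.columns:
            molar = desalted["ic50_uM"].to_numpy(dtype=float) * 1e-6
        else:
            raise SchemaError("curation needs an IC50 (molar/nM/uM) or pic50 column")
        desalted["pic50"] = to_pic50(molar)
    withdesc = compute_descriptors(desalted)
    trimmed, r3 = trim_outliers(withdesc, k_sd=k_sd)
    report.n_after_trim = len(trimmed)
    report.removed_ids["trim"] = r3.removed_ids["trim"]
    report.notes.extend(r3.notes)
    return trimmed, report
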