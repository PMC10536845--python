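"""Virtual screening of a drug library.

Predicts activities for every library compound with a trained QSAR model,
merges externally produced docking affinities (site-specific and blind;
docking itself is consumed, never executed), combines predicted potency and
site affinity into a 0–1 min-max composite score, filters off-site binders,
and ranks the hits.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .exceptions import ParameterError, SchemaError
from .models import check_featurizer_match


def pic50_to_ic50_nM(pic50) -> np.ndarray | float:
    """Predicted IC50 in nM = 10^(9 − pIC50)."""
    arr = np.asarray(pic50, dtype=float)
    out = 10.0 ** (9.0 - arr)
    return float(out) if out.ndim == 0 else out


def predict_library(model, featurizer, library: pd.DataFrame,
                    model_provenance: dict | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Predict pIC50/IC50 for every parseable library SMILES.

    ``library`` needs columns name and smiles. When ``model_provenance`` (the
    featurizer provenance stored with a persisted model) is given, it must
    match the provenance of ``featurizer`` or prediction is refused.
    Returns (predictions, failures)."""
    for col in ("name", "smiles"):
        if col not in library.columns:
            raise SchemaError(f"library table is missing column {col!r}")
    if model_provenance is not None:
        check_featurizer_match(model_provenance, featurizer.provenance())
    rows, failures = [], []
    for _, rec in library.iterrows():
        try:
            vec = featurizer.transform([rec["smiles"]])
        except Exception as exc:  # unparseable SMILES → failure row
            failures.append({"name": rec["name"], "smiles": rec["smiles"], "reason": str(exc)})
            continue
        pic50 = float(model.predict(vec)[0])
        rows.append({"name": rec["name"], "smiles": rec["smiles"],
                     "pic50_pred": pic50, "ic50_pred_nM": pic50_to_ic50_nM(pic50)})
    columns = ["name", "smiles", "pic50_pred", "ic50_pred_nM"]
    preds = pd.DataFrame(rows, columns=columns)
    fails = pd.DataFrame(failures, columns=["name", "smiles", "reason"])
    return preds, fails


def read_affinity_csv(path) -> pd.DataFrame:
    """Docking affinity table: name, affinity_site, optional affinity_blind
    (kcal/mol; more negative = better binding)."""
    df = pd.read_csv(path)
    for col in ("name", "affinity_site"):
        if col not in df.columns:
            raise SchemaError(f"affinity table is missing column {col!r}")
    if "affinity_blind" not in df.columns:
        df["affinity_blind"] = np.nan
    return df


def _minmax(values: np.ndarray, lo: float, hi: float, weight: float) -> np.ndarray:
    if hi == lo:
        warnings.warn("degenerate component range: all compounds share its full weight")
        return np.full(len(values), weight)
    return weight * np.clip((values - lo) / (hi - lo), 0.0, 1.0)


def composite_score(
    pic50_pred, affinity_site, weights: tuple[float, float] = (0.5, 0.5), ranges=None
) -> np.ndarray:
    """0–1 scoring matrix over the screened library.

    score = w1·minmax(pic50_pred) + w2·minmax(−affinity_site), each component
    min-max scaled over the library's observed range (or explicit ``ranges``
    of the form ((pic50_lo, pic50_hi), (aff_lo, aff_hi)) on the raw scales).
    Higher predicted potency and more negative site affinity both raise the
    score; weights must sum to 1."""
    w1, w2 = weights
    if not np.isclose(w1 + w2, 1.0) or w1 < 0 or w2 < 0:
        raise ParameterError("weights must be non-negative and sum to 1")
    pic50_pred = np.asarray(pic50_pred, dtype=float)
    neg_aff = -np.asarray(affinity_site, dtype=float)
    if ranges is None:
        p_lo, p_hi = pic50_pred.min(), pic50_pred.max()
        a_lo, a_hi = neg_aff.min(), neg_aff.max()
    else:
        (p_lo, p_hi), (aff_lo, aff_hi) = ranges
        a_lo, a_hi = -aff_hi, -aff_lo  # raw affinity range → negated scale
    return _minmax(pic50_pred, p_lo, p_hi, w1) + _minmax(neg_aff, a_lo, a_hi, w2)


def site_specificity_filter(table: pd.DataFrame, tol: float = 0.0) -> pd.DataFrame:
    """Flag off-site binders: a drug is dropped when its blind-docking
    affinity is strictly better (more negative) than its site-specific
    affinity by more than ``tol`` kcal/mol. Records without a blind affinity
    pass unchecked (site_check = 'unchecked')."""
    if "affinity_site" not in table.columns:
        raise SchemaError("site_specificity_filter requires affinity_site")
    df = table.copy()
    blind = df.get("affinity_blind", pd.Series(np.nan, index=df.index)).astype(float)
    site = df["affinity_site"].astype(float)
    unchecked = blind.isna()
    offsite = ~unchecked & (blind < site - tol)
    df["site_check"] = np.where(unchecked, "unchecked", np.where(offsite, "drop", "keep"))
    df["site_check_reason"] = np.where(
        offsite, "blind affinity better than site affinity", ""
    )
    return df


def rank_hits(table: pd.DataFrame, top_n: int | None = None) -> pd.DataFrame:
    """Rank by composite score descending; ties prefer the more negative site
    affinity, then name. Drops rows failing the site-specificity check when
    that column is present."""
    if "score" not in table.columns:
        raise SchemaError("rank_hits requires a score column")
    df = table.copy()
    if "site_check" in df.columns:
        df = df[df["site_check"] != "drop"]
    sort_cols, ascending = ["score"], [False]
    if "affinity_site" in df.columns:
        sort_cols.append("affinity_site")
        ascending.append(True)
    sort_cols.append("name")
    ascending.append(True)
    df = df.sort_values(sort_cols, ascending=ascending, kind="stable").reset_index(drop=True)
    return df if top_n is None else df.head(top_n)


def screen(
    model, featurizer, library: pd.DataFrame, affinities: pd.DataFrame,
    weights: tuple[float, float] = (0.5, 0.5), tol: float = 0.0,
    top_n: int | None = None, model_provenance: dict | None = None,
) -> pd.DataFrame:
    """End-to-end screening: predict, merge affinities, score, filter, rank."""
    preds, _ = predict_library(model, featurizer, library, model_provenance)
    merged = preds.merge(affinities, on="name", how="left")
    has_aff = merged["affinity_site"].notna()
    scored = merged[has_aff].copy()
    if len(scored):
        scored["score"] = composite_score(
            scored["pic50_pred"], scored["affinity_site"], weights=weights
        )
        scored = site_specificity_filter(scored, tol=tol)
    else:
        scored["score"] = pd.Series(dtype=float)
    hits = rank_hits(scored, top_n=top_n)
    hits.attrs["n_dropped_offsite"] = int((scored.get("site_check") == "drop").sum())
    return hits
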