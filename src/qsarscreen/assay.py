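"""Wet-lab assay analytics: dose-response IC50 fitting and qPCR relative
expression.

Viability plates (590/690 nm absorbance) are normalized against vehicle
wells and fitted with the four-parameter logistic model on log10
concentration; IC50 is reported in mass units with an asymptotic 95% CI and
converted to molar units with the compound's free-base molecular weight.
qPCR Ct tables are analysed by the 2^−ΔΔCt method against the mean of the
endogenous control genes, with an unpaired two-tailed t-test on the
per-replicate ΔCt values.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import DataError, FitConvergenceError, ParameterError, SchemaError

#: free-base molecular weights (g/mol) used for mass↔molar IC50 conversion
FREE_BASE_MW = {
    "cetirizine": 388.89,
    "rupatadine": 415.96,
}


# ---------------------------------------------------------------------------
# viability normalization and 4PL fitting
# ---------------------------------------------------------------------------

def normalize_viability(plate: pd.DataFrame) -> pd.DataFrame:
    """Blank-correct (abs590 − abs690) and scale to percent of the mean
    vehicle-well signal. Input columns: well, conc, abs590, abs690, role."""
    for col in ("conc", "abs590", "abs690", "role"):
        if col not in plate.columns:
            raise SchemaError(f"plate table is missing column {col!r}")
    df = plate.copy()
    df["signal"] = df["abs590"].astype(float) - df["abs690"].astype(float)
    vehicle = df.loc[df["role"] == "vehicle", "signal"]
    if len(vehicle) == 0:
        raise SchemaError("plate has no vehicle wells")
    v_mean = vehicle.mean()
    if v_mean <= 0:
        raise DataError("mean vehicle signal is non-positive; plate unusable")
    df["viability"] = 100.0 * df["signal"] / v_mean
    return df


@dataclass
class DoseResponseFit:
    """4PL fit result; ic50_mass in the concentration unit of the input
    (μg/mL by convention), ci95 an asymptotic interval on the same scale."""

    top: float
    bottom: float
    hill: float
    log_ic50: float
    ic50_mass: float
    ci95: tuple[float, float]
    r_squared: float
    n_points: int

    def ic50_molar(self, mw: float) -> float:
        return mass_to_molar(self.ic50_mass, mw)


def _four_pl_log(logc, top, bottom, hill, log_ic50):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logc - log_ic50)))


def fit_4pl(
    conc, viability,
    fix_top: float | None = None, fix_bottom: float | None = None,
    flat_tol: float = 5.0,
) -> DoseResponseFit:
    """Least-squares 4PL fit of viability (%) against concentration.

    Fits on log10 concentration with multi-start initialization over both
    slope signs. ``fix_top``/``fix_bottom`` pin the plateaus (the
    normalized-response convention fixes them at 100 and 0, leaving slope and
    midpoint free); by default all four parameters are estimated. Raises
    :class:`FitConvergenceError` — never a silent fallback — when the
    optimizer fails or the response is flat (span below ``flat_tol``
    percent)."""
    conc = np.asarray(conc, dtype=float)
    viability = np.asarray(viability, dtype=float)
    if (conc <= 0).any():
        raise ParameterError("concentrations must be strictly positive")
    if len(np.unique(conc)) < 4:
        raise ParameterError("4PL fitting needs at least 4 distinct concentrations")
    logc = np.log10(conc)
    span = viability.max() - viability.min()
    if span < flat_tol:
        raise FitConvergenceError(
            "flat dose-response: no IC50 is identifiable",
            diagnostics={"response_span": float(span), "flat_tol": flat_tol},
        )

    free = [name for name, fixed in
            (("top", fix_top), ("bottom", fix_bottom)) if fixed is None]
    free += ["hill", "log_ic50"]

    def model(logc_, *params):
        values = dict(zip(free, params))
        return _four_pl_log(
            logc_,
            values.get("top", fix_top),
            values.get("bottom", fix_bottom),
            values["hill"],
            values["log_ic50"],
        )

    defaults = {"top": float(viability.max()), "bottom": float(viability.min())}
    best = None
    errors = []
    for hill0 in (1.0, 2.0, 0.5, -1.0):
        p0 = [defaults[name] for name in free if name in defaults]
        p0 += [hill0, float(np.median(logc))]
        try:
            popt, pcov = optimize.curve_fit(model, logc, viability, p0=p0, maxfev=20000)
        except (RuntimeError, optimize.OptimizeWarning) as exc:
            errors.append(str(exc))
            continue
        sse = float(((viability - model(logc, *popt)) ** 2).sum())
        if best is None or sse < best[0]:
            best = (sse, popt, pcov)
    if best is None:
        raise FitConvergenceError(
            "4PL fit did not converge from any start", diagnostics={"errors": errors}
        )
    sse, popt, pcov = best
    values = dict(zip(free, popt))
    top = values.get("top", fix_top)
    bottom = values.get("bottom", fix_bottom)
    hill, log_ic50 = values["hill"], values["log_ic50"]
    if bottom > top:  # canonical orientation: top is the high-response plateau
        top, bottom, hill = bottom, top, -hill
    sst = float(((viability - viability.mean()) ** 2).sum())
    r_squared = 1.0 - sse / sst if sst > 0 else float("nan")

    dof = max(1, len(viability) - len(free))
    i_log = free.index("log_ic50")
    se_log = float(np.sqrt(pcov[i_log, i_log])) if np.isfinite(pcov[i_log, i_log]) else float("nan")
    tcrit = stats.t.ppf(0.975, dof)
    ci = (10.0 ** (log_ic50 - tcrit * se_log), 10.0 ** (log_ic50 + tcrit * se_log))
    return DoseResponseFit(
        top=float(top), bottom=float(bottom), hill=float(hill),
        log_ic50=float(log_ic50), ic50_mass=float(10.0**log_ic50),
        ci95=(float(ci[0]), float(ci[1])), r_squared=float(r_squared),
        n_points=len(viability),
    )


def fit_plate(plate: pd.DataFrame, normalized_response: bool = True) -> DoseResponseFit:
    """Normalize a raw plate and fit the treated wells.

    By default uses the normalized-response convention (plateaus fixed at
    100% and 0%, slope variable), the standard treatment for vehicle-scaled
    viability; pass ``normalized_response=False`` to free all four
    parameters."""
    df = normalize_viability(plate)
    treated = df[df["role"] == "treated"]
    kwargs = {"fix_top": 100.0, "fix_bottom": 0.0} if normalized_response else {}
    return fit_4pl(treated["conc"].to_numpy(), treated["viability"].to_numpy(), **kwargs)


def mass_to_molar(ic50_mass: float, mw: float) -> float:
    """μg/mL → μM: 1000 · (μg/mL) / (g/mol)."""
    if mw <= 0:
        raise ParameterError("molecular weight must be positive")
    return 1000.0 * ic50_mass / mw


def molar_to_mass(ic50_molar: float, mw: float) -> float:
    """μM → μg/mL (inverse of :func:`mass_to_molar`)."""
    if mw <= 0:
        raise ParameterError("molecular weight must be positive")
    return ic50_molar * mw / 1000.0


# ---------------------------------------------------------------------------
# qPCR relative expression
# ---------------------------------------------------------------------------

@dataclass
class ExpressionResult:
    """Per-gene 2^−ΔΔCt analysis: replicate ΔCt per group, ΔΔCt, fold change
    and the unpaired t-test p-value. ``fold_sd_replicate`` is the SD of the
    per-replicate treated fold changes; ``fold_sd_propagated`` propagates the
    ΔΔCt standard error onto the fold scale."""

    gene: str
    delta_ct_treated: np.ndarray
    delta_ct_control: np.ndarray
    delta_delta_ct: float
    fold_change: float
    p_value: float
    fold_sd_replicate: float
    fold_sd_propagated: float


def delta_delta_ct(
    ct: pd.DataFrame,
    targets,
    endo: tuple[str, ...] = ("ACTB", "GAPDH"),
    treated: str = "treated",
    control: str = "control",
    equal_var: bool = True,
) -> list[ExpressionResult]:
    """2^−ΔΔCt relative quantification with significance testing.

    Per replicate, ΔCt = Ct_target − mean(Ct of the endogenous genes in the
    same group/replicate); ΔΔCt = mean ΔCt_treated − mean ΔCt_control;
    fold = 2^−ΔΔCt. The two-tailed unpaired t-test compares replicate ΔCt
    between groups (amplification efficiency is assumed to be exactly 2)."""
    for col in ("gene", "group", "replicate", "ct"):
        if col not in ct.columns:
            raise SchemaError(f"Ct table is missing column {col!r}")
    present = set(ct["gene"])
    missing_endo = [g for g in endo if g not in present]
    if missing_endo:
        raise SchemaError(f"endogenous control gene(s) missing: {missing_endo}")
    results = []
    for gene in targets:
        if gene not in present:
            raise SchemaError(f"target gene missing from Ct table: {gene!r}")
        per_group = {}
        for group in (treated, control):
            sub = ct[ct["group"] == group]
            if len(sub) == 0:
                raise SchemaError(f"group missing from Ct table: {group!r}")
            tgt = sub[sub["gene"] == gene].set_index("replicate")["ct"]
            endo_mean = (
                sub[sub["gene"].isin(endo)]
                .groupby("replicate")["ct"].mean()
            )
            reps = tgt.index.intersection(endo_mean.index)
            if len(reps) < 2:
                raise SchemaError(
                    f"gene {gene!r} needs at least 2 complete replicates in group {group!r}"
                )
            per_group[group] = (tgt.loc[reps] - endo_mean.loc[reps]).to_numpy(dtype=float)
        dct_t, dct_c = per_group[treated], per_group[control]
        ddct = float(dct_t.mean() - dct_c.mean())
        fold = 2.0 ** (-ddct)
        t_res = stats.ttest_ind(dct_t, dct_c, equal_var=equal_var)
        rep_folds = 2.0 ** (-(dct_t - dct_c.mean()))
        se_ddct = math.sqrt(
            dct_t.var(ddof=1) / len(dct_t) + dct_c.var(ddof=1) / len(dct_c)
        )
        results.append(
            ExpressionResult(
                gene=gene,
                delta_ct_treated=dct_t,
                delta_ct_control=dct_c,
                delta_delta_ct=ddct,
                fold_change=fold,
                p_value=float(t_res.pvalue),
                fold_sd_replicate=float(rep_folds.std(ddof=1)),
                fold_sd_propagated=float(fold * math.log(2) * se_ddct),
            )
        )
    return results


def expression_table(results: list[ExpressionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "delta_delta_ct": [r.delta_delta_ct for r in results],
            "fold_change": [r.fold_change for r in results],
            "p_value": [r.p_value for r in results],
            "fold_sd_replicate": [r.fold_sd_replicate for r in results],
            "fold_sd_propagated": [r.fold_sd_propagated for r in results],
        }
    )
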