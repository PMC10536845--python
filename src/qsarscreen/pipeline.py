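"""End-to-end orchestration: curate → featurize → benchmark → AD → screen.

A single :class:`RunConfig` drives the stages; every run writes per-stage
artifacts plus a manifest recording the config, input hashes, seeds and
record counts, so any number in any report is traceable and a rerun with the
same config reproduces identical outputs.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .exceptions import ParameterError
from . import ad as ad_mod
from . import curation, featurize, models, screening, synthetic

ALL_STAGES = ("curate", "featurize", "benchmark", "ad", "screen")


@dataclass
class RunConfig:
    """Pipeline configuration; every threshold defaults to the study value."""

    outdir: str = "qsarscreen_run"
    seed: int = 42
    stages: tuple[str, ...] = ALL_STAGES
    # inputs (None → synthetic demo inputs)
    bioactivity_csv: str | None = None
    library_csv: str | None = None
    affinity_csv: str | None = None
    # synthetic demo inputs
    n_compounds: int = 400
    dup_fraction: float = 0.05
    salt_fraction: float = 0.05
    outlier_fraction: float = 0.05
    noise_sd: float = 0.3
    n_library: int = 60
    # featurizer
    dimension: int = 64
    radii: tuple[int, ...] = (0, 1)
    # modelling / thresholds
    k_folds: int = 10
    registry_names: tuple[str, ...] | None = None
    k_sd: float = 1.5
    h_star_multiplier: float = 3.0
    res_cut: float = 2.5
    score_weights: tuple[float, float] = (0.5, 0.5)
    site_tol: float = 0.0
    d_max: float = 4.0
    angle_min: float = 120.0

    def __post_init__(self):
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ParameterError(f"unknown stage(s): {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["radii"] = list(self.radii)
        d["score_weights"] = list(self.score_weights)
        if self.registry_names is not None:
            d["registry_names"] = list(self.registry_names)
        return d

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = json.load(fh)
        for key in ("stages", "radii", "score_weights", "registry_names"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def _sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _sha256_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()


def _synthetic_screen_inputs(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A synthetic screening library (lattice molecules unseen in the demo
    training slice) with plausibly correlated docking affinities."""
    rng = np.random.default_rng(config.seed + 1)
    start = synthetic.MAX_DISTINCT - config.n_library
    rows = []
    for i in range(start, start + config.n_library):
        j, a, b = synthetic._lattice_index(i)
        smiles = synthetic._assemble(
            synthetic.SCAFFOLDS[j], synthetic.SUBSTITUENTS_A[a], synthetic.SUBSTITUENTS_B[b]
        )
        rows.append({"name": f"DRUG-{i - start:04d}", "smiles": smiles})
    library = pd.DataFrame(rows)
    site = -7.0 - rng.normal(0.0, 0.8, len(library))
    blind = site + np.abs(rng.normal(0.5, 0.5, len(library)))
    offsite = rng.random(len(library)) < 0.1
    blind[offsite] = site[offsite] - np.abs(rng.normal(0.5, 0.3, offsite.sum()))
    affinities = pd.DataFrame(
        {"name": library["name"], "affinity_site": np.round(site, 2),
         "affinity_blind": np.round(blind, 2)}
    )
    return library, affinities


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns the manifest (also
    written to <outdir>/manifest.json). A stage failure halts the run with
    the failing stage named; artifacts of completed stages are retained."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": config.to_dict(),
        "inputs": {},
        "stages": {},
        "outputs": {},
    }
    state: dict = {}
    stage = None
    try:
        for stage in ALL_STAGES:
            if stage in config.stages:
                _STAGE_FUNCS[stage](config, state, manifest, out)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _stage_curate(config: RunConfig, state, manifest, out: Path):
    if config.bioactivity_csv is not None:
        raw, rejects = curation.read_bioactivity_csv(config.bioactivity_csv)
        manifest["inputs"]["bioactivity_csv"] = _sha256_file(config.bioactivity_csv)
    else:
        spec = synthetic.SyntheticLibrarySpec(
            n_compounds=config.n_compounds, seed=config.seed,
            noise_sd=config.noise_sd, dup_fraction=config.dup_fraction,
            salt_fraction=config.salt_fraction, outlier_fraction=config.outlier_fraction,
        )
        generated = synthetic.gen_bioactivity_library(spec)
        raw_path = out / "synthetic_bioactivity.csv"
        generated.to_csv(raw_path, index=False)
        manifest["inputs"]["bioactivity_csv"] = _sha256_file(raw_path)
        raw, rejects = curation.read_bioactivity_csv(raw_path)
    curated, report = curation.curate(raw, k_sd=config.k_sd)
    curated.to_csv(out / "curated.csv", index=False)
    (out / "curation_report.json").write_text(report.to_json())
    manifest["stages"]["curate"] = {
        "n_input": report.n_input,
        "n_rejected_rows": len(rejects),
        "n_after_dedup": report.n_after_dedup,
        "n_after_desalt": report.n_after_desalt,
        "n_after_trim": report.n_after_trim,
    }
    manifest["outputs"]["curated_csv"] = _sha256_frame(curated)
    state["curated"] = curated


def _stage_featurize(config: RunConfig, state, manifest, out: Path):
    curated = state["curated"]
    feat = featurize.Mol2VecFeaturizer(
        dimension=config.dimension, radii=config.radii, seed=config.seed
    ).fit()
    X = feat.transform(curated["smiles"].tolist())
    np.savetxt(out / "features.csv", X, delimiter=",")
    manifest["stages"]["featurize"] = {
        "n_compounds": len(curated),
        "dimension": feat.dimension_,
        "provenance": feat.provenance(),
    }
    state["featurizer"] = feat
    state["X"] = X
    state["y"] = curated["pic50"].to_numpy(dtype=float)


def _stage_benchmark(config: RunConfig, state, manifest, out: Path):
    registry = models.default_registry(seed=config.seed, names=config.registry_names)
    table = models.benchmark(registry, state["X"], state["y"], k=config.k_folds, seed=config.seed)
    table.to_csv(out / "benchmark.csv", index=False)
    best_name = table.iloc[0]["algorithm"]
    manifest["stages"]["benchmark"] = {
        "n_learners": len(registry),
        "best": best_name,
        "best_r2": float(table.iloc[0]["r2"]),
        "best_rmse": float(table.iloc[0]["rmse"]),
        "seed": config.seed,
    }
    manifest["outputs"]["benchmark_csv"] = _sha256_frame(table.drop(columns="status"))
    model = models.KNeighborsActivityRegressor().fit(state["X"], state["y"])
    models.save_model(model, out / "model.json", state["featurizer"].provenance())
    state["model"] = model


def _stage_ad(config: RunConfig, state, manifest, out: Path):
    curated = state["curated"]
    report = ad_mod.ad_report(
        models.KNeighborsActivityRegressor(), state["X"], state["y"],
        k=config.k_folds, seed=config.seed,
        multiplier=config.h_star_multiplier, res_cut=config.res_cut,
        compound_ids=curated["compound_id"].tolist(),
    )
    report.to_frame().to_csv(out / "williams.csv", index=False)
    summary = report.summary()
    (out / "ad_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    evaluation = ad_mod.ad_evaluation(
        models.KNeighborsActivityRegressor(), state["X"], state["y"], report,
        k=config.k_folds, seed=config.seed,
    )
    manifest["stages"]["ad"] = {
        **summary,
        "inside_cv_r2": evaluation.inside.mean["r2"],
        "inside_cv_rmse": evaluation.inside.mean["rmse"],
        "outside": evaluation.outside,
    }


def _stage_screen(config: RunConfig, state, manifest, out: Path):
    if config.library_csv is not None:
        library = pd.read_csv(config.library_csv)
        affinities = screening.read_affinity_csv(config.affinity_csv)
        manifest["inputs"]["library_csv"] = _sha256_file(config.library_csv)
        manifest["inputs"]["affinity_csv"] = _sha256_file(config.affinity_csv)
    else:
        library, affinities = _synthetic_screen_inputs(config)
        library.to_csv(out / "synthetic_library.csv", index=False)
        affinities.to_csv(out / "synthetic_affinities.csv", index=False)
        manifest["inputs"]["library_csv"] = _sha256_frame(library)
        manifest["inputs"]["affinity_csv"] = _sha256_frame(affinities)
    hits = screening.screen(
        state["model"], state["featurizer"], library, affinities,
        weights=config.score_weights, tol=config.site_tol,
    )
    hits.to_csv(out / "hits.csv", index=False)
    manifest["stages"]["screen"] = {
        "n_library": len(library),
        "n_ranked": len(hits),
        "n_dropped_offsite": hits.attrs.get("n_dropped_offsite", 0),
        "top_hit": hits.iloc[0]["name"] if len(hits) else None,
        "top_score": float(hits.iloc[0]["score"]) if len(hits) else None,
    }
    manifest["outputs"]["hits_csv"] = _sha256_frame(hits)


_STAGE_FUNCS = {
    "curate": _stage_curate,
    "featurize": _stage_featurize,
    "benchmark": _stage_benchmark,
    "ad": _stage_ad,
    "screen": _stage_screen,
}


def run_demo(outdir, seed: int = 42, n_compounds: int = 400, **overrides) -> dict:
    """The full synthetic end-to-end pipeline with demo defaults."""
    config = RunConfig(outdir=str(outdir), seed=seed, n_compounds=n_compounds, **overrides)
    return run_pipeline(config)
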