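# Methods

This note records the models, conventions and numerical choices behind each
stage, the reasoning where the design was genuinely open, and what the
synthetic benchmarks do and do not demonstrate.

## Curation

The curation pipeline runs in a fixed order: deduplicate → desalt → pIC50
transform → property trim. Deduplication keys on **canonical SMILES**, not on
compound identifiers: the same structure reported twice under different
database IDs must collapse to one record. The kept record is the one with
the latest publication year; exact year ties keep the later file position.
Desalting removes *disconnected single-atom* metal/halide fragments
(Na, K, Li, Cs, Mg, Ca, Zn, Fe, Cu, Mn, Al, F, Cl, Br, I as bare ions) and
retains the largest organic fragment; a record is dropped only when nothing
organic remains. Covalently bound halogens are untouched. The property trim
is **single-pass and non-iterative**: means and population SDs of molecular
weight, Crippen LogP and pIC50 are computed once on the incoming table and a
record is removed if *any* of the three values falls outside
mean ± 1.5 SD. Zero-variance columns remove nothing, and tables with fewer
than three rows skip the trim with a warning. `k_sd` is configurable
(default 1.5). MW and LogP are computed from the cleaned structure with
RDKit (`Descriptors.MolWt`, Crippen `MolLogP`).

pIC50 = −log10(IC50 in mol/L); nM and μM input columns are converted to
molar before the transform, and the inverse transform round-trips to 1e−9
relative precision.

## Featurization

A molecule is tokenised into per-atom circular-environment identifiers
(Morgan/ECFP hashes) at radii 0 and 1, radius-ascending per atom, atoms in
canonical order — the mol2vec "sentence" convention. Input SMILES are
round-tripped through canonical form first, so every spelling of a molecule
yields the identical sentence and hence the identical feature vector.
Redundant environments are retained so symmetry-equivalent atoms carry equal
identifiers at every radius; an isolated atom, whose environment cannot
grow, reuses its radius-0 identifier at radius 1 so each atom always
contributes one token per radius.

The compound vector is the plain sum of its tokens' embedding vectors.
Embeddings come from either

* a **pre-trained table** in a plain-text `identifier v1 … v300` format
  (dimension inferred and validated; unknown identifiers map to the stored
  `UNK` vector), or
* the **hashed fallback table**: each identifier maps to a standard-normal
  vector drawn from a PCG64 stream seeded by the first 8 bytes of
  SHA-256(`identifier|seed`) — deterministic across processes and platforms,
  no training, unit variance by construction.

All tests and synthetic benchmarks use the hashed table; reproducing
features from any particular pre-trained embedding requires that table file.
Radii and dimension are configurable (defaults {0, 1} and 300).

## Model selection

Ten regression learners sit behind a registry (K-neighbors plus nine
library-backed learners from scikit-learn, lightgbm and xgboost, all seeded
and single-threaded for reproducibility). All are benchmarked with 10-fold
shuffled cross-validation **on identical folds**, scoring R², MSE, MAE and
RMSE on held-out data only; aggregates are the arithmetic mean and sample
(n−1) SD over folds, with rounding only at presentation time. Ranking is by
mean R² descending with RMSE ascending as tie-break. A learner that throws
becomes a `failed` row; the run continues.

Only the K-neighbors regressor — the selected model — has its prediction
semantics pinned in-package: Minkowski-p distance, uniform weights = mean of
the k nearest labels, distance weights = inverse-distance weighting with an
exact match (distance 0) returning that label, and neighbour ties at the
k-th distance broken by **lowest training index**, making predictions fully
deterministic. `leaf_size` is accepted for interface compatibility but is
prediction-neutral (it only tunes search trees); the grid search therefore
evaluates each prediction-relevant (n_neighbors, p, weights) cell once and
shares the result across leaf sizes. Grid-search ties prefer smaller
n_neighbors, then smaller p. Features are not scaled before KNN by default.

Models persist as a single JSON document (hyperparameters, training arrays,
featurizer provenance, SHA-256 training-data hash). Loading verifies the
format version and the hash, and prediction through the screening API
refuses queries featurized under different provenance (kind, dimension,
radii, seed or table path). JSON float round-tripping is exact, so a loaded
model predicts bit-for-bit identically.

## Applicability domain (leverage approach)

Leverages are the diagonal of the projection ("hat") matrix of the
intercept-augmented design, computed from the SVD with tolerance-based rank
truncation — with hundreds of correlated features the Gram matrix can be
ill-conditioned, and the pseudo-inverse route guarantees 0 ≤ h_i ≤ 1 and
Σh_i = rank(X_aug) without ever inverting it. The threshold is
h\* = 3P/n with P = number of model variables + 1 (the intercept); the
multiplier is configurable (2P/n is a common sensitivity variant).

Standardized cross-validated residuals divide the held-out residuals by
their overall sample SD. A per-point leverage correction
(res_i/(s·√(1−h_i))) is available behind a flag but off by default — the
plain form is the simplest reading of "standardized" and the two differ
negligibly at small h. Williams classification uses **strict inequalities**:
a point exactly on a threshold stays in-domain. X outlier ⇔ h > h\* only;
Y outlier ⇔ |res| > 2.5 only; XY ⇔ both.

Domain evaluation reports (a) 10-fold CV restricted to in-domain compounds
and (b) RMSE/MAE of a model trained on the in-domain set and tested on the
outliers; with no outliers the outside metrics are reported as absent rather
than fabricated.

## Virtual screening

Docking is consumed, never executed: affinities arrive as a CSV of
(name, site-specific kcal/mol, optional blind kcal/mol), more negative =
better binding. The composite score is

score = w₁ · minmax(pIC50_pred) + w₂ · minmax(−affinity_site)

with min-max taken over the screened library's observed range (explicit
ranges may be supplied), weights summing to 1 (default 0.5/0.5), and the
result clipped to [0, 1]. The exact weighting used to produce any particular
published score set is not part of this package's contract; the implemented
score guarantees the published *properties* — range [0, 1], monotone in both
components, invariant to affine rescaling of either component. A degenerate
component range (all drugs equal) contributes its full weight to every drug,
with a warning. The off-site filter drops a drug when its blind affinity is
strictly better than its site affinity beyond a tolerance (default 0);
missing blind affinities pass "unchecked". Ranking is score-descending with
more-negative site affinity, then name, as tie-breaks.

## Assay analytics

**Dose-response.** Wells are blank-corrected (A590 − A690) and scaled to
percent of the mean vehicle signal. Fitting uses the four-parameter
logistic on log10 concentration,
viability = bottom + (top − bottom)/(1 + 10^(hill·(log c − log IC50))),
with multi-start initialization over both slope signs. `fit_plate` defaults
to the **normalized-response convention** — plateaus fixed at 100% and 0%,
slope and midpoint free — which is the standard treatment for
vehicle-normalized viability and the right model when the dilution series
does not reach the lower plateau (an 11-point 1/2 dilution from 780 μg/mL
with IC50 near 270 μg/mL never does; freeing the bottom there inflates the
IC50 error severalfold). The full 4-parameter fit remains available
(`normalized_response=False`, or `fit_4pl` with free plateaus). A flat
response (span < 5%) or optimizer failure raises an explicit error with
diagnostics — never a silent fallback. The 95% CI on IC50 is asymptotic: the
curve-fit standard error of log10 IC50 with a t critical value, mapped back
to the mass scale. Mass→molar conversion is μM = 1000·(μg/mL)/(g/mol) using
**free-base** molecular weights, which live in a config dictionary
(`FREE_BASE_MW`), not in code logic.

**qPCR.** Per replicate, ΔCt = Ct_target − mean(Ct of the endogenous
genes); ΔΔCt = mean ΔCt_treated − mean ΔCt_control; fold = 2^−ΔΔCt
(amplification efficiency assumed exactly 2; no efficiency correction).
The two-tailed unpaired t-test runs on the replicate ΔCt values — the scale
on which the normality assumption is most defensible — with equal variances
by default. Because which dispersion a bar chart should carry is genuinely
ambiguous, results expose both the SD of per-replicate fold changes and the
ΔΔCt standard error propagated onto the fold scale (fold·ln2·SE).

## Trajectory metrics

Superposition uses the Kabsch algorithm (SVD with a determinant correction
against improper rotations). RMSD series superpose every frame onto frame 0
(the analysis reference) over the chosen selection; RMSF superposes frames
the same way, then measures each atom's fluctuation about its time-mean
position and averages over the residue's atoms. Frame 0 (not the mean
structure) is the alignment reference throughout, with the reference frame
configurable.

Hydrogen bonds: a donor–acceptor pair counts when the donor-heavy-atom to
acceptor distance is ≤ 4.0 Å and some hydrogen covalently attached to the
donor (inferred by a 1.25 Å distance cut, since PDB carries no bond table)
makes a D–H···A angle ≥ 120°. The "donor–acceptor angle" is read as the
angle at the hydrogen — the chemically meaningful convention — with both the
distance and angle cut-offs configurable; hydrogen-free structures fall back
to distance-only counting, detectable by the caller. Donors are N/O with an
attached H; acceptors are any N/O. Hydrophobic contacts count **distinct
residues** from {G, A, V, L, I, P, F, M, W} with at least one heavy atom
within 4.0 Å of any ligand heavy atom — residue-level, never atom-pair
counts. Trajectory I/O is multi-model PDB via MDAnalysis; conversion from
binary engine formats is the user's concern.

## Synthetic data: what it emulates, and what it does not

The bioactivity generator builds molecules from a fixed lattice: 10
two-attachment aromatic scaffolds × 20 C7-alkyl × 20 C8-alkyl substituents
(4000 distinct structures, assembled with RDKit molzip and verified
distinct). Latent activity is an exactly linear function of the fragment
composition — a dominant bimodal scaffold-group term (±0.73 of the half
activity range) plus small within-group and substituent terms — with
Gaussian observation noise (default 0.3 pIC50 units) on top. Defaults span
pIC50 ≈ 5–10, the range typical of a curated inhibitor series.

The fragment sets were chosen so the *base* library's MW and LogP are exact
two-point distributions (two scaffold mass/LogP classes; each substituent
set shares one molecular formula and one Crippen atom-type profile). This is
deliberate: under a ±1.5 SD trim a bounded unimodal sample always risks
losing honest tail compounds, whereas a two-point distribution keeps every
base compound within ~1.0 SD of its column mean. Planted defects are
therefore *exactly* separable — duplicates (appended later-year copies),
salts (appended counter-ions), and property outliers (a C18–C22 chain for
MW, a similar-mass polyol for LogP, a ±2.2-half-range activity for pIC50)
are recovered with 100% sensitivity and zero false removals at zero noise,
and the tests assert exactly that.

What passing these tests shows: the pipeline's rules are implemented
correctly and recover planted structure through the full chain. What it does
not show: performance on real medicinal chemistry. Real libraries have
unimodal, skewed property distributions (so a ±1.5 SD trim *will* remove
honest compounds), activity cliffs that no linear fragment map reproduces,
and assay noise that is neither Gaussian nor homoscedastic. The synthetic
benchmark's R² ≈ 0.95 at default noise reflects the generator's linearity,
not an expectation for real data. Dose-response plates, Ct tables and toy
trajectories likewise emulate the *statistical shape* of their real
counterparts (4PL with Gaussian % noise; Ct shifts of exactly −log2 fold;
planted exact geometries with isotropic jitter), not plate-position effects,
amplification-efficiency drift, or real conformational dynamics.

## Problem sizes and defaults

The pipeline demo and acceptance computations use 400 generated compounds,
64 embedding dimensions and 10-fold CV — large enough that fold sizes,
leverage ranks and outlier censuses behave like the full-scale setting,
while a complete run stays interactive on one core. Dose-response
recovery uses the assay's own design (11-point 1/2 dilution from 780 μg/mL,
sextuplicate, 2% viability noise); qPCR recovery uses triplicates at 0.1
cycle noise. All randomness flows from explicit integer seeds: generators
use `numpy.random.default_rng(seed)`, fold shuffling uses the seeded
scikit-learn `KFold`, and every report records its seed.

## Known limitations

* The leverage approach assumes a linear-design notion of extrapolation;
  it is kept even though the selected model is non-parametric, because that
  is the standard Williams-plot protocol. Distance- or density-based domains
  are out of scope.
* The composite screening score is a declared surrogate with the published
  range and monotonicity properties; absolute score values depend on the
  library's observed ranges and on the weights.
* Grid search re-uses the same 10-fold protocol for inner evaluation; no
  nested CV, so grid-selected performance estimates are mildly optimistic.
* The hashed embedding table carries no chemistry beyond substructure
  identity; two similar substructures get unrelated vectors. It preserves
  the summation algebra, not chemical smoothness.
* PDB round-trips quantize coordinates to 0.001 Å and the H-attachment
  inference assumes no N–H/O–H bond stretches beyond 1.25 Å.
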