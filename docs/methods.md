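# Methods

This note documents the models, conventions and numerical choices behind
flavopot, and what its synthetic test-bed does and does not demonstrate.

## Structure model and flavin geometry

PDB text is parsed with gemmi into a light internal model (chains of
residues of named, element-typed atoms). Conventions:

* only the first model of multi-model files is read (the target data are
  X-ray structures);
* alternate locations: the highest-occupancy altloc is kept per atom name,
  ties preferring altloc `A`;
* hydrogens are retained in the model but excluded from every distance
  computation and atom count, so descriptor values do not depend on
  whether a deposition includes hydrogens;
* waters and non-flavin hetero groups never enter environment descriptors,
  which are defined over protein amino acids only.

A flavin site is any FMN/FAD hetero group. The isoalloxazine ring system
is taken inclusively as 17 atoms — N1, C2, O2, N3, C4, O4, C4A, N5, C5A,
C6, C7, C7M, C8, C8M, C9, C9A, N10 — i.e. the three fused rings plus the
two methyls and the two carbonyl oxygens (FAD's C4X/C5X names are mapped
to C4A/C5A). The barycenter is the unweighted mean of these 17 positions.
The "owning" chain of a cofactor is the protein chain with the smallest
any-heavy-atom distance to the barycenter; this nearest-chain rule is a
package convention (the association is not derivable from the PDB itself)
and is the chain used for the sequence-based blocks.

## Descriptor schema

The 246-vector is: 3 scopes × 55 region descriptors, 3 ring-proximity
atom counts, 28 + 28 N5 descriptors, 21 CTD values, and pH. Exact choices
that the counts force but do not uniquely determine:

* The 55 per-region values are 20 residue-type counts + 11 class counts
  (total, polar, apolar, charged, positive, negative, hydrophobic,
  aromatic, small, H-bond donor, H-bond acceptor) + 8 property sums +
  8 property means + 4 side-chain element-count sums (N, O, C, S) +
  4 derived counts (net formal charge = positives − negatives; aromatic
  ring-atom, donor-atom and acceptor-atom counts). The schema is fixed in
  `descriptors.region_feature_names()` and the naming contract
  (`Protein.X` / `Bar.X` / `Ring.X`, `N5_nearest_X`, `Around_N5.X`,
  `Nitrogen_Around`, `Oxygen_Around`, `Carbon_Around`) is bit-exact in CSV
  headers.
* Region membership uses *any* heavy atom of a residue (not Cα only):
  side-chain contacts are what interact with the flavin.
* The `Ring` scope is the union of the per-ring-atom spheres, which is
  what keeps the repeated set at 55 (per-atom replication would multiply
  it); the three `*_Around` atom counts count each protein atom once even
  when it falls into several spheres.
* The 28 N5 descriptors are a 20-dim residue-identity block plus the 8
  property values; the `Around_N5` variant sums them over the nearest
  residue and its two neighbours in the owning chain's residue order
  (chain termini contribute the residues that exist). Exact distance ties
  resolve to the first residue in structure order.
* Empty regions produce all-zero blocks; means use the 0-convention
  rather than NaN so design matrices stay dense. Region sums iterate
  residues in sorted order so results are bit-identical for any input
  order.
* Distances are plain Euclidean in Å: no periodic images, no symmetry
  mates.

CTD uses the standard three-class Dubchak partitions; exactly one
attribute (hydrophobicity by default, configurable) contributes its
3 + 3 + 15 = 21 values, computed on the owning chain's sequence.
Distribution percentiles are the 1st, ⌈25 %⌉-th, ⌈50 %⌉-th, ⌈75 %⌉-th and
last occurrence positions, as % of sequence length; an absent class
contributes zeros.

## Property table

The per-residue scales (volume, flexibility, hydrophobicity, steric
hindrance, polarity, isoelectric point, helix/sheet propensity) are a
bundled TSV assembled from standard published sets (Zamyatnin;
Bhaskaran–Ponnuswamy; Kyte–Doolittle; Charton; Grantham; Zimmerman;
Chou–Fasman). Side-chain element counts follow residue chemistry exactly
(ARG n_N = 3, HIS n_N = 2, …). Class flags may overlap (HIS is positive
*and* aromatic; membership of CYS in "polar" and the Taylor "small" set
are documented conventions). The table is versioned and swappable via
`PropertyTable.from_file`; swapping scales changes feature values but not
pipeline structure.

## Preprocessing and model comparison

Pipeline order is fixed: impute missing pH with the training mean → drop
zero-variance columns, then drop the later column of any pair with
|Pearson r| > 0.99 against a retained column (absolute correlation;
deterministic column-order tie-break) → for LR/SVR/KNR/GPR only,
standardize and select features by elastic net, keeping non-zero
coefficients of the cost (1/2n)·Σ(y − Xw)² + αρ‖w‖₁ + (α(1−ρ)/2)‖w‖₂²
solved by coordinate descent at tol 1e-6. An empty selection falls back
to all filtered features with a warning. (α, ρ) are searched jointly with
each estimator's grid (α ∈ {10, 100}, ρ ∈ {0.5, 0.75, 1}). Tree models
(RF, XGB) skip scaling/selection and carry a max-depth grid {3, 4, 5}.
Every statistic is fitted inside the training part of each split/fold, so
no test-row information reaches fitted state.

Default evaluation is 10 repetitions of a random 80/20 split, each with
an inner 5-fold grid search minimizing MAE (ties resolve to grid order)
and a refit on the full 80 %; a true outer-k-fold protocol is available
as a switch (`protocol="outer-kfold"`). Metrics are MAE, RMSE, the
coefficient of determination (the "R2" reported; squared Pearson is the
other possible reading and can be derived from the predictions), and
Spearman correlation. Pairwise model comparison uses the two-sided
Mann–Whitney U test on per-repetition metric samples at p < 0.05; two
identical constant samples are assigned p = 1. All repetition seeds
derive from a single master seed via `numpy.random.SeedSequence`, making
every result bit-reproducible.

## Shapley interpretation

Attributions are additive per-feature scores φ (mV) with base value φ₀
such that φ₀ + Σφ equals the prediction for every sample (local
accuracy). Implementations:

* linear models: closed form φ_ij = w_j (x_ij − μ_j) with μ the
  background means;
* sklearn decision trees / random forests: the polynomial-time
  path-dependent TreeSHAP recursion, implemented here in double precision
  and validated against brute-force subset enumeration over each tree's
  conditional expectation function;
* XGBoost: the same recursion run over the parsed booster trees in double
  precision. The booster's native contribution predictor implements this
  algorithm in float32 and is used as an independent cross-check in the
  tests; recomputing in float64 keeps local accuracy at ~1e-13 mV on
  mV-scale outputs, where float32 accumulation alone drifts to ~5e-4.
  Local accuracy is asserted against the double-precision evaluation of
  the fitted trees; the booster's float32 `predict` agrees with that
  evaluation to accumulation rounding.
* other models: exact Shapley by subset enumeration against a background
  sample for ≤13 features, otherwise seeded coalition sampling with a
  kernel-weighted regression constrained to satisfy local accuracy.

The attribution background is the explained data (training-feature means
for the linear closed form; training cover weights for trees). Ranking is
by mean |φ| descending, name-order on exact ties. The final-model
workflow refits XGB on all rows at a chosen (r1, r2) — (13, 3) by
default — re-searches hyperparameters by inner CV, and exports the
summary (feature, mean |φ|) and per-sample attribution CSVs plus a
bar/violin figure.

## Synthetic test-bed

Two generators make every stage testable without external data.

**Structures.** An idealized planar isoalloxazine (three fused 1.40 Å
hexagons with methyls and carbonyls; internal coordinates in
`synthetic.isoalloxazine_template`) is written as an FMN/FAD HETATM group,
with protein residues placed at controlled distances from the barycenter
or a named ring atom. Residues carry backbone N/CA/C/O plus the full
heavy side-chain atom set (so element counts are chemically exact), all
atoms within 1 Å of the anchor; distinct placements keep ≥2 Å separation
with bounded rejection sampling. Geometry is *not* a protein fold — it is
exactly as real as distance-based descriptors require, no more.

**Planted feature tables.** Standard-normal features over the 246 names,
with exact duplicate columns and a constant column planted to exercise
the correlation/variance filter, a missing fraction of pH, and labels
E_m = μ + Σ c_j x_j + ε. Defaults are the study conditions: n = 141,
5 informative features, noise sd 20 mV, label mean −223 mV and sd
109 mV. Auto-chosen coefficients are equal-magnitude, alternating-sign,
calibrated so the realized signal sd is exactly √(109² − 20²) and the
realized noise vector is standardized to exactly 20 mV — the label
moments then sit at their targets up to the small signal–noise sample
covariance, and the analytic MAE floor of an ideal predictor, √(2/π)·σ ≈
16 mV, is exact by construction. User-supplied coefficients are honoured
verbatim (no rescaling).

What passing tests show — and what they do not. On these fixtures the
pipeline provably recovers everything the generators plant: band
membership, atom counts, filter targets, sparse supports (elastic-net
recall 1), near-floor linear MAE, and top-ranked informative features
under XGB + Shapley. They do not show predictive accuracy on real
flavoproteins: real descriptors are correlated, non-Gaussian and tied to
fold geometry, real labels are not linear in the descriptors, and the
curated experimental dataset is outside this repository. The pipeline's
numeric contracts transfer; its measured errors on synthetic data do not.

## Problem sizes and runtime choices

Tests and the acceptance script use the study-scale planted dataset
(141 × 247) but reduced hyperparameter grids (documented in each call
site; e.g. XGB at 100 rounds, depth ∈ {3, 5}) and 2–10 repetitions, which
keeps a full run on one CPU in tens of seconds to a couple of minutes
while exercising identical code paths. The full study grids in
`evaluation.default_estimator_specs()` remain the library defaults.

## Known limitations

* Covalently bound flavins, structure-quality checks and resolution
  filtering are out of scope; descriptors of explicit cofactor–protein
  interaction patterns (H-bonds, stacking) are deliberately excluded.
* No pH-dependent protonation assignment: pH enters only as a feature.
* The bundled property scales are standard but not unique; absolute
  feature values (and hence fitted coefficients) change under other
  scales.
* The nearest-chain rule for multi-chain cofactor association is a
  heuristic; interleaved-chain edge cases may warrant manual assignment.
* Kernel-sampling attributions (non-linear, non-tree models with >13
  features) are estimates, not exact Shapley values.
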