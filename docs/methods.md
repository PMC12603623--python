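# Methods

`crosspath` implements a cross-species translatability workflow for bulk
transcriptomics: it asks which disease-associated pathways carry
phenotype-defining information in *both* an animal model and human patients,
without ever mapping homologous genes.  The unit of comparison is the
pathway, named identically in both species' gene-set collections while the
underlying gene universes stay disjoint.

## Pipeline overview

1. **Gene-set harmonization.** Both species' GMT collections are restricted
   to pathway names present in both, with sizes strictly between 5 and 1000
   genes in each.  Pathway order is lexicographic everywhere downstream, so
   loadings and weights are comparable across runs.
2. **Per-sample pathway enrichment (NES).** Each sample is converted to a
   ranked gene list by `log2((x + eps) / (control_mean + eps))` against the
   mean of its dataset's healthy group (a healthy sample's own value is part
   of that mean; no leave-self-out by default — an optional flag exists for
   sensitivity analysis).  Per pathway the classic weighted
   Kolmogorov–Smirnov running sum gives the enrichment score ES (hit weight
   `|r|^p`, `p = 1`), normalized to NES by the mean |ES| of same-sign random
   gene sets of equal size (1000 draws; the draws depend only on the seed
   and the pathway, never on the sample, so the matrix is equivariant under
   sample permutation and bit-reproducible under a fixed seed).
3. **Per-pathway Yeo–Johnson transform.** Each NES row is power transformed
   (lambda by bounded maximum likelihood on [-5, 5], tolerance 1e-6) and
   standardized to mean 0, variance 1.  The per-pathway (lambda, mean, sd)
   triples form a frozen model; new data are pushed through these exact
   parameters without refitting.
4. **Sparse principal components on the model species.** The loadings
   minimize `1/2‖X − XBAᵀ‖² + α′‖B‖₁ + β′/2‖B‖²` with `AᵀA = I`, solved by
   alternating proximal soft-threshold steps in B with orthogonal-Procrustes
   steps in A (variable projection), initialized at the top-k PCA loadings
   (fully deterministic).  **Penalty scale:** the user-facing α and β are
   dimensionless — internally multiplied by the leading squared singular
   value of X (`α′ = α σ₁²`).  This follows the reference variable-projection
   implementations and is what makes a grid such as 1e-6 … 1 meaningful on
   any data scale; at `α = β = 0` the model is exact PCA.  Components are
   ordered by adjusted explained variance and sign-fixed (largest |loading|
   positive).
5. **Choosing α.** For each grid α (default: 10 log-spaced values from 1
   down to 1e-6) and each leave-one-out fold (fold re-centered), the model
   is refit and the cumulative adjusted variance of the first three
   components recorded; the chosen α is the largest with mean ≥ 50% of total
   variance.  When *no* grid value reaches that absolute floor — which
   happens whenever the sample count is large enough that variance spreads
   over many comparable directions (with 16 samples and 100 near-independent
   pathways the ceiling is ≈ 34% even at α = 0) — the workflow applies the
   same floor *relative to the attainable maximum*: the largest α whose mean
   LOOCV cumulative variance is ≥ threshold × the best grid value, flagged
   `alpha_threshold_met: false` in the report.  A strict mode aborts
   instead.  The relative floor deliberately keeps the model in the sparse
   regime: with dense components the downstream shared-component restriction
   would filter nothing, and the species-blind refinement could assemble
   false "translatable" sets by pairing one pathway per species (each
   separating only its own species' samples).
6. **Projection and species-specific SVMs.** Human data are projected as
   `Y·B`; variance per component is attributed sequentially (QR-adjusted:
   each component credited only with score variance orthogonal to its
   predecessors — plain column variance is available behind a flag).  Per
   species an L1-regularized squared-hinge linear SVM with balanced class
   weights is trained on the component scores; C is chosen by pooled-LOOCV
   F1 over 50 log-spaced values in [1e-3, 1e2], ties to the smallest C.
   The solver is liblinear's primal coordinate descent, whose objective
   includes the intercept in the L1 term — the convention kept here and
   verified against an independent split-variable convex solver.
7. **Translatable pathways.** Components with nonzero weight in *both*
   species' SVMs are the shared set; pathways loading on a shared component
   are candidates.  Candidates' raw NES from both species are pooled (no
   species column — the classifier cannot see the species), jointly power
   transformed, and a second L1 SVM is trained on phenotype; its
   nonzero-weight pathways are the final translatable set.  An empty shared
   set short-circuits to the status `"no translatable pathways"`;
   `relax_alpha` optionally walks α downward (20 points per decade to 1e-6)
   until an overlap appears.
8. **Drug-response qualification.** A treated dataset (treated animals plus
   their own untreated controls) is pushed through the *frozen* untreated
   artifacts: NES with the same enrichment parameters (fold change against
   the arm's own control group), the frozen power transform, the fixed
   sparse PC model, and the already-trained mouse SVM (the human SVM is an
   alternative behind a flag).  Reported are the fraction of treated samples
   classified diseased and of controls classified healthy.

## Synthetic two-species studies

The generator emulates the data regime the workflow targets: two species
with disjoint gene universes and shared pathway names; 100 pathways of 12
genes each plus 800 background genes; 8 samples per phenotype per species;
3 shared-dysregulated pathways and 4 species-specific ones per species;
log-normal expression (log-scale baseline N(5, 1) per gene) with i.i.d.
log-scale noise (sd 1) and an additive log-scale disease shift of
`effect_size × noise_sd` (default 1.5) on every gene of a dysregulated
pathway.  Additive log-scale effects are multiplicative on intensities, so
planted effects translate monotonically into the log2-fold-change ranking.
`shared_effect_size` can silence the shared pathways for null studies while
species-specific effects stay on.  Treatment arms contain diseased-type
samples with the disease shift scaled by `(1 − efficacy)` plus fresh
controls (5 treated / 4 controls by default, the shape of a small
qualification arm).

What the generator does *not* emulate: correlated pathway membership (real
gene sets overlap; here they are disjoint), batch effects, probe-level
artifacts, and biologically structured co-expression beyond the planted
phenotype axis.  Consequently the background pathway space is nearly
isotropic — harder for the variance-based α rule than real data, where
co-expression concentrates variance in few components — and passing tests
show the machinery recovers planted structure under honest noise, not that
real cohorts of this size would behave identically.

## Numerical choices

* Enrichment tie-breaks: equal ranking metrics order by gene id;
  a magnitude tie between the positive and negative running-sum extrema
  (within 1e-9) resolves to the negative extremum, so structurally symmetric
  deviations do not flip sign on floating-point noise.
* All-zero hit weights fall back to unweighted (`1/N_h`) hit increments.
* Duplicate gene rows collapse to the row with the greatest mean intensity.
* Sparse PCA stops on relative objective change < 1e-6 or 1000 iterations;
  the Procrustes step uses the k×k Gram eigendecomposition with an SVD
  fallback for rank-deficient `GB`.
* LinearSVC runs at tolerance 1e-6 with `random_state=0`; much tighter
  tolerances make liblinear's shrinking heuristic stall without improving
  the optimum (verified against the convex oracle).
* Text round-trips write floats as `%.17g` and read with
  `float_precision="round_trip"`, so expression tables survive disk exactly.

## Known limitations

* The 50%-in-three-components rule is calibrated for very small cohorts
  (3–5 samples/group); with more samples it becomes unattainable and the
  relative-floor fallback takes over.  A single α then serves two competing
  goals.  *Sparse* components make the shared-component restriction a real
  filter, keep the frozen drug-response classifier high signal-to-noise
  (out-of-sample discrimination of treated arms is then essentially
  perfect), and keep the shared-null false-positive rate lower — but their
  support can prune the weakest genuinely shared pathways out of the
  candidate set, capping recall of planted translatable pathways at roughly
  0.55 under the default synthetic conditions (precision stays ≈ 0.8).
  *Dense* components give
  full candidate coverage (recall ≈ 0.9) but carry noise-fitted background
  loadings whose training-time class separation does not generalize: fresh
  samples see a score signal-to-noise ratio near 1 plus a common per-arm
  shift from the small control-group fold-change reference (occasionally
  amplified by Yeo–Johnson extrapolation), making frozen-threshold
  classification of treated arms unreliable, and the vacuous candidate
  filter lets species-blind refinement assemble false translatable sets on
  shared-null data.  The package resolves the trade-off in favor of the
  sparse regime, which is where the method's own logic operates.
* Shared-component detection has limited specificity at this scale: under a
  shared-null (species-specific effects only), the human-side SVM — whose C
  is picked by maximizing a pooled-LOOCV F1 over a fine grid on 16 samples —
  still keeps several components with nonzero weight, and intersects the
  mouse disease component by chance in roughly 40% of runs, yielding
  false-positive "translatable" sets.  The workflow, following its source
  design, places no classifier-quality gate before the intersection; users
  should read the per-species LOOCV metrics in the report before trusting a
  small overlap.
* NES normalization uses gene-sampling nulls only; no p-values or FDR are
  computed, and none are needed downstream.
* The combined refinement step assumes both species contribute both
  phenotypes; heavily unbalanced pools would need the class weights
  revisited.
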