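# crosspath

Cross-species pathway translatability for bulk transcriptomics.

Animal models of disease rarely mirror human biology gene by gene, and
mapping homologs across species is itself error-prone.  `crosspath` sidesteps
genes entirely: it compares species at the *pathway* level and asks which
pathways carry phenotype-defining information in **both** an animal model
and human patients — the "translatable" pathways that make the animal model
a useful proxy for trials.  It also provides the qualification counterpart:
classifying drug-treated animals through the frozen, untreated-data pipeline
to ask whether a treatment actually moves the disease signature.

The pipeline, stage by stage:

1. **Per-sample pathway enrichment.**  Each sample is ranked by
   `log2` fold change against its dataset's healthy-group mean, and each
   pathway gets a normalized enrichment score (NES): the weighted
   Kolmogorov–Smirnov running-sum statistic, divided by the mean |ES| of
   same-sign random gene sets of equal size.  Result: a pathways × samples
   NES matrix per species.
2. **Yeo–Johnson power transform** per pathway to mean 0, variance 1, with
   the fitted parameters frozen for later reuse.
3. **Sparse principal components** fit on the animal-model matrix —
   minimizing ½‖X − XBAᵀ‖² + α′‖B‖₁ over sparse loadings B and an
   orthonormal rotation A — with the penalty chosen by leave-one-out
   cross-validation (largest α keeping ≥ 50% of total variance in the first
   three components).  Human data are projected into the same coordinates by
   matrix multiplication; no homology needed, only shared pathway names.
4. **Species-specific sparse classifiers.**  One L1-regularized linear SVM
   per species on the component scores (C by pooled-LOOCV F1, balanced
   class weights).  Components used by *both* species' classifiers are the
   shared, candidate-defining set.
5. **Refinement.**  Candidate pathways' raw NES from both species are
   pooled — with no species label — re-transformed, and a second L1 SVM is
   trained on phenotype alone; its nonzero-weight pathways are the final
   translatable set.
6. **Drug-response qualification.**  Treated samples pass through the frozen
   transforms, the fixed component model and the trained SVM; reported is
   the fraction of treated animals still classified diseased.

A first-class synthetic-study generator (two species, disjoint gene
universes, planted shared and species-specific pathway dysregulation,
tunable drug efficacy) makes every stage testable end to end with known
ground truth.  See `docs/methods.md` for the model details and numerical
conventions.

## Worked example

The numbered drivers under `analysis/` walk one synthetic study through the
whole workflow, writing tables under `results/`:

```bash
python analysis/01_simulate_study.py
python analysis/02_pathway_enrichment.py
python analysis/03_sparse_pca.py
python analysis/04_species_classifiers.py
python analysis/05_translatable_pathways.py
python analysis/06_drug_response.py
```

The study (seed 1) plants three shared-dysregulated pathways among 100.
Enrichment turns the planted log-scale expression shifts into a mean
diseased-vs-healthy NES gap of ≈ 2.9 in both species (background ≈ 0.04).
The end-to-end run then reports:

```
status: ok
alpha used: 0.01 (absolute floor met: False)
mouse SVM components: ['sPC1'] (LOOCV accuracy 1.00)
human SVM components: ['sPC1', 'sPC11', 'sPC12', 'sPC14', 'sPC3'] (LOOCV accuracy 0.88)
shared components: ['sPC1']
candidate pathways: 7
translatable pathways: ['PW_0013', 'PW_0024', 'PW_0042', 'PW_0086', 'PW_0088']
planted shared pathways: ['PW_0013', 'PW_0046', 'PW_0086']
recovered 2/3 planted; 3 false positives
combined species-blind SVM: C=1.456, LOOCV accuracy 1.00, F1 1.00, AUC 1.0
```

Both species' classifiers rely on sparse component sPC1, whose seven-pathway
support becomes the candidate set; the species-blind SVM keeps five of them,
including two of the three planted translatable pathways (the third was
pruned by the sparse component — the coverage/sparsity trade-off discussed
in `docs/methods.md`).  The drug-qualification step then pushes simulated
treatment arms through the frozen pipeline:

```
efficacy 0.0: 1.00 of treated classified diseased (5/5); 1.00 of controls classified healthy
efficacy 0.5: 1.00 of treated classified diseased (5/5); 1.00 of controls classified healthy
efficacy 1.0: 0.00 of treated classified diseased (0/5); 1.00 of controls classified healthy
```

— an ineffective drug (efficacy 0) leaves the disease signature fully
detectable, a completely effective one removes it.

The same stages are available as a command-line suite for on-disk data
(TSV expression + metadata, GMT gene sets):

```bash
crosspath simulate --seed 1 --out study/
crosspath translate --mouse-expression study/mouse_expression.tsv ... --out run/
crosspath evaluate-drug --artifacts run/ --expression treated.tsv ... --out drug/
```

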