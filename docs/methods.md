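# Methods

## The measurement problem

A gene-targeted panel estimates a patient's tumor mutational burden
(TMB) from the mutations that fall inside its gene set: the panel-based
TMB is `x = (qualifying mutations in panel genes) / (panel size in Mb)`
and the WES-based reference is `y = (qualifying mutations exome-wide) /
(exome size in Mb)`. Panel evaluation asks how close x tracks y across a
cohort. `panelgauge` implements two cohort-level summaries and the
machinery around them.

## Linear fit and R²

The least-squares line `y = a·x + b` is fitted with the closed forms
`a = Σ(xᵢ−x̄)(yᵢ−ȳ)/Σ(xᵢ−x̄)²`, `b = ȳ − a·x̄`, and
`R² = 1 − SSR/SST` with `SSR = Σ(yᵢ−a·xᵢ−b)²`, `SST = Σ(yᵢ−ȳ)²`. The
implementation is deliberately self-contained (no stats-library
delegation) so the whole report pipeline can be cross-checked against an
independent solver; the test suite verifies slope/intercept against
`numpy.linalg.lstsq` and `scipy.stats.linregress` to 1e−9 relative, the
R²-equals-squared-Pearson identity, and that residuals sum to zero.

R²'s weakness on TMB data is structural. Cohort TMB distributions are
long-tailed: most patients sit below 10 mutations/Mb while a small
hypermutated tail exceeds 50 and can exceed 400. Both SST and the
residuals are dominated by that tail — two patients with identical
relative bias but TMBs differing by a factor k contribute squared
residuals differing by ≈ k². A handful of extreme patients can
therefore hold R² near 1 for a panel that estimates the typical patient
poorly.

## Angular distance

Mapping each patient's (x, y) to polar coordinates, `r = √(x²+y²)`,
`φ = arctan(y/x)`, a perfect estimate lies on the diagonal φ = π/4. The
angular distance `θᵢ = |π/4 − φᵢ|` measures the patient's relative
estimation bias on a scale from 0 (exact) to π/4 (panel detects
nothing); the panel score is the unweighted mean `θ̄ = Σθᵢ/n`. θ is
symmetric in x and y, scale invariant, and strictly increasing as x
diverges from y — so every patient counts equally regardless of TMB.
Useful reference points: a 20% relative bias gives θ = 0.1107 and 10%
gives θ = 0.0526 (by `arctan(r) + arctan(1/r) = π/2` the under- and
over-estimation cases coincide).

Degenerate conventions, logged when triggered:

* `(x, y) = (0, 0)` → θ = 0. The ratio y/x is 0/0-undefined; a patient
  with zero mutations correctly reported as zero is treated as a
  perfect prediction.
* `x = 0, y > 0` → θ = π/4 (the arctan limit): the panel missed
  everything.
* `bias_ratio = x/y` is NaN (excluded from summaries, counted in logs)
  when y = 0.

## Mutation counting

A TCGA-style MAF annotates 16 variant classifications. Four fall
outside the coding region (Intron, RNA, 3'Flank, 5'Flank) and are never
counted. Two counting modes are built in:

* **total_point** (F1CDx-style): {Missense_Mutation, Silent,
  Nonsense_Mutation, Nonstop_Mutation, Translation_Start_Site,
  Splice_Site}, restricted to SNP records. Indels are excluded because
  they are not point mutations; UTR classes because they are not
  protein-coding.
* **nonsynonymous** (MSK-IMPACT-style): total_point minus Silent.

Assay definitions vary, so both class sets are constructable via
`MutationMode` rather than hard-coded only. Whether splice-site and
translation-start events belong in "point mutations in the coding
region", and whether indels belong in a nonsynonymous count, differ
between vendors; the defaults above are one defensible reading and the
tests pin them explicitly.

Hypermutated patients are those with WES-level **total-point** TMB
strictly above 50 mutations/Mb. The basis is deliberately independent
of the evaluation mode so the hypermutated/non-hypermutated split of a
cohort is the same whichever mode is being scored.

Gene-model coordinates: `cds_locations` intervals are inclusive on both
ends (length = end − start + 1). Intervals of the same gene across CCDS
rows are unioned, so overlapping transcripts never double-count; the
exome denominator defaults to the union length of the loaded universe
and is user-overridable (per-transcript summation would give a slightly
larger figure, and published totals do not always state which was
used). Sample barcodes are truncated to 12 characters (TCGA patient
level) by default, configurable. Duplicate MAF rows are counted — TMB
counts rows, not distinct loci.

## In-silico panel simulation

Each simulated panel draws `N ~ Uniform{1..max_genes}` and then N
distinct genes uniformly without replacement (gene sampling is uniform,
not length-weighted); the panel footprint is the summed CDS length of
the sampled genes. Each panel is evaluated on the
hypermutation-included cohort and the non-hypermutated subset,
yielding R² and θ̄ per panel plus an optional TMB-high/low
classification accuracy restricted to a WES-TMB band (default band
[9, 11] around the clinical 10 mutations/Mb threshold; "high" means
TMB ≥ threshold, and the band is closed on both ends).

Per-panel child seeds are spawned from the master seed
(`SeedSequence(seed).spawn(n_panels)`), so runs are bit-reproducible
and panels independent of evaluation order; duplicate panels across
draws are possible and allowed. The full-replication setting is 10,000
panels with max_genes = 3,000 on a ~19,600-gene coding-region catalog;
the test suite runs 200 panels on a 500-gene synthetic universe with a
1,000-patient cohort, which reproduces the qualitative size–performance
trends in a few seconds.

## Synthetic cohort generator

The generator produces the statistical structure the evaluation method
assumes, without attempting biological realism:

* **Rates.** Each patient draws a true coding point-mutation rate λ
  (mutations/Mb): with probability `hyper_fraction` (default 0.03) from
  `50 + LogNormal(ln 80, 0.6)` (mean ≈ 146, always above the cutoff),
  otherwise from `LogNormal(ln 2.6, 1.2)` (median 2.6, mean ≈ 5.3).
  The mixture gives an overall mean ≈ 9.6 and median ≈ 2.6
  mutations/Mb — the long-tailed, right-skewed shape of pan-cancer WES
  cohorts. These are qualitative calibrations, not fits to any dataset.
* **Counts and placement.** The patient's emitted mutation count is
  `Poisson(λ·A / (1 − noncoding_fraction))` with A the region size in
  Mb (defaulting to the universe's total CDS length); each mutation
  lands on a gene with probability proportional to its CDS length.
  Defining λ as the *coding point* rate and inflating the total by the
  non-coding share keeps WES total-point TMB an unbiased estimator of
  λ, which the parameter-recovery tests verify (cohort-level relative
  bias < 2% at 2,000 patients on an exome-scale universe).
* **Classes.** Each record is Silent with probability `silent_fraction`
  (default 0.30), one of the non-counted classes (Intron, UTRs, RNA,
  flanks) with probability `noncoding_fraction` (default 0.10), else a
  nonsynonymous class (missense-dominated). Non-coding records are
  emitted, not skipped, so the class filters are exercised end-to-end.
  All generated records are SNPs.
* **Universe.** Synthetic gene models draw CDS lengths log-uniformly
  from 300–10,000 bp (1–3 exons laid along a synthetic chromosome) and
  round-trip through the CCDS reader. A 500-gene universe (~1.4 Mb)
  serves the simulation tests; recovery tests use 2,000 genes of
  8–30 kb (~30 Mb) so the exome scale matches real WES denominators.
* **Truth sidecar.** The per-patient table (patient_id, λ, emitted
  count, realised hypermutation flag) is written alongside the MAF so
  tests never reach into the generator's internals. Patients whose
  Poisson draw is 0 cannot appear in a MAF; they are present in the
  truth table and enter oracle comparisons as (0, 0).

What the generator does *not* model — mutational signatures, hotspot
genes, per-cancer-type structure, sequencing depth, germline
contamination — bounds what passing tests show: they certify the
metrics, the filtering and the simulation logic under the assumed
sampling model, not panel performance on any real assay.

A separate Monte-Carlo oracle, `expected_panel_theta`, computes E[θ]
for a single patient directly from the thinning model (exome count
Poisson, panel count binomially thinned by the panel's length
fraction). End-to-end tests check the pipeline-measured θ̄ against this
oracle; it also exhibits the negative TMB–θ relationship (high-TMB
patients are well served by small panels, low-TMB patients need large
ones).

## Numerical choices

* Slope uses the centred sums (numerically stabler than the raw-moment
  form, algebraically identical).
* Identity assertions (residual sum, R²-vs-Pearson) use 1e−9 relative
  tolerance.
* Regression on a degenerate split (fewer than 2 patients, constant x,
  or zero y-variance) reports NaN with a warning; θ̄ is still reported.
  NaN is likewise the undefined-marker for empty accuracy bands and
  zero-WES bias ratios.
* The identity panel (panel = whole universe, size = exome size) yields
  x = y exactly, hence θ̄ = 0 and R² = 1 exactly, not within tolerance —
  used as an exactness check on the whole pipeline.

## Problem sizes

Test-suite defaults: 500-gene universe, 1,000-patient cohort, 200
panels for the size-trend checks; 100 matched panels for the
mode-comparison; 2,000 patients on a ~30 Mb universe for parameter
recovery. These desk-scale settings reproduce every qualitative claim;
the CLI exposes the full-scale settings (10,000 panels, max 3,000
genes) for use with a real cohort MAF and CCDS catalog.

## Known limitations

* Panel footprints are exonic (CDS) sums; intronic content of
  commercial panels is representable only via an explicit
  `--panel-size-mb` override.
* No germline-database (dbSNP/COSMIC) filtering; records are assumed
  somatic and pre-annotated.
* No confidence intervals on R² or θ̄ — both are reported as point
  values.
* Gene symbols are matched case-sensitively, with no alias resolution.
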