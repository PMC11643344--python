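# Methods

`gwaskit` implements the standard single-trait association and genomic
prediction workflow for diploid, biallelic marker panels (crop
diversity panels, breeding populations, model-organism collections).
This note records the models, the numerical choices, and what the
synthetic validation data can and cannot establish.

## Genotype representation and I/O

Genotypes are additive dosages: the per-sample count of A1 copies,
where A1 is the minor allele of the loaded cohort (ties break toward
the VCF ALT allele, or toward the listed A1 in a BIM file). Dosages are
`int8` with −1 as the missing sentinel.

The PLINK 1 binary codec is implemented directly (no maintained reader
was available in the target environment): magic bytes `6C 1B 01`,
SNP-major, 2-bit codes `00/01/10/11` = hom-A1 / missing / het / hom-A2,
samples packed low-order bit-pair first, zero pad bits. Writing then
reading is a bit-exact identity, property-tested over random matrices.

VCF parsing (via cyvcf2) keeps only biallelic, non-symbolic records;
multiallelic and symbolic sites are skipped and tallied, never split.
Any missing allele slot (`./.`, `0/.`) makes the whole genotype
missing — a conservative, deterministic rule. Positions are copied
verbatim (1-based); there is no liftover or strand handling.

Phenotypes are delimited text (`IID value` or `FID IID value`,
comma/tab/whitespace auto-detected). Matching is by individual ID alone
by default (`match_on="fid_iid"` for the strict pair), `NA` and `-9`
are missing, and other non-numeric values are masked and counted. Zero
matches raises, since it almost always signals an ID-scheme mismatch.

## Quality control

Per-variant MAF, missing rate and heterozygosity are computed over
non-missing calls. Filters are boundary-inclusive — keep when
`maf >= maf_min` and `missing_rate <= missing_max` — matching PLINK's
`--maf` / `--geno` semantics; "genotyping rate cutoff" is read as a
maximum per-variant missing rate. In the conversion report the
missing-rate filter is attributed before the MAF filter, so the four
counts are additive. Missing cells are mean-imputed per variant before
any matrix computation; a variant with no calls at all is an error, not
a silent zero.

## Kinship and PCA

The genomic relationship matrix defaults to the unit-variance-SNP
("standardized") estimator: each dosage column is centered and scaled
to unit empirical variance, K = W·Wᵀ/m over the m non-zero-variance
columns. This is the FaST-LMM "Unit" convention; its diagonal averages
≈1, and it agrees with the binomial scaling √(2f(1−f)) in expectation
under Hardy–Weinberg. A plain centered estimator is available. Allele
frequencies always come from the analyzed (post-imputation) cohort.

PCA operates on centered (not re-standardized) dosages via SVD;
component signs are fixed by making each component's largest-magnitude
loading positive, so results are fully deterministic. Heatmap ordering
uses average-linkage clustering on the distance `max(K) − K[i,j]`,
which tolerates kinship entries above 1.

## The mixed model

The association model is y ~ N(Xβ, σg²K + σe²I). With K = U·S·Uᵀ
computed once, rotation by Uᵀ turns every GLS solve into weighted least
squares with weights 1/(Sᵢ+δ), δ = σe²/σg². σg² profiles out
analytically; δ is estimated on the null model by REML (the default
criterion; ML is switchable) over a 100-point log grid on [1e−5, 1e5]
refined by golden section between the best grid point's neighbors.
Each SNP then enters the fixed effects with δ held at the null estimate
(the fast approximation); `refit_delta_per_snp=True` re-optimizes δ per
SNP and is guaranteed never to lower the per-SNP restricted likelihood.
Tests are Wald χ²(1) for the mixed model and two-sided t (n−2 df) for
the plain per-SNP OLS; the two agree at K = I up to the documented
t-vs-normal reference difference. The tested SNP stays inside the
kinship (no leave-one-chromosome-out), covariates default to an
intercept only, and zero-variance SNPs are reported with β=0, p=1 to
keep output row-aligned. Genomic inflation is
λ = median(χ²)/0.4549364, the χ²(1) median.

Pseudo-heritability h² = σg²/(σg²+σe²) = 1/(1+δ) is the quantity shown
by the heritability panel.

## ML marker importance

The repeated-split protocol: for each of 10 iterations draw a random
70% training subset (uniform, without replacement, seeded via
`SeedSequence` spawning so iterations are independent and
order-invariant), fit the learner, record its per-marker importance and
the 30% split's R². The final score is the elementwise **sum** across
iterations (mean and median available); vectors are deliberately not
re-normalized before aggregation. Importance is the estimator's native
impurity-based score for random forest and gradient-boosted trees
(both 200 trees, depth 3, otherwise scikit-learn defaults) and the
absolute standardized coefficient for ridge, whose penalty is chosen by
generalized cross-validation over 1e−3…1e3 on each training split.
Qualitative traits are 0/1-coded and fed to the same regression
learners — one code path, no classifier mode.

## Genomic prediction

`gp_holdout` excludes a seeded random subset (default 30 samples),
trains `n_models` (default 10) models on the remainder — differing only
by learner seed — and averages their predictions. GBLUP predicts
μ̂ + K[test,train](K[train,train] + δ̂I)⁻¹(y_train − μ̂) with δ̂ and the
GLS intercept μ̂ from the training-block REML fit; being deterministic,
its model count collapses to 1 (noted in the result). Evaluation is
Pearson r (undefined, with a note, when either vector is constant) and
a Bland–Altman summary: bias = mean(predicted − observed), limits of
agreement bias ± 1.96·sd (unbiased sd).

## Synthetic data

`simulate_genotypes` uses the Balding–Nichols model: ancestral
frequencies uniform on `maf_range` (default [0.05, 0.5]), per-population
frequencies Beta-perturbed at the requested Fst, genotypes
Binomial(2, p), samples split evenly across populations, missing calls
i.i.d. This is the simplest standard construction that yields the
allele-frequency confounding the mixed-model calibration test needs;
an independent Hudson-style estimator recovers the target Fst.
`simulate_phenotype` places causal markers among variants with
MAF ≥ 0.05, draws standard-normal effects on standardized dosages, and
rescales (and residualizes) the noise so the **sample** variance ratio
equals h² exactly — parameter-recovery tests get a sharp target.
Qualitative traits threshold the liability at its median.

What the generator does **not** emulate: linkage disequilibrium,
pedigree relatedness within populations, genotyping-error structure,
MAF-dependent effect sizes, epistasis. A green end-to-end test
therefore establishes correct mechanics and calibration under
idealized unlinked markers, not performance on real LD-structured
panels.

Default problem sizes in the validation suite mirror realistic
desk-scale panels (hundreds of samples, 10³–10⁴ markers); the generator
itself handles the thousands-of-samples × ~10⁵-marker shape of real
validation datasets, which the test suite down-scales for runtime.

## Known limitations and deliberate choices

- Gradient boosting is scikit-learn's `GradientBoostingRegressor`; its
  impurity-based importance differs from XGBoost's total gain, so
  absolute importance values are not comparable across implementations
  (rankings generally are).
- Ridge genomic prediction in the markers ≫ samples regime cannot
  exploit sparse architectures; on a noiseless 5-causal trait with
  2000 markers and ~400 training samples its hold-out correlation
  plateaus near 0.36 regardless of penalty. The strong-signal unit test
  therefore runs in the identifiable regime (markers < samples).
- Unlinked-marker GBLUP accuracy follows the usual
  √(h²·Nh²/(Nh²+M)) expectation; at n=500, m=2000, h²=0.6 this is
  ≈0.25–0.27, which bounds what any hold-out evaluation at that size
  can show.
- Sample-level filtering (`--mind`), Hardy–Weinberg tests, LD pruning,
  dosage formats (BGEN/PGEN), and covariate files beyond
  intercept-plus-PCs are out of scope.
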