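# Methods

This note documents the models, assumptions, parameter choices, and
numerical details behind `mmresp`, in the order the pipeline runs them.

## Clinical endpoint and cohort discipline

Clinical benefit (CB) is progression-free survival (PFS) ≥ 6 months;
its absence (N-CB) is the *positive* class for every sensitivity /
specificity figure, because the clinical use case is confidently
identifying non-benefiting patients early. Three patient cohorts are kept
strictly separate: *discovery* trains (DEA + classifier fitting),
*test* selects (model choice, multimodal band tuning), *validation* is
evaluated exactly once with everything frozen. In code this is enforced,
not just promised: validation truth labels live in a `SealedLabels`
container that raises `LeakageError` for any stage other than
`final_evaluation`, and a leakage test poisons held-out fold labels to
confirm out-of-fold predictions cannot see them.

## Synthetic cohort generator

The generator is first-class, tested code, not a fixture. A single latent
responder status per patient drives PFS, ctDNA kinetics, and the RNA
effect, so the two modalities correlate with outcome but carry
independent noise — the premise on which multimodal fusion rests.

* **Clinical**: responders draw PFS = 6 + Exp(mean 12 mo); non-responders
  Exp(mean 3 mo) truncated below 6 (inverse-CDF); administrative
  censoring at 36 mo. This makes CB ⇔ PFS ≥ 6 exact by construction.
* **ctDNA assay**: baseline tumor fraction (TF) is log-uniform,
  10^U(−2.5, −1); the OT fraction multiplies it by a lognormal factor
  centered at 0.25 (CB) or 1.6 (N-CB), σ = 0.4. Tracked variants
  (10/patient) carry per-variant cancer-cell fractions U(0.3, 1]; VAF =
  TF·ccf/2 in copy-neutral regions; reads ~ Binomial(depth ~ Poisson
  5000) with a 10⁻⁴ background error floor. 12.5% of patients are
  tumor-fraction-zero at both timepoints (mirroring the 11/88
  undetectable patients of the study cohort); an additional tail of
  low-TF patients falls below the calling limits organically. 10% of
  tracked variants are clonal-hematopoiesis-like: present at both
  timepoints and in the matched WBC sample at comparable VAF,
  independent of tumor burden, to exercise the WBC rejection rule.
  A 22-sample control cfDNA panel is drawn at the error floor.
* **RNA counts**: negative binomial (dispersion 0.18) around lognormal
  gene baselines, library ~10⁶, with a shared patient × gene lognormal
  random effect (σ = 0.2) giving the paired structure. 50 of 2,000 genes
  are signal genes, drawn from the upper half of baseline abundance (the
  immune-activation genes measurable in whole blood are well expressed);
  CB patients shift them at OT by log2FC ~ U(0.4, 1.1), 20% downward
  (the myeloid-type down-regulated genes).
* **Discordance injection**: 20% of patients are "ctDNA-discordant"
  (OT multiplier pinned to 1, σ = 0.05, so their ratio hugs the cutoff)
  and a further 20% "RNA-discordant" (expression effect attenuated ×0.3,
  landing their probability near 0.55, for CB and N-CB patients alike).
  This reproduces the empirical pattern that wrong standalone calls sit
  close to the cutoffs, and is exactly the regime in which band
  arbitration can help. Attenuation, not label flipping, is used: hard
  flips would make the modalities irreconcilable rather than uncertain.

Calibration: where the study reports numbers (93/42/51 composition,
29/29/21 cohorts, 11/88 undetectable, 12/27 discordant, standalone
operating points of roughly SN 0.59 / SP 0.92 for ctDNA and test AUC
0.84 for RNA), the defaults above were tuned to land near them; the
remaining values are desk-scale realism choices. What the generator does
**not** emulate: sequencing error profiles beyond binomial noise, UMI
artifacts, batch effects, gene–gene correlation beyond the patient
random effect, non-exponential PFS shapes, and informative censoring.
Passing tests therefore demonstrate correctness and calibration of the
*analysis machinery* under the assumed structure, not clinical
performance on real cohorts.

## ctDNA quantification

Calling proceeds in two tiers. Independent calling keeps variants with
≥ 5 supporting reads and VAF > 0.1%. Because upstream somatic calling
(with its matched-normal filtering) is out of scope, the control-panel
(≥ 20× mean control VAF, per nucleotide change, floored at 10⁻⁵) and
WBC (≥ 3×) checks are applied to independently-called variants as the
stand-in for germline/CHIP exclusion. Dependent calling rescues variants
detected at the other timepoint with the relaxed ≥ 3-read threshold but
identical control/WBC checks — dependent calling only ever relaxes read
and VAF thresholds, never the contamination checks.

CNV segments are classified by relative coverage (rc) and major-allele
fraction (MAF): loss if rc ≤ −0.3, or rc ≤ −0.1 with MAF ≥ 0.6; gain
symmetric with positive thresholds; boundaries inclusive.

Tumor fraction uses standard allele-dosage algebra. Primary route: the
called variant with highest VAF v outside gain regions gives TF = 2v
(copy-neutral heterozygous) or TF = 2v/(1+v) (variant on the retained
copy of a single-copy loss). Fallback: a germline SNP's major-allele
fraction m in a called loss gives TF = 2 − 1/m. The three routes agree
by construction on noiseless mixtures (tested at TF ∈ {0.1, 0.3, 0.5}).
Copies/mL = TF × cfDNA concentration (ng/mL) × 303, the haploid genome
count per nanogram of human DNA.

Uncertainty limits are exact 95% Clopper–Pearson bounds (beta quantiles)
on the defining variant's VAF, pushed through the same TF formula and
conversion; they are monotone-narrowing in depth. The germline-MAF route
carries no read-level interval and reports a degenerate one.

Dichotomization: ratio = OT copies / BL copies. Ratio ≥ 1 ("increase or
stable") → predicted N-CB; ratio < 1 → predicted CB; undetectable at both
timepoints → predicted CB with ratio defined as 0 (low ctDNA is
prognostically favorable); BL undetectable with detectable OT → ratio
+∞ → N-CB (it is an increase). Stability at exactly 1 groups with
increase. Point estimates are used for the ratio; an uncertainty-overlap
mode was considered and not enabled by default because the dichotomy at
ratio 1 is itself re-examined by the multimodal bands.

## RNA analysis

Genes are kept if CPM ≥ 1 in at least one sample, then dropped if the
percent coefficient of variation of CPM exceeds 100 in *every* condition
group. Normalization is trimmed-mean-of-M-values: reference sample =
closest upper-quartile CPM to the mean; 30%/5% two-sided trims on M/A;
precision-weighted mean M; factors rescaled to unit product. Expression
values are log2(CPM + 0.5) on TMM-adjusted library sizes — a
deterministic, monotone, everywhere-finite variance-control transform;
the classifier standardizes features anyway, so the exact transform is
not load-bearing.

The three contrasts are: paired BL→OT within CB, paired BL→OT within
N-CB, and unpaired CB vs N-CB at OT. Each uses a moderated t: per-gene
sample variances s² with d degrees of freedom are shrunk toward a prior
via posterior = (d₀s₀² + d·s²)/(d₀ + d), where d₀ and s₀² are fit by
method of moments on log s² (trigamma inversion by Newton iteration;
infinite d₀ when variances are under-dispersed relative to chi-square,
which also guards zero-variance genes — no NaNs). Two-sided p from t with
d + d₀ df; Benjamini–Hochberg across genes; DEG = adjusted p ≤ 0.05 for
all three contrasts (the uniform-threshold choice; the study states the
threshold explicitly only for enrichment). The null type-I error of this
pipeline on generator data is inside the binomial band around 0.05
(acceptance-tested over 40,000 gene-tests).

Venn partitioning of the three DEG sets exports the signature set
(CB-longitudinal ∩ OT-group) \ N-CB-longitudinal by default — the genes
that both move during treatment in benefiting patients and separate the
groups at OT; including the N-CB overlap is a flag. Signature scoring is
the per-patient mean of normalized expression over the set at one
timepoint, compared between groups by rank-sum test. Enrichment is a
one-sided hypergeometric upper tail against user-supplied GMT sets,
BH-adjusted.

## Sparse-PLS classifier

Features are per-patient OT − BL changes of the candidate genes (the
DEGs of the discovery CB contrast, padded with top-ranked genes to at
least 30 when the DEG list is shorter). The change representation is the
natural pairing-respecting choice; OT-only features remain available via
`build_change_features`' caller. The fit is NIPALS-style PLS on
standardized X and centered y with hard sparsity: component 1's weight
vector X'y keeps its k largest-magnitude entries, is renormalized, and
later components are restricted to the same support, so every fitted
model has exactly k active genes. Two components (the customary default
for discriminant PLS at n ≈ 30), deflation between them. The
discriminant score Σ t·q is mapped to a probability by 1-D logistic
regression on training scores (sign-normalized so the map is increasing);
CB is predicted when P(CB) ≥ 0.55.

Model development: repeated stratified 3-fold CV with 10 repeats on
discovery over k ∈ {10, 15, 20}; out-of-fold probabilities pool into a
CV AUC per (k, repeat). Each k's candidate is refit on full discovery and
scored on the test cohort by (a) ROC AUC and (b) the absolute difference
in Kaplan–Meier median PFS between predicted groups — an unreached
median substitutes the largest observed time, a deliberate totalization
of the ranking that is flagged in reports. Winner = smallest rank sum,
ties to the higher AUC.

## Multimodal arbitration

Bands: ctDNA [2^−d, 2^d] around ratio 1 (symmetric on log2, because a
ratio is multiplicative) and RNA [0.55 − d′, 0.55 + d′]; both closed.
Precedence: ratio in band → RNA call (also when both are in band — the
RNA model is prioritized); probability in band, ratio not → ctDNA call;
neither in band → ctDNA call, ctDNA being the base prediction that RNA
"adjusts". Ratio 0 (undetectable-both) and +∞ are unambiguous and never
in-band. A missing modality falls back to the other.

Tuning maximizes (SN + SP)_multimodal − (SN + SP)_RNA-standalone on the
test cohort over the default grid d ∈ {0, 0.25, 0.5, 0.75, 1.0} ×
d′ ∈ {0, 0.05, 0.10, 0.15, 0.20}, unweighted; ties prefer the narrower
total band, then the narrower ctDNA band (smallest intervention wins).
The tuned config is written as JSON and applied unmodified to the
validation cohort.

## Survival and metrics

Kaplan–Meier is the product-limit estimator from its definition; median
is the first time survival ≤ 0.5. The log-rank test is the
Mantel–Haenszel per-event-time 2×2 summation with hypergeometric
variance; hazard ratio = (O_A/E_A)/(O_B/E_B) with log-scale CI using
se = √(1/E_A + 1/E_B) — an O/E estimator in the same family as the test,
avoiding iterative model fitting. AUC is Mann–Whitney concordance with
half tie credit. Wilcoxon tests are exact for n ≤ 25 without ties,
normal-approximated with tie correction otherwise. lifelines and
scikit-learn implementations serve as independent cross-checks in the
test suite, never as the implementation.

## Problem sizes and determinism

Default desk-scale sizes — 2,000 genes, 50 signal genes, 10 tracked
variants at depth 5,000, 93 patients — keep a full pipeline run at a few
seconds and the complete test suite at a few minutes. One run seed fans
out to per-stage child seeds via `numpy.random.SeedSequence.spawn`, so
stages are individually reproducible and a rerun with the same manifest
is bit-identical.

## Known limitations

* The DEA substitutes a fully specified moderated-t pipeline for the
  study's proprietary algorithms; DEG *counts* are therefore not
  comparable, only the downstream machinery that consumes DEG lists.
* The variance-stabilizing transform is log2(CPM + 0.5), not a fitted
  dispersion-model transform.
* The LOH correction, germline-MAF inversion, and Clopper–Pearson
  uncertainty are reconstructed from standard allele-dosage algebra, the
  study deferring their exact forms to prior work.
* At default calibration the strict DEG threshold can yield few genes at
  n = 29; the classifier then pads candidates with top-ranked genes,
  which keeps the feature path defined but means "DEG" lists at
  desk scale are shorter than study scale.
* Synthetic performance figures validate machinery, not clinical claims;
  real cohorts add batch, assay, and biological structure the generator
  does not model.
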