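# Methods

`omicsqc` implements the quality-control computations that a multi-omics
postmortem-brain cohort needs before any integrative analysis is credible:
batch correction with missing-not-at-random (MNAR) imputation for label-free
proteomics, and genotype-based verification that every sample — WGS, WES,
RNA-seq variant calls, proteomics — really comes from the donor brain it is
labeled with. A synthetic-cohort generator with full ground truth stands in
for restricted human data, so every stage is exercised and scored end to end.

## Mixed-effects MNAR model (BCMI)

Each protein is modeled independently. For sample *k* in MS batch *i*:

    y_ki = mu + alpha * I_ki + b_i + e_ki,        b_i ~ N(0, d^2)

where `I_ki` flags pooled reference-standard injections (run at the start,
middle and end of each batch), `e_ki ~ N(0, sigma0^2)` for reference
injections and `N(0, sigma^2)` for regular samples. Missingness follows the
exponential selection model

    P(M_ki = 1 | y_ki) = exp(-gamma0 - gamma1 * y_ki),

so low-abundance measurements drop out preferentially.

**Estimating the mechanism.** A single protein rarely identifies its own
(gamma0, gamma1); the pair is estimated once, across proteins, by regressing
`log(per-protein missing rate)` on the per-protein observed mean (least
squares over proteins with missing rate strictly inside (0, 1); the slope is
clamped at zero when positive). The estimate is then held fixed in every
per-protein fit. On cohorts of 2,000 proteins x 300 samples the estimates
land within a few percent of truth; the known small biases (the
`gamma1^2 tau^2 / 2` curvature term in the intercept and the MNAR shift of
the observed mean) stay inside the 10% band the tests enforce.

**ECM fit.** With gamma fixed, each protein is fitted by expectation
conditional maximization. The E-step is exact for this selection model and
closed-form: integrating the missing values out of the likelihood leaves a
per-missing-entry factor `exp(-gamma0 - gamma1 (m0 + b) + gamma1^2 s^2/2)`
that is log-linear in `b`, so the posterior of `b_i` remains Gaussian with
variance `v_b = (1/d^2 + sum_obs 1/s_k^2)^-1` and mean
`v_b (sum_obs r_k / s_k^2 - gamma1 h_i)`, where `h_i` is the number of
missing entries in the batch — the selection mechanism pulls the inferred
batch effect down. Conditionally, each missing residual is independently
`N(-gamma1 s^2, s^2)`, so an imputed value sits *below* its untilted
conditional mean by `gamma1 * (h_i v_b + s^2)`: exactly the MNAR correction,
and identical to plain mixed-model conditioning when `gamma1 = 0`. The CM
step updates (mu, alpha) by group means of `E[y - b]`, `d^2` from the
posterior second moments of `b`, and `sigma0^2 / sigma^2` from the residual
moments of reference / regular entries. Because both steps are exact, the
observed-data log-likelihood (also closed-form) never decreases; the fitter
monitors it and the suite asserts non-decrease to 1e-8 on random instances.

Numerical choices: convergence when the maximum relative parameter change
drops below 1e-6, cap 500 iterations, variance floor 1e-8 (a fit pinned at
the floor reports `converged=False`). Two safeguards address a genuine
pathology of the *unclipped* exponential mechanism, whose likelihood is
unbounded when missing entries dominate (sending mu to -inf, or a batch
with no observed entry sending d to +inf): batches with zero observed
entries keep their prior (`b_hat = 0`, variance `d^2`) and contribute no
selection tilt, and a divergence guard freezes a runaway fit at its last
stable state with `converged=False`. Neither safeguard is ever active for
data that passed the 15% missing-rate filter, which is the intended input
to BCMI.

**Corrected output** is `(observed or imputed value) - b_hat_i`. The
reference-sample offset alpha is retained so regular samples are untouched
by it; reference samples stay in the matrix, flagged. The missing-rate
filter keeps proteins with missing fraction strictly below the threshold
(default 0.15).

**Evaluation.** Technical replicate pairs (the batch-7/8 design: 18 samples
measured in both batches) are compared by Pearson correlation across
proteins — raw complete-case versus each completed matrix. Good imputation
should raise replicate agreement; median/minimum per-protein fills should
lower it.

## Synthetic cohorts

The generators define the study conditions under which everything is tested.

*Genotypes.* One latent diploid genotype per brain: ancestral allele
frequencies Uniform(0.05, 0.95), population frequencies from a
Balding-Nichols beta model with per-population divergence (defaults: 80%
EUR at Fst 0.05, 12% AFR at 0.12, 8% LAT at 0.08 — a minimal model that
reproduces PC-plane separation by ancestry). Sexes are ~65% female,
mirroring typical brain-bank demographics. Male X genotypes are hemizygous
and coded {0, 2}, the way diploid callers report them, which is what makes
the X-inbreeding sex check behave as in practice. Each modality (defaults:
WGS covering 90% of brains, WES 80%, RNA 95%) observes an independent copy
with its own genotype-error and missingness rates; contamination is
emulated only as elevated heterozygosity.

*Label errors.* Injected corruptions — swaps, brain relabels, unknown ids,
orphans, sex and race mislabels — are recorded in a `TruthLog`.
Recoverable corruptions are placed so the true brain keeps at least two
other samples; orphans are placed on single-sample brains and relabeled to
a populated brain, making their identity genuinely unrecoverable (they have
suspicious flags but no duplicate-level partner).

*Proteomics.* 8 batches; batches 1–7 hold regular samples, batch 8
re-measures 18 of batch 7's samples plus a reference standard. Defaults:
per-protein means N(20, 2^2) on the log2-intensity scale, alpha = 0.5,
d = 0.8, sigma0 = 0.2, sigma = 1.0, gamma = (-4.4, 0.3) (about 20% missing
at the centre of the scale; these are free parameters of the simulator, not
estimates of any real cohort). A regular sample's residual variance is
split into a donor biological component (90%) and measurement noise (10%);
the two members of a replicate pair share the donor component, because a
technical replicate re-injects the same tissue homogenate. This split
leaves every marginal distribution unchanged but is what makes naive
median imputation *hurt* replicate correlation: a cohort-median fill
destroys the donor-specific signal the partner replicate still carries,
while the MNAR-tilted model imputation preserves it. With purely
independent replicate residuals that ordering cannot arise — median fills
then carry as much cross-protein signal as real measurements.
Reference standards are a pooled homogenate, so their residual is pure
measurement noise.

*What the generator does not emulate:* raw reads or spectra, peptide-level
quantification, related donors, read-level contamination mixtures,
protein-protein abundance correlation, batch-size imbalance beyond the
replicate batch. Passing tests therefore certify the algorithms under the
stated generative model, not performance on any particular real cohort.

## Identity QC

*Variant filters* (strict inequalities, exactly as conventionally printed):
missing rate > 0.5, minor allele frequency < 0.01, Hardy-Weinberg exact
test p < 0.001 (autosomes only). The HWE test conditions on allele counts
and sums the probabilities of heterozygote counts as or less likely than
observed (log-factorial closed form; no mid-p).

*Heterozygosity outliers*: per-sample autosomal heterozygosity more than 3
SD from the cohort mean (high: possible contamination; low: inbreeding).

*Sex.* From genotypes: X inbreeding coefficient
`F = (O_hom - E_hom) / (L - E_hom)` with `E_hom = sum_l (1 - 2 p_l q_l)`
over the sample's non-missing X loci; call male above 0.8, female below
0.2 (common-practice cutoffs, overridable), else ambiguous. Hemizygous
males give F = 1 identically. From expression: XIST (female axis) versus
the mean of DDX3Y/RPS4Y1 (male axis); each axis is split at the largest
gap between order statistics, declared unimodal when that gap does not
exceed a third of the range — calls by quadrant, with both-high (the mixed
sample signature) and both-low ambiguous. A rank-only split cannot locate
modes (ranks are always a permutation of 1..n), so gap position on the
values is used; calls are invariant to any monotone rescaling that keeps
the between-mode gap dominant.

*Ancestry.* PCA on mean-imputed, frequency-standardized autosomal dosages;
nearest labeled-group centroid in the PC1/PC2 plane. A mismatch requires
(i) assigned != claimed, (ii) margin greater than half the inter-centroid
distance, and (iii) centroids separated by more than either group's
within-group radial spread — condition (iii) prevents mislabel calls when
the PCs carry no population signal at all. Weaker evidence is ambiguous,
as are members of groups too small (< 3) to form a centroid.

*Kinship.* The robust heterozygote-normalized estimator
`phi = (N_Aa,Aa - 2 N_AA,aa) / (N_Aa(i) + N_Aa(j))` over loci non-missing
in both samples: exactly 0.5 for duplicates, expectation 0 for unrelated
pairs, invariant to allele-label flips, and computed for all pairs with
one pass of matrix products.

*Concordance and resolution.* Pairs claimed to share a brain with
phi < 0.1 are *suspicious*; pairs from different claimed brains with
phi > 0.354 are *spurious* (duplicate/MZ-twin threshold). Resolution
iterates: pick the sample with the most flags (ties by id); its
duplicate-level partners (phi > 0.354) vote with their claimed brains; a
strict majority for a brain different from the claim triggers a remap
(an *assign* when the claim was unknown) provided the relabel clears the
sample's flags; otherwise the sample is excluded. Two refinements keep
the procedure sound where a literal reading fails: a sample whose
partners majority-support its current claim is skipped (its flags are
someone else's fault — excluding it would discard clean victims), and the
flag-clearing check ignores residual flags against samples that are
themselves still flagged (otherwise the two sides of a swap veto each
other and one is always lost). A sample selected for a second remap is
force-excluded, guaranteeing termination; the whole procedure is a pure
function of the kinship matrix and labels.

## cis-pQTL sample matching

Proteins under cis genetic control let genotypes be read off abundance.
For each protein with coordinates, simple linear regression of abundance
on dosage over variants within ±1 Mb; the best variant is kept at
p < 1e-3 (defaults declared, not inferred from any real analysis). For a
proteomics profile, each model is inverted to the dosage in {0, 1, 2}
nearest to `(y - beta0)/beta1` (ties toward the cohort-modal genotype;
beta1 = 0 models are uninformative and skipped). The similarity S_ij is
the fraction of models where the dosage inferred from proteomics sample i
equals genotype sample j's observed dosage (pairs with fewer than 10
comparable models are undefined). A sample is self-aligned when S against
its claimed partner ranks in the top 3 of its row *or* its column (the
relaxed criterion); failures are re-examined by the reciprocal rule — remap
P_i to G_j only when each is the other's best unmatched match — after which
models are refitted under the updated labels and the loop repeats to
convergence (cap 20 rounds, ties broken by sample id).

Expected behavior, verified in the suite: at effect/noise = 2 with 200
models and 100 samples the self-alignment rate exceeds 95%; with no signal
it sits at top-3 chance level; accuracy is monotone in effect/noise; a
swapped pair of proteomics columns is detected and remapped within two
rounds.

## Pipeline

`run_pipeline` chains variant QC -> heterozygosity/sex/ancestry -> kinship
-> identity resolution -> missing-rate filter + BCMI -> cis-pQTL alignment
(proteomics paired to resolved genotype samples by brain id), writing every
stage artifact as TSV/CSV plus a JSON report whose counts reconcile at each
stage. All randomness flows from the run seed; reports are byte-identical
across repeated runs.

## Known limitations

* The exponential selection model is used unclipped inside the E-step (the
  clip at probability 1 has negligible mass for post-filter data); fits on
  heavily missing proteins are flagged rather than repaired.
* With 8 batches the ML variance component `d` carries the classic ~10%
  downward finite-sample bias (no REML correction); it stays inside the 15%
  recovery band the tests enforce.
* Majority voting is unweighted across modalities, and "majority" means
  strictly more than half of duplicate-level partners.
* The ancestry check is a two-PC nearest-centroid rule, not a mixture or
  supervised model; closely diverged populations yield ambiguous calls
  rather than mismatches.
* mRNA-protein correlation-based matching is documented as a non-starter
  (cis mRNA-protein correlations in brain are weak) and deliberately not
  implemented.
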