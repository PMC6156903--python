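# Methods

## Problem setting

Cohorts treated with a lipid-lowering drug are dichotomized into
responders and non-responders; the question is whether a SNP and a CpG
site in cis (within a fixed genomic window) interact on that outcome.
Regression approaches must posit a functional form for the interaction;
the W-test instead compares the *distribution* of subjects over the joint
genotype–methylation categories between the two phenotype groups, making
it model-free with respect to the interaction shape.

## Variables

- **SNP**: biallelic, additively coded as the count of the dataset minor
  allele (0, 1, 2). Polarization uses the observed allele frequency in the
  analysis cohort; if the counted allele's frequency exceeds 0.5 the codes
  are flipped g → 2−g. Monomorphic SNPs are flagged and skipped by the
  scan.
- **CpG**: methylation beta value in [0, 1], split into low/high states by
  one-dimensional two-mean clustering computed on all retained subjects
  (never per phenotype group, so the binarization cannot leak outcome
  information). Lloyd iterations start deterministically from centers at
  the min and max; because that initialization can stall in a local
  optimum (e.g. on values 0, 0, 0.5, 1), the converged split is replaced
  by an exact threshold scan — every SSE-optimal two-cluster partition of
  1-D data is a threshold partition — whenever n ≤ 1000. The procedure is
  deterministic and globally optimal in that regime.
- **Drug response**: TG_pre is the mean of the two pre-treatment
  triglyceride visits, TG_post of the two post-treatment visits;
  ΔTG% = (TG_pre − TG_post)/TG_pre, and a subject is a responder when
  ΔTG% strictly exceeds 0.30 (an exact 30% decrease is a non-responder).
  Being a ratio, the label is invariant under common rescaling of TG
  units. Precomputed binary responses pass through unchanged.
- **Cohort**: complete-case. Subjects are intersected by id across the
  genotype, methylation and phenotype tables and any subject missing a
  value in a used variable is dropped, with per-reason counts logged.
  Subject order is sorted, so results never depend on input row order.

## The statistic

For one pair, subjects fall into at most 6 categories (3 genotype × 2
methylation levels); categories empty in both groups are dropped and k is
the retained count. Per category i the 2×2 collapse (category vs rest) ×
(case vs control) yields a log odds ratio and its standard error
SEᵢ = √(1/n₁ᵢ + 1/(n₁−n₁ᵢ) + 1/n₀ᵢ + 1/(n₀−n₀ᵢ)); the raw statistic is
S = Σᵢ (log ORᵢ / SEᵢ)². If any entry of a cell's collapse is zero, 0.5 is
added to all four entries of that collapse (Haldane–Anscombe), keeping S
finite; the correction is recorded per cell. Tables with k < 2 are
degenerate and rejected.

The per-cell z-scores are correlated (the category counts share margins),
so S is not chi-squared with k degrees of freedom. Instead W = h·S is
referred to χ²_f with (h, f) estimated from the data: bootstrap
replicates resample subjects with replacement, permute the phenotype
within the draw (enforcing the null while preserving the marker and
phenotype margins), evaluate S on a randomly chosen candidate pair, and
group the resulting samples by their observed k. Moment matching gives
h = 2m/v and f = 2m²/v from each group's mean m and variance v — the
unique two-parameter choice making E[hS] = f and Var(hS) = 2f. The
identities h·m = f and h²·v = 2f hold exactly by construction. On
balanced null tables the estimated f tracks k − 1, reflecting the one
linear constraint among the category proportions.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `window_bp` | 10 000 | cis pairing distance, boundary inclusive, on 1-based coordinates |
| `boot_reps` (B) | 400 | bootstrap replicates for (h, f) |
| `subsample_size` | min(n, 1000) | subjects per bootstrap draw (with replacement) |
| `sample_floor` | 50 | minimum per-k samples; smaller groups use the pooled estimate |
| `alpha` | 0.05 | nominal per-test level; the scan reports the Bonferroni threshold alpha/m |

Calibration is fitted once per cohort and reused across pairs and
permutation replicates, mirroring real usage; a per-replicate
recalibration flag exists for sensitivity analysis. All stochastic
operations take an explicit seed; fixed stream tags derived from that
seed keep the genotype, methylation, position and experiment streams
independent yet reproducible.

## Benchmarks

LR-m1 and LR-m2 fit `Y ~ 1 + G + M + G·M` by maximum likelihood
(statsmodels) with G the numeric additive code and M the binarized label
(m1) or raw beta (m2), and test the interaction with a 1-df
likelihood-ratio test — chosen over Wald because it behaves better in
sparse cells. Non-convergence and complete or quasi separation
(divergent coefficients) are reported as `converged = False` with a
missing p-value rather than a spurious number.

## Synthetic cohorts

The generator emulates the target study's statistical shape: n = 680
unrelated subjects; SNP genotypes in Hardy–Weinberg proportions with MAF
drawn uniformly from [0.05, 0.5]; methylation betas from the bimodal
mixture ½·Beta(2, 8) + ½·Beta(8, 2) (low/high methylation modes typical
of array data); CpGs placed within 10 kb of a random SNP with probability
0.8 so cis pairs always exist; and a binary response from
P(Y=1) = logistic(β₀ + β_G·G + β_M·M + β_GM·G·M) on one designated causal
pair (all effects zero under the null, β₀ = 0 giving balanced groups).

It deliberately does **not** model family structure or kinship, linkage
disequilibrium between SNPs, cell-type composition effects on
methylation, covariates (age, sex, smoking, center), or longitudinal TG
trajectories. Passing simulation studies therefore demonstrate the
statistical calibration and power of the machinery on clean, independent
data — not robustness to relatedness or confounding in real cohorts.

The type-I-error study permutes the phenotype of one generated cohort
(2000 replicates by default) and counts p ≤ alpha on a fixed SNP–CpG
pair, the calibration having been fitted once from the same cohort; a
flag averages over rotating pairs instead. The power study redraws the
phenotype per replicate from the interaction model across a grid of
interaction log-odds. At desk scale (n = 680, one pair, B = 400, 2000
replicates) the full study runs in seconds.

## Numerical choices and edge cases

- Ties in two-mean clustering: a beta exactly at the midpoint of the
  centers is assigned low.
- Equal W-test p-values in the results file break ties by
  (snp_id, cpg_id) lexicographic order; ranking is stable.
- p-values of exactly 0 are rejected by the Q-Q routine; the scan's
  chi-squared survival function underflows only below ~1e-308.
- The genomic inflation factor λ is the median 1-df chi-squared quantile
  of the observed p-values over the theoretical null median (≈0.4549).
- Bootstrap draws that produce a single-class phenotype or a k < 2 table
  are redrawn (they carry no case/control contrast); a 50×B attempt guard
  prevents pathological loops.

## Known limitations

- **Deep-tail p-values are approximate.** Moment matching calibrates the
  center of the null distribution of h·S; its far tail is that of a
  weighted sum of correlated chi-squares, which a single χ²_f can under-
  or over-state. Null uniformity holds at conventional levels (KS and Q-Q
  diagnostics pass at 2000 permutations), but for very strong signals the
  reported p can differ from a 1-df likelihood-ratio p by orders of
  magnitude even when both are decisive. Rankings and threshold decisions
  at genome-scan significance levels are unaffected in our experiments;
  exact tail probabilities beyond ~1e-6 should not be over-interpreted.
- The per-k calibration needs enough bootstrap mass per k; rare k values
  silently fall back to the pooled estimate (flagged in the calibration
  table).
- The two-mean split assumes bimodal methylation; CpGs with unimodal
  intermediate betas get an arbitrary but deterministic split.
- No covariate adjustment, kinship correction or SNP–SNP epistasis; see
  the generator's non-goals above.
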