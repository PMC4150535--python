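# Methods

## Model and tests

`snipscan` tests each genotyped anchor SNP for association conditional on
one nearby partner SNP. Binary traits: nested logistic regressions
(intercept + anchor + partner + covariates vs. intercept + partner +
covariates) compared by a likelihood-ratio statistic on one degree of
freedom. Quantitative traits: the analogous nested OLS models compared by
`F = (RSS0 − RSS1)/(RSS1/(n − 3 − c))` on (1, n − 3 − c) degrees of freedom,
where `c` is the number of covariates (the single-SNP companion test uses
n − 2 − c). Genotypes always enter additively on the log-odds / linear
scale — an allelic (multiplicative-odds) coding. Dominant or recessive
codings of the *test* are deliberately not offered: when LD with the causal
variant is weak they reduce power even for data generated under those
models, so only the score metric has model variants.

Assumptions: unrelated individuals, autosomal biallelic SNPs,
Hardy-Weinberg-style random mating in the simulators, and a causal effect
expressible through local LD. The conditional test's null hypothesis is "the
anchor adds nothing beyond the partner (and covariates)".

### Fitting and numerical choices

Logistic models are maximized by Newton/IRLS with step-halving; convergence
when the largest score component falls below 1e-8 or the relative
log-likelihood change falls below 1e-10, with a 50-iteration cap. Complete
separation is detected after convergence (every observation classified with
fitted probability within 1e-6 of its outcome) and reported as
`not_converged`; no penalized fallback is attempted. Collinear design
columns are removed by left-to-right Gram-Schmidt (earlier columns win, so
the anchor survives before the partner, both before covariates); a dropped
genotype column makes the test `degenerate`, a dropped covariate is only
flagged. Linear models use `numpy.linalg.lstsq`; an (essentially) zero full
RSS yields F = 0 when the null model also fits perfectly and `degenerate`
otherwise. Likelihood-ratio statistics are clamped at 0 against round-off.
P-values are upper-tail χ²₁ / F probabilities with no small-sample
correction.

Missing-data policy is complete-case per test: an individual is excluded
from one anchor's test if its phenotype, either genotype, or any covariate
is missing, so the effective n varies by anchor. Correlations and
minor-allele orientation, by contrast, use all individuals regardless of
phenotype.

## Partner selection

Candidates come from a window of `w` SNPs (default 10) around the anchor on
the same chromosome — ⌊w/2⌋ left, ⌈w/2⌉ right, extended to the other side
near chromosome ends so the total is min(w, available); the odd-`w` split is
our choice. A base-pair window (symmetric, boundary-inclusive) is available
as an alternative. Each candidate's squared Pearson correlation r² with the
anchor, computed on minor-allele dosages over pairwise-complete individuals
of the whole sample, is mapped through the score curve; the highest score
wins, ties going to the candidate earliest in the window. Monomorphic
candidates (undefined r²) score 0 and never beat a candidate with defined
r²; if every candidate is undefined the anchor is reported `no_partner`.
Because selection never reads the phenotype, it is independent of the test —
the property behind the method's null calibration, and one we test directly
by phenotype permutation.

We implement r² as the plain squared Pearson correlation of dosage vectors
(computable from unphased genotypes), not a composite-LD variant.

## Score-curve construction

The curve is rebuilt by `run_metric_construction` as follows, per replicate:

1. Eight haplotype frequencies over (anchor, causal, partner) are drawn by
   sequential uniform stick-breaking: haplotypes are visited in uniformly
   random order, each frequency drawn uniformly on [0, 1 − S] with S the sum
   already assigned, the last taking the remainder. The upper bound 1 − S is
   the only choice that leaves a valid remainder for the final step.
2. A panel of 1,000 cases and 1,000 controls is simulated under penetrances
   P(disease | 0/1/2 causal alleles). Defaults: multiplicative
   (0.01, 0.015, 0.0225). The dominant (0.01, 0.0225, 0.0225) and recessive
   (0.01, 0.01, 0.0225) sets preserve that baseline and maximum; they are a
   modelling assumption of this package. Sampling is exact-conditional: the
   9-cell (anchor × partner dosage) distributions given case and control
   status are computed analytically and multinomial counts drawn from them,
   which is distributionally identical to individual-level rejection
   sampling but yields exact case/control totals.
3. The all-sample anchor–partner r², the conditional statistic, and the
   single-SNP logistic statistic at the anchor are recorded. All likelihoods
   are evaluated on the 9-cell × status contingency table with a batched
   Newton solver — mathematically identical to per-individual fits and fast
   enough that the full 10⁶-replicate construction runs in under a minute.
   Replicates whose sampled panel is monomorphic at either SNP are dropped.

The statistic differences (conditional − single-SNP) are thresholded at
their top 1%; r² values are binned at width 0.05 (half-open bins, r² = 1 in
the last); each populated bin's top-1% probability is computed; a degree-5
polynomial is least-squares fitted to the bin midpoints excluding the three
lowest and three highest populated bins, with anchor points (0,0) and (1,0).
The excluded tails are covered by straight segments from the anchor points
through the first/last included bin value ("fitted separately" is not
specified further; linear interpolation is our choice). The curve is clamped
at 0 and scaled so its maximum over a 10⁻³-spaced grid is 100. Lowering the
top fraction shifts the peak toward lower correlations, a property the test
suite asserts.

The three shipped curves were generated with seed 1 and 10⁶ replicates;
their peaks sit at r² ≈ 0.32 (multiplicative), 0.40 (dominant) and 0.42
(recessive). `snipscan build-metric` regenerates them.

## Synthetic data

The simulators draw diploid individuals as two independent haplotypes from a
small explicit pool and assign disease by genotype relative risks at a
designated causal SNP (defaults 1.5/2.25, prevalence 0.01, 1,000 + 1,000
samples), optionally withholding the causal column to emulate an untyped
variant. The bundled pools were designed once by numerical search on the
haplotype simplex: a weak-tagging pool (anchor–partner r² 0.297,
causal–anchor 0.145, causal–partner 0.062, causal vs. anchor+partner
combination 0.439), a strong-tagging pool (causal–anchor 0.890), and a
five-typed-SNP null pool in moderate mutual LD (pairwise r² 0.24–0.84) for
type-I evaluation.

What these generators do **not** emulate: recombination within the region,
genotyping error, missingness, population structure, related individuals, or
realistic genome-scale LD decay. Passing tests therefore demonstrate the
statistical behaviour of the method under its own model — calibration,
power ordering, independence of selection — not its performance on any real
cohort.

## Evaluation harness

`evaluate_power` scans replicate panels and counts a detection when any
tested anchor within 110 kb (the default detection window) of the causal
position passes a p-value threshold. Under a null generator the Bonferroni
reference is a × nominal with a the number of anchors in the window; because
neighbouring anchors are positively dependent the observed proportion falls
below it. The acceptance checks use thresholds 0.05 and 0.02 with 2,000
replicates — the smallest rates that replicate count resolves with useful
precision — and 600 replicates for the power-ordering comparisons, where
"equivalent power" is operationalized as agreement within 0.1 absolute
power. Null calibration uses 10,000 anchor/partner replicates at n = 2,000;
genomic-control λ is the median statistic over the χ²₁ null median.

## Known limitations

- Only PLINK 1 binary input (SNP-major); no VCF/BGEN, no dosage data.
- One partner per anchor; no multi-partner or haplotype extensions.
- No family-based tests; pseudocontrol data are accepted only as
  pre-converted case/control input.
- The anchor×partner interaction variant of the test is intentionally
  absent (it showed no advantage).
- Sex chromosomes receive no special handling.
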