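# Methods

## Model

Case–control status is modeled prospectively by additive logistic
regression over a subset `M` of SNPs coded as 0/1/2 counts of one allele:

    logit P(y_i = 1 | x_i) = β₀ + Σ_{j∈M} β_j x_ij.

Coefficients are estimated by Firth's bias-reduced method: the
log-likelihood is penalized by half the log-determinant of the Fisher
information (`ℓ*(β) = ℓ(β) + ½ log det I(β)`, the Jeffreys prior). This
removes the O(1/n) bias of the MLE and — crucial here — keeps every
estimate finite under complete separation, which occurs routinely when a
search visits many SNP subsets. Fitting uses Newton iterations on the
Firth-modified score `X'(y − π + h(½ − π))` (`h` = weighted hat-matrix
diagonal), with step-halving whenever a step would decrease `ℓ*`.
Convergence is declared when the modified score's sup-norm falls below
`tol` (default 1e-8 in `firth_fit`; the search's candidate refits use 1e-6,
which changes criterion values by far less than the move-acceptance margin
of 1e-7). Iteration cap 50; non-convergence is flagged on the fit rather
than raised, so a caller can decide. `log det I` comes from a Cholesky
factorization of `X'WX`; a rank-deficient design raises an error listing
the collinear columns found by QR.

## Selection criteria

A model with `k` of `p` candidate SNPs on `n` individuals is scored by

    mBIC2  = −2 ℓ̂ + k log(n p²/c²) − 2 log k!     (c = 4, default)
    mBIC_E = −2 ℓ̂ + k log(n p²/E²)                (E = 60, default)

smaller is better, natural logs throughout. The constants follow the
mBIC/mBIC2 literature: `p²/c²` encodes a sparse binomial prior on model
size, and the `−2 log k!` relaxation makes mBIC2 act like a step-up
(Benjamini–Hochberg-type) rule, controlling the FDR of selected SNPs at
roughly the 10% level. mBIC_E with prior expected model size `E = 60`
("mBIC_60") is deliberately milder and is used only in early search rounds
to avoid local minima; it carries no `k!` term. Both constants are
configurable in `CriterionConfig`.

**Which likelihood enters the criterion.** `ℓ̂` is, by default, the
*ordinary* log-likelihood evaluated at the Firth estimate
(`CriterionConfig.loglik_source = "ml"`); the penalized maximum
`ℓ*` is available via `loglik_source = "penalized"`. The Jeffreys term
grows by about `½ log(n·w̄·σ²_x)` for every SNP added (≈ +2.3 at
n = 1000 for a common SNP), so scoring models by `ℓ*` hands each extra
regressor a systematic bonus that re-levels the carefully FDR-calibrated
penalty; at desk-scale simulations (p ≈ 1000) this inflates the realized
FDR several-fold. Firth penalization is an estimation device (bias
reduction, finite estimates); the criterion compares evidence, so the
package scores with the ordinary likelihood by default. With this choice
the empirical FDR of the full procedure in the acceptance simulation sits
well below the 10% design level; with the penalized variant it does not.

## Search

Exact minimization over all subsets is a hopeless integer program at GWAS
scale, so the package uses a fast stepwise search (FSS). One FSS call
fixes a candidate ordering (marginal Cochran–Armitage trend statistics, or
Rao score statistics conditional on the current model), forms the groups
P1 (top `p1`, default 100) and P2 (top `p2`, default `min(p, 5000)`), and
cycles three moves until a full cycle brings no improvement:

1. **Directed forward** — walk P1 in order; add the *first* SNP whose
   inclusion strictly lowers the criterion.
2. **Exchange** — for each model SNP in turn, try swapping it with every
   P2 SNP within 49 index positions on the same chromosome (both sides);
   apply the best improving swap. This lets an LD proxy picked up early be
   replaced by the better, nearby signal carrier.
3. **Extended backward** — greedily remove the least explanatory SNP up
   to 3 times, keeping the best model seen; exploring deeper removals even
   when the first one hurts lets the search escape one-step local minima.

The full procedure runs FSS three times:
`M1 = FSS(∅, Cochran–Armitage, mBIC_60)`,
`M2 = FSS(M1, score test, mBIC_60)`,
`M3 = FSS(M2, score test, mBIC2)`, returning `M3`. The milder first rounds
deliberately overshoot so that the final mBIC2 round can prune rather than
miss. Every candidate model is evaluated by an exact Firth refit —
warm-started from the incumbent and cached by SNP set, which makes
repeated sweeps cheap — and every accepted move strictly decreases the
active criterion (margin 1e-7), so each FSS call terminates and the search
is fully deterministic. When the model outgrows `p2_shrink_threshold`
(default 25), the exchange group is halved as a runtime guard. Ties are
broken toward the lowest SNP index everywhere. The exchange neighborhood
uses index distance within a chromosome (SNP arrays have roughly uniform
marker spacing, and the windowed default is stated in marker counts);
`window`, `p1`, `p2` and the backward depth are all configurable.

The conditional ordering of rounds 2–3 is computed once per FSS call, not
after every model change — a deliberate trade of a slightly staler ranking
for one vectorized pass.

## Association tests and the single-marker comparator

The Cochran–Armitage trend test uses scores (0, 1, 2). Its default
variance is the classical conditional (finite-population-corrected) form,
giving `(N−1)·r²` for the genotype/status correlation `r`; the model-based
variant `N·r²` (`variance="model"`) coincides *exactly* with the logistic
Rao score test at the unpenalized intercept-only model, so the two
conventions differ by the factor `N/(N−1)`. The package keeps both and
documents the factor instead of hiding it. The conditional score test for
adding SNP `x` to a fitted model is `U²/V` with `U = x'(y − π̂)` and `V`
the efficient information of `x` after projecting out the fitted design
under weights `π̂(1−π̂)`; a naive-variance variant (no projection) exists
behind a flag. Candidates collinear with the design score 0.

The single-marker comparator fits, per SNP, an ordinary (non-Firth)
logistic regression of status on that SNP plus the leading principal
components of the column-standardized genotype matrix (default 4, the
usual population-structure adjustment), takes likelihood-ratio p-values,
and applies Benjamini–Hochberg at level `q` (default 0.05). SNPs whose
unpenalized fit fails to converge (separation) fall back to the trend-test
p-value. All `p` fits run as one batched Newton iteration.

## Synthetic data

The generator emulates the structure the method is meant to exploit:

* **Genotypes.** Per-SNP minor allele frequencies are uniform on
  `maf_range` (default [0.1, 0.5]). Two latent Gaussian haplotype vectors
  per individual share an equicorrelation `block_rho` within each LD block
  and are thresholded at `Φ⁻¹(maf)`; summing the two allele indicators
  yields 0/1/2 genotypes with exact Hardy–Weinberg margins and
  within-block LD (the genotype-scale correlation sits below the latent
  `block_rho`, as verified against a brute-force copula oracle). Blocks
  are laid contiguously on six pseudo-chromosomes.
* **Trait.** `k_causal` SNPs — one per block, spread evenly along the
  genome, optionally restricted to common SNPs (`causal_maf_min`, 0.3 in
  the k6/k12/k24 presets, since complex-trait studies ascertain common
  causal variants) — get log-odds effects uniform on `effect_range`
  (default [0.3, 0.6], chosen to give intermediate per-SNP power at
  n = 1000). The intercept is calibrated by monotone root-finding so the
  mean simulated risk over the realized genotypes hits
  `target_prevalence` (default 0.5, balanced cases/controls); statuses are
  independent Bernoulli draws (prospective sampling).
* **Hidden causal SNPs.** A fraction (`hide_fraction`, 0.5 in the
  presets) of causal SNPs is removed before analysis, leaving only
  same-block LD proxies — the realistic situation where the associated
  marker tags, not is, the cause. Scenarios that would hide a SNP without
  a correlated partner are rejected at construction.

Everything is deterministic given the scenario seed (independent
SeedSequence streams for genotypes, causal choice, statuses and hiding).

What the generator does **not** emulate: population structure/admixture,
haplotype-level coalescent LD decay, genotyping error, missingness
patterns, sex chromosomes, and retrospective case-control ascertainment at
low prevalence. Passing tests therefore demonstrate the method's internal
error-control and power properties under its own model assumptions, not
robustness to confounding on real cohorts.

## Evaluation

A detection is a true positive when its genotype correlation (Pearson, on
the pre-hiding matrix) with some causal SNP exceeds `r_threshold` (default
0.3) in absolute value; several detections tagging one causal SNP count as
a single true positive. Power = detected causal / total causal;
misclassifications = false positives + missed causal; per-replicate FDP =
FP / max(1, TP + FP) (0 when nothing is detected — the standard
convention). For redundant selectors (the single-marker scan), false
positives are first collapsed into r-clusters — built greedily in genomic
order, admitting a SNP only if it correlates above `r_threshold` with
*every* current member, which provably satisfies the all-pairs invariant —
while criterion-based selection is scored unclustered (it already picks
one representative per region). The same constant serves matching and
clustering. `run_experiment` repeats generate → hide → select → score over
replicates (per-replicate seeds spawned from one seed) and reports means
with Monte-Carlo standard errors; with `k_causal = 0` the mean
false-positive count is the per-family error rate.

## Problem sizes and numerical choices

Simulation-backed checks run at desk scale, chosen as the smallest sizes
at which the asymptotic error-control claims are meaningfully testable:
FDR and global-null experiments use n = 1000, p = 1000 over 100
replicates; the power experiment uses the k6 preset (p = 500) over 50
replicates; search-optimality checks compare against exhaustive
enumeration at p = 12, n = 400 over 50 instances. Move acceptance requires
a criterion decrease > 1e-7; candidate refits warm-start from the
incumbent model and are cached by SNP set; intercept calibration is exact
to 1e-10 in mean risk. Degenerate inputs (constant SNPs, collinear
candidates, all-missing columns, non-binary phenotypes) raise or are
scored 0 as documented on each function.

## Known limitations

* No covariates other than SNPs in the selected model (the comparator's
  principal components are not available to the joint search).
* Index-window exchange neighborhoods ignore physical base-pair gaps.
* The exhaustive-search guarantee is only verified at tiny p; at GWAS
  scale FSS is a heuristic and can miss the global mBIC2 minimum.
* Quantitative traits, mixed-model structure correction, and genotype
  imputation beyond per-SNP mean filling are out of scope.
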