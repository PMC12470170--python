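# Methods

`mixdeconv` implements a complete in-silico study of forensic DNA mixture
deconvolution from massively parallel sequencing (MPS) read counts,
comparing two marker classes: microhaplotypes (MH) — short amplicons
carrying several phased SNPs, stutter-free and length-invariant across
alleles — and short tandem repeats (STR), whose alleles differ by whole
copies of a 3–5 bp motif and whose amplification produces stutter
artefacts. This note documents the models, the synthetic-data generator,
the numerical choices, and what the package's tests do and do not
demonstrate about real casework data.

## The probabilistic genotyping model

Evidence at a locus is the vector of retained allele read counts after an
analytical threshold (AT, default 11 reads: the minimum count treated as
signal). For a mixture of `K` contributors with proportions
`ω = (ω₁…ω_K)` on the simplex, panel-wide expected depth `μ` (reads per
locus at unit efficiency) and shared dispersion `θ`, a proposed genotype
set assigns each allele `a` the expectation

    E[a] = μ · e_l · Σ_k ω_k · d_k(a) / 2

where `e_l` is the locus's calibrated efficiency (mean 1 across the panel)
and `d_k(a) ∈ {0,1,2}` counts copies of `a` in contributor `k`'s genotype.
For STR loci, a calibrated fraction of each parent allele's expectation is
redistributed to the sequence one repeat unit shorter (stutter). Observed
counts of expected alleles are modelled as negative binomial with mean
`E[a]` and variance `E + E²/θ`; an expected allele that was not retained
contributes the NB probability of falling below the AT (drop-out); a
retained allele with no expected source is noise, with a Poisson law on
the number of noise alleles per locus and a geometric law (support
starting at the AT) on their counts.

Unknown contributors are marginalised by exact enumeration of unordered
genotypes over the locus's observed alleles plus a drop-out symbol `Q`,
weighted by Hardy–Weinberg priors from the allele frequency table; `Q`
carries the residual frequency mass (floored at the rare-allele floor
5/(2N)). Genotype posteriors are the prior-weighted likelihoods at the
fitted `(ω, μ, θ)`, marginalised per contributor. A call is reported
*Undetermined* when its posterior is strictly below 0.9 or the top
genotype proposes a drop-out; the boundary (exactly 0.9 is determinate)
is tested explicitly.

The likelihood ratio compares the fitted prosecution hypothesis
(suspect conditioned as a known contributor, `K−1` unknowns) against the
all-unknown defence hypothesis: `log₁₀ LR = (logL_Hp − logL_Hd)/ln 10`,
with separate maximum-likelihood fits per hypothesis (the
EuroForMix-style ML LR, no integration over parameters). A numerically
impossible prosecution hypothesis yields `−inf`, which is reported
explicitly rather than clamped.

### Fitting

The likelihood is maximised over `(ω, μ, θ)` with a deterministic
procedure: a fixed grid of simplex points (9 points for two contributors,
a 10%-step simplex grid for three) is scored at data-driven starting
values `μ₀` (mean retained reads per locus) and `θ₀` (calibrated
dispersion); the two best starts are refined with Nelder–Mead on
softmax/log-transformed parameters (`fatol` 1e-6). There is no randomness
anywhere in the fit, so identical inputs give identical results.

Two performance devices keep fits around a second at full panel scale
without changing results beyond reported precision: loci are grouped by
array shape so each objective evaluation is a handful of vectorised
tensor operations, and after the grid stage genotype sets whose best
log-likelihood across all grid points falls more than 60 log units below
the per-locus best are dropped (discarded posterior mass < e⁻⁶⁰). The
enumeration universe is capped at 8 observed alleles per locus for two
contributors (6 for three); capped-out alleles are treated as
unconditional noise.

## Calibration

Calibration consumes single-source samples with known genotypes. Every
retained allele receives a *dose*: 0 for noise, 1 for each allele of a
heterozygous locus, 2 for a homozygous allele. From the dosed counts:

* **Locus efficiency** — each locus's mean share of a sample's assigned
  reads, normalised to mean 1.
* **Dispersion** — pooled moment estimator from heterozygous (dose-1)
  pairs: `θ̂ = Σ m² / Σ max((c₁−c₂)²/2 − m, 0)` with `m = (c₁+c₂)/2`,
  which absorbs heterozygote imbalance into the NB variance.
* **Noise** — rate = mean number of dose-0 retained alleles per
  locus-sample (STR alleles one repeat below a true allele are stutter,
  not noise); the count law's geometric parameter is the MLE
  `p̂ = 1/(1 + mean(c − AT))`.
* **Stutter (STR)** — per locus, the ratio count(n−1)/count(parent) is
  regressed on the parent repeat number by weighted least squares
  (weights = parent read count, matching the ratio's sampling variance),
  using parents whose n−1 sequence is not itself a true allele and has at
  least twice the AT in parent reads; fewer than 3 points falls back to
  the panel-pooled mean ratio. Predictions are clamped to [0, 0.5).

The generator sheds a fraction `s` of a parent's reads to the stutter
sequence, so the calibrated ratio converges to `s/(1−s)`; deconvolution
converts back (`shed = r/(1+r)`), keeping the two sides consistent.

## The synthetic-data generator

No real cohort data ship with the package; the generator emulates the
statistical structure the study conditions assume:

* **Panels** — 74 MH loci (random 200–300 bp amplicons, 2–5 SNPs, 0–2
  "ignored" positions masked during calling) and 26 STR loci (random
  flanks, a 3–5 bp motif repeated 8–24 times in the reference). Locus
  efficiencies are log-normal (SD 0.25 on the log scale) normalised to
  mean 1; STR stutter rates are uniform on [0.03, 0.12], typical of
  sequence-level stutter.
* **Populations** — per locus, allele frequencies from a symmetric
  Dirichlet(1) over 5 alleles (MH) or 8 repeat-number alleles (STR);
  genotypes under Hardy–Weinberg equilibrium. Every allele carried by a
  sampled individual is in the frequency table with nonzero frequency.
* **Reads** — error-free amplicon copies at a fixed total per sample
  (370,000 for the MH panel, 220,000 for the STR panel; reduced panels
  scale depth proportionally to keep per-locus coverage). Per-allele
  weights multiply locus efficiency, a per-sample log-normal heterozygote
  imbalance multiplier (SD 0.15, consistent with published MPS
  heterozygote balances that rarely fall below 0.6), and for STRs an
  `exp(−0.02 · repeat)` length attenuation (longer alleles sequence less
  efficiently). Noise alleles arrive as Poisson(0.05) per locus with
  geometric read counts (p = 0.15). Totals are exact: noise counts are
  drawn first and the remainder is a single multinomial draw.
* **Mixtures** — read-level subsampling without replacement from the
  contributors' FASTQ read sets, with largest-remainder apportionment of
  the total (9:1 of 370,000 → 333,000 + 37,000) and a seeded shuffle.
  Truth never reaches the caller: read headers carry only the source
  sample id and a serial number.

What the generator does **not** model: PCR/sequencing base errors and
quality values (reads are exact amplicon copies; the caller is an
exact-matcher, standing in for alignment-based MH/STR analysis tools),
n+1 or double-back stutter, degradation, inhibition, index hopping, or
amplification correlation between contributors. Passing tests therefore
demonstrate the correctness and calibration of the inference machinery
under the stated generative assumptions — not performance on real
casework, where allele-calling errors and unmodelled artefacts add
failure modes.

## Study designs

Full scale, reproduced by the planner's arithmetic: per panel, 45 donor
pairs per two-person ratio (19:1, 9:1, 3:1, 1:1 → 180 mixtures/panel, 360
total) and 56 donor triples per three-person ratio (14:5:1, 14:3:3, 9:9:2
→ 168/panel, 336 total); 50 suspects per mixture, exactly one a true
contributor (two-person: the minor; 9:9:2: the minor; 14:3:3: the major;
14:5:1: the intermediate), giving 18,000 + 16,800 = 34,800 LR
deconvolutions, of which 17,640 + 16,464 involve non-contributors. Ten
donors admit C(10,3) = 120 triples; the design takes the first 56 in
lexicographic order (recorded in the manifest). Within pairs/triples,
roles follow lexicographic sample-id order.

Executed runs use a desk-scale profile (12 loci per panel, per-locus
depth matched to the full assays, 20 calibration samples, 6 mixtures per
unbalanced ratio and 20 per 1:1, reduced suspect panels). These sizes
were chosen so a complete run with tests finishes in minutes on one core
while keeping per-locus coverage, and are stated alongside every reported
number.

## Evaluation

Deconvolutions are scored per (locus, contributor) as exactly one of
Correct / Wrong / Undetermined; truth contributors are matched to fitted
contributor ranks by design-proportion rank, and equal-proportion blocks
(1:1 pairs, the 9:9:2 majors, the 14:3:3 minors) are matched by the
permutation minimising Wrong calls, since the labelling is genuinely
unidentifiable there. Duplicate deconvolutions merge into a consensus
that keeps only identical determinate calls. The random match probability
of a (partial) profile is the plain HWE product `Π p²` / `Π 2pq` over
determinate loci (no coancestry correction). Contributor-proportion
accuracy is compared between assays with Shapiro–Wilk checks (reported,
not gating) and a two-sided Wilcoxon rank sum test on absolute deviations
of the estimated major/minor ratio from the design ratio. A 1:1 estimate
is called "accurate" when the fitted ratio is ≤ 1.1.

## Known limitations

* The enumeration cap (8/6 observed alleles) and set pruning are exact in
  practice at the simulated noise levels but are approximations for
  extremely allele-dense loci.
* The dispersion estimator pools across loci; strongly locus-specific
  overdispersion would be averaged.
* Three-person fitting is supported and tested at small panel sizes; at
  74 loci with many observed alleles the joint enumeration is the
  dominant cost.
* `Q` (drop-out) aggregates all unobserved alleles; its stutter
  contribution is ignored, slightly favouring drop-out explanations at
  stutter-heavy STR loci.
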