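# mixdeconv

Probabilistic deconvolution of sequenced forensic DNA mixtures, comparing
microhaplotype (MH) and short-tandem-repeat (STR) marker panels.

Crime-scene samples often contain DNA from more than one person.
Interpreting such a mixture means inferring, from massively parallel
sequencing (MPS) read counts, each contributor's genotype at every marker
and the weight of evidence for or against a suspect's presence. MHs —
short amplicons carrying several phased SNPs — are attractive for this
because they produce no stutter artefacts and all alleles of a locus have
the same length, while STR alleles differ in length and shed stutter
reads one repeat unit below each allele. `mixdeconv` implements the whole
comparison as a tested, seedable pipeline for forensic genetics
researchers: synthetic single-source read sets, read-level mixture
simulation, amplicon allele calling, per-locus model calibration,
probabilistic genotyping, likelihood ratios, and scoring.

## The model

For a mixture of `K` contributors with proportions `ω` on the simplex,
depth `μ` and dispersion `θ`, a proposed genotype set gives allele `a` at
locus `l` the expected count

    E[a] = μ · e_l · Σ_k ω_k · d_k(a)/2

(`e_l` = calibrated locus efficiency, `d_k(a)` = copies of `a` in
contributor `k`'s genotype; for STRs a calibrated stutter fraction moves
to the n−1 sequence). Retained counts (≥ the analytical threshold of 11
reads) are negative binomial; expected-but-unseen alleles contribute the
probability of dropping below the threshold; unexplained retained alleles
follow a calibrated noise law. Unknown contributors are marginalised by
exact enumeration over observed alleles plus the drop-out symbol `Q` with
Hardy–Weinberg priors, `(ω, μ, θ)` is fitted by deterministic maximum
likelihood, and genotype calls with posterior below 0.9 (or proposing a
drop-out) are reported Undetermined. The evidential weight for a suspect
is `log₁₀ LR = (logL_Hp − logL_Hd)/ln 10` with Hp = "the suspect plus
K−1 unknowns" and Hd = "K unknowns". See `docs/methods.md` for the full
account.

## Worked example

```python
from collections import Counter

from mixdeconv import (
    build_panel, calibrate, call_alleles, classify, deconvolute,
    generate_reads, likelihood_ratio, mix, sample_population,
)
from mixdeconv.mixtures import MixtureSpec, ratio_to_proportions
from mixdeconv.reads import ReadGenerationParams

# a 12-locus microhaplotype panel and a synthetic population
panel = build_panel("MH", 12, seed=7)
freqs, people = sample_population(panel, n_alleles_per_locus=5,
                                  n_individuals=100, seed=8)

# calibrate from 20 single-source samples (depth scaled to 12 loci)
depth = 60_000
samples = []
for i, prof in enumerate(people[20:40]):
    reads = generate_reads(prof, panel,
                           ReadGenerationParams(total_reads=depth, seed=1000 + i))
    samples.append((prof, call_alleles(reads, panel)))
calib = calibrate(samples, panel)

# simulate a 3:1 two-person mixture and deconvolute it
major, minor = people[0], people[1]
spec = MixtureSpec((major.sample_id, minor.sample_id),
                   ratio_to_proportions("3:1"), depth, seed=5, label="3:1/demo")
mixture = mix([generate_reads(major, panel, ReadGenerationParams(depth, 101)),
               generate_reads(minor, panel, ReadGenerationParams(depth, 102))], spec)
counts = call_alleles(mixture, panel)
result = deconvolute(counts, noc=2, calib=calib, freqs=freqs)
print("fitted proportions:", [round(w, 3) for w in result.fit.omega])

records = classify(result, [major, minor], spec.proportions, spec.label)
print("classification:", dict(Counter(r.classification for r in records)))

# likelihood ratios: the true minor contributor vs a non-contributor
lr_true = likelihood_ratio(counts, minor, 2, calib, freqs, fit_hd=result.fit)
lr_non = likelihood_ratio(counts, people[50], 2, calib, freqs, fit_hd=result.fit)
print(f"log10 LR (true minor):      {lr_true.log10_lr:8.1f}")
print(f"log10 LR (non-contributor): {lr_non.log10_lr:8.1f}")
```

Output:

```
fitted proportions: [0.755, 0.245]
classification: {'Undetermined': 6, 'Correct': 18}
log10 LR (true minor):          10.6
log10 LR (non-contributor):    -25.2
```

The fit recovers the designed 3:1 proportions (0.755/0.245); 18 of the 24
(locus, contributor) genotypes are deconvoluted correctly and the rest are
flagged Undetermined rather than miscalled. The true minor contributor
receives overwhelming support (log₁₀ LR ≈ 10.6 from just 12 loci) while an
unrelated person from the same population is firmly excluded (≈ −25).

## Command line

A thin CLI wraps the library:

```bash
mixdeconv mixsim --sources a.fq --sources b.fq \
    --proportions 0.9 --proportions 0.1 --total 370000 --seed 11 --out mix.fq
mixdeconv call --panel panel.json --fastq mix.fq --at 11 --out counts.tsv
mixdeconv calibrate --panel panel.json --truth truth.tsv \
    --counts s1.tsv --counts s2.tsv --out calib.json
mixdeconv deconv --counts counts.tsv --noc 2 --calib calib.json \
    --freqs freqs.tsv --out result.json
mixdeconv lr --counts counts.tsv --suspect truth.tsv --suspect-id IND001 \
    --noc 2 --calib calib.json --freqs freqs.tsv
mixdeconv plan --full-scale      # design arithmetic only
mixdeconv run --out-dir results/study --seed 1
```

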