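"""Independent direct-summation reference for the mixture likelihood.

Everything here is written with explicit Python loops and scipy.stats
distributions, sharing no code with the package's vectorised engine, so it
can serve as an oracle for likelihoods and genotype posteriors on small
loci.
"""

import itertools
import math

from scipy import stats

Q = "Q"


def enumerate_pairs(symbols):
    return [
        (symbols[i], symbols[j])
        for i in range(len(symbols))
        for j in range(i, len(symbols))
    ]


def hwe_prior(pair, freq):
    a, b = pair
    return freq[a] ** 2 if a == b else 2.0 * freq[a] * freq[b]


def set_likelihood(
    counts, genotype_set, omega, mu, theta, eff, threshold,
    noise_rate, geom_p, stutter_ratio=None,
):
    """Likelihood of observed counts for one joint genotype set."""
    universe = sorted(set(counts) | {a for g in genotype_set for a in g} | {Q})
    expected = {a: 0.0 for a in universe}
    for w, pair in zip(omega, genotype_set):
        for a in pair:
            expected[a] += 0.5 * mu * eff * w
    if stutter_ratio:
        shed_out = {}
        for a in list(expected):
            try:
                n = int(a)
            except ValueError:
                continue
            target = str(n - 1)
            r = stutter_ratio.get(a, 0.0)
            if n >= 2 and r > 0 and expected[a] > 0:
                shed = expected[a] * r / (1.0 + r)
                shed_out[a] = shed
                expected.setdefault(target, 0.0)
                expected[target] += shed
        for a, s in shed_out.items():
            expected[a] -= s
    lik = 1.0
    n_noise = 0
    for a in universe:
        e = expected.get(a, 0.0)
        c = counts.get(a, 0)
        if a == Q:
            c = 0
        nb = stats.nbinom(theta, theta / (theta + e)) if e > 1e-9 else None
        if c >= threshold:
            if nb is not None:
                lik *= nb.pmf(c)
            else:
                n_noise += 1
                lik *= geom_p * (1.0 - geom_p) ** (c - threshold)
        else:
            if nb is not None:
                lik *= nb.cdf(threshold - 1)
    if noise_rate > 0:
        lik *= stats.poisson(noise_rate).pmf(n_noise)
    elif n_noise > 0:
        lik = 0.0
    return lik


def locus_likelihood_and_posteriors(
    counts, noc, omega, mu, theta, eff, threshold, freq, floor,
    noise_rate, geom_p,
):
    """Marginal likelihood and per-contributor genotype posteriors.

    ``counts`` maps observed (retained) alleles to read counts; genotypes
    are enumerated over those alleles plus Q, with HWE priors from ``freq``
    (Q takes the residual mass, floored).
    """
    observed = sorted(counts, key=lambda a: (-counts[a], a))
    symbols = observed + [Q]
    fr = {a: freq.get(a, floor) for a in observed}
    fr[Q] = max(1.0 - sum(fr.values()), floor)
    pairs = enumerate_pairs(symbols)
    total = 0.0
    marg = [{g: 0.0 for g in pairs} for _ in range(noc)]
    for gset in itertools.product(pairs, repeat=noc):
        prior = math.prod(hwe_prior(g, fr) for g in gset)
        lik = set_likelihood(
            counts, gset, omega, mu, theta, eff, threshold, noise_rate, geom_p
        )
        contrib = prior * lik
        total += contrib
        for k, g in enumerate(gset):
            marg[k][g] += contrib
    posteriors = [
        {g: (v / total if total > 0 else 0.0) for g, v in m.items()} for m in marg
    ]
    return total, posteriors
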