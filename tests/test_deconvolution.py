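import math

import numpy as np
import pytest

from _bruteforce import locus_likelihood_and_posteriors
from mixdeconv import (
    AlleleFrequencyTable,
    CalibrationModel,
    Hypothesis,
    Q,
    deconvolute,
    enumerate_genotypes,
    fit_hypothesis,
    likelihood_ratio,
    locus_log_likelihood,
)
from mixdeconv.calling import AlleleCountTable
from mixdeconv.deconvolution import MixtureModel
from mixdeconv.mixtures import MixtureSpec, ratio_to_proportions
from mixdeconv.population import GenotypeProfile
from mixdeconv import call_alleles, mix


def _simple_calib(loci, kind="MH", noise_rate=0.05, geom_p=0.2, threshold=11):
    n = len(loci)
    return CalibrationModel(
        panel_kind=kind,
        analytical_threshold=threshold,
        locus_efficiency={l: 1.0 for l in loci},
        dispersion=30.0,
        noise_rate=noise_rate,
        noise_geom_p=geom_p,
    )


class TestEnumeration:
    def test_single_allele_with_dropout(self):
        got = enumerate_genotypes(["a"], allow_dropout=True)
        assert set(got) == {("a", "a"), ("a", Q), (Q, Q)}

    def test_two_alleles_with_dropout_and_joint_count(self):
        got = enumerate_genotypes(["a", "b"], allow_dropout=True)
        assert len(got) == 6
        joint = [(g1, g2) for g1 in got for g2 in got]
        assert len(joint) == 36

    def test_two_alleles_without_dropout(self):
        got = enumerate_genotypes(["a", "b"], allow_dropout=False)
        assert set(got) == {("a", "a"), ("a", "b"), ("b", "b")}

    def test_empty_without_dropout_raises(self):
        with pytest.raises(ValueError):
            enumerate_genotypes([], allow_dropout=False)

    @pytest.mark.parametrize("n", [1, 2, 3, 4, 5])
    def test_counts_match_closed_form(self, n):
        alleles = [f"a{i}" for i in range(n)]
        assert len(enumerate_genotypes(alleles, True)) == (n + 1) * (n + 2) // 2
        assert len(enumerate_genotypes(alleles, False)) == n * (n + 1) // 2


class TestLocusLogLikelihood:
    def test_contributor_label_symmetry(self):
        calib = _simple_calib(["L1"])
        counts = {"A": 900, "B": 300}
        g1, g2 = ("A", "A"), ("A", "B")
        v1 = locus_log_likelihood(counts, [g1, g2], [0.7, 0.3], 1200, 30, calib, "L1")
        v2 = locus_log_likelihood(counts, [g2, g1], [0.3, 0.7], 1200, 30, calib, "L1")
        assert v1 == pytest.approx(v2, abs=1e-10)

    def test_poisson_limit(self):
        """At huge dispersion the NB law matches a Poisson implementation."""
        from scipy import stats

        calib = _simple_calib(["L1"], noise_rate=0.0)
        counts = {"A": 520, "B": 480}
        mu, eff = 1000.0, 1.0
        got = locus_log_likelihood(
            counts, [("A", "B")], [1.0], mu, 1e8, calib, "L1"
        )
        expected = sum(
            stats.poisson(0.5 * mu * eff).logpmf(c) for c in counts.values()
        )
        assert got == pytest.approx(expected, abs=1e-4)

    def test_empty_evidence_all_dropout(self):
        """No observed counts + QQ genotypes = pure drop-out baseline."""
        from scipy import stats

        calib = _simple_calib(["L1"], noise_rate=0.05)
        mu, theta = 800.0, 40.0
        got = locus_log_likelihood({}, [(Q, Q), (Q, Q)], [0.6, 0.4], mu, theta, calib, "L1")
        e = 0.5 * mu * 2.0  # both contributors fully dropped
        nb = stats.nbinom(theta, theta / (theta + e))
        expected = math.log(nb.cdf(10)) + stats.poisson(0.05).logpmf(0)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_invalid_arguments(self):
        calib = _simple_calib(["L1"])
        with pytest.raises(ValueError):
            locus_log_likelihood({"A": 50}, [("A", "A")], [0.5, 0.5], 100, 10, calib, "L1")
        with pytest.raises(ValueError):
            locus_log_likelihood({"A": 50}, [("A", "A")], [1.0], -5, 10, calib, "L1")


def _table_from(counts_by_locus, sample_id="mix"):
    return AlleleCountTable(sample_id=sample_id, counts=counts_by_locus)


class TestOracleEquivalence:
    def test_engine_matches_bruteforce_on_small_loci(self):
        """Vectorised likelihood and posteriors equal direct summation
        within 1e-6 relative on loci with <= 3 alleles, two contributors."""
        rng = np.random.default_rng(1234)
        for case in range(12):
            n_alleles = int(rng.integers(1, 4))
            alleles = [f"a{i}" for i in range(n_alleles)]
            counts = {
                a: int(rng.integers(11, 2000)) for a in alleles
            }
            raw = rng.dirichlet(np.ones(n_alleles + 1))
            freq_vals = raw / raw.sum()
            freqs = AlleleFrequencyTable(
                {"L1": {a: float(f) for a, f in zip(alleles + ["other"], freq_vals)}},
                population_size=100,
            )
            calib = _simple_calib(["L1"], noise_rate=0.1, geom_p=0.25)
            omega = (0.65, 0.35)
            mu = float(rng.uniform(500, 4000))
            theta = float(rng.uniform(5, 80))
            model = MixtureModel(_table_from({"L1": counts}), Hypothesis(2), calib, freqs)
            got_ll = model.per_locus_log_likelihood(np.array(omega), mu, theta)["L1"]
            got_post = model.posteriors(np.array(omega), mu, theta)["L1"]
            exp_total, exp_post = locus_likelihood_and_posteriors(
                counts, 2, omega, mu, theta, 1.0, 11,
                freqs.freqs["L1"], freqs.floor, 0.1, 0.25,
            )
            assert got_ll == pytest.approx(math.log(exp_total), rel=1e-6)
            for k in range(2):
                for g, p in exp_post[k].items():
                    key = tuple(sorted(g))
                    got_p = got_post[k].get(key, 0.0) + (
                        got_post[k].get(tuple(reversed(key)), 0.0) if key[0] != key[1] else 0.0
                    )
                    assert got_post[k][g] == pytest.approx(p, rel=1e-6, abs=1e-12)


@pytest.fixture(scope="module")
def mh_mixture(mh_ctx):
    a, b = mh_ctx.population[0], mh_ctx.population[1]
    ra, rb = mh_ctx.readset(a, 101), mh_ctx.readset(b, 102)
    spec = MixtureSpec(
        (a.sample_id, b.sample_id), ratio_to_proportions("3:1"),
        mh_ctx.depth, 5, "3:1/ab",
    )
    counts = call_alleles(mix([ra, rb], spec), mh_ctx.panel)
    return a, b, counts


class TestFitting:
    def test_single_contributor_degenerate_simplex(self, mh_ctx):
        prof = mh_ctx.population[2]
        counts = call_alleles(mh_ctx.readset(prof, 300), mh_ctx.panel)
        fit = fit_hypothesis(counts, Hypothesis(noc=1), mh_ctx.calib, mh_ctx.freqs)
        assert fit.omega == (1.0,)

    def test_fit_invariants(self, mh_ctx, mh_mixture):
        _, _, counts = mh_mixture
        fit = fit_hypothesis(counts, Hypothesis(noc=2), mh_ctx.calib, mh_ctx.freqs)
        assert sum(fit.omega) == pytest.approx(1.0, abs=1e-9)
        assert list(fit.omega) == sorted(fit.omega, reverse=True)
        assert np.isfinite(fit.log_likelihood)
        assert fit.mu > 0 and fit.theta > 0
        # per-locus decomposition sums to the total
        assert sum(fit.per_locus_log_likelihood.values()) == pytest.approx(
            fit.log_likelihood, abs=1e-6
        )

    def test_three_to_one_proportion_recovered(self, mh_ctx, mh_mixture):
        _, _, counts = mh_mixture
        fit = fit_hypothesis(counts, Hypothesis(noc=2), mh_ctx.calib, mh_ctx.freqs)
        assert 0.65 <= fit.omega[0] <= 0.85

    def test_fit_is_deterministic(self, mh_ctx, mh_mixture):
        _, _, counts = mh_mixture
        f1 = fit_hypothesis(counts, Hypothesis(noc=2), mh_ctx.calib, mh_ctx.freqs)
        f2 = fit_hypothesis(counts, Hypothesis(noc=2), mh_ctx.calib, mh_ctx.freqs)
        assert f1.omega == f2.omega
        assert f1.log_likelihood == f2.log_likelihood


class TestDeconvolute:
    def test_posteriors_within_unit_interval(self, mh_ctx, mh_mixture):
        _, _, counts = mh_mixture
        res = deconvolute(counts, 2, mh_ctx.calib, mh_ctx.freqs)
        for locus, calls in res.calls.items():
            assert len(calls) == 2
            for call in calls:
                assert 0.0 <= call.posterior <= 1.0 + 1e-12

    def test_determinate_rule_boundaries(self, mh_ctx, mh_mixture):
        """p >= 0.9 without drop-out is determinate; drop-out never is."""
        _, _, counts = mh_mixture
        res = deconvolute(counts, 2, mh_ctx.calib, mh_ctx.freqs)
        for locus, calls in res.calls.items():
            for rank, call in enumerate(calls):
                det = res.is_determinate(locus, rank)
                if call.dropout or call.posterior < 0.9:
                    assert not det
                else:
                    assert det

    def test_invalid_noc_rejected(self, mh_ctx, mh_mixture):
        _, _, counts = mh_mixture
        with pytest.raises(ValueError):
            deconvolute(counts, 5, mh_ctx.calib, mh_ctx.freqs)


class TestLikelihoodRatio:
    def test_identical_hypotheses_give_zero(self, mh_ctx, mh_mixture):
        """Hp == Hd (same all-unknown hypothesis) -> log10 LR = 0 exactly."""
        _, _, counts = mh_mixture
        f1 = fit_hypothesis(counts, Hypothesis(noc=2), mh_ctx.calib, mh_ctx.freqs)
        f2 = fit_hypothesis(counts, Hypothesis(noc=2), mh_ctx.calib, mh_ctx.freqs)
        assert (f1.log_likelihood - f2.log_likelihood) / math.log(10) == 0.0

    def test_true_contributor_strongly_included(self, mh_ctx, mh_mixture):
        a, b, counts = mh_mixture
        lr = likelihood_ratio(counts, b, 2, mh_ctx.calib, mh_ctx.freqs)
        assert lr.log10_lr > 5

    def test_noncontributor_strongly_excluded(self, mh_ctx, mh_mixture):
        _, _, counts = mh_mixture
        stranger = mh_ctx.population[50]
        lr = likelihood_ratio(counts, stranger, 2, mh_ctx.calib, mh_ctx.freqs)
        assert lr.log10_lr < -5

    def test_per_locus_terms_sum_to_total(self, mh_ctx, mh_mixture):
        a, b, counts = mh_mixture
        lr = likelihood_ratio(counts, b, 2, mh_ctx.calib, mh_ctx.freqs)
        assert sum(lr.per_locus_log10_lr.values()) == pytest.approx(
            lr.log10_lr, abs=1e-6
        )
        assert lr.log10_lr == pytest.approx(
            (lr.logl_hp - lr.logl_hd) / math.log(10), abs=1e-9
        )

    def test_hypothesis_validation(self):
        with pytest.raises(ValueError):
            Hypothesis(noc=0)
        prof = GenotypeProfile("s", {})
        with pytest.raises(ValueError):
            Hypothesis(noc=1, known_contributors=(prof, prof))
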