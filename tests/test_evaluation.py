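import numpy as np
import pytest

from mixdeconv import (
    AlleleFrequencyTable,
    classify,
    compare_proportion_estimates,
    consensus,
    contributor_ratio,
    overall_error_rate,
    random_match_probability,
    summarize,
)
from mixdeconv.deconvolution import (
    DeconvolutionResult,
    FitResult,
    GenotypeCall,
    Hypothesis,
    Q,
)
from mixdeconv.errors import InsufficientDataError
from mixdeconv.population import GenotypeProfile


def _result(calls, omega=(0.75, 0.25)):
    fit = FitResult(
        omega=tuple(omega),
        omega_by_contributor=tuple(omega),
        mu=1000.0,
        theta=30.0,
        log_likelihood=-10.0,
        per_locus_log_likelihood={},
        hypothesis=Hypothesis(noc=len(omega)),
    )
    return DeconvolutionResult(fit=fit, calls=calls)


def _call(genotype, posterior, dropout=False):
    return GenotypeCall(genotype=genotype, posterior=posterior, dropout=dropout)


TRUTH = [
    GenotypeProfile("major", {"L1": ("a", "b")}),
    GenotypeProfile("minor", {"L1": ("a", "c")}),
]


class TestClassify:
    def test_correct_call(self):
        res = _result({"L1": [_call(("a", "b"), 0.97), _call(("a", "c"), 0.95)]})
        recs = classify(res, TRUTH, (0.75, 0.25), "m")
        assert [r.classification for r in recs] == ["Correct", "Correct"]

    def test_one_wrong_allele_is_wrong(self):
        res = _result({"L1": [_call(("a", "b"), 0.97), _call(("a", "a"), 0.95)]})
        recs = classify(res, TRUTH, (0.75, 0.25), "m")
        assert recs[1].classification == "Wrong"

    def test_threshold_is_strictly_below(self):
        """posterior 0.90 is determinate; 0.89... is Undetermined."""
        res = _result({"L1": [_call(("a", "b"), 0.90), _call(("a", "c"), 0.8999)]})
        recs = classify(res, TRUTH, (0.75, 0.25), "m")
        assert recs[0].classification == "Correct"
        assert recs[1].classification == "Undetermined"

    def test_dropout_genotype_is_undetermined(self):
        res = _result({"L1": [_call(("a", "b"), 0.99), _call(("a", Q), 0.99, True)]})
        recs = classify(res, TRUTH, (0.75, 0.25), "m")
        assert recs[1].classification == "Undetermined"

    def test_equal_proportions_matched_to_minimise_wrong(self):
        # ranks carry the two truth genotypes in swapped order; with a 1:1
        # design either pairing is admissible, so the zero-wrong one wins
        res = _result(
            {"L1": [_call(("a", "c"), 0.95), _call(("a", "b"), 0.95)]},
            omega=(0.51, 0.49),
        )
        recs = classify(res, TRUTH, (0.5, 0.5), "m")
        assert [r.classification for r in recs] == ["Correct", "Correct"]

    def test_unequal_proportions_fix_the_pairing(self):
        res = _result({"L1": [_call(("a", "c"), 0.95), _call(("a", "b"), 0.95)]})
        recs = classify(res, TRUTH, (0.75, 0.25), "m")
        assert [r.classification for r in recs] == ["Wrong", "Wrong"]

    def test_contributor_count_mismatch_rejected(self):
        res = _result({"L1": [_call(("a", "b"), 0.95), _call(("a", "c"), 0.95)]})
        with pytest.raises(ValueError):
            classify(res, TRUTH[:1], (1.0,), "m")


class TestConsensus:
    def test_identical_determinate_calls_kept(self):
        r1 = _result({"L1": [_call(("a", "b"), 0.95), _call(("a", "c"), 0.95)]})
        r2 = _result({"L1": [_call(("a", "b"), 0.96), _call(("a", "c"), 0.94)]})
        cp = consensus(r1, r2)
        assert cp.genotypes[("L1", 0)] == ("a", "b")
        assert cp.provenance[("L1", 0)] == "both"

    def test_disagreement_is_undetermined(self):
        r1 = _result({"L1": [_call(("a", "b"), 0.95), _call(("a", "c"), 0.95)]})
        r2 = _result({"L1": [_call(("a", "a"), 0.95), _call(("a", "c"), 0.95)]})
        cp = consensus(r1, r2)
        assert cp.genotypes[("L1", 0)] is None
        assert cp.provenance[("L1", 0)] == "disagree"

    def test_one_undetermined_side_is_undetermined(self):
        r1 = _result({"L1": [_call(("a", "b"), 0.95), _call(("a", "c"), 0.95)]})
        r2 = _result({"L1": [_call(("a", "b"), 0.5), _call(("a", "c"), 0.95)]})
        cp = consensus(r1, r2)
        assert cp.genotypes[("L1", 0)] is None
        assert cp.provenance[("L1", 0)] == "undetermined"

    def test_consensus_never_invents_genotypes(self):
        r1 = _result({"L1": [_call(("a", "b"), 0.95), _call(("b", "c"), 0.95)]})
        r2 = _result({"L1": [_call(("a", "c"), 0.95), _call(("a", "c"), 0.99)]})
        cp = consensus(r1, r2)
        for key, g in cp.genotypes.items():
            if g is not None:
                assert g in {("a", "b"), ("b", "c"), ("a", "c")}

    def test_locus_mismatch_rejected(self):
        r1 = _result({"L1": [_call(("a", "b"), 0.95), _call(("a", "c"), 0.95)]})
        r2 = _result({"L2": [_call(("a", "b"), 0.95), _call(("a", "c"), 0.95)]})
        with pytest.raises(ValueError):
            consensus(r1, r2)


class TestRMP:
    def _freqs(self, table):
        return AlleleFrequencyTable(table, population_size=100)

    def test_empty_profile_gives_one(self):
        freqs = self._freqs({"L1": {"a": 1.0}})
        assert random_match_probability({}, freqs) == 1.0
        assert random_match_probability({("L1", 0): None}, freqs) == 1.0

    def test_single_heterozygous_locus_half(self):
        freqs = self._freqs({"L1": {"a": 0.5, "b": 0.5}})
        assert random_match_probability({("L1", 0): ("a", "b")}, freqs) == pytest.approx(0.5)

    def test_multilocus_product_matches_direct_oracle(self):
        rng = np.random.default_rng(77)
        table, genotypes = {}, {}
        for i in range(10):
            locus = f"L{i}"
            p = rng.dirichlet(np.ones(4))
            alleles = ["a", "b", "c", "d"]
            table[locus] = {a: float(x) for a, x in zip(alleles, p / p.sum())}
            pair = tuple(sorted(rng.choice(alleles, size=2, replace=rng.random() < 0.5)))
            if len(pair) == 1:
                pair = (pair[0], pair[0])
            genotypes[(locus, 0)] = pair
        freqs = self._freqs(table)
        got = random_match_probability(genotypes, freqs)
        expected = 1.0
        for (locus, _), (a, b) in genotypes.items():
            pa, pb = table[locus][a], table[locus][b]
            expected *= pa * pa if a == b else 2 * pa * pb
        assert got == pytest.approx(expected, rel=1e-12)

    def test_rmp_monotone_in_loci(self):
        freqs = self._freqs({"L1": {"a": 0.5, "b": 0.5}, "L2": {"a": 0.3, "b": 0.7}})
        partial = random_match_probability({("L1", 0): ("a", "b")}, freqs)
        full = random_match_probability(
            {("L1", 0): ("a", "b"), ("L2", 0): ("a", "a")}, freqs
        )
        assert full <= partial


class TestProportionComparison:
    def test_identical_groups_not_significant(self):
        vals = [1.1, 1.3, 0.9, 1.2, 1.0, 1.4]
        out = compare_proportion_estimates(vals, vals, expected_ratio=1.0)
        assert out["wilcoxon_p"] > 0.99

    def test_shifted_group_detected_and_matches_permutation_oracle(self):
        rng = np.random.default_rng(5)
        mh = list(1.0 + 0.1 * rng.standard_normal(45))
        st = [x + 1.0 for x in 1.0 + 0.1 * rng.standard_normal(45)]
        out = compare_proportion_estimates(mh, st, expected_ratio=1.0)
        assert out["wilcoxon_p"] < 0.001
        # permutation oracle on the rank-sum statistic
        dev = np.abs(np.array(mh + st) - 1.0)
        labels = np.array([0] * 45 + [1] * 45)
        from scipy.stats import rankdata

        obs = rankdata(dev)[labels == 0].sum()
        perm_rng = np.random.default_rng(6)
        n_extreme = 0
        n_perm = 2000
        expected_mean = rankdata(dev).sum() * 45 / 90
        for _ in range(n_perm):
            perm = perm_rng.permutation(labels)
            s = rankdata(dev)[perm == 0].sum()
            if abs(s - expected_mean) >= abs(obs - expected_mean):
                n_extreme += 1
        assert (n_extreme + 1) / (n_perm + 1) < 0.001

    def test_constant_group_still_compares(self):
        out = compare_proportion_estimates(
            [1.0, 1.0, 1.0, 1.0], [2.0, 2.1, 2.2, 1.9], expected_ratio=1.0
        )
        assert np.isnan(out["shapiro_p_mh"])  # degenerate group flagged
        assert out["wilcoxon_p"] < 0.05

    def test_too_small_groups_rejected(self):
        with pytest.raises(InsufficientDataError):
            compare_proportion_estimates([1.0], [1.0, 2.0, 3.0], 1.0)


class TestSummaries:
    def _records(self, classifications, label="19:1/a+b"):
        from mixdeconv.evaluation import EvaluationRecord

        return [
            EvaluationRecord(label, f"L{i}", i % 2, ("a", "a"), ("a", "a"), cls)
            for i, cls in enumerate(classifications)
        ]

    def test_rows_partition_to_hundred_percent(self):
        recs = self._records(
            ["Correct", "Wrong", "Undetermined", "Correct", "Correct", "Wrong"]
        )
        table = summarize(recs, {"19:1/a+b": "19:1"})
        for _, row in table.iterrows():
            assert row["Correct"] + row["Wrong"] + row["Undetermined"] == pytest.approx(
                100.0, abs=0.1
            )

    def test_all_undetermined(self):
        recs = self._records(["Undetermined"] * 6)
        table = summarize(recs, {"19:1/a+b": "19:1"})
        for _, row in table.iterrows():
            assert (row["Correct"], row["Wrong"], row["Undetermined"]) == (0, 0, 100)

    def test_overall_error_rate(self):
        recs = self._records(["Correct", "Wrong", "Wrong", "Undetermined"])
        wrong, total, pct = overall_error_rate(recs)
        assert (wrong, total) == (2, 4)
        assert pct == pytest.approx(50.0)


def test_contributor_ratio_is_major_over_minor():
    assert contributor_ratio((0.25, 0.75)) == pytest.approx(3.0)
    assert contributor_ratio((0.5, 0.5)) == pytest.approx(1.0)
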