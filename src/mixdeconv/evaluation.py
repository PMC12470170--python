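"""Scoring deconvolutions against truth, consensus profiles and statistics.

Every (locus, contributor) call is classified as exactly one of Correct,
Wrong or Undetermined: Undetermined when the posterior is strictly below
the probability threshold (0.9 by default) or the proposed genotype
contains a drop-out; otherwise Correct when the called pair equals the
truth and Wrong when at least one allele is mispredicted.  Truth
contributors are matched to fitted contributor ranks by proportion rank;
for contributors designed to contribute equally the pairing is ambiguous,
so all pairings of the tied block are evaluated and the one minimising
Wrong calls is kept.

Duplicate deconvolutions merge into a consensus that keeps only identical
determinate calls.  The random match probability (RMP) of a (partial)
profile is the product of Hardy-Weinberg genotype frequencies over its
determinate loci.  Contributor-proportion accuracy across assays is
compared with Shapiro-Wilk normality checks and a two-sided Wilcoxon rank
sum test on the absolute deviations of the estimated major/minor ratio from
the design ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .deconvolution import DeconvolutionResult
from .errors import InsufficientDataError
from .population import AlleleFrequencyTable, GenotypeProfile

CLASSIFICATIONS = ("Correct", "Wrong", "Undetermined")


@dataclass(frozen=True)
class EvaluationRecord:
    mixture_label: str
    locus: str
    contributor_rank: int  # 0 = largest fitted proportion
    truth_genotype: tuple
    called_genotype: tuple | None
    classification: str


@dataclass
class ConsensusProfile:
    """Merged duplicate deconvolutions: identical determinate calls only."""

    genotypes: dict  # (locus, rank) -> genotype tuple or None
    provenance: dict  # (locus, rank) -> "both" | "disagree" | "undetermined"

    def determinate(self):
        return {k: g for k, g in self.genotypes.items() if g is not None}


def _classify_one(call, truth_pair, p_threshold: float) -> str:
    if call.posterior < p_threshold or call.dropout:
        return "Undetermined"
    return "Correct" if tuple(sorted(call.genotype)) == tuple(sorted(truth_pair)) else "Wrong"


def _tied_blocks(proportions) -> list:
    """Indices of truth contributors grouped by equal design proportion."""
    blocks = []
    for i, p in enumerate(proportions):
        if blocks and abs(proportions[blocks[-1][-1]] - p) < 1e-9:
            blocks[-1].append(i)
        else:
            blocks.append([i])
    return blocks


def classify(
    result: DeconvolutionResult,
    truth: list,
    truth_proportions,
    mixture_label: str = "",
    p_threshold: float | None = None,
) -> list:
    """Classify every (locus, contributor) of a deconvolution.

    ``truth`` lists the contributors' GenotypeProfiles in design order and
    ``truth_proportions`` their design proportions.  Ranks are matched to
    truth by descending proportion; equal-proportion blocks are matched by
    the permutation minimising Wrong calls.
    """
    if len(truth) != len(truth_proportions):
        raise ValueError("truth and proportions differ in length")
    if len(truth) != len(result.fit.omega):
        raise ValueError("contributor count mismatch with the fitted result")
    p_threshold = result.p_threshold if p_threshold is None else p_threshold
    order = sorted(
        range(len(truth)), key=lambda i: (-truth_proportions[i], truth[i].sample_id)
    )
    truth_sorted = [truth[i] for i in order]
    props_sorted = [truth_proportions[i] for i in order]

    loci = sorted(result.calls)

    def records_for(assignment) -> list:
        recs = []
        for locus in loci:
            for rank, truth_idx in enumerate(assignment):
                call = result.calls[locus][rank]
                truth_pair = truth_sorted[truth_idx].genotypes[locus]
                cls = _classify_one(call, truth_pair, p_threshold)
                recs.append(
                    EvaluationRecord(
                        mixture_label=mixture_label,
                        locus=locus,
                        contributor_rank=rank,
                        truth_genotype=tuple(truth_pair),
                        called_genotype=None
                        if cls == "Undetermined"
                        else tuple(call.genotype),
                        classification=cls,
                    )
                )
        return recs

    # permute within equal-proportion blocks only, keep fewest Wrong calls
    best = None
    blocks = _tied_blocks(props_sorted)
    assignments = [[]]
    for block in blocks:
        assignments = [
            a + list(perm) for a in assignments for perm in permutations(block)
        ]
    for assignment in assignments:
        recs = records_for(assignment)
        n_wrong = sum(r.classification == "Wrong" for r in recs)
        key = (n_wrong, tuple(assignment))
        if best is None or key < best[0]:
            best = (key, recs)
    return best[1]


def consensus(r1: DeconvolutionResult, r2: DeconvolutionResult) -> ConsensusProfile:
    """Merge duplicate deconvolutions, keeping identical determinate calls."""
    if sorted(r1.calls) != sorted(r2.calls):
        raise ValueError("duplicate deconvolutions cover different loci")
    genotypes = {}
    provenance = {}
    for locus in sorted(r1.calls):
        if len(r1.calls[locus]) != len(r2.calls[locus]):
            raise ValueError(f"{locus}: contributor count differs between replicates")
        for rank in range(len(r1.calls[locus])):
            key = (locus, rank)
            d1 = r1.is_determinate(locus, rank)
            d2 = r2.is_determinate(locus, rank)
            if not (d1 and d2):
                genotypes[key] = None
                provenance[key] = "undetermined"
                continue
            g1 = tuple(sorted(r1.calls[locus][rank].genotype))
            g2 = tuple(sorted(r2.calls[locus][rank].genotype))
            if g1 == g2:
                genotypes[key] = g1
                provenance[key] = "both"
            else:
                genotypes[key] = None
                provenance[key] = "disagree"
    return ConsensusProfile(genotypes=genotypes, provenance=provenance)


def random_match_probability(
    genotypes: dict, freqs: AlleleFrequencyTable
) -> float:
    """HWE multilocus match probability of a (partial) profile.

    ``genotypes`` maps locus -> allele pair (or None for Undetermined, which
    contributes a factor of 1).  Accepts a ConsensusProfile-style dict keyed
    by (locus, rank) as well; the rank is ignored for frequency lookup.
    """
    rmp = 1.0
    for key, pair in genotypes.items():
        if pair is None:
            continue
        locus = key[0] if isinstance(key, tuple) and not isinstance(key, str) else key
        a, b = pair
        pa, pb = freqs.get(locus, a), freqs.get(locus, b)
        rmp *= pa * pa if a == b else 2.0 * pa * pb
    return rmp


def contributor_ratio(omega) -> float:
    """Estimated major/minor ratio (>= 1) from fitted proportions."""
    w = sorted(omega, reverse=True)
    return w[0] / w[-1]


def compare_proportion_estimates(
    mh_ratios, str_ratios, expected_ratio: float
) -> dict:
    """Shapiro-Wilk per group plus Wilcoxon rank sum across groups.

    The compared quantity is each mixture's absolute deviation of the
    estimated major/minor ratio from the design ratio.
    """
    mh = np.asarray(list(mh_ratios), dtype=float)
    st = np.asarray(list(str_ratios), dtype=float)
    if len(mh) < 3 or len(st) < 3:
        raise InsufficientDataError("need at least 3 ratios per group")
    dev_mh = np.abs(mh - expected_ratio)
    dev_st = np.abs(st - expected_ratio)
    out = {}
    for name, dev in (("mh", dev_mh), ("str", dev_st)):
        if np.ptp(dev) == 0:
            out[f"shapiro_p_{name}"] = float("nan")  # degenerate, flagged
        else:
            out[f"shapiro_p_{name}"] = float(stats.shapiro(dev).pvalue)
    if np.ptp(np.concatenate([dev_mh, dev_st])) == 0:
        out["wilcoxon_p"] = 1.0
    else:
        out["wilcoxon_p"] = float(stats.ranksums(dev_mh, dev_st).pvalue)
    return out


def summarize(records, ratio_of, role_names=None) -> pd.DataFrame:
    """Success-rate table: percent Correct/Wrong/Undetermined per row.

    ``ratio_of`` maps a mixture label to its ratio string; rows are
    (ratio, contributor rank).  Percentages are rounded to one decimal and
    each row sums to 100 +- 0.1.
    """
    rows = []
    df = pd.DataFrame(
        [
            {
                "ratio": ratio_of[r.mixture_label],
                "rank": r.contributor_rank,
                "classification": r.classification,
            }
            for r in records
        ]
    )
    if df.empty:
        return pd.DataFrame(
            columns=["ratio", "contributor", "Correct", "Wrong", "Undetermined", "n"]
        )
    for (ratio, rank), grp in df.groupby(["ratio", "rank"], sort=True):
        n = len(grp)
        counts = grp["classification"].value_counts()
        row = {"ratio": ratio, "contributor": rank + 1, "n": n}
        for cls in CLASSIFICATIONS:
            row[cls] = round(100.0 * counts.get(cls, 0) / n, 1)
        rows.append(row)
    return pd.DataFrame(rows, columns=["ratio", "contributor", "Correct", "Wrong", "Undetermined", "n"])


def overall_error_rate(records) -> tuple:
    """(wrong, total, percent) across all evaluated genotypes."""
    total = len(records)
    wrong = sum(r.classification == "Wrong" for r in records)
    pct = 100.0 * wrong / total if total else 0.0
    return wrong, total, pct
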