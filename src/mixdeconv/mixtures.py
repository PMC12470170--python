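"""Mixture construction from single-source read sets.

A mixture FASTQ is produced by sampling, without replacement, an exact
number of reads from each contributor's single-source read set and shuffling
the union.  Read counts per contributor follow largest-remainder rounding of
``total_reads * proportion`` (e.g. a 9:1 mixture of 370,000 reads takes
333,000 reads from the major and 37,000 from the minor contributor), so the
output total is always exact.

The two study designs are also built here: all 45 unordered pairs of a
10-donor cohort per two-person ratio (19:1, 9:1, 3:1, 1:1) and 56 donor
triples per three-person ratio (14:5:1, 14:3:3, 9:9:2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from itertools import combinations

import numpy as np

from .errors import InsufficientReadsError
from .reads import ReadSet
from .util import derive_seed

TWO_PERSON_RATIOS = ("19:1", "9:1", "3:1", "1:1")
THREE_PERSON_RATIOS = ("14:5:1", "14:3:3", "9:9:2")
#: ratio grid of the laboratory-typed two-person mixtures
REAL_GRID_RATIOS = ("29:1", "9:1", "3:1", "2:1", "1:1", "1:2", "1:3", "1:9", "1:29")


def ratio_to_proportions(ratio: str) -> tuple:
    parts = [float(x) for x in ratio.split(":")]
    total = sum(parts)
    return tuple(p / total for p in parts)


@dataclass(frozen=True)
class MixtureSpec:
    """One mixture: ordered contributors, proportions, total reads, seed."""

    contributor_sample_ids: tuple
    proportions: tuple
    total_reads: int
    seed: int
    label: str

    def __post_init__(self):
        if len(self.contributor_sample_ids) != len(self.proportions):
            raise ValueError("contributors and proportions differ in length")
        if not self.contributor_sample_ids:
            raise ValueError("at least one contributor required")
        if any(p <= 0 or p > 1 for p in self.proportions):
            raise ValueError("proportions must lie in (0, 1]")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")
        if self.total_reads <= 0:
            raise ValueError("total_reads must be positive")


@dataclass
class MixtureDesign:
    """A grid of mixture specs for one panel kind."""

    panel_kind: str
    ratio_labels: tuple
    mixture_specs: list = field(default_factory=list)

    def specs_for_ratio(self, ratio: str):
        return [s for s in self.mixture_specs if s.label.startswith(f"{ratio}/")]

    def to_json(self, path) -> None:
        payload = {
            "panel_kind": self.panel_kind,
            "ratio_labels": list(self.ratio_labels),
            "mixture_specs": [
                {**asdict(s), "read_counts": apportion_reads(s.total_reads, s.proportions)}
                for s in self.mixture_specs
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def apportion_reads(total_reads: int, proportions) -> list:
    """Integer read counts per contributor by largest-remainder rounding.

    The result sums exactly to ``total_reads``; remainder ties go to the
    earlier contributor.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    props = [float(p) for p in proportions]
    if any(p < 0 for p in props):
        raise ValueError("proportions must be nonnegative")
    if abs(sum(props) - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    exact = [total_reads * p for p in props]
    floors = [int(np.floor(x)) for x in exact]
    shortfall = total_reads - sum(floors)
    remainders = [x - f for x, f in zip(exact, floors)]
    # stable sort: largest remainder first, earlier contributor wins ties
    order = sorted(range(len(props)), key=lambda i: (-remainders[i], i))
    for i in order[:shortfall]:
        floors[i] += 1
    return floors


def mix(readsets, spec: MixtureSpec) -> ReadSet:
    """Create a mixture read set per ``spec`` from single-source read sets.

    Sampling per source is without replacement with a per-source seed derived
    from the spec seed, label and source index; the union is then shuffled.
    Deterministic for identical inputs.
    """
    if len(readsets) != len(spec.contributor_sample_ids):
        raise ValueError("number of read sets must match contributors")
    counts = apportion_reads(spec.total_reads, spec.proportions)
    picked_ids: list = []
    picked_seqs: list = []
    for k, (rs, need) in enumerate(zip(readsets, counts)):
        if need > len(rs):
            raise InsufficientReadsError(
                f"source {rs.label!r} has {len(rs)} reads, {need} requested"
            )
        # seed by contributor id: jointly permuting sources and proportions
        # then yields the same multiset of sampled reads
        rng = np.random.default_rng(
            derive_seed(spec.seed, spec.label, spec.contributor_sample_ids[k])
        )
        idx = rng.choice(len(rs), size=need, replace=False)
        picked_ids.extend(rs.ids[i] for i in idx)
        picked_seqs.extend(rs.seqs[i] for i in idx)
    rng = np.random.default_rng(derive_seed(spec.seed, spec.label, "shuffle"))
    order = rng.permutation(len(picked_ids))
    out = ReadSet(label=spec.label)
    out.ids = [picked_ids[i] for i in order]
    out.seqs = [picked_seqs[i] for i in order]
    return out


def _design(
    panel_kind: str,
    sample_ids,
    total_reads: int,
    base_seed: int,
    ratios,
    groups,
) -> MixtureDesign:
    design = MixtureDesign(panel_kind=panel_kind, ratio_labels=tuple(ratios))
    for ratio in ratios:
        props = ratio_to_proportions(ratio)
        for group in groups:
            label = f"{ratio}/" + "+".join(group)
            design.mixture_specs.append(
                MixtureSpec(
                    contributor_sample_ids=tuple(group),
                    proportions=props,
                    total_reads=total_reads,
                    seed=derive_seed(base_seed, panel_kind, label),
                    label=label,
                )
            )
    return design


def build_two_person_design(
    panel_kind: str,
    sample_ids,
    total_reads: int,
    base_seed: int,
    ratios=TWO_PERSON_RATIOS,
    *,
    cohort_size: int = 10,
) -> MixtureDesign:
    """All unordered donor pairs per ratio; 45 pairs x 4 ratios at full scale.

    Within a pair the lexicographically smaller sample id takes the major
    role in unbalanced ratios.
    """
    ids = sorted(sample_ids)
    if len(ids) != cohort_size or len(set(ids)) != cohort_size:
        raise ValueError(f"expected {cohort_size} distinct sample ids, got {len(ids)}")
    pairs = list(combinations(ids, 2))
    return _design(panel_kind, ids, total_reads, base_seed, ratios, pairs)


def build_three_person_design(
    panel_kind: str,
    sample_ids,
    total_reads: int,
    base_seed: int,
    ratios=THREE_PERSON_RATIOS,
    *,
    cohort_size: int = 10,
    triples_per_ratio: int = 56,
) -> MixtureDesign:
    """First ``triples_per_ratio`` donor triples (lexicographic) per ratio.

    Contributor roles within a triple follow lexicographic order of the
    sample ids (first id = largest ratio part).
    """
    ids = sorted(sample_ids)
    if len(ids) != cohort_size or len(set(ids)) != cohort_size:
        raise ValueError(f"expected {cohort_size} distinct sample ids, got {len(ids)}")
    triples = list(combinations(ids, 3))[:triples_per_ratio]
    return _design(panel_kind, ids, total_reads, base_seed, ratios, triples)
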