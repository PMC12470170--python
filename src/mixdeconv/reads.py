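"""Amplicon read simulation for single-source samples.

The generator emulates the statistical structure of targeted MPS data from
a multiplexed amplicon assay:

* per-locus read shares proportional to a locus amplification efficiency;
* heterozygote imbalance via a per-sample, per-allele log-normal multiplier;
* fewer reads for longer STR alleles (multiplicative attenuation per repeat);
* STR stutter: a fraction of each parent allele's reads carry the sequence
  one repeat unit shorter;
* low-level noise alleles (Poisson number per locus, geometric read counts).

The read count of the output is exactly ``total_reads``: noise reads are
drawn first and the remainder is apportioned by a single multinomial draw
over the per-sequence weights.  Reads are error-free amplicon copies with a
constant placeholder base quality; read identifiers carry the sample id and
a serial number only, never the generating allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panels import LocusPanel, LocusDefinition
from .population import GenotypeProfile
from .util import BASES

#: constant Phred+33 quality character (Q40) used for all simulated reads
QUALITY_CHAR = "I"


@dataclass
class ReadSet:
    """An in-memory FASTQ-equivalent: parallel lists of ids and sequences."""

    label: str
    ids: list = field(default_factory=list)
    seqs: list = field(default_factory=list)

    def __len__(self):
        return len(self.seqs)

    def to_fastq(self, path) -> None:
        with open(path, "w") as fh:
            for rid, seq in zip(self.ids, self.seqs):
                fh.write(f"@{rid}\n{seq}\n+\n{QUALITY_CHAR * len(seq)}\n")

    @classmethod
    def from_fastq(cls, path, label=None) -> "ReadSet":
        from Bio import SeqIO

        rs = cls(label=label or str(path))
        for rec in SeqIO.parse(str(path), "fastq"):
            rs.ids.append(rec.id)
            rs.seqs.append(str(rec.seq))
        return rs


@dataclass(frozen=True)
class ReadGenerationParams:
    """Knobs of the single-source read generator.

    ``total_reads`` defaults mirror the assays emulated downstream (370,000
    for the 74-locus MH panel, 220,000 for the 26-locus STR kit; pass the
    appropriate value).  ``heterozygote_imbalance_sd`` is the log-scale SD of
    the per-allele multiplier; ``length_attenuation`` multiplies an STR
    allele's weight by exp(-length_attenuation * repeat_number);
    ``noise_rate`` is the expected number of noise alleles per locus;
    ``noise_count_param`` is the geometric success parameter for noise read
    counts (support 1, 2, ...).
    """

    total_reads: int
    seed: int
    heterozygote_imbalance_sd: float = 0.15
    length_attenuation: float = 0.02
    noise_rate: float = 0.05
    noise_count_param: float = 0.15

    def __post_init__(self):
        if self.total_reads <= 0:
            raise ValueError("total_reads must be positive")
        for name in ("heterozygote_imbalance_sd", "length_attenuation", "noise_rate"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and nonnegative")
        if not 0 < self.noise_count_param <= 1:
            raise ValueError("noise_count_param must be in (0, 1]")


def _random_noise_allele(
    locus: LocusDefinition, exclude: set, rng: np.random.Generator
) -> str | None:
    """An allele id not carried by the sample, for drop-in noise."""
    for _ in range(20):
        if locus.kind == "MH":
            cand = "".join(rng.choice(list(BASES), size=len(locus.variant_positions)))
        else:
            cand = str(int(rng.integers(2, locus.reference_repeats + 6)))
        if cand not in exclude:
            return cand
    return None


def generate_reads(
    profile: GenotypeProfile,
    panel: LocusPanel,
    params: ReadGenerationParams,
) -> ReadSet:
    """Simulate a single-source amplicon read set for ``profile``.

    Deterministic for identical (profile, panel, params).
    """
    missing = [l.name for l in panel if l.name not in profile.genotypes]
    if missing:
        raise ValueError(f"profile {profile.sample_id} lacks loci: {missing[:3]}")
    rng = np.random.default_rng(params.seed)

    weight_seqs: list = []  # amplicon sequences
    weights: list = []
    noise_seqs: list = []
    noise_counts: list = []

    for locus in panel:
        pair = profile.genotypes[locus.name]
        alleles = {}
        for a in pair:
            alleles[a] = alleles.get(a, 0) + 1
        seq_weight: dict = {}
        for allele_id, copies in sorted(alleles.items()):
            w = locus.efficiency_truth * (copies / 2.0)
            if params.heterozygote_imbalance_sd > 0:
                w *= float(
                    np.exp(rng.normal(0.0, params.heterozygote_imbalance_sd))
                )
            seq = locus.allele_sequence(allele_id)
            if locus.kind == "STR":
                rep = int(allele_id)
                w *= float(np.exp(-params.length_attenuation * rep))
                s = locus.stutter_truth
                if s > 0 and rep >= 2:
                    stutter_seq = locus.allele_sequence(str(rep - 1))
                    seq_weight[stutter_seq] = seq_weight.get(stutter_seq, 0.0) + w * s
                    w = w * (1.0 - s)
            seq_weight[seq] = seq_weight.get(seq, 0.0) + w
        for seq, w in seq_weight.items():
            weight_seqs.append(seq)
            weights.append(w)
        # drop-in noise alleles
        if params.noise_rate > 0:
            n_noise = int(rng.poisson(params.noise_rate))
            for _ in range(n_noise):
                cand = _random_noise_allele(locus, set(pair), rng)
                if cand is None:
                    continue
                noise_seqs.append(locus.allele_sequence(cand))
                noise_counts.append(int(rng.geometric(params.noise_count_param)))

    total_noise = sum(noise_counts)
    if total_noise >= params.total_reads:
        # pathological noise settings; keep the total exact by dropping noise
        noise_seqs, noise_counts, total_noise = [], [], 0
    remaining = params.total_reads - total_noise
    w = np.asarray(weights, dtype=float)
    counts = rng.multinomial(remaining, w / w.sum())

    seqs: list = []
    for seq, c in zip(weight_seqs, counts):
        seqs.extend([seq] * int(c))
    for seq, c in zip(noise_seqs, noise_counts):
        seqs.extend([seq] * int(c))
    order = rng.permutation(len(seqs))
    rs = ReadSet(label=profile.sample_id)
    rs.seqs = [seqs[i] for i in order]
    rs.ids = [f"{profile.sample_id}:{i}" for i in range(len(rs.seqs))]
    return rs
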