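"""Synthetic populations: allele frequency tables and HWE genotype profiles.

The study's donor cohorts are emulated here: per locus, an allele universe is
drawn with a symmetric Dirichlet(1) frequency spectrum (uneven but not
degenerate, as real multi-allelic forensic markers are), and individuals are
sampled under Hardy-Weinberg equilibrium.  The returned frequency table is
guaranteed to contain every allele carried by any sampled individual with
nonzero frequency, mirroring the forensic convention of augmenting a
frequency database with the profiles under analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd

from .panels import LocusPanel, LocusDefinition
from .util import BASES


@dataclass(frozen=True)
class GenotypeProfile:
    """A single-source profile: one unordered allele pair per locus."""

    sample_id: str
    genotypes: dict  # locus name -> (allele_id, allele_id), sorted

    def pair(self, locus: str) -> tuple:
        return self.genotypes[locus]


class AlleleFrequencyTable:
    """Per-locus allele frequencies with a rare-allele floor.

    ``population_size`` is the number of individuals behind the table; the
    floor for alleles absent from the table follows the minimum-allele-count
    convention 5/(2N).
    """

    def __init__(self, freqs: dict, population_size: int):
        self.freqs = {
            locus: dict(sorted(d.items())) for locus, d in sorted(freqs.items())
        }
        self.population_size = int(population_size)
        for locus, d in self.freqs.items():
            total = sum(d.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{locus}: frequencies sum to {total}, not 1")
            if any(f <= 0 for f in d.values()):
                raise ValueError(f"{locus}: nonpositive frequency")

    @property
    def floor(self) -> float:
        return 5.0 / (2.0 * self.population_size)

    def get(self, locus: str, allele_id: str) -> float:
        """Frequency of an allele, floored at 5/(2N) when unseen."""
        return self.freqs.get(locus, {}).get(allele_id, self.floor)

    def alleles(self, locus: str):
        return list(self.freqs[locus])

    # --- persistence ----------------------------------------------------
    def to_tsv(self, path) -> None:
        rows = [
            {"locus": locus, "allele": a, "frequency": f}
            for locus, d in self.freqs.items()
            for a, f in d.items()
        ]
        df = pd.DataFrame(rows)
        df["population_size"] = self.population_size
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "AlleleFrequencyTable":
        df = pd.read_csv(path, sep="\t", dtype={"allele": str})
        freqs: dict = {}
        for row in df.itertuples():
            freqs.setdefault(row.locus, {})[row.allele] = float(row.frequency)
        return cls(freqs, population_size=int(df["population_size"].iloc[0]))


def _mh_allele_universe(
    locus: LocusDefinition, n_alleles: int, rng: np.random.Generator
) -> list:
    """Distinct haplotypes over the variant positions, reference included."""
    n_var = len(locus.variant_positions)
    if n_alleles > 4**n_var:
        raise ValueError(
            f"{locus.name}: {n_alleles} alleles exceed the 4^{n_var} haplotype space"
        )
    universe = [locus.reference_haplotype()]
    seen = set(universe)
    while len(universe) < n_alleles:
        hap = "".join(rng.choice(list(BASES), size=n_var))
        if hap not in seen:
            seen.add(hap)
            universe.append(hap)
    return sorted(universe)


def _str_allele_universe(
    locus: LocusDefinition, n_alleles: int, rng: np.random.Generator
) -> list:
    """Distinct repeat numbers around the reference count."""
    ref = locus.reference_repeats
    lo = max(2, ref - n_alleles)
    candidates = np.arange(lo, lo + 2 * n_alleles + 1)
    chosen = rng.choice(candidates, size=n_alleles, replace=False)
    if ref not in chosen:
        chosen[0] = ref
    return [str(n) for n in sorted(set(int(c) for c in chosen))]


def sample_population(
    panel: LocusPanel,
    n_alleles_per_locus: int,
    n_individuals: int,
    seed: int,
    *,
    sample_prefix: str = "IND",
) -> tuple:
    """Draw a frequency table and ``n_individuals`` HWE genotype profiles.

    Returns ``(AlleleFrequencyTable, [GenotypeProfile, ...])``.  Frequencies
    per locus come from a symmetric Dirichlet(1); genotypes are two
    independent draws per locus.  Alleles the sampled individuals carry are
    by construction present in the table with nonzero frequency.
    """
    if n_alleles_per_locus < 1:
        raise ValueError("n_alleles_per_locus must be >= 1")
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    rng = np.random.default_rng(seed)
    freqs = {}
    locus_alleles = {}
    for locus in panel:
        if locus.kind == "MH":
            universe = _mh_allele_universe(locus, n_alleles_per_locus, rng)
        else:
            universe = _str_allele_universe(locus, n_alleles_per_locus, rng)
        p = rng.dirichlet(np.ones(len(universe)))
        # guard against numerically tiny frequencies
        p = np.maximum(p, 1e-6)
        p = p / p.sum()
        freqs[locus.name] = {a: float(x) for a, x in zip(universe, p)}
        locus_alleles[locus.name] = (universe, p)

    profiles = []
    for i in range(n_individuals):
        genotypes = {}
        for locus in panel:
            universe, p = locus_alleles[locus.name]
            pair = rng.choice(len(universe), size=2, p=p)
            a, b = sorted(universe[j] for j in pair)
            genotypes[locus.name] = (a, b)
        profiles.append(GenotypeProfile(f"{sample_prefix}{i+1:03d}", genotypes))
    table = AlleleFrequencyTable(freqs, population_size=n_individuals)
    return table, profiles


def write_truth_tsv(profiles, path) -> None:
    """Persist genotype truth as a TSV (sample, locus, allele1, allele2)."""
    rows = [
        {"sample": p.sample_id, "locus": locus, "allele1": a, "allele2": b}
        for p in profiles
        for locus, (a, b) in sorted(p.genotypes.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype={"allele1": str, "allele2": str})
    profiles = []
    for sample_id, grp in df.groupby("sample", sort=True):
        genotypes = {
            row.locus: tuple(sorted((row.allele1, row.allele2)))
            for row in grp.itertuples()
        }
        profiles.append(GenotypeProfile(sample_id, genotypes))
    return profiles
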