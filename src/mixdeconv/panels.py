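"""Locus panels for microhaplotype (MH) and STR amplicon sequencing.

An MH locus is a 200-300 bp amplicon carrying 2-5 SNPs; every allele of the
locus has the same amplicon length, and the phased combination of bases at
the variant positions names the allele.  An STR locus is an amplicon whose
middle section is a run of a 3-5 bp motif; alleles differ by whole motif
copies, so allele lengths differ and amplification produces stutter.

Panels built here are synthetic: amplicon sequences are random DNA, but the
structural constraints (shared length for MH alleles, whole-motif length
differences for STR alleles, unique flanks between loci) are enforced so the
downstream exact-match caller behaves like a real amplicon analysis tool.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

from .errors import AmbiguousPanelError
from .util import random_dna

#: number of leading bases used to assign a read to a locus
PREFIX_LEN = 16


@dataclass(frozen=True)
class LocusDefinition:
    """One marker of a panel, with the truth parameters used in simulation.

    Offsets are 0-based; ``repeat_region`` is a half-open interval within the
    reference amplicon.  ``efficiency_truth`` is the relative amplification
    efficiency of the locus (mean 1 across a panel); ``stutter_truth`` is the
    expected fraction of a parent STR allele's reads shed to the one-repeat-
    shorter (n-1) sequence.
    """

    name: str
    kind: str  # "MH" | "STR"
    reference_sequence: str
    variant_positions: tuple = ()
    ignored_positions: tuple = ()
    repeat_motif: Optional[str] = None
    repeat_region: Optional[tuple] = None
    efficiency_truth: float = 1.0
    stutter_truth: float = 0.0

    def __post_init__(self):
        if self.kind not in ("MH", "STR"):
            raise ValueError(f"unknown locus kind: {self.kind!r}")
        L = len(self.reference_sequence)
        for p in list(self.variant_positions) + list(self.ignored_positions):
            if not 0 <= p < L:
                raise ValueError(f"{self.name}: position {p} outside amplicon")
        if set(self.variant_positions) & set(self.ignored_positions):
            raise ValueError(f"{self.name}: variant and ignored positions overlap")
        if self.kind == "STR":
            if not self.repeat_motif or not self.repeat_region:
                raise ValueError(f"{self.name}: STR locus needs motif and repeat region")
            if not 3 <= len(self.repeat_motif) <= 5:
                raise ValueError(f"{self.name}: motif length must be 3-5")

    @property
    def amplicon_length(self) -> int:
        return len(self.reference_sequence)

    # --- STR geometry -------------------------------------------------
    @property
    def left_flank(self) -> str:
        return self.reference_sequence[: self.repeat_region[0]]

    @property
    def right_flank(self) -> str:
        return self.reference_sequence[self.repeat_region[1]:]

    @property
    def reference_repeats(self) -> int:
        start, end = self.repeat_region
        return (end - start) // len(self.repeat_motif)

    # --- allele sequences ---------------------------------------------
    def allele_sequence(self, allele_id: str) -> str:
        """Full amplicon sequence of an allele.

        MH allele ids are haplotype strings over the variant positions; STR
        allele ids are repeat numbers (as strings) for uninterrupted alleles.
        """
        if self.kind == "MH":
            if len(allele_id) != len(self.variant_positions):
                raise ValueError(
                    f"{self.name}: haplotype {allele_id!r} does not cover "
                    f"{len(self.variant_positions)} variant positions"
                )
            seq = list(self.reference_sequence)
            for pos, base in zip(self.variant_positions, allele_id):
                seq[pos] = base
            return "".join(seq)
        n = int(allele_id)
        if n < 1:
            raise ValueError(f"{self.name}: repeat number must be >= 1")
        return self.left_flank + self.repeat_motif * n + self.right_flank

    def reference_haplotype(self) -> str:
        return "".join(self.reference_sequence[p] for p in self.variant_positions)


class LocusPanel:
    """An ordered collection of loci with unique names and unique flanks."""

    def __init__(self, loci, kind: Optional[str] = None):
        self.loci = list(loci)
        if not self.loci:
            raise ValueError("panel must contain at least one locus")
        kinds = {l.kind for l in self.loci}
        if kind is None:
            if len(kinds) != 1:
                raise ValueError("mixed-kind panel requires explicit kind")
            kind = kinds.pop()
        self.kind = kind
        self.by_name = {}
        prefixes = {}
        for locus in self.loci:
            if locus.name in self.by_name:
                raise ValueError(f"duplicate locus name {locus.name}")
            prefix = locus.reference_sequence[:PREFIX_LEN]
            if prefix in prefixes:
                raise AmbiguousPanelError(
                    f"loci {prefixes[prefix]} and {locus.name} share the "
                    f"amplicon prefix {prefix}"
                )
            prefixes[prefix] = locus.name
            self.by_name[locus.name] = locus

    def __len__(self):
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    def __getitem__(self, name: str) -> LocusDefinition:
        return self.by_name[name]

    @property
    def names(self):
        return [l.name for l in self.loci]

    # --- persistence ----------------------------------------------------
    def to_json(self, path) -> None:
        payload = {"kind": self.kind, "loci": [asdict(l) for l in self.loci]}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "LocusPanel":
        with open(path) as fh:
            payload = json.load(fh)
        loci = []
        for d in payload["loci"]:
            d["variant_positions"] = tuple(d["variant_positions"])
            d["ignored_positions"] = tuple(d["ignored_positions"])
            if d.get("repeat_region") is not None:
                d["repeat_region"] = tuple(d["repeat_region"])
            loci.append(LocusDefinition(**d))
        return cls(loci, kind=payload["kind"])


def _nonrepetitive_motif(rng: np.random.Generator) -> str:
    """A 4-mer that is not a homopolymer or a 2-periodic repeat."""
    while True:
        motif = random_dna(rng, 4)
        if len(set(motif)) >= 2 and motif[:2] != motif[2:]:
            return motif


def build_panel(
    kind: str,
    n_loci: int,
    seed: int,
    *,
    efficiency_sd: float = 0.25,
    stutter_range: tuple = (0.03, 0.12),
    mh_amplicon_range: tuple = (200, 300),
    str_flank_range: tuple = (30, 60),
    str_reference_repeats: tuple = (8, 24),
) -> LocusPanel:
    """Build a seeded synthetic panel of ``n_loci`` MH or STR loci.

    MH loci carry 2-5 variant positions and 0-2 ignored positions, placed
    away from the locus-identifying prefix.  STR reference alleles carry
    ``str_reference_repeats`` motif copies.  Locus efficiencies are drawn
    log-normally with spread ``efficiency_sd`` and normalised to mean 1.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if kind not in ("MH", "STR"):
        raise ValueError(f"unknown panel kind: {kind!r}")
    rng = np.random.default_rng(seed)
    loci = []
    seen_prefixes = set()
    for i in range(n_loci):
        name = f"{kind}{i+1:03d}"
        while True:
            if kind == "MH":
                length = int(rng.integers(*mh_amplicon_range))
                seq = random_dna(rng, length)
                n_var = int(rng.integers(2, 6))
                n_ign = int(rng.integers(0, 3))
                positions = rng.choice(
                    np.arange(PREFIX_LEN + 4, length - 4),
                    size=n_var + n_ign,
                    replace=False,
                )
                positions = np.sort(positions)
                # interleave: variants are a sorted random subset
                var_idx = np.sort(rng.choice(n_var + n_ign, size=n_var, replace=False))
                variant_positions = tuple(int(positions[j]) for j in var_idx)
                ignored_positions = tuple(
                    int(p) for j, p in enumerate(positions) if j not in var_idx
                )
                locus = LocusDefinition(
                    name=name,
                    kind="MH",
                    reference_sequence=seq,
                    variant_positions=variant_positions,
                    ignored_positions=ignored_positions,
                )
            else:
                left = random_dna(rng, int(rng.integers(*str_flank_range)))
                right = random_dna(rng, int(rng.integers(*str_flank_range)))
                motif = _nonrepetitive_motif(rng)
                n_rep = int(rng.integers(*str_reference_repeats))
                # flank must not extend the repeat run on either side
                if left.endswith(motif) or right.startswith(motif):
                    continue
                seq = left + motif * n_rep + right
                locus = LocusDefinition(
                    name=name,
                    kind="STR",
                    reference_sequence=seq,
                    repeat_motif=motif,
                    repeat_region=(len(left), len(left) + len(motif) * n_rep),
                    stutter_truth=float(rng.uniform(*stutter_range)),
                )
            prefix = locus.reference_sequence[:PREFIX_LEN]
            if prefix not in seen_prefixes:
                seen_prefixes.add(prefix)
                break
        loci.append(locus)
    # log-normal efficiencies, normalised to mean 1
    eff = np.exp(rng.normal(0.0, efficiency_sd, size=n_loci))
    eff = eff / eff.mean()
    loci = [
        LocusDefinition(**{**asdict(l), "efficiency_truth": float(e)})
        for l, e in zip(loci, eff)
    ]
    # dataclass asdict converts tuples to lists; restore
    fixed = []
    for l in loci:
        d = asdict(l)
        d["variant_positions"] = tuple(d["variant_positions"])
        d["ignored_positions"] = tuple(d["ignored_positions"])
        if d["repeat_region"] is not None:
            d["repeat_region"] = tuple(d["repeat_region"])
        fixed.append(LocusDefinition(**d))
    return LocusPanel(fixed, kind=kind)
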