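"""Exact-match amplicon allele calling.

Reads are assigned to loci by their leading bases (every panel locus has a
unique amplicon prefix; colliding prefixes raise at panel load).  An MH read
must have the locus amplicon length and match the reference at every
position outside the variant and ignored positions; its allele id is the
concatenation of the bases at the variant positions.  An STR read must match
both flanks exactly; the middle section is run-length encoded against the
repeat motif, giving either a plain repeat number ("11") or a bracketed
string for interrupted alleles ("[ATCT]2 ATGT [ATCT]8").

Counts below the analytical threshold (11 reads by default, the minimum
read count for an allele to be treated as signal) are kept separately for
audit; reads matching no locus are tallied as unassigned.  The caller never
sees truth metadata.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .errors import NoRepeatError
from .panels import LocusPanel, LocusDefinition, PREFIX_LEN
from .reads import ReadSet

DEFAULT_ANALYTICAL_THRESHOLD = 11


@dataclass(frozen=True)
class BracketedAllele:
    """An STR allele in bracketed nomenclature."""

    locus: str
    bracketed_string: str
    repeat_number: int


@dataclass
class AlleleCountTable:
    """Per-locus allele read counts for one sample after thresholding."""

    sample_id: str
    counts: dict = field(default_factory=dict)  # locus -> {allele_id: count}
    below_threshold: dict = field(default_factory=dict)
    unassigned_reads: int = 0
    analytical_threshold: int = DEFAULT_ANALYTICAL_THRESHOLD

    @property
    def total_reads(self) -> int:
        retained = sum(c for d in self.counts.values() for c in d.values())
        below = sum(c for d in self.below_threshold.values() for c in d.values())
        return retained + below + self.unassigned_reads

    def locus_total(self, locus: str) -> int:
        return sum(self.counts.get(locus, {}).values())

    def combined(self, locus: str) -> dict:
        """Retained plus below-threshold counts for one locus."""
        merged = Counter(self.counts.get(locus, {}))
        merged.update(self.below_threshold.get(locus, {}))
        return dict(merged)

    # --- persistence ----------------------------------------------------
    def to_tsv(self, path) -> None:
        rows = []
        for status, table in (("retained", self.counts), ("below_threshold", self.below_threshold)):
            for locus, d in sorted(table.items()):
                for allele, count in sorted(d.items()):
                    rows.append(
                        {"sample": self.sample_id, "locus": locus,
                         "allele": allele, "count": count, "status": status}
                    )
        df = pd.DataFrame(rows, columns=["sample", "locus", "allele", "count", "status"])
        df.attrs["unassigned"] = self.unassigned_reads
        with open(path, "w") as fh:
            fh.write(f"#unassigned_reads={self.unassigned_reads}\t"
                     f"analytical_threshold={self.analytical_threshold}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "AlleleCountTable":
        with open(path) as fh:
            header = fh.readline().strip().lstrip("#")
            meta = dict(kv.split("=") for kv in header.split("\t"))
            df = pd.read_csv(fh, sep="\t", dtype={"allele": str})
        sample_id = str(df["sample"].iloc[0]) if len(df) else "unknown"
        out = cls(
            sample_id=sample_id,
            unassigned_reads=int(meta["unassigned_reads"]),
            analytical_threshold=int(meta["analytical_threshold"]),
        )
        for row in df.itertuples():
            table = out.counts if row.status == "retained" else out.below_threshold
            table.setdefault(row.locus, {})[str(row.allele)] = int(row.count)
        return out


def bracket_str_sequence(repeat_region: str, motif: str) -> BracketedAllele:
    """Greedy left-to-right run-length encoding of a repeat region.

    Runs of the motif become ``[MOTIF]n`` blocks; interrupting bases are
    emitted literally between blocks.  The repeat number is the sum of the
    bracketed copy counts.
    """
    if not 3 <= len(motif) <= 5:
        raise ValueError("motif length must be 3-5")
    if len(repeat_region) < len(motif):
        raise NoRepeatError(
            f"repeat region {repeat_region!r} shorter than one {motif!r} copy"
        )
    m = len(motif)
    blocks = []
    literal = []
    i = 0
    total = 0
    while i < len(repeat_region):
        if repeat_region[i : i + m] == motif:
            if literal:
                blocks.append("".join(literal))
                literal = []
            run = 0
            while repeat_region[i : i + m] == motif:
                run += 1
                i += m
            total += run
            blocks.append(f"[{motif}]{run}")
        else:
            literal.append(repeat_region[i])
            i += 1
    if literal:
        blocks.append("".join(literal))
    if total == 0:
        raise NoRepeatError(f"no copy of motif {motif!r} in {repeat_region!r}")
    return BracketedAllele(locus="", bracketed_string=" ".join(blocks), repeat_number=total)


def expand_bracketed(bracketed_string: str) -> str:
    """Inverse of :func:`bracket_str_sequence` (round-trip identity)."""
    out = []
    for token in bracketed_string.split(" "):
        m = re.fullmatch(r"\[([ACGT]+)\](\d+)", token)
        out.append(m.group(1) * int(m.group(2)) if m else token)
    return "".join(out)


def mh_allele_from_read(read_sequence: str, locus: LocusDefinition):
    """Allele id of an MH read, or None if it does not match the locus.

    The read must equal the reference outside variant positions, except at
    ignored positions which are masked from the comparison.
    """
    ref = locus.reference_sequence
    if len(read_sequence) != len(ref):
        return None
    skip = set(locus.variant_positions) | set(locus.ignored_positions)
    for i, (a, b) in enumerate(zip(read_sequence, ref)):
        if a != b and i not in skip:
            return None
    return "".join(read_sequence[p] for p in locus.variant_positions)


def str_allele_from_read(read_sequence: str, locus: LocusDefinition):
    """Allele id of an STR read (repeat number, or bracketed string)."""
    left, right = locus.left_flank, locus.right_flank
    if len(read_sequence) < len(left) + len(right) + len(locus.repeat_motif):
        return None
    if not read_sequence.startswith(left) or not read_sequence.endswith(right):
        return None
    middle = read_sequence[len(left) : len(read_sequence) - len(right)]
    motif = locus.repeat_motif
    n, rem = divmod(len(middle), len(motif))
    if rem == 0 and middle == motif * n:
        return str(n)
    try:
        return bracket_str_sequence(middle, motif).bracketed_string
    except NoRepeatError:
        return None


def call_alleles(
    reads: ReadSet,
    panel: LocusPanel,
    analytical_threshold: int = DEFAULT_ANALYTICAL_THRESHOLD,
    *,
    excluded_loci=(),
) -> AlleleCountTable:
    """Count reads per (locus, allele) and apply the analytical threshold.

    An allele is retained iff its read count is >= the threshold; smaller
    counts go to ``below_threshold``.  Loci in ``excluded_loci`` are dropped
    entirely (their reads count as unassigned), mirroring the practice of
    excluding a marker whose behaviour is too unbalanced to interpret.
    """
    excluded = set(excluded_loci)
    by_prefix = {
        locus.reference_sequence[:PREFIX_LEN]: locus
        for locus in panel
        if locus.name not in excluded
    }
    seq_counts = Counter(reads.seqs)
    out = AlleleCountTable(
        sample_id=reads.label, analytical_threshold=analytical_threshold
    )
    raw: dict = {}
    for seq, count in seq_counts.items():
        locus = by_prefix.get(seq[:PREFIX_LEN])
        allele = None
        if locus is not None:
            if locus.kind == "MH":
                allele = mh_allele_from_read(seq, locus)
            else:
                allele = str_allele_from_read(seq, locus)
        if allele is None:
            out.unassigned_reads += count
            continue
        locus_table = raw.setdefault(locus.name, {})
        locus_table[allele] = locus_table.get(allele, 0) + count
    for locus_name, d in raw.items():
        for allele, count in d.items():
            target = out.counts if count >= analytical_threshold else out.below_threshold
            target.setdefault(locus_name, {})[allele] = count
    return out
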