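"""Molecular-barcode (UMI) duplicate collapsing at a single locus.

Targeted ctDNA panels tag each source molecule with a random barcode so
that PCR duplicates can be collapsed into one consensus observation per
original molecule, removing the depth/VAF bias duplicates would otherwise
introduce and suppressing isolated sequencing errors.

Grouping is by exact ``(umi, chrom, start, strand)`` match; the consensus
allele of a family is the strict majority of its member reads, and
families with no strict majority are dropped from both the depth and the
variant-supporting count (a conservative tie rule).  When variant input
arrives as VCF the counts are taken as already collapsed and this module
is bypassed.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .variant_io import VariantKey

__all__ = ["TaggedRead", "DedupCounts", "group_reads", "collapse_families",
           "dedup_counts", "read_tagged_reads"]

FamilyKey = tuple[str, str, int, str]


@dataclass(frozen=True)
class TaggedRead:
    """One aligned read interrogating one candidate variant locus."""

    umi: str
    chrom: str
    start: int  # 1-based alignment start
    strand: str  # "+" or "-"
    allele: str  # observed base/sequence at the locus
    locus: VariantKey

    def __post_init__(self) -> None:
        if not self.umi:
            raise ValueError("umi must be non-empty")
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class DedupCounts:
    """UMI-family counts at a locus: depth = surviving families."""

    locus: VariantKey | None
    depth: int
    alt_families: int

    def __post_init__(self) -> None:
        if not 0 <= self.alt_families <= self.depth:
            raise ValueError(
                f"require 0 <= alt_families <= depth, got {self.alt_families}/{self.depth}"
            )

    @property
    def vaf(self) -> float:
        return self.alt_families / self.depth if self.depth else 0.0


def group_reads(reads: Sequence[TaggedRead]) -> dict[FamilyKey, list[TaggedRead]]:
    """Partition reads into UMI families keyed by (umi, chrom, start, strand).

    All reads must interrogate the same locus; mixing loci in one call is
    an error because the family partition is locus-specific.
    """
    loci = {r.locus for r in reads}
    if len(loci) > 1:
        raise ValueError(f"reads span {len(loci)} distinct loci; group one locus at a time")
    families: dict[FamilyKey, list[TaggedRead]] = {}
    for read in reads:
        families.setdefault((read.umi, read.chrom, read.start, read.strand), []).append(read)
    return families


def collapse_families(families: Mapping[FamilyKey, Sequence[TaggedRead]]) -> DedupCounts:
    """Collapse each family to one consensus observation.

    Consensus = strict majority allele of the member reads; families with
    no strict majority (e.g. a 1-1 ref/alt tie) are discarded entirely.
    """
    locus = None
    depth = 0
    alt_families = 0
    for members in families.values():
        if not members:
            continue
        locus = members[0].locus
        counts = Counter(r.allele for r in members)
        allele, top = counts.most_common(1)[0]
        if 2 * top <= len(members):  # no strict majority
            continue
        depth += 1
        if allele == locus.alt:
            alt_families += 1
    return DedupCounts(locus=locus, depth=depth, alt_families=alt_families)


def dedup_counts(reads: Sequence[TaggedRead]) -> DedupCounts:
    """Convenience: group then collapse."""
    return collapse_families(group_reads(reads))


def read_tagged_reads(path: str | Path, locus: VariantKey) -> list[TaggedRead]:
    """Read the TSV read-record format (umi, chrom, start, strand, allele)."""
    reads: list[TaggedRead] = []
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"umi", "chrom", "start", "strand", "allele"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for row in reader:
            reads.append(
                TaggedRead(
                    umi=row["umi"],
                    chrom=row["chrom"],
                    start=int(row["start"]),
                    strand=row["strand"],
                    allele=row["allele"],
                    locus=locus,
                )
            )
    return reads
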