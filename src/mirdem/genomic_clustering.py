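"""Genomic clustering of miRNA loci.

miRNAs transcribed from a shared locus tend to sit within a few kilobases
of each other.  This module groups located miRNAs into clusters by
single-linkage on the genomic gap between their intervals: two features on
the same chromosome belong together when the gap between them is at most
``max_gap`` base pairs (default 5000, inclusive), and the relation is
closed transitively.  Groups smaller than ``min_size`` are discarded.

Coordinates are 1-based inclusive throughout.  Input tables may encode the
minus strand by printing start > end; :func:`normalize_coordinates` maps
any (start, end) pair to an ordered interval plus an inferred strand.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicFeature",
    "MirnaCluster",
    "normalize_coordinates",
    "chromosome_sort_key",
    "interval_distance",
    "cluster_features",
]


@dataclass(frozen=True)
class GenomicFeature:
    """A located miRNA: ordered 1-based inclusive interval on a chromosome."""

    name: str
    chromosome: str
    low: int
    high: int
    strand: str = "unknown"
    accession: str = ""

    def __post_init__(self) -> None:
        if not self.chromosome:
            raise ValueError("chromosome label must be non-empty")
        if self.low > self.high:
            raise ValueError(
                f"{self.name}: low ({self.low}) > high ({self.high}); "
                "use normalize_coordinates on raw start/end first"
            )
        if self.low <= 0:
            raise ValueError(f"{self.name}: coordinates must be positive")
        if self.strand not in {"+", "-", "unknown"}:
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass(frozen=True)
class MirnaCluster:
    """A ≥2-member single-linkage group of features on one chromosome."""

    cluster_id: str
    members: tuple[GenomicFeature, ...]
    chromosome: str
    span_low: int
    span_high: int
    max_internal_gap: int

    def __len__(self) -> int:
        return len(self.members)

    @property
    def member_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.members)


def normalize_coordinates(start: int, end: int) -> tuple[int, int, str]:
    """Order a raw (start, end) pair and infer strand.

    Tables in the field sometimes print minus-strand loci with start > end;
    that convention is decoded here: start > end means minus strand,
    start < end plus, equality leaves the strand unknown.

    Returns ``(low, high, strand)`` with ``low <= high``.
    """
    start, end = int(start), int(end)
    if start <= 0 or end <= 0:
        raise ValueError(f"coordinates must be positive, got ({start}, {end})")
    if start > end:
        return end, start, "-"
    if start < end:
        return start, end, "+"
    return start, end, "unknown"


_CHROM_NUM = re.compile(r"^(?:chr)?(\d+)$", re.IGNORECASE)
_CHROM_XY = re.compile(r"^(?:chr)?([XY])$", re.IGNORECASE)


def chromosome_sort_key(label: str) -> tuple[int, int, str]:
    """Canonical chromosome order: autosomes numerically, then X, then Y,
    then anything else lexicographically."""
    m = _CHROM_NUM.match(label)
    if m:
        return (0, int(m.group(1)), "")
    m = _CHROM_XY.match(label)
    if m:
        return (1, "XY".index(m.group(1).upper()), "")
    return (2, 0, label.lower())


def interval_distance(f1: GenomicFeature, f2: GenomicFeature) -> float:
    """Gap in bp between two features: infinite across chromosomes, 0 for
    overlapping or touching intervals, else (later low) − (earlier high)."""
    if f1.chromosome != f2.chromosome:
        return math.inf
    gap = max(f1.low, f2.low) - min(f1.high, f2.high)
    return max(0, gap)


def _dedupe(features: Iterable[GenomicFeature]) -> list[GenomicFeature]:
    seen: set[tuple] = set()
    out: list[GenomicFeature] = []
    dropped = 0
    for f in features:
        key = (f.name, f.chromosome, f.low, f.high)
        if key in seen:
            dropped += 1
            continue
        seen.add(key)
        out.append(f)
    if dropped:
        logger.warning("dropped %d duplicate feature record(s)", dropped)
    return out


def cluster_features(
    features: Sequence[GenomicFeature],
    max_gap: int = 5000,
    min_size: int = 2,
) -> list[MirnaCluster]:
    """Single-linkage clustering of genomic features.

    Two features are linked when :func:`interval_distance` is at most
    ``max_gap`` (inclusive); clusters are the transitive closure of that
    relation.  Groups smaller than ``min_size`` are dropped.  Output order
    is deterministic for any permutation of the input: clusters are sorted
    by (canonical chromosome order, span low) and labelled C1…Cn.

    Because features live on a line, the closure equals a sorted sweep per
    chromosome: walk features by ascending low, keep a running maximum
    high, and start a new group whenever ``low − running_high > max_gap``.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    feats = _dedupe(features)

    by_chrom: dict[str, list[GenomicFeature]] = {}
    for f in feats:
        by_chrom.setdefault(f.chromosome, []).append(f)

    groups: list[list[GenomicFeature]] = []
    for chrom in sorted(by_chrom, key=chromosome_sort_key):
        ordered = sorted(by_chrom[chrom], key=lambda f: (f.low, f.high, f.name))
        current: list[GenomicFeature] = []
        running_high = -1
        for f in ordered:
            if current and f.low - running_high > max_gap:
                groups.append(current)
                current = []
                running_high = -1
            current.append(f)
            running_high = max(running_high, f.high)
        if current:
            groups.append(current)

    clusters: list[MirnaCluster] = []
    kept = [g for g in groups if len(g) >= min_size]
    kept.sort(key=lambda g: (chromosome_sort_key(g[0].chromosome), min(f.low for f in g)))
    for i, members in enumerate(kept, start=1):
        gaps = [
            max(0, members[j + 1].low - max(f.high for f in members[: j + 1]))
            for j in range(len(members) - 1)
        ]
        clusters.append(
            MirnaCluster(
                cluster_id=f"C{i}",
                members=tuple(members),
                chromosome=members[0].chromosome,
                span_low=min(f.low for f in members),
                span_high=max(f.high for f in members),
                max_internal_gap=max(gaps) if gaps else 0,
            )
        )
    return clusters
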