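"""Core domain types shared across the pipeline.

All coordinates held in these types are **0-based, half-open** ``[start, end)``.
Conversions from external dialects (BLAST tabular, GFF3, printed interval
strings) happen exactly once, at the I/O boundary (:mod:`hgtscan.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

TAXON_BINS = ("host", "symbiont", "other")
FEATURE_TYPES = ("gene", "transposase", "marker")
STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval ``[start, end)`` on a named scaffold."""

    scaffold_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(
                f"interval start must be >= 0, got {self.start} on {self.scaffold_id}"
            )
        if self.end <= self.start:
            raise ValueError(
                f"empty or reversed interval [{self.start}, {self.end}) "
                f"on {self.scaffold_id}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.scaffold_id == other.scaffold_id
            and self.start < other.end
            and other.start < self.end
        )

    def gap_to(self, other: "GenomicInterval") -> int:
        """Distance in bp between two intervals on one scaffold; 0 if they touch
        or overlap."""
        if self.scaffold_id != other.scaffold_id:
            raise ValueError("intervals on different scaffolds have no gap")
        if self.overlaps(other):
            return 0
        return max(self.start, other.start) - min(self.end, other.end)


def merge_intervals(
    intervals: Iterable[tuple[int, int]], join_gap: int = 0
) -> list[tuple[int, int]]:
    """Merge (start, end) pairs whose gap is <= ``join_gap`` into maximal runs.

    Plain-tuple variant used by coverage accounting and block segmentation;
    input need not be sorted.
    """
    ivs = sorted(intervals)
    if not ivs:
        return []
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s - merged[-1][1] <= join_gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def union_length(intervals: Iterable[tuple[int, int]], min_run: int = 1) -> int:
    """Total bp covered by the union of intervals, counting only merged runs
    of length >= ``min_run``."""
    return sum(e - s for s, e in merge_intervals(intervals) if e - s >= min_run)


@dataclass(frozen=True)
class TabularHit:
    """One similarity-search hit, as read from a 12-column tabular file."""

    query_id: str
    subject_id: str
    taxon_bin: str
    percent_identity: float
    query_interval: GenomicInterval
    subject_interval: GenomicInterval
    bitscore: float
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.taxon_bin not in TAXON_BINS:
            raise ValueError(f"unknown taxon bin {self.taxon_bin!r}")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(f"percent identity out of range: {self.percent_identity}")
        if self.bitscore < 0:
            raise ValueError(f"negative bitscore: {self.bitscore}")


@dataclass
class DepthTrack:
    """Per-base read depth along one scaffold."""

    scaffold_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("depth track must be one-dimensional")
        if self.values.size and self.values.min() < 0:
            raise ValueError(f"negative depth on {self.scaffold_id}")

    def __len__(self) -> int:
        return int(self.values.size)

    def mean(self, start: int | None = None, end: int | None = None) -> float:
        """Arithmetic mean depth over ``[start, end)`` (whole track by default)."""
        s = 0 if start is None else start
        e = len(self) if end is None else end
        if not 0 <= s < e <= len(self):
            raise ValueError(
                f"empty or out-of-range interval [{s}, {e}) on {self.scaffold_id} "
                f"(length {len(self)})"
            )
        return float(self.values[s:e].mean())


@dataclass(frozen=True)
class FeatureRecord:
    """A gene, transposase, or marker annotation on a scaffold."""

    scaffold_id: str
    interval: GenomicInterval
    feature_type: str
    feature_id: str
    strand: str = "."

    def __post_init__(self) -> None:
        if self.feature_type not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.feature_type!r}")
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand {self.strand!r}")
        if self.interval.scaffold_id != self.scaffold_id:
            raise ValueError("feature interval lies on a different scaffold")


@dataclass(frozen=True)
class VariantSite:
    """A biallelic site with read support for reference and alternate bases."""

    scaffold_id: str
    position: int
    ref_base: str
    alt_base: str
    ref_count: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError("ref and alt base identical")
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError("negative allele count")

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count

    @property
    def minor_allele_fraction(self) -> float:
        if self.depth == 0:
            return 0.0
        return min(self.ref_count, self.alt_count) / self.depth
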