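"""Taxon-annotated GC-coverage (TAGC) scaffold screening.

Scaffolds are placed on a GC x depth plane and annotated with the taxon of
their similarity hits. Pure-symbiont scaffolds (fully covered by symbiont
hits, symbiont-like depth) belong to the endosymbiont assembly; scaffolds
carrying *both* host and symbiont blocks at host-like depth are the HGT
candidates the detector inspects. GC itself is computed for the blob plot
but is deliberately not a classification criterion: a ~36% GC host and a
~35% GC symbiont are inseparable on that axis, and the separation comes
from taxonomy and coverage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .types import DepthTrack, GenomicInterval, TabularHit, merge_intervals

__all__ = [
    "TagcParams",
    "ScaffoldRecord",
    "ScaffoldClassification",
    "compute_gc",
    "mean_depth",
    "assign_taxon_coverage",
    "classify_scaffold",
    "classify_assembly",
]

_GC_BASES = frozenset(b"GC")
_AT_BASES = frozenset(b"AT")


@dataclass(frozen=True)
class TagcParams:
    """Thresholds of the scaffold classifier.

    f_pure
        Fraction of scaffold length that must be covered by symbiont-bin
        hits for a "matched completely" (pure symbiont) verdict; 0.90
        tolerates unaligned scaffold ends.
    min_block
        Minimum merged hit run (bp) counted as real signal; 300 bp sits
        below the smallest genuine insert worth calling while absorbing
        alignment fraying.
    tau_depth
        Fold-ratio band for depth-cluster assignment; a scaffold within
        log2(tau_depth) of both reference depths is "intermediate".
    """

    f_pure: float = 0.90
    min_block: int = 300
    tau_depth: float = 1.5


@dataclass(frozen=True)
class ScaffoldRecord:
    """One assembly sequence on the TAGC plane."""

    scaffold_id: str
    length: int
    gc_fraction: float
    mean_depth: float

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"scaffold {self.scaffold_id}: non-positive length")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError(f"scaffold {self.scaffold_id}: GC out of [0, 1]")
        if self.mean_depth < 0:
            raise ValueError(f"scaffold {self.scaffold_id}: negative depth")


@dataclass(frozen=True)
class ScaffoldClassification:
    scaffold_id: str
    label: str                  #: host | symbiont | hgt_candidate | unassigned
    symbiont_covered: int
    host_covered: int
    depth_cluster: str          #: host-like | symbiont-like | intermediate
    evidence_notes: str = ""


def compute_gc(sequence: str) -> float:
    """(G+C) / (A+C+G+T); ambiguity codes excluded from both sides.

    Returns 0.0 when no unambiguous base is present.
    """
    if not sequence:
        raise ValueError("empty sequence")
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    gc = int(np.isin(arr, np.frombuffer(b"GC", np.uint8)).sum())
    at = int(np.isin(arr, np.frombuffer(b"AT", np.uint8)).sum())
    denom = gc + at
    return gc / denom if denom else 0.0


def mean_depth(
    track: DepthTrack, interval: GenomicInterval | None = None
) -> float:
    """Arithmetic mean of per-base depth over an interval (whole track if None)."""
    if interval is None:
        return track.mean()
    return track.mean(interval.start, interval.end)


def assign_taxon_coverage(
    hits: Iterable[TabularHit],
    scaffold_length: int,
    min_block: int = 300,
) -> tuple[int, int]:
    """Union coverage (bp) of symbiont-bin and host-bin hits on one scaffold.

    Overlapping hits of a bin are merged; only merged runs of at least
    ``min_block`` bp are counted. Hits must all lie on one scaffold and
    within its length.
    """
    if min_block <= 0:
        raise ValueError("min_block must be positive")
    by_bin: dict[str, list[tuple[int, int]]] = {"symbiont": [], "host": []}
    for h in hits:
        qi = h.query_interval
        if qi.end > scaffold_length:
            raise ValueError(
                f"hit interval [{qi.start}, {qi.end}) exceeds scaffold length "
                f"{scaffold_length} on {qi.scaffold_id}"
            )
        if h.taxon_bin in by_bin:
            by_bin[h.taxon_bin].append((qi.start, qi.end))
    covered = {}
    for bin_, ivs in by_bin.items():
        covered[bin_] = sum(
            e - s for s, e in merge_intervals(ivs) if e - s >= min_block
        )
    return covered["symbiont"], covered["host"]


def _depth_cluster(
    depth: float, host_ref: float, symbiont_ref: float, tau: float
) -> str:
    eps = 0.5
    d_host = abs(math.log2((depth + eps) / (host_ref + eps)))
    d_sym = abs(math.log2((depth + eps) / (symbiont_ref + eps)))
    band = math.log2(tau)
    if d_host <= band and d_sym <= band:
        return "intermediate"
    return "host-like" if d_host <= d_sym else "symbiont-like"


def classify_scaffold(
    record: ScaffoldRecord,
    coverage: tuple[int, int],
    depth_refs: tuple[float, float],
    params: TagcParams = TagcParams(),
) -> ScaffoldClassification:
    """Label one scaffold from its taxon coverage and depth.

    coverage
        ``(symbiont_covered, host_covered)`` in bp (see
        :func:`assign_taxon_coverage`).
    depth_refs
        ``(host_median_depth, symbiont_median_depth)`` from confidently
        labelled cohorts.
    """
    host_ref, sym_ref = depth_refs
    if host_ref <= 0 or sym_ref <= 0:
        raise ValueError("reference depths must be positive")
    sym_cov, host_cov = coverage
    mb = params.min_block
    if sym_cov >= params.f_pure * record.length and host_cov < mb:
        label = "symbiont"
    elif sym_cov >= mb and host_cov >= mb:
        label = "hgt_candidate"
    elif host_cov >= mb and sym_cov < mb:
        label = "host"
    else:
        label = "unassigned"
    cluster = _depth_cluster(record.mean_depth, host_ref, sym_ref, params.tau_depth)
    notes = ""
    if label == "hgt_candidate":
        notes = (
            f"interleaved host ({host_cov} bp) and symbiont ({sym_cov} bp) "
            f"similarity at {cluster} depth"
        )
    return ScaffoldClassification(
        scaffold_id=record.scaffold_id,
        label=label,
        symbiont_covered=sym_cov,
        host_covered=host_cov,
        depth_cluster=cluster,
        evidence_notes=notes,
    )


def classify_assembly(
    records: Sequence[ScaffoldRecord],
    hits_by_scaffold: Mapping[str, Sequence[TabularHit]],
    params: TagcParams = TagcParams(),
) -> list[ScaffoldClassification]:
    """Two-pass classification of a whole assembly.

    Pass one labels scaffolds from hit coverage alone and takes the median
    depth of the host- and symbiont-labelled cohorts as the reference depths
    (medians resist outliers); pass two refines every label with the depth
    clusters attached. Falls back to the overall median when a cohort is
    empty.
    """
    coverages = {
        r.scaffold_id: assign_taxon_coverage(
            hits_by_scaffold.get(r.scaffold_id, ()), r.length, params.min_block
        )
        for r in records
    }

    def _label_only(r: ScaffoldRecord) -> str:
        sym_cov, host_cov = coverages[r.scaffold_id]
        mb = params.min_block
        if sym_cov >= params.f_pure * r.length and host_cov < mb:
            return "symbiont"
        if sym_cov >= mb and host_cov >= mb:
            return "hgt_candidate"
        if host_cov >= mb and sym_cov < mb:
            return "host"
        return "unassigned"

    first = {r.scaffold_id: _label_only(r) for r in records}
    all_depths = [r.mean_depth for r in records]
    host_depths = [r.mean_depth for r in records if first[r.scaffold_id] == "host"]
    sym_depths = [r.mean_depth for r in records if first[r.scaffold_id] == "symbiont"]
    host_ref = float(np.median(host_depths if host_depths else all_depths))
    sym_ref = float(np.median(sym_depths if sym_depths else all_depths))
    return [
        classify_scaffold(
            r, coverages[r.scaffold_id], (host_ref, sym_ref), params
        )
        for r in records
    ]
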