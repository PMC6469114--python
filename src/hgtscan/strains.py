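"""Evidence that an endosymbiont assembly pools multiple co-infecting strains.

Three independent signals are scored: (1) reference single-copy genes placed
at two or more non-overlapping assembly loci (separate strain copies that
escaped collapse), (2) single-copy genes carrying within-sample sequence
variation (strain copies that collapsed onto one locus), and (3) typing
markers (MLST and CI genes) duplicated on distinct scaffolds. Any one
signal above threshold flags the assembly as multi-strain. Reference
gene-set recovery accounting lives here too.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_DOWN, Decimal
from typing import Iterable, Mapping, Sequence

from .types import FeatureRecord, TabularHit, VariantSite, merge_intervals

__all__ = [
    "StrainParams",
    "StrainEvidenceReport",
    "duplicated_single_copy",
    "polymorphic_single_copy",
    "marker_duplication",
    "gene_set_recovery",
    "strain_report",
]


@dataclass(frozen=True)
class StrainParams:
    """Thresholds, conservative against split-hit and sequencing-noise
    artifacts: id_min/cov_min qualify a placement as a real gene locus;
    v_min/maf_min/d_min qualify a gene as genuinely polymorphic; t_dup and
    t_poly are the gene counts above which each signal flags multi-strain."""

    id_min: float = 0.90
    cov_min: float = 0.80
    v_min: int = 2
    maf_min: float = 0.10
    d_min: int = 10
    t_dup: int = 5
    t_poly: int = 5


@dataclass(frozen=True)
class StrainEvidenceReport:
    n_duplicated_single_copy: int
    n_polymorphic_single_copy: int
    duplicated_markers: tuple[str, ...]
    n_single_copy_total: int
    multi_strain_flag: bool
    duplicated_genes: tuple[str, ...] = ()
    polymorphic_genes: tuple[str, ...] = ()


def duplicated_single_copy(
    placements: Iterable[TabularHit],
    gene_lengths: Mapping[str, int],
    id_min: float = 0.90,
    cov_min: float = 0.80,
) -> set[str]:
    """Genes placed at two or more distinct assembly loci.

    A placement qualifies when its identity is at least ``id_min`` and it
    covers at least ``cov_min`` of the gene length; qualifying placements
    that overlap on the assembly (split hits of one locus) are merged before
    counting loci.
    """
    by_gene: dict[str, list[TabularHit]] = {}
    for h in placements:
        if h.percent_identity / 100.0 < id_min:
            continue
        glen = gene_lengths.get(h.query_id)
        if glen is None or h.query_interval.length / glen < cov_min:
            continue
        by_gene.setdefault(h.query_id, []).append(h)
    duplicated: set[str] = set()
    for gene, hits in by_gene.items():
        loci = 0
        by_scaffold: dict[str, list[tuple[int, int]]] = {}
        for h in hits:
            si = h.subject_interval
            by_scaffold.setdefault(h.subject_id, []).append((si.start, si.end))
        for ivs in by_scaffold.values():
            loci += len(merge_intervals(ivs))
        if loci >= 2:
            duplicated.add(gene)
    return duplicated


def polymorphic_single_copy(
    variants: Iterable[VariantSite],
    gene_features: Iterable[FeatureRecord],
    v_min: int = 2,
    maf_min: float = 0.10,
    d_min: int = 10,
) -> set[str]:
    """Genes containing at least ``v_min`` well-supported variant sites.

    A site counts when its total depth is at least ``d_min`` and its
    minor-allele fraction at least ``maf_min``.
    """
    if v_min <= 0 or maf_min <= 0 or d_min <= 0:
        raise ValueError("thresholds must be positive")
    good = [
        v
        for v in variants
        if v.depth >= d_min and v.minor_allele_fraction >= maf_min
    ]
    flagged: set[str] = set()
    for f in gene_features:
        if f.feature_type != "gene":
            continue
        n = sum(
            1
            for v in good
            if v.scaffold_id == f.scaffold_id
            and f.interval.start <= v.position < f.interval.end
        )
        if n >= v_min:
            flagged.add(f.feature_id)
    return flagged


def marker_duplication(
    marker_scaffolds: Mapping[str, Iterable[str]]
) -> list[str]:
    """Markers whose placements span two or more distinct scaffolds."""
    return sorted(
        m for m, scaffolds in marker_scaffolds.items() if len(set(scaffolds)) >= 2
    )


def gene_set_recovery(
    reference: Iterable[str], found: Iterable[str]
) -> tuple[int, float]:
    """Count and percentage of a reference gene set recovered in an assembly.

    The percentage is truncated (not rounded) to two decimals, matching the
    accounting convention under which 80/84 prints as 95.23.
    """
    ref = set(reference)
    if not ref:
        raise ValueError("reference gene set is empty")
    n_found = len(ref & set(found))
    pct = (Decimal(100 * n_found) / Decimal(len(ref))).quantize(
        Decimal("0.01"), rounding=ROUND_DOWN
    )
    return n_found, float(pct)


def strain_report(
    placements: Iterable[TabularHit],
    gene_lengths: Mapping[str, int],
    variants: Iterable[VariantSite],
    gene_features: Iterable[FeatureRecord],
    marker_scaffolds: Mapping[str, Iterable[str]],
    params: StrainParams = StrainParams(),
) -> StrainEvidenceReport:
    """Score all three evidence lines and flag multi-strain assemblies.

    The flag is true as soon as the duplicated-gene count reaches ``t_dup``,
    the polymorphic-gene count reaches ``t_poly``, or any marker is
    duplicated across scaffolds.
    """
    duplicated = duplicated_single_copy(
        placements, gene_lengths, params.id_min, params.cov_min
    )
    polymorphic = polymorphic_single_copy(
        variants, gene_features, params.v_min, params.maf_min, params.d_min
    )
    markers = marker_duplication(marker_scaffolds)
    n_total = len(gene_lengths)
    flag = (
        len(duplicated) >= params.t_dup
        or len(polymorphic) >= params.t_poly
        or bool(markers)
    )
    return StrainEvidenceReport(
        n_duplicated_single_copy=len(duplicated),
        n_polymorphic_single_copy=len(polymorphic),
        duplicated_markers=tuple(markers),
        n_single_copy_total=n_total,
        multi_strain_flag=flag,
        duplicated_genes=tuple(sorted(duplicated)),
        polymorphic_genes=tuple(sorted(polymorphic)),
    )
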