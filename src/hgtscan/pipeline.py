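"""End-to-end orchestration: classify scaffolds, detect HGT, write reports.

The in-memory entry point is :func:`analyze`, which takes the assembly,
depth tracks and references directly (this is what tests and the simulator
round-trip use); :func:`run_pipeline` is the file-based wrapper behind the
command line.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import io as hio
from .detect import (
    DetectParams,
    HgtCall,
    SimilarityBlock,
    anchor_chain_align,
    blocks_from_hits,
    detect_scaffold,
    _concat_contigs,
)
from .stats import assembly_stats
from .tagc import (
    ScaffoldClassification,
    ScaffoldRecord,
    TagcParams,
    classify_assembly,
    compute_gc,
)
from .types import DepthTrack, FeatureRecord, GenomicInterval, TabularHit

logger = logging.getLogger("hgtscan")

__all__ = ["analyze", "run_pipeline", "AnalysisResult"]


class AnalysisResult:
    """Classification, calls and assembly statistics for one run."""

    def __init__(
        self,
        classifications: list[ScaffoldClassification],
        calls: list[HgtCall],
        records: list[ScaffoldRecord],
        stats: dict,
    ) -> None:
        self.classifications = classifications
        self.calls = calls
        self.records = records
        self.stats = stats

    def labels(self) -> dict[str, str]:
        return {c.scaffold_id: c.label for c in self.classifications}

    def hgt_calls(self) -> list[HgtCall]:
        return [c for c in self.calls if c.verdict == "hgt"]


def _blocks_to_hit_stubs(blocks: Sequence[SimilarityBlock]) -> list[TabularHit]:
    """Adapt aligner blocks to the hit shape the classifier consumes."""
    stubs = []
    for b in blocks:
        if b.taxon_bin not in ("host", "symbiont"):
            continue
        stubs.append(
            TabularHit(
                query_id=b.interval.scaffold_id,
                subject_id=b.taxon_bin,
                taxon_bin=b.taxon_bin,
                percent_identity=100.0 * b.identity,
                query_interval=b.interval,
                subject_interval=b.ref_interval
                or GenomicInterval(b.taxon_bin, 0, b.interval.length),
                bitscore=float(b.interval.length),
            )
        )
    return stubs


def analyze(
    scaffolds: Mapping[str, str],
    tracks: Mapping[str, DepthTrack],
    host_refs: Sequence[tuple[str, str]] = (),
    symbiont_refs: Sequence[tuple[str, str]] = (),
    alt_assemblies: Sequence[Sequence[tuple[str, str]]] = (),
    features: Sequence[FeatureRecord] = (),
    fpkm: Mapping[str, float] | None = None,
    hits_by_scaffold: Mapping[str, Sequence[TabularHit]] | None = None,
    tagc_params: TagcParams = TagcParams(),
    detect_params: DetectParams = DetectParams(),
) -> AnalysisResult:
    """Classify every scaffold, then run HGT detection on the candidates.

    Similarity evidence comes either from an external hit table
    (``hits_by_scaffold``) or from aligning each scaffold against the host
    and symbiont references with the built-in anchor aligner.
    """
    missing = [sid for sid in scaffolds if sid not in tracks]
    if missing:
        raise ValueError(
            f"no depth track for scaffold(s): {', '.join(sorted(missing))}"
        )
    records = [
        ScaffoldRecord(
            scaffold_id=sid,
            length=len(seq),
            gc_fraction=compute_gc(seq),
            mean_depth=tracks[sid].mean(),
        )
        for sid, seq in scaffolds.items()
    ]

    blocks_by_scaffold: dict[str, list[SimilarityBlock]] = {}
    if hits_by_scaffold is not None:
        for sid in scaffolds:
            blocks_by_scaffold[sid] = blocks_from_hits(
                hits_by_scaffold.get(sid, ()), detect_params.min_block
            )
    else:
        spacer = detect_params.max_gap + detect_params.k + 1
        refs_concat = [
            (_concat_contigs(host_refs, spacer), "host") if host_refs else None,
            (_concat_contigs(symbiont_refs, spacer), "symbiont")
            if symbiont_refs
            else None,
        ]
        for sid, seq in scaffolds.items():
            blocks: list[SimilarityBlock] = []
            for item in refs_concat:
                if item is None:
                    continue
                ref, bin_ = item
                blocks.extend(
                    anchor_chain_align(
                        seq,
                        ref,
                        k=detect_params.k,
                        max_gap=detect_params.max_gap,
                        min_block=detect_params.min_block,
                        m_rep=detect_params.m_rep,
                        taxon_bin=bin_,
                        query_id=sid,
                    )
                )
            blocks_by_scaffold[sid] = blocks

    hit_stubs = {
        sid: _blocks_to_hit_stubs(blocks_by_scaffold[sid]) for sid in scaffolds
    }
    classifications = classify_assembly(records, hit_stubs, tagc_params)
    labels = {c.scaffold_id: c.label for c in classifications}

    host_depths = [r.mean_depth for r in records if labels[r.scaffold_id] == "host"]
    sym_depths = [
        r.mean_depth for r in records if labels[r.scaffold_id] == "symbiont"
    ]
    depth_refs = None
    if host_depths and sym_depths:
        depth_refs = (float(np.median(host_depths)), float(np.median(sym_depths)))

    calls: list[HgtCall] = []
    for sid, seq in scaffolds.items():
        if labels[sid] != "hgt_candidate":
            continue
        calls.extend(
            detect_scaffold(
                sid,
                seq,
                tracks[sid],
                host_refs,
                symbiont_refs,
                alt_assemblies=alt_assemblies,
                features=features,
                fpkm=fpkm,
                params=detect_params,
                depth_refs=depth_refs,
                blocks=blocks_by_scaffold[sid],
            )
        )
    calls.sort(key=lambda c: (c.scaffold_id, c.interval.start))

    stats = assembly_stats(list(scaffolds.items())).to_dict()
    return AnalysisResult(classifications, calls, records, stats)


def _write_reports(result: AnalysisResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "classifications.tsv", "w") as fh:
        fh.write(
            "scaffold\tlabel\tlength\tgc\tmean_depth\tsymbiont_covered\t"
            "host_covered\tdepth_cluster\tnotes\n"
        )
        rec = {r.scaffold_id: r for r in result.records}
        for c in result.classifications:
            r = rec[c.scaffold_id]
            fh.write(
                f"{c.scaffold_id}\t{c.label}\t{r.length}\t{r.gc_fraction:.4f}\t"
                f"{r.mean_depth:.2f}\t{c.symbiont_covered}\t{c.host_covered}\t"
                f"{c.depth_cluster}\t{c.evidence_notes}\n"
            )
    hio.write_bed(
        [
            (c.interval, f"{c.verdict}_{i}")
            for i, c in enumerate(result.calls)
            if c.verdict == "hgt"
        ],
        outdir / "calls.bed",
    )
    with open(outdir / "calls.tsv", "w") as fh:
        fh.write(
            "scaffold\tstart\tend\tlength\tverdict\tjunction_ratios\t"
            "corroborations\ttransposase_distance\tn_genes\tn_transcribed\tnotes\n"
        )
        for c in result.calls:
            ratios = ",".join(
                "nan" if j.log2_ratio != j.log2_ratio else f"{j.log2_ratio:.3f}"
                for j in c.junctions
            )
            tdist = "" if c.transposase_distance is None else c.transposase_distance
            fh.write(
                f"{c.scaffold_id}\t{c.interval.start}\t{c.interval.end}\t"
                f"{c.length}\t{c.verdict}\t{ratios}\t{c.corroborations}\t"
                f"{tdist}\t{len(c.genes)}\t{len(c.transcribed)}\t{c.notes}\n"
            )
    with open(outdir / "stats.json", "w") as fh:
        json.dump(result.stats, fh, indent=2)


def run_pipeline(
    assembly_fasta: str | Path,
    depth_tsv: str | Path,
    outdir: str | Path,
    host_ref_fasta: str | Path | None = None,
    symbiont_ref_fasta: str | Path | None = None,
    hits_tsv: str | Path | None = None,
    gff: str | Path | None = None,
    fpkm_tsv: str | Path | None = None,
    alt_fastas: Sequence[str | Path] = (),
    tagc_params: TagcParams = TagcParams(),
    detect_params: DetectParams = DetectParams(),
) -> AnalysisResult:
    """File-based pipeline: read inputs, analyze, write all reports.

    Either a hit table (``hits_tsv``, subjects binned by reference scaffold
    id) or host/symbiont reference FASTAs must be supplied. Every parameter
    value used is logged for reproducibility.
    """
    outdir = Path(outdir)
    scaffolds = dict(hio.read_fasta(assembly_fasta))
    tracks = hio.read_depth_tsv(depth_tsv, {s: len(q) for s, q in scaffolds.items()})
    host_refs = hio.read_fasta(host_ref_fasta) if host_ref_fasta else []
    symbiont_refs = hio.read_fasta(symbiont_ref_fasta) if symbiont_ref_fasta else []
    if hits_tsv is None and not (host_refs and symbiont_refs):
        raise ValueError(
            "need either a hits table or both host and symbiont references"
        )
    hits_by_scaffold = None
    if hits_tsv is not None:
        taxon_map = {sid: "host" for sid, _ in host_refs}
        taxon_map.update({sid: "symbiont" for sid, _ in symbiont_refs})
        hits = hio.read_tabular_hits(hits_tsv, taxon_map)
        hits_by_scaffold = {}
        for h in hits:
            hits_by_scaffold.setdefault(h.query_id, []).append(h)
    features = hio.read_gff(gff) if gff else []
    fpkm = hio.read_fpkm_tsv(fpkm_tsv) if fpkm_tsv else {}
    alt_assemblies = [hio.read_fasta(p) for p in alt_fastas]

    logger.info(
        "pipeline parameters: tagc=%s detect=%s", asdict(tagc_params),
        asdict(detect_params),
    )
    result = analyze(
        scaffolds,
        tracks,
        host_refs,
        symbiont_refs,
        alt_assemblies,
        features,
        fpkm,
        hits_by_scaffold=hits_by_scaffold,
        tagc_params=tagc_params,
        detect_params=detect_params,
    )
    _write_reports(result, outdir)
    with open(outdir / "params.json", "w") as fh:
        json.dump(
            {"tagc": asdict(tagc_params), "detect": asdict(detect_params)},
            fh,
            indent=2,
        )
    return result
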