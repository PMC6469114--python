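"""HGT detection on candidate scaffolds.

The detector locates symbiont-derived blocks on a candidate scaffold with a
light k-mer anchor-chaining aligner, tests read-depth continuity at every
host/symbiont junction against the chimeric-assembly hypothesis, corroborates
junctions across independently produced assemblies, annotates transposase
proximity and overlapping genes, and emits one call per candidate insertion.

A genuine insertion sits in host chromatin and is sequenced at host depth
throughout, so its junctions show no depth change; an artifactual chimera
joins molecules sequenced at different depths and betrays itself by a depth
step at the join.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .types import DepthTrack, FeatureRecord, GenomicInterval, TabularHit

__all__ = [
    "DetectParams",
    "SimilarityBlock",
    "JunctionVerdict",
    "Junction",
    "CandidateInsertion",
    "HgtCall",
    "anchor_chain_align",
    "blocks_from_hits",
    "segment_candidate",
    "junction_depth_test",
    "corroborate_junction",
    "transposase_proximity",
    "overlap_genes",
    "transcribed_subset",
    "call_hgt",
    "detect_scaffold",
]

_BASE_INDEX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i

_EPS_DEPTH = 0.5  # pseudo-depth in log-ratios; avoids division by zero


@dataclass(frozen=True)
class DetectParams:
    """Detector thresholds; every key is a config/CLI flag.

    k / m_rep / max_gap / min_block drive the anchor aligner (k=21 keeps
    random 1.4 Mb-scale genomes anchor-free; m_rep=10 skips repeats;
    max_gap=500 bridges anchor dropouts from ~1% divergence at k=21;
    min_block=300 sits below the smallest insert worth calling).
    window/guard/tau_junction/w_min parameterise the junction depth test
    (500 bp windows give a depth-mean standard error well under the 1.5x
    band at tens-fold coverage; the 50 bp guard skips junction-adjacent
    assembly fraying). flank/flank_covered/c_min control cross-assembly
    corroboration; max_dist bounds transposase proximity; min_fpkm calls a
    gene transcribed.
    """

    k: int = 21
    m_rep: int = 10
    max_gap: int = 500
    min_block: int = 300
    window: int = 500
    guard: int = 50
    tau_junction: float = 1.5
    w_min: int = 100
    flank: int = 500
    flank_covered: int = 200
    c_min: int = 1
    max_dist: int = 2000
    min_fpkm: float = 0.01


@dataclass(frozen=True)
class SimilarityBlock:
    """A chained-anchor alignment block on the candidate scaffold."""

    interval: GenomicInterval           #: on the query scaffold
    taxon_bin: str | None               #: host | symbiont | None (untagged)
    identity: float                     #: anchored bases / block span, in [0, 1]
    anchor_count: int
    ref_interval: GenomicInterval | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"identity out of [0, 1]: {self.identity}")
        if self.anchor_count < 1:
            raise ValueError("a block needs at least one anchor")


# ---------------------------------------------------------------------------
# Anchor-chaining aligner
# ---------------------------------------------------------------------------

def _kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Base-4 codes of all k-mers and a validity mask (no ambiguity codes)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    idx = _BASE_INDEX[arr]
    n = arr.size - k + 1
    if n <= 0:
        return np.empty(0, np.uint64), np.empty(0, bool)
    safe = np.where(idx == 255, 0, idx).astype(np.uint64)
    codes = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        codes = codes * np.uint64(4) + safe[j : j + n]
    bad = np.concatenate([[0], np.cumsum((idx == 255).astype(np.int64))])
    ok = (bad[k:] - bad[:-k]) == 0
    return codes, ok


def _anchors(
    query: str, reference: str, k: int, m_rep: int
) -> tuple[np.ndarray, np.ndarray]:
    """All (query_pos, ref_pos) exact k-mer matches, skipping reference
    k-mers occurring more than ``m_rep`` times."""
    rcodes, rok = _kmer_codes(reference, k)
    qcodes, qok = _kmer_codes(query, k)
    rpos = np.flatnonzero(rok)
    qpos = np.flatnonzero(qok)
    if rpos.size == 0 or qpos.size == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    rc = rcodes[rpos]
    order = np.argsort(rc, kind="stable")
    rc_sorted = rc[order]
    rpos_sorted = rpos[order]
    qc = qcodes[qpos]
    lo = np.searchsorted(rc_sorted, qc, side="left")
    hi = np.searchsorted(rc_sorted, qc, side="right")
    occ = hi - lo
    keep = (occ > 0) & (occ <= m_rep)
    if not keep.any():
        return np.empty(0, np.int64), np.empty(0, np.int64)
    lo, cnt, qp = lo[keep], occ[keep], qpos[keep]
    total = int(cnt.sum())
    rep_q = np.repeat(qp, cnt).astype(np.int64)
    offs = np.arange(total, dtype=np.int64) - np.repeat(np.cumsum(cnt) - cnt, cnt)
    rep_r = rpos_sorted[np.repeat(lo, cnt) + offs].astype(np.int64)
    return rep_q, rep_r


def anchor_chain_align(
    query: str,
    reference: str,
    k: int = 21,
    max_gap: int = 500,
    min_block: int = 300,
    m_rep: int = 10,
    taxon_bin: str | None = None,
    query_id: str = "query",
    ref_id: str = "ref",
) -> list[SimilarityBlock]:
    """Find similarity blocks between two sequences by exact-anchor chaining.

    Exact k-mer anchors (reference k-mers occurring more than ``m_rep`` times
    are skipped) are chained along each diagonal when consecutive anchors are
    at most ``max_gap`` apart; chains whose query and reference gaps are both
    within ``max_gap`` are merged into blocks. Block identity is anchored
    bases over block span; blocks shorter than ``min_block`` are dropped.
    Output is sorted by query position. Forward strand only.
    """
    if k < 11:
        raise ValueError("k must be >= 11")
    if len(query) < k or len(reference) < k:
        raise ValueError("sequences must be at least k long")
    q, r = _anchors(query, reference, k, m_rep)
    if q.size == 0:
        return []
    diag = q - r
    order = np.lexsort((q, diag))
    q, r, diag = q[order], r[order], diag[order]
    new = np.ones(q.size, dtype=bool)
    new[1:] = (diag[1:] != diag[:-1]) | (q[1:] - q[:-1] > max_gap)
    chain_id = np.cumsum(new) - 1
    n_chains = int(chain_id[-1]) + 1
    starts = np.flatnonzero(new)
    ends = np.append(starts[1:], q.size)
    qs, qe = q[starts], q[ends - 1] + k
    rs, re = r[starts], r[ends - 1] + k
    na = ends - starts
    internal = ~new[1:]
    gaps = np.minimum(q[1:] - q[:-1], k)
    anchored = (
        np.bincount(chain_id[1:][internal], weights=gaps[internal], minlength=n_chains)
        + k
    ).astype(np.int64)

    # merge collinear chains into blocks, in query-position order
    c_order = np.lexsort((rs, qs))
    qs, qe, rs, re, na, anchored = (
        a[c_order] for a in (qs, qe, rs, re, na, anchored)
    )
    blocks: list[list[int]] = []  # [q0, q1, r0, r1, anchors, anchored]
    for i in range(n_chains):
        if blocks:
            b = blocks[-1]
            if (
                qs[i] - b[1] <= max_gap
                and rs[i] - b[3] <= max_gap
                and rs[i] - b[3] >= -max_gap
            ):
                b[1] = max(b[1], int(qe[i]))
                b[3] = max(b[3], int(re[i]))
                b[4] += int(na[i])
                b[5] += int(anchored[i])
                continue
        blocks.append(
            [int(qs[i]), int(qe[i]), int(rs[i]), int(re[i]), int(na[i]),
             int(anchored[i])]
        )

    out: list[SimilarityBlock] = []
    for q0, q1, r0, r1, n_anch, anch in blocks:
        span = q1 - q0
        if span < min_block:
            continue
        out.append(
            SimilarityBlock(
                interval=GenomicInterval(query_id, q0, q1),
                taxon_bin=taxon_bin,
                identity=min(1.0, anch / span),
                anchor_count=n_anch,
                ref_interval=GenomicInterval(ref_id, r0, r1),
            )
        )
    out.sort(key=lambda b: (b.interval.start, b.interval.end))
    return out


def blocks_from_hits(
    hits: Iterable[TabularHit], min_block: int = 300
) -> list[SimilarityBlock]:
    """Convert externally computed tabular hits into similarity blocks."""
    out = [
        SimilarityBlock(
            interval=h.query_interval,
            taxon_bin=h.taxon_bin,
            identity=h.percent_identity / 100.0,
            anchor_count=1,
            ref_interval=h.subject_interval,
        )
        for h in hits
        if h.query_interval.length >= min_block and h.taxon_bin in ("host", "symbiont")
    ]
    out.sort(key=lambda b: (b.interval.start, b.interval.end))
    return out


# ---------------------------------------------------------------------------
# Candidate segmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Junction:
    """A host/symbiont block boundary on a candidate scaffold."""

    position: int
    kind: str  #: internal | edge | unflanked | ambiguous


@dataclass(frozen=True)
class CandidateInsertion:
    scaffold_id: str
    interval: GenomicInterval
    junctions: tuple[Junction, ...]
    n_symbiont_blocks: int
    mean_identity: float


def _resolve_overlaps(
    host: list[dict], sym: list[dict], overlap_tol: int = 30
) -> list[tuple[int, int]]:
    """Trim the lower-identity block wherever host and symbiont blocks
    overlap; identity ties on substantial overlaps yield an ambiguous zone
    both blocks are cut to. Overlaps within ``overlap_tol`` bp (chance
    anchor extension across a clean boundary) are split at the midpoint
    without flagging ambiguity. Returns the ambiguous (start, end) zones."""
    ambiguous: list[tuple[int, int]] = []
    for hb in host:
        for sb in sym:
            lo = max(hb["start"], sb["start"])
            hi = min(hb["end"], sb["end"])
            if lo >= hi or hb["dead"] or sb["dead"]:
                continue
            if hi - lo <= overlap_tol:
                mid = (lo + hi) // 2
                left, right = (hb, sb) if hb["start"] <= sb["start"] else (sb, hb)
                left["end"] = min(left["end"], mid)
                right["start"] = max(right["start"], mid)
                for b in (left, right):
                    if b["end"] - b["start"] < 1:
                        b["dead"] = True
                continue
            if abs(hb["identity"] - sb["identity"]) < 1e-9:
                mid = (lo + hi) // 2
                ambiguous.append((lo, hi))
                left, right = (hb, sb) if hb["start"] <= sb["start"] else (sb, hb)
                left["end"] = min(left["end"], mid)
                right["start"] = max(right["start"], mid)
                for b in (left, right):
                    if b["end"] - b["start"] < 1:
                        b["dead"] = True
                continue
            lower, higher = (
                (hb, sb) if hb["identity"] < sb["identity"] else (sb, hb)
            )
            if lower["start"] >= higher["start"] and lower["end"] <= higher["end"]:
                lower["dead"] = True
            elif lower["start"] < higher["start"]:
                lower["end"] = higher["start"]
            else:
                lower["start"] = higher["end"]
            if lower["end"] - lower["start"] < 1:
                lower["dead"] = True
    return ambiguous


def segment_candidate(
    blocks: Sequence[SimilarityBlock],
    scaffold_length: int,
    max_gap: int = 500,
    scaffold_id: str | None = None,
    overlap_tol: int = 30,
) -> list[CandidateInsertion]:
    """Locate candidate insertions from the host/symbiont block alternation.

    A candidate is a maximal run of symbiont blocks (merged across gaps of at
    most ``max_gap``) flanked by a host block on at least one side or by a
    scaffold end. Junction positions are the midpoints of the inter-block
    gaps; a symbiont run starting or ending within ``max_gap`` of a scaffold
    end gets an ``edge`` junction there, which carries no depth evidence.
    """
    sid = scaffold_id or (blocks[0].interval.scaffold_id if blocks else "scaffold")
    host = [
        {"start": b.interval.start, "end": b.interval.end,
         "identity": b.identity, "dead": False}
        for b in blocks if b.taxon_bin == "host"
    ]
    sym = [
        {"start": b.interval.start, "end": b.interval.end,
         "identity": b.identity, "dead": False}
        for b in blocks if b.taxon_bin == "symbiont"
    ]
    ambiguous = _resolve_overlaps(host, sym, overlap_tol)
    host = sorted(
        (b for b in host if not b["dead"]), key=lambda b: (b["start"], b["end"])
    )
    sym = sorted(
        (b for b in sym if not b["dead"]), key=lambda b: (b["start"], b["end"])
    )
    if not sym:
        return []

    # merge symbiont blocks into runs
    runs: list[list] = []  # [start, end, n_blocks, identity_sum]
    for b in sym:
        if runs and b["start"] - runs[-1][1] <= max_gap:
            runs[-1][1] = max(runs[-1][1], b["end"])
            runs[-1][2] += 1
            runs[-1][3] += b["identity"]
        else:
            runs.append([b["start"], b["end"], 1, b["identity"]])

    def _in_ambiguous(pos: int) -> bool:
        return any(a <= pos < z for a, z in ambiguous)

    out: list[CandidateInsertion] = []
    for r0, r1, n_blocks, ident_sum in runs:
        left_host = max(
            (h for h in host if h["end"] <= r0), key=lambda h: h["end"], default=None
        )
        right_host = min(
            (h for h in host if h["start"] >= r1),
            key=lambda h: h["start"],
            default=None,
        )
        junctions: list[Junction] = []
        if left_host is not None:
            pos = (left_host["end"] + r0) // 2
            kind = "ambiguous" if _in_ambiguous(pos) else "internal"
            junctions.append(Junction(pos, kind))
            c_start = pos
        elif r0 <= max_gap:
            junctions.append(Junction(0, "edge"))
            c_start = 0
        else:
            junctions.append(Junction(r0, "unflanked"))
            c_start = r0
        if right_host is not None:
            pos = (r1 + right_host["start"]) // 2
            kind = "ambiguous" if _in_ambiguous(pos) else "internal"
            junctions.append(Junction(pos, kind))
            c_end = pos
        elif scaffold_length - r1 <= max_gap:
            junctions.append(Junction(scaffold_length, "edge"))
            c_end = scaffold_length
        else:
            junctions.append(Junction(r1, "unflanked"))
            c_end = r1
        if all(j.kind == "unflanked" for j in junctions):
            continue  # not flanked by host or scaffold end on any side
        if c_end <= c_start:
            continue
        out.append(
            CandidateInsertion(
                scaffold_id=sid,
                interval=GenomicInterval(sid, c_start, c_end),
                junctions=tuple(junctions),
                n_symbiont_blocks=n_blocks,
                mean_identity=ident_sum / n_blocks,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Junction depth continuity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JunctionVerdict:
    position: int
    left_mean: float
    right_mean: float
    log2_ratio: float
    verdict: str  #: continuous | step_change | indeterminate
    kind: str = "internal"


def junction_depth_test(
    track: DepthTrack,
    position: int,
    window: int = 500,
    guard: int = 50,
    tau_junction: float = 1.5,
    w_min: int = 100,
    kind: str = "internal",
) -> JunctionVerdict:
    """Test read-depth continuity across one junction.

    Compares mean depth in ``[position-guard-window, position-guard)`` against
    ``[position+guard, position+guard+window)``; the verdict is ``continuous``
    when the absolute log2 ratio (with pseudo-depth 0.5) is within
    ``log2(tau_junction)``, ``step_change`` when it exceeds it, and
    ``indeterminate`` when either window leaves the scaffold or has fewer
    than ``w_min`` covered bases.
    """
    if window < 100:
        raise ValueError("window must be >= 100 bp")
    if guard < 0:
        raise ValueError("guard must be >= 0")
    l0, l1 = position - guard - window, position - guard
    r0, r1 = position + guard, position + guard + window
    n = len(track)
    if l0 < 0 or r1 > n:
        return JunctionVerdict(position, math.nan, math.nan, math.nan,
                               "indeterminate", kind)
    left = track.values[l0:l1]
    right = track.values[r0:r1]
    if (left > 0).sum() < w_min or (right > 0).sum() < w_min:
        return JunctionVerdict(position, float(left.mean()), float(right.mean()),
                               math.nan, "indeterminate", kind)
    lm, rm = float(left.mean()), float(right.mean())
    ratio = math.log2((lm + _EPS_DEPTH) / (rm + _EPS_DEPTH))
    verdict = "continuous" if abs(ratio) <= math.log2(tau_junction) else "step_change"
    return JunctionVerdict(position, lm, rm, ratio, verdict, kind)


# ---------------------------------------------------------------------------
# Cross-assembly corroboration
# ---------------------------------------------------------------------------

def _concat_contigs(contigs: Sequence[tuple[str, str]], spacer: int) -> str:
    """Join contigs with runs of N long enough that no block can span two
    contigs (ambiguous k-mers anchor nothing; the spacer exceeds max_gap)."""
    pad = "N" * spacer
    return pad.join(seq for _cid, seq in contigs)


def corroborate_junction(
    scaffold_seq: str,
    position: int,
    alt_assemblies: Sequence[Sequence[tuple[str, str]]],
    flank: int = 500,
    k: int = 21,
    max_gap: int = 500,
    flank_covered: int = 200,
    m_rep: int = 10,
) -> int:
    """Count alternative assemblies containing a contig that aligns
    contiguously across the junction.

    The ``2*flank`` bp window centred on the junction is aligned against each
    assembly; an assembly corroborates when a single block covers at least
    ``flank_covered`` bases on each side of the junction within one contig.
    """
    if flank < 200:
        raise ValueError("flank must be >= 200 bp")
    if position - flank < 0 or position + flank > len(scaffold_seq):
        raise ValueError("junction +/- flank must lie within the scaffold")
    query = scaffold_seq[position - flank : position + flank]
    count = 0
    for contigs in alt_assemblies:
        if not contigs:
            continue
        ref = _concat_contigs(contigs, spacer=max_gap + k + 1)
        blocks = anchor_chain_align(
            query, ref, k=k, max_gap=max_gap,
            min_block=min(300, 2 * flank_covered), m_rep=m_rep,
        )
        for b in blocks:
            if (
                b.interval.start <= flank - flank_covered
                and b.interval.end >= flank + flank_covered
            ):
                count += 1
                break
    return count


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def transposase_proximity(
    candidate: GenomicInterval,
    features: Iterable[FeatureRecord],
    max_dist: int = 2000,
) -> int | None:
    """Distance (bp) to the nearest transposase feature on the same scaffold;
    0 if one overlaps the candidate; None when none lies within ``max_dist``."""
    best: int | None = None
    for f in features:
        if f.feature_type != "transposase":
            continue
        if f.scaffold_id != candidate.scaffold_id:
            continue
        gap = candidate.gap_to(f.interval)
        if best is None or gap < best:
            best = gap
    if best is None or best > max_dist:
        return None
    return best


def overlap_genes(
    candidate: GenomicInterval, features: Iterable[FeatureRecord]
) -> list[str]:
    """IDs of gene features intersecting the candidate by at least 1 bp."""
    return [
        f.feature_id
        for f in features
        if f.feature_type == "gene"
        and f.scaffold_id == candidate.scaffold_id
        and f.interval.overlaps(candidate)
    ]


def transcribed_subset(
    gene_ids: Iterable[str], fpkm: Mapping[str, float], min_fpkm: float = 0.01
) -> list[str]:
    """Genes whose FPKM meets ``min_fpkm``; genes absent from the table are
    treated as unexpressed."""
    if min_fpkm < 0:
        raise ValueError("min_fpkm must be >= 0")
    return [g for g in gene_ids if fpkm.get(g, 0.0) >= min_fpkm]


# ---------------------------------------------------------------------------
# Calls
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HgtCall:
    """A called insertion with all evidence channels attached."""

    scaffold_id: str
    interval: GenomicInterval
    junctions: tuple[JunctionVerdict, ...]
    corroborations: int
    transposase_distance: int | None
    genes: tuple[str, ...]
    transcribed: tuple[str, ...]
    verdict: str  #: hgt | chimera_suspect | unresolved
    notes: str = ""

    @property
    def length(self) -> int:
        return self.interval.length


def _verdict(
    junctions: Sequence[JunctionVerdict], corroborations: int, c_min: int
) -> str:
    if any(j.verdict == "step_change" for j in junctions):
        return "chimera_suspect"
    blocked = any(
        j.verdict == "indeterminate" and j.kind not in ("edge",)
        for j in junctions
    )
    if not blocked and corroborations >= c_min:
        return "hgt"
    return "unresolved"


def call_hgt(
    evidence: Sequence[tuple[CandidateInsertion, Sequence[JunctionVerdict], int]],
    features: Sequence[FeatureRecord] = (),
    fpkm: Mapping[str, float] | None = None,
    params: DetectParams = DetectParams(),
    notes_by_candidate: Mapping[int, str] | None = None,
) -> list[HgtCall]:
    """Assemble final calls from per-candidate evidence.

    ``evidence`` holds ``(candidate, junction_verdicts, corroborations)``
    triples. The verdict is ``chimera_suspect`` as soon as any junction shows
    a depth step; ``hgt`` when every junction is continuous (edge junctions,
    which carry no depth evidence, do not block) and the corroboration count
    meets ``c_min``; ``unresolved`` otherwise.
    """
    fpkm = fpkm or {}
    calls: list[HgtCall] = []
    for i, (cand, verdicts, corroborations) in enumerate(evidence):
        genes = overlap_genes(cand.interval, features)
        transcribed = transcribed_subset(genes, fpkm, params.min_fpkm)
        calls.append(
            HgtCall(
                scaffold_id=cand.scaffold_id,
                interval=cand.interval,
                junctions=tuple(verdicts),
                corroborations=corroborations,
                transposase_distance=transposase_proximity(
                    cand.interval, features, params.max_dist
                ),
                genes=tuple(genes),
                transcribed=tuple(transcribed),
                verdict=_verdict(verdicts, corroborations, params.c_min),
                notes=(notes_by_candidate or {}).get(i, ""),
            )
        )
    calls.sort(key=lambda c: (c.scaffold_id, c.interval.start))
    return calls


def detect_scaffold(
    scaffold_id: str,
    sequence: str,
    track: DepthTrack,
    host_refs: Sequence[tuple[str, str]],
    symbiont_refs: Sequence[tuple[str, str]],
    alt_assemblies: Sequence[Sequence[tuple[str, str]]] = (),
    features: Sequence[FeatureRecord] = (),
    fpkm: Mapping[str, float] | None = None,
    params: DetectParams = DetectParams(),
    depth_refs: tuple[float, float] | None = None,
    blocks: Sequence[SimilarityBlock] | None = None,
) -> list[HgtCall]:
    """Run the full detection chain on one candidate scaffold.

    Host and symbiont similarity blocks are found with the anchor aligner
    against the respective reference sequences (or taken from ``blocks`` when
    precomputed, e.g. from an external hit table); the blocks are segmented
    into candidate insertions; each internal junction gets a depth-continuity
    test and cross-assembly corroboration; annotations and verdicts are
    attached by :func:`call_hgt`.
    """
    spacer = params.max_gap + params.k + 1
    evidence: list[tuple[CandidateInsertion, list[JunctionVerdict], int]] = []
    notes: dict[int, str] = {}

    if blocks is None:
        blocks = []
        for refs, bin_ in ((host_refs, "host"), (symbiont_refs, "symbiont")):
            if not refs:
                continue
            ref = _concat_contigs(refs, spacer)
            blocks.extend(
                anchor_chain_align(
                    sequence, ref, k=params.k, max_gap=params.max_gap,
                    min_block=params.min_block, m_rep=params.m_rep,
                    taxon_bin=bin_, query_id=scaffold_id,
                )
            )
    candidates = segment_candidate(
        blocks, len(sequence), max_gap=params.max_gap, scaffold_id=scaffold_id
    )

    confound = ""
    if depth_refs is not None:
        h, s = depth_refs
        if abs(math.log2((h + _EPS_DEPTH) / (s + _EPS_DEPTH))) <= math.log2(
            params.tau_junction
        ):
            confound = (
                "host and symbiont depth regimes are within the junction "
                "ratio band; the depth test cannot separate chimeras here"
            )

    for i, cand in enumerate(candidates):
        verdicts: list[JunctionVerdict] = []
        corroborations: list[int] = []
        for j in cand.junctions:
            if j.kind == "edge":
                verdicts.append(
                    JunctionVerdict(j.position, math.nan, math.nan, math.nan,
                                    "indeterminate", "edge")
                )
                continue
            if j.kind == "ambiguous":
                continue  # excluded from junction evidence
            verdicts.append(
                junction_depth_test(
                    track, j.position, params.window, params.guard,
                    params.tau_junction, params.w_min, kind=j.kind,
                )
            )
            if (
                alt_assemblies
                and params.flank <= j.position <= len(sequence) - params.flank
            ):
                corroborations.append(
                    corroborate_junction(
                        sequence, j.position, alt_assemblies,
                        flank=params.flank, k=params.k, max_gap=params.max_gap,
                        flank_covered=params.flank_covered, m_rep=params.m_rep,
                    )
                )
        if corroborations:
            corr = min(corroborations)
        elif alt_assemblies:
            # no testable internal junction: corroborate across the centre
            centre = (cand.interval.start + cand.interval.end) // 2
            centre = min(max(centre, params.flank), len(sequence) - params.flank)
            corr = corroborate_junction(
                sequence, centre, alt_assemblies,
                flank=params.flank, k=params.k, max_gap=params.max_gap,
                flank_covered=params.flank_covered, m_rep=params.m_rep,
            )
        else:
            corr = 0
        evidence.append((cand, verdicts, corr))
        if confound:
            notes[i] = confound

    return call_hgt(evidence, features, fpkm, params, notes)
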