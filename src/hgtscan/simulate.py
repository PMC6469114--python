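"""Synthetic data generator for endosymbiont-to-host HGT detection.

Emulates the statistical structure the detection pipeline assumes: a host
genome and a symbiont genome at nearly identical GC but very different
sequencing depth; symbiont-derived insertions planted in host scaffolds
(uniform read depth across the junctions); chimeric scaffolds whose depth
steps exactly at the join; optional co-infecting symbiont strains at small
divergence (pooled reads create duplicated/polymorphic single-copy-gene
signals); shredded alternative assemblies for cross-assembly corroboration;
and truth tables for every planted event.

Reads are *placed*, never mapped: depth tracks are computed exactly from the
recorded placements, which is the evidence channel the detector consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .types import DepthTrack, FeatureRecord, GenomicInterval, TabularHit, VariantSite

__all__ = [
    "SimulationConfig",
    "StrainSimConfig",
    "TruthTable",
    "PlantedInsertion",
    "StudyBundle",
    "StrainBundle",
    "PlacementError",
    "generate_genome",
    "derive_strain",
    "plant_insertions",
    "simulate_reads",
    "make_chimera",
    "shred_assembly",
    "simulate_study",
    "simulate_strain_study",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# index of each base byte in ACGT order; 255 marks non-ACGT
_BASE_INDEX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


class PlacementError(RuntimeError):
    """Raised when non-overlapping placement cannot be satisfied."""


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Primitive generators
# ---------------------------------------------------------------------------

def generate_genome(length: int, gc: float, seed: int | np.random.Generator) -> str:
    """I.i.d. random nucleotide sequence with P(G) + P(C) = ``gc``.

    Deterministic for a fixed integer seed.
    """
    if length <= 0:
        raise ValueError(f"genome length must be positive, got {length}")
    if not 0.0 < gc < 1.0:
        raise ValueError(f"gc must lie strictly inside (0, 1), got {gc}")
    rng = _as_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p).tobytes().decode("ascii")


def derive_strain(
    genome: str, divergence: float, seed: int | np.random.Generator
) -> tuple[str, np.ndarray]:
    """Substitute each base independently with probability ``divergence``.

    Returns the variant sequence and the (sorted) array of substituted
    positions. A substituted base never equals the original.
    """
    if not 0.0 <= divergence < 0.2:
        raise ValueError(f"divergence must lie in [0, 0.2), got {divergence}")
    arr = np.frombuffer(genome.encode("ascii"), dtype=np.uint8).copy()
    rng = _as_rng(seed)
    hit = rng.random(arr.size) < divergence
    idx = _BASE_INDEX[arr]
    hit &= idx != 255  # never substitute ambiguity codes
    positions = np.flatnonzero(hit)
    if positions.size:
        shift = rng.integers(1, 4, size=positions.size)
        arr[positions] = _BASES[(idx[positions] + shift) % 4]
    return arr.tobytes().decode("ascii"), positions


@dataclass(frozen=True)
class PlantedInsertion:
    """Truth record for one planted symbiont fragment."""

    site: GenomicInterval      #: destination on the modified host scaffold
    source: GenomicInterval    #: origin on the symbiont genome

    @property
    def length(self) -> int:
        return self.site.length


def plant_insertions(
    host: str,
    symbiont: str,
    n_insertions: int,
    length_range: tuple[int, int],
    seed: int | np.random.Generator,
    *,
    scaffold_id: str = "host",
    source_id: str = "symbiont",
    edge_margin: int = 2000,
    min_separation: int = 1000,
    source_exclude: list[tuple[int, int]] | None = None,
    source_windows: Sequence[tuple[int, int]] | None = None,
    max_retries: int = 200,
) -> tuple[str, list[PlantedInsertion]]:
    """Insert ``n_insertions`` non-overlapping symbiont fragments into the host.

    Fragment lengths are uniform in ``length_range``; insertion points are
    uniform over the host, kept ``edge_margin`` bp away from scaffold ends and
    ``min_separation`` bp apart. ``source_exclude`` lets callers forbid reuse
    of symbiont regions across multiple calls (the list is extended in place
    with the chosen source intervals); ``source_windows`` restricts where on
    the symbiont fragments may originate (e.g. within single reference
    scaffolds), defaulting to the whole sequence.
    """
    if n_insertions == 0:
        return host, []
    rng = _as_rng(seed)
    lo, hi = length_range
    if lo < 100 or hi < lo:
        raise ValueError(f"bad insertion length range {length_range}")
    if hi >= len(symbiont):
        raise ValueError("symbiont too short to supply requested fragments")
    windows = list(source_windows) if source_windows else [(0, len(symbiont))]

    exclude = source_exclude if source_exclude is not None else []
    sources: list[tuple[int, int]] = []
    for _ in range(n_insertions):
        for _try in range(max_retries):
            L = int(rng.integers(lo, hi + 1))
            fitting = [(a, z) for a, z in windows if z - a >= L]
            if not fitting:
                continue
            w = fitting[int(rng.integers(0, len(fitting)))]
            s = int(rng.integers(w[0], w[1] - L + 1))
            cand = (s, s + L)
            if all(cand[1] <= a or cand[0] >= b for a, b in exclude + sources):
                sources.append(cand)
                break
        else:
            raise PlacementError("could not place non-overlapping source fragments")
    exclude.extend(sources)

    span = len(host) - 2 * edge_margin
    if span <= n_insertions * min_separation:
        raise PlacementError("host too short for requested insertion spacing")
    positions: list[int] = []
    for _ in range(n_insertions):
        for _try in range(max_retries):
            p = int(rng.integers(edge_margin, len(host) - edge_margin))
            if all(abs(p - q) >= min_separation for q in positions):
                positions.append(p)
                break
        else:
            raise PlacementError("could not space insertion points on host")

    order = np.argsort(positions)
    pieces: list[str] = []
    insertions: list[PlantedInsertion] = []
    prev = 0
    offset = 0
    for k in order:
        p = positions[k]
        s0, s1 = sources[k]
        pieces.append(host[prev:p])
        pieces.append(symbiont[s0:s1])
        insertions.append(
            PlantedInsertion(
                site=GenomicInterval(scaffold_id, p + offset, p + offset + (s1 - s0)),
                source=GenomicInterval(source_id, s0, s1),
            )
        )
        offset += s1 - s0
        prev = p
    pieces.append(host[prev:])
    return "".join(pieces), insertions


# ---------------------------------------------------------------------------
# Read placement
# ---------------------------------------------------------------------------

@dataclass
class SimulatedReads:
    """Placed reads and the depth tracks they induce."""

    read_length: int
    sequences: dict[str, str]
    placements: dict[str, np.ndarray]   #: sorted read start positions
    tracks: dict[str, DepthTrack]

    def to_fastq(self, path: str | Path, error_rate: float = 0.0,
                 seed: int | np.random.Generator = 0) -> int:
        """Materialise reads as FASTQ (fixed quality 'I'); returns read count."""
        rng = _as_rng(seed)
        qual = "I" * self.read_length
        n = 0
        with open(path, "w") as fh:
            for rid in self.placements:
                seq = self.sequences[rid]
                for start in self.placements[rid]:
                    read = seq[start : start + self.read_length]
                    if error_rate > 0:
                        read = _apply_errors(read, error_rate, rng)
                    fh.write(f"@{rid}_{start}\n{read}\n+\n{qual}\n")
                    n += 1
        return n


def _apply_errors(read: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(read.encode("ascii"), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(arr.size) < rate)
    if hit.size:
        idx = _BASE_INDEX[arr[hit]]
        shift = rng.integers(1, 4, size=hit.size)
        arr[hit] = _BASES[(idx + shift) % 4]
    return arr.tobytes().decode("ascii")


def _depth_from_starts(starts: np.ndarray, length: int, read_length: int) -> np.ndarray:
    delta = np.zeros(length + read_length + 1, dtype=np.float64)
    np.add.at(delta, starts, 1.0)
    np.add.at(delta, starts + read_length, -1.0)
    return np.cumsum(delta)[:length]


def simulate_reads(
    replicons: Sequence[tuple[str, str, float]],
    read_length: int,
    seed: int | np.random.Generator,
) -> SimulatedReads:
    """Place single-end reads uniformly on each replicon.

    ``replicons`` is a sequence of ``(id, sequence, mean_depth)``. The read
    count per replicon is ``round(depth * length / read_length)``; depth
    tracks are computed exactly from the placements.
    """
    rng = _as_rng(seed)
    sequences: dict[str, str] = {}
    placements: dict[str, np.ndarray] = {}
    tracks: dict[str, DepthTrack] = {}
    for rid, seq, depth in replicons:
        if read_length >= len(seq):
            raise ValueError(
                f"read length {read_length} >= replicon {rid} length {len(seq)}"
            )
        n_reads = int(round(depth * len(seq) / read_length))
        if n_reads == 0:
            warnings.warn(f"replicon {rid}: depth {depth} yields zero reads")
            starts = np.empty(0, dtype=np.int64)
        else:
            starts = np.sort(
                rng.integers(0, len(seq) - read_length + 1, size=n_reads)
            ).astype(np.int64)
        sequences[rid] = seq
        placements[rid] = starts
        tracks[rid] = DepthTrack(rid, _depth_from_starts(starts, len(seq), read_length))
    return SimulatedReads(read_length, sequences, placements, tracks)


def make_chimera(
    host_fragment: str,
    symbiont_fragment: str,
    host_depth: float,
    symbiont_depth: float,
    read_length: int,
    seed: int | np.random.Generator,
    *,
    scaffold_id: str = "chimera",
    policy: str = "step",
) -> tuple[str, DepthTrack, int]:
    """Join a host and a symbiont fragment into one artifactual scaffold.

    Reads are simulated on each fragment separately (no read spans the join,
    as in a genuine mis-assembly), so the depth track steps from the host to
    the symbiont regime exactly at the junction. Returns
    ``(sequence, depth_track, junction_position)`` with the junction equal to
    the host fragment length.
    """
    if policy != "step":
        raise ValueError(f"unknown junction policy {policy!r}")
    if min(len(host_fragment), len(symbiont_fragment)) < 2 * read_length:
        raise ValueError("chimera fragments must each span at least two reads")
    rng = _as_rng(seed)
    sim = simulate_reads(
        [("h", host_fragment, host_depth), ("s", symbiont_fragment, symbiont_depth)],
        read_length,
        rng,
    )
    seq = host_fragment + symbiont_fragment
    values = np.concatenate([sim.tracks["h"].values, sim.tracks["s"].values])
    return seq, DepthTrack(scaffold_id, values), len(host_fragment)


def shred_assembly(
    genome: str,
    mean_fragment: int,
    seed: int | np.random.Generator,
    *,
    avoid: Iterable[tuple[int, int]] = (),
    id_prefix: str = "alt",
) -> list[tuple[str, str]]:
    """Cut a genome at random breakpoints into an 'alternative assembly'.

    Breakpoints form a uniform (Poisson) process with ``round(L/mean) - 1``
    expected cuts, giving exponential fragment spacing with the requested
    mean; fragments tile the genome exactly and are returned in shuffled
    order. Breakpoints falling inside ``avoid`` windows are dropped (the
    neighbouring fragments merge), modelling assemblers that have no reason
    to break at those positions.
    """
    if mean_fragment < 1000:
        raise ValueError("mean fragment must be >= 1 kb")
    rng = _as_rng(seed)
    L = len(genome)
    n_cuts = int(rng.poisson(max(0.0, L / mean_fragment - 1.0)))
    cuts = sorted(set(int(c) for c in rng.integers(1, L, size=n_cuts)))
    cuts = [c for c in cuts if not any(a <= c < b for a, b in avoid)]
    bounds = [0] + cuts + [L]
    frags = [
        (f"{id_prefix}_{i:05d}", genome[bounds[i] : bounds[i + 1]])
        for i in range(len(bounds) - 1)
    ]
    rng.shuffle(frags)
    return frags


# ---------------------------------------------------------------------------
# Study-scale bundle
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Conditions of the emulated study.

    Defaults follow the system the pipeline targets: a ~36% GC host sequenced
    to ~47x and a ~35% GC intracellular symbiont at much higher depth (120x
    here), with a handful of 0.5-20 kb symbiont-derived insertions in host
    scaffolds and one depth-step chimera artifact.
    """

    seed: int
    host_length: int = 1_000_000
    host_gc: float = 0.36
    symbiont_length: int = 300_000
    symbiont_gc: float = 0.3513
    host_depth: float = 47.37
    symbiont_depth: float = 120.0
    n_insertions: int = 3
    insertion_length_range: tuple[int, int] = (500, 20_000)
    strain_divergence: float = 0.03
    n_strains: int = 1
    chimera_count: int = 1
    read_length: int = 100
    # layout knobs
    n_host_scaffolds: int = 4
    n_symbiont_scaffolds: int = 6
    transposase_near_inserts: bool = True
    error_rate: float = 0.0
    n_alt_assemblies: int = 1
    alt_mean_fragment: int = 50_000
    chimera_host_len: int = 30_000
    chimera_symbiont_len: int = 20_000
    edge_margin: int = 3_000
    gene_spacing: int = 5_000

    def __post_init__(self) -> None:
        if self.host_length <= 0 or self.symbiont_length <= 0:
            raise ValueError("genome lengths must be positive")
        for gc in (self.host_gc, self.symbiont_gc):
            if not 0.0 < gc < 1.0:
                raise ValueError(f"gc out of (0, 1): {gc}")
        if self.host_depth <= 0 or self.symbiont_depth <= 0:
            raise ValueError("depths must be positive")
        if self.insertion_length_range[0] < 100:
            raise ValueError("minimum insertion length is 100 bp")
        if not 0.0 <= self.strain_divergence < 0.2:
            raise ValueError("strain divergence must lie in [0, 0.2)")
        if self.n_strains < 1:
            raise ValueError("n_strains must be >= 1")


@dataclass
class TruthTable:
    """Ground truth for one simulated study."""

    insertions: list[PlantedInsertion]
    chimera_junctions: list[tuple[str, int]]
    strain_variant_sites: list[tuple[str, int]]


@dataclass
class StudyBundle:
    """Everything the pipeline consumes, plus the truth that produced it."""

    config: SimulationConfig
    scaffolds: dict[str, str]                 #: the assembly under test
    tracks: dict[str, DepthTrack]
    host_scaffold_ids: list[str]
    symbiont_scaffold_ids: list[str]
    chimera_scaffold_ids: list[str]
    host_ref: list[tuple[str, str]]           #: insertion-free host reference
    symbiont_ref: list[tuple[str, str]]
    alt_assemblies: list[list[tuple[str, str]]]
    features: list[FeatureRecord]
    fpkm: dict[str, float]
    variant_sites: list[VariantSite]
    truth: TruthTable

    def write(self, outdir: str | Path, *, fastq: bool = False) -> dict[str, str]:
        """Write the bundle to ``outdir``; returns {filename: sha256} manifest."""
        import hashlib
        import json

        from . import io as hio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        hio.write_fasta(self.scaffolds.items(), outdir / "assembly.fasta")
        hio.write_depth_tsv(self.tracks.values(), outdir / "depth.tsv")
        hio.write_fasta(self.host_ref, outdir / "host_ref.fasta")
        hio.write_fasta(self.symbiont_ref, outdir / "symbiont_ref.fasta")
        for a, alt in enumerate(self.alt_assemblies):
            hio.write_fasta(alt, outdir / f"alt_assembly_{a}.fasta")
        hio.write_gff(self.features, outdir / "features.gff3")
        hio.write_fpkm_tsv(self.fpkm, outdir / "fpkm.tsv")
        hio.write_bed(
            [(ins.site, f"insertion_{i}") for i, ins in enumerate(self.truth.insertions)],
            outdir / "truth_insertions.bed",
        )
        with open(outdir / "truth_chimeras.tsv", "w") as fh:
            fh.write("#scaffold\tjunction\n")
            for sid, pos in self.truth.chimera_junctions:
                fh.write(f"{sid}\t{pos}\n")
        hio.write_variants_tsv(self.variant_sites, outdir / "variants.tsv")
        if fastq:
            sim = simulate_reads(
                [(sid, seq, self.config.host_depth) for sid, seq in
                 ((i, self.scaffolds[i]) for i in self.host_scaffold_ids)],
                self.config.read_length,
                self.config.seed,
            )
            sim.to_fastq(outdir / "reads.fastq", self.config.error_rate,
                         self.config.seed)
        manifest = {}
        for f in sorted(p for p in outdir.iterdir() if p.name != "manifest.json"):
            manifest[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest


def _split_even(seq: str, n: int, prefix: str) -> list[tuple[str, str]]:
    bounds = np.linspace(0, len(seq), n + 1).astype(int)
    return [
        (f"{prefix}_{i + 1}", seq[bounds[i] : bounds[i + 1]]) for i in range(n)
    ]


def _reads_overlapping(starts: np.ndarray, pos: int, read_length: int) -> int:
    lo = np.searchsorted(starts, pos - read_length + 1, side="left")
    hi = np.searchsorted(starts, pos, side="right")
    return int(hi - lo)


def simulate_study(config: SimulationConfig) -> StudyBundle:
    """Generate a full study: assembly, depth, references, truth.

    Host scaffolds carry the planted insertions (the last host scaffold is
    always left insertion-free as a negative control); symbiont scaffolds are
    pure symbiont at symbiont depth; chimera scaffolds join host and symbiont
    fragments with a depth step at the junction. Alternative assemblies are
    shreds of the true (post-insertion) scaffolds whose breakpoints avoid the
    truth junctions, so every junction is spanned by some alternative contig.
    """
    rng = np.random.default_rng(config.seed)

    host = generate_genome(config.host_length, config.host_gc, rng)
    symbiont = generate_genome(config.symbiont_length, config.symbiont_gc, rng)

    host_ref = _split_even(host, config.n_host_scaffolds, "host")
    symbiont_ref = _split_even(symbiont, config.n_symbiont_scaffolds, "wsym")

    # distribute insertions round-robin over all host scaffolds but the last
    targets = max(1, config.n_host_scaffolds - 1)
    per_scaffold = [0] * config.n_host_scaffolds
    for i in range(config.n_insertions):
        per_scaffold[i % targets] += 1

    # sources drawn within single symbiont reference scaffolds (the donor is
    # one molecule; a fragment has no reason to straddle a reference split)
    sym_piece_bounds = np.linspace(
        0, len(symbiont), config.n_symbiont_scaffolds + 1
    ).astype(int)
    source_windows = [
        (int(sym_piece_bounds[i]), int(sym_piece_bounds[i + 1]))
        for i in range(config.n_symbiont_scaffolds)
    ]

    scaffolds: dict[str, str] = {}
    insertions: list[PlantedInsertion] = []
    source_used: list[tuple[int, int]] = []
    for (sid, seq), k in zip(host_ref, per_scaffold):
        if k == 0:
            scaffolds[sid] = seq
            continue
        mod, ins = plant_insertions(
            seq,
            symbiont,
            k,
            config.insertion_length_range,
            rng,
            scaffold_id=sid,
            source_id="symbiont",
            edge_margin=config.edge_margin,
            min_separation=2 * config.insertion_length_range[0] + 2000,
            source_exclude=source_used,
            source_windows=source_windows,
        )
        scaffolds[sid] = mod
        insertions.extend(ins)
    host_ids = [sid for sid, _ in host_ref]

    # symbiont strains: pooled reads over variant genomes at equal proportions
    strain_variants: list[tuple[str, np.ndarray]] = [(symbiont, np.empty(0, int))]
    for _ in range(config.n_strains - 1):
        strain_variants.append(derive_strain(symbiont, config.strain_divergence, rng))

    sym_ids = [sid for sid, _ in symbiont_ref]
    for sid, seq in symbiont_ref:
        scaffolds[sid] = seq

    # reads: host scaffolds at host depth; symbiont scaffolds pooled over strains
    tracks: dict[str, DepthTrack] = {}
    host_sim = simulate_reads(
        [(sid, scaffolds[sid], config.host_depth) for sid in host_ids],
        config.read_length,
        rng,
    )
    tracks.update(host_sim.tracks)

    sym_bounds = np.linspace(0, len(symbiont), config.n_symbiont_scaffolds + 1).astype(int)
    strain_starts: list[dict[str, np.ndarray]] = []
    per_strain_depth = config.symbiont_depth / config.n_strains
    for s, (sseq, _pos) in enumerate(strain_variants):
        pieces = [
            (sid, sseq[sym_bounds[i] : sym_bounds[i + 1]], per_strain_depth)
            for i, sid in enumerate(sym_ids)
        ]
        sim = simulate_reads(pieces, config.read_length, rng)
        strain_starts.append(sim.placements)
        for sid in sym_ids:
            if sid in tracks:
                tracks[sid] = DepthTrack(
                    sid, tracks[sid].values + sim.tracks[sid].values
                )
            else:
                tracks[sid] = sim.tracks[sid]

    # variant site table from pooled read support at planted strain differences
    variant_sites: list[VariantSite] = []
    strain_variant_positions: list[tuple[str, int]] = []
    if config.n_strains > 1:
        all_positions = np.unique(
            np.concatenate([pos for _seq, pos in strain_variants[1:]])
        )
        for p in all_positions:
            i = int(np.searchsorted(sym_bounds, p, side="right") - 1)
            sid = sym_ids[i]
            local = int(p - sym_bounds[i])
            if local >= len(scaffolds[sid]):
                continue
            # support: reads of strains carrying a variant here vs the rest
            carriers = [
                t
                for t in range(1, config.n_strains)
                if np.isin(p, strain_variants[t][1], assume_unique=True)
            ]
            alt = sum(
                _reads_overlapping(strain_starts[t][sid], local, config.read_length)
                for t in carriers
            )
            ref = sum(
                _reads_overlapping(strain_starts[t][sid], local, config.read_length)
                for t in range(config.n_strains)
                if t not in carriers
            )
            if alt == 0:
                continue
            variant_sites.append(
                VariantSite(
                    scaffold_id=sid,
                    position=local,
                    ref_base=symbiont[p],
                    alt_base=strain_variants[carriers[0]][0][p],
                    ref_count=ref,
                    alt_count=alt,
                )
            )
            strain_variant_positions.append((sid, local))

    # chimera scaffolds: host fragment + symbiont fragment, depth step at join
    chimera_ids: list[str] = []
    chimera_junctions: list[tuple[str, int]] = []
    free_host = host_ids[-1]
    for c in range(config.chimera_count):
        hseq = scaffolds[free_host]
        h0 = int(rng.integers(0, len(hseq) - config.chimera_host_len))
        s0 = int(rng.integers(0, len(symbiont) - config.chimera_symbiont_len))
        cid = f"chimera_{c + 1}"
        seq, track, junction = make_chimera(
            hseq[h0 : h0 + config.chimera_host_len],
            symbiont[s0 : s0 + config.chimera_symbiont_len],
            config.host_depth,
            config.symbiont_depth,
            config.read_length,
            rng,
            scaffold_id=cid,
        )
        scaffolds[cid] = seq
        tracks[cid] = track
        chimera_ids.append(cid)
        chimera_junctions.append((cid, junction))

    # annotations: transposases near insertion ends, genes inside insertions
    features: list[FeatureRecord] = []
    fpkm: dict[str, float] = {}
    for i, ins in enumerate(insertions):
        sid = ins.site.scaffold_id
        slen = len(scaffolds[sid])
        if config.transposase_near_inserts:
            off = int(rng.integers(0, 1500))
            t0 = ins.site.end + off
            if t0 + 300 > slen:
                t0 = max(0, ins.site.start - off - 300)
            features.append(
                FeatureRecord(
                    sid,
                    GenomicInterval(sid, t0, t0 + 300),
                    "transposase",
                    f"tnp_{i}",
                )
            )
        n_genes = ins.length // config.gene_spacing
        for j in range(n_genes):
            g0 = ins.site.start + 200 + j * config.gene_spacing
            g1 = min(g0 + 600, ins.site.end - 1)
            if g1 - g0 < 100:
                continue
            gid = f"hgt_gene_{i}_{j}"
            features.append(
                FeatureRecord(sid, GenomicInterval(sid, g0, g1), "gene", gid, "+")
            )
            if j % 4 == 0:
                fpkm[gid] = float(np.round(rng.uniform(0.04, 1.6), 2))

    # alternative assemblies: shreds of the true scaffolds avoiding junctions
    avoid_by_scaffold: dict[str, list[tuple[int, int]]] = {}
    for ins in insertions:
        avoid_by_scaffold.setdefault(ins.site.scaffold_id, []).extend(
            [(ins.site.start - 1500, ins.site.start + 1500),
             (ins.site.end - 1500, ins.site.end + 1500)]
        )
    alt_assemblies: list[list[tuple[str, str]]] = []
    for a in range(config.n_alt_assemblies):
        contigs: list[tuple[str, str]] = []
        for sid in host_ids + sym_ids:
            contigs.extend(
                shred_assembly(
                    scaffolds[sid],
                    min(config.alt_mean_fragment, max(1000, len(scaffolds[sid]))),
                    rng,
                    avoid=avoid_by_scaffold.get(sid, ()),
                    id_prefix=f"alt{a}_{sid}",
                )
            )
        rng.shuffle(contigs)
        alt_assemblies.append(contigs)

    return StudyBundle(
        config=config,
        scaffolds=scaffolds,
        tracks=tracks,
        host_scaffold_ids=host_ids,
        symbiont_scaffold_ids=sym_ids,
        chimera_scaffold_ids=chimera_ids,
        host_ref=host_ref,
        symbiont_ref=symbiont_ref,
        alt_assemblies=alt_assemblies,
        features=features,
        fpkm=fpkm,
        variant_sites=variant_sites,
        truth=TruthTable(insertions, chimera_junctions, strain_variant_positions),
    )


# ---------------------------------------------------------------------------
# Strain-evidence bundle
# ---------------------------------------------------------------------------

MARKER_GENES = ("ftsZ", "hcpA", "gatB", "cifA", "cifB")


@dataclass
class StrainSimConfig:
    """Conditions for the multi-strain symbiont assembly simulation."""

    seed: int
    genome_length: int = 60_000
    gc: float = 0.3513
    n_genes: int = 40
    gene_length: int = 900
    marker_length: int = 450
    divergence: float = 0.03
    n_strains: int = 2
    depth: float = 120.0
    p_split: float = 0.3

    def __post_init__(self) -> None:
        needed = self.n_genes * (self.gene_length + 500) + len(MARKER_GENES) * (
            self.marker_length + 350
        )
        if self.genome_length < needed:
            raise ValueError(
                f"genome too short for layout: need >= {needed} bp"
            )
        if not 0.0 <= self.divergence < 0.2:
            raise ValueError("divergence must lie in [0, 0.2)")


@dataclass
class StrainBundle:
    """Inputs for the strain-evidence module plus the planted truth.

    The 'assembly' is emulated at the bookkeeping level: for each single-copy
    gene the co-infecting strain's copy either assembled as a separate locus
    (probability ``p_split`` -> a duplicated gene) or collapsed onto the
    primary locus (-> within-sample polymorphism at the planted variant
    sites). Markers always split when more than one strain is present.
    """

    config: StrainSimConfig
    placements: list[TabularHit]              #: gene -> assembly loci
    gene_lengths: dict[str, int]
    gene_features: list[FeatureRecord]        #: gene intervals on the assembly
    marker_scaffolds: dict[str, list[str]]
    variant_sites: list[VariantSite]
    truth_duplicated: set[str]
    truth_site_counts: dict[str, int]         #: planted variant sites per collapsed gene
    single_copy_genes: list[str]


def simulate_strain_study(config: StrainSimConfig) -> StrainBundle:
    rng = np.random.default_rng(config.seed)
    genome = generate_genome(config.genome_length, config.gc, rng)

    # gene layout: evenly spaced single-copy genes, markers in the tail
    gene_ids = [f"scg_{i:03d}" for i in range(config.n_genes)]
    spacing = config.gene_length + 500
    gene_iv = {
        g: (100 + i * spacing, 100 + i * spacing + config.gene_length)
        for i, g in enumerate(gene_ids)
    }
    tail = 100 + config.n_genes * spacing
    marker_iv = {}
    for i, m in enumerate(MARKER_GENES):
        m0 = tail + i * (config.marker_length + 350)
        marker_iv[m] = (m0, m0 + config.marker_length)

    multi = config.n_strains > 1
    strains = [(genome, np.empty(0, dtype=int))]
    for _ in range(config.n_strains - 1):
        strains.append(derive_strain(genome, config.divergence, rng))

    primary = "wasm_1"
    placements: list[TabularHit] = []
    variant_sites: list[VariantSite] = []
    truth_duplicated: set[str] = set()
    truth_site_counts: dict[str, int] = {}
    gene_features: list[FeatureRecord] = []
    gene_lengths = {g: config.gene_length for g in gene_ids}

    def _identity(a: str, b: str) -> float:
        arr_a = np.frombuffer(a.encode(), np.uint8)
        arr_b = np.frombuffer(b.encode(), np.uint8)
        return float((arr_a == arr_b).mean() * 100.0)

    for g in gene_ids:
        g0, g1 = gene_iv[g]
        glen = g1 - g0
        gene_features.append(
            FeatureRecord(primary, GenomicInterval(primary, g0, g1), "gene", g, "+")
        )
        placements.append(
            TabularHit(
                query_id=g,
                subject_id=primary,
                taxon_bin="symbiont",
                percent_identity=100.0,
                query_interval=GenomicInterval(g, 0, glen),
                subject_interval=GenomicInterval(primary, g0, g1),
                bitscore=2.0 * glen,
            )
        )
        split = multi and bool(rng.random() < config.p_split)
        if split:
            truth_duplicated.add(g)
            dup_sid = f"wasm_dup_{g}"
            ident = _identity(genome[g0:g1], strains[1][0][g0:g1])
            placements.append(
                TabularHit(
                    query_id=g,
                    subject_id=dup_sid,
                    taxon_bin="symbiont",
                    percent_identity=ident,
                    query_interval=GenomicInterval(g, 0, glen),
                    subject_interval=GenomicInterval(dup_sid, 0, glen),
                    bitscore=2.0 * glen * ident / 100.0,
                )
            )
        elif multi:
            # collapsed: pooled reads show the planted differences as variants
            n_sites = 0
            for s in range(1, config.n_strains):
                vseq, positions = strains[s]
                inside = positions[(positions >= g0) & (positions < g1)]
                for p in inside:
                    total = int(rng.poisson(config.depth))
                    alt = int(rng.binomial(total, 1.0 / config.n_strains))
                    if alt == 0 or alt == total:
                        continue
                    variant_sites.append(
                        VariantSite(
                            scaffold_id=primary,
                            position=int(p),
                            ref_base=genome[p],
                            alt_base=vseq[p],
                            ref_count=total - alt,
                            alt_count=alt,
                        )
                    )
                    n_sites += 1
            truth_site_counts[g] = n_sites

    marker_scaffolds: dict[str, list[str]] = {}
    for m in MARKER_GENES:
        marker_scaffolds[m] = [primary]
        if multi:
            marker_scaffolds[m].append(f"wasm_dup_{m}")

    return StrainBundle(
        config=config,
        placements=placements,
        gene_lengths=gene_lengths,
        gene_features=gene_features,
        marker_scaffolds=marker_scaffolds,
        variant_sites=variant_sites,
        truth_duplicated=truth_duplicated,
        truth_site_counts=truth_site_counts,
        single_copy_genes=gene_ids,
    )
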