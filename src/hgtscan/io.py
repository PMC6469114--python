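"""Readers and writers for the external formats the pipeline touches.

Every coordinate dialect is converted to the internal 0-based half-open
convention here, and nowhere else:

========================  =========================  =========================
format                    external convention        conversion on read
========================  =========================  =========================
BLAST tabular (12 col)    1-based inclusive,         start-1; reversed subject
                          subject may be reversed    coordinates normalised,
                                                     strand recorded
GFF3                      1-based inclusive          start-1
BED                       0-based half-open          none
depth TSV                 1-based positions          pos-1
printed interval strings  length = end - start       kept verbatim (see
                          (see parse_printed_        parse_printed_interval)
                          interval)
========================  =========================  =========================
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import (
    DepthTrack,
    FeatureRecord,
    GenomicInterval,
    TabularHit,
    VariantSite,
)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_tabular_hits",
    "write_tabular_hits",
    "parse_printed_interval",
    "read_bed",
    "write_bed",
    "read_depth_tsv",
    "write_depth_tsv",
    "read_gff",
    "write_gff",
    "read_fpkm_tsv",
    "write_fpkm_tsv",
    "read_variants_tsv",
    "write_variants_tsv",
]


class ParseError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(record_id, sequence), ...]`` in file order.

    Sequences are upper-cased; IUPAC ambiguity codes are preserved. Empty
    records are rejected.
    """
    records: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ParseError(f"{path}: FASTA record with empty header")
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append((rec.id, seq))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


# ---------------------------------------------------------------------------
# BLAST-style tabular hits
# ---------------------------------------------------------------------------

#: column order of the 12-column tabular dialect
TABULAR_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


def read_tabular_hits(
    path: str | Path, taxon_map: Mapping[str, str]
) -> list[TabularHit]:
    """Read 12-column tabular hits, binning subjects via ``taxon_map``.

    Subjects absent from ``taxon_map`` are binned ``"other"``. Reversed
    subject coordinates (sstart > send) are normalised to forward intervals
    with strand ``"-"``.
    """
    hits: list[TabularHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(
                    f"{path}:{lineno}: expected >=12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                pident = float(fields[2])
                qstart, qend = int(fields[6]), int(fields[7])
                sstart, send = int(fields[8]), int(fields[9])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric field: {exc}") from exc
            if qstart > qend:
                raise ParseError(
                    f"{path}:{lineno}: reversed query coordinates {qstart}..{qend}"
                )
            strand = "+"
            if sstart > send:
                sstart, send = send, sstart
                strand = "-"
            hits.append(
                TabularHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    taxon_bin=taxon_map.get(fields[1], "other"),
                    percent_identity=pident,
                    query_interval=GenomicInterval(fields[0], qstart - 1, qend),
                    subject_interval=GenomicInterval(fields[1], sstart - 1, send),
                    bitscore=bitscore,
                    strand=strand,
                )
            )
    return hits


def write_tabular_hits(hits: Iterable[TabularHit], path: str | Path) -> None:
    """Write hits back to the 12-column dialect (1-based inclusive; minus-strand
    hits get reversed subject coordinates)."""
    with open(path, "w") as fh:
        for h in hits:
            qi, si = h.query_interval, h.subject_interval
            sstart, send = si.start + 1, si.end
            if h.strand == "-":
                sstart, send = send, sstart
            row = [
                h.query_id,
                h.subject_id,
                f"{h.percent_identity:.2f}",
                str(qi.length),
                "0",
                "0",
                str(qi.start + 1),
                str(qi.end),
                str(sstart),
                str(send),
                "0.0",
                f"{h.bitscore:.1f}",
            ]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Printed interval strings
# ---------------------------------------------------------------------------

_PRINTED_RE = re.compile(
    r"^\s*(?P<id>\S+)\s*:\s*(?P<start>[\d,]+)\s*[–—-]\s*(?P<end>[\d,]+)\s*$"
)


def parse_printed_interval(text: str) -> GenomicInterval:
    """Parse an interval printed as ``"<scaffold>: <start>–<end>"``.

    Accepts en-dash, em-dash or hyphen separators and optional thousands
    separators. Published reports of this form state lengths equal to
    ``end - start``, so the printed numbers are kept verbatim as the internal
    half-open bounds (no ``start - 1`` shift, unlike BLAST/GFF input). Whether
    the printed start is itself 0- or 1-based cannot be recovered from length
    arithmetic alone; only the length convention is fixed here.
    """
    m = _PRINTED_RE.match(text)
    if not m:
        raise ParseError(f"unparseable printed interval: {text!r}")
    start = int(m.group("start").replace(",", ""))
    end = int(m.group("end").replace(",", ""))
    if end <= start:
        raise ValueError(f"printed interval has end <= start: {text!r}")
    return GenomicInterval(m.group("id"), start, end)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_bed(
    intervals: Sequence[tuple[GenomicInterval, str]], path: str | Path
) -> None:
    """Write named intervals as BED4 (0-based half-open), sorted by scaffold
    then start. An empty call set yields a file holding only a header comment."""
    rows = sorted(intervals, key=lambda x: (x[0].scaffold_id, x[0].start, x[0].end))
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\n")
        for iv, name in rows:
            fh.write(f"{iv.scaffold_id}\t{iv.start}\t{iv.end}\t{name}\n")


def read_bed(path: str | Path) -> list[tuple[GenomicInterval, str]]:
    out: list[tuple[GenomicInterval, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: BED row with <3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric coordinate") from exc
            name = fields[3] if len(fields) > 3 else ""
            out.append((GenomicInterval(fields[0], start, end), name))
    return out


# ---------------------------------------------------------------------------
# Depth TSV  (scaffold <tab> 1-based position <tab> depth)
# ---------------------------------------------------------------------------

def read_depth_tsv(
    path: str | Path, scaffold_lengths: Mapping[str, int]
) -> dict[str, DepthTrack]:
    """Read per-base depth rows into one :class:`DepthTrack` per scaffold.

    Every scaffold in ``scaffold_lengths`` must be fully covered by rows
    (positions 1..length); shorter tracks are an error naming the scaffold.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=["scaffold", "pos", "depth"]
    )
    if len(df) and (df["depth"] < 0).any():
        bad = df[df["depth"] < 0].iloc[0]
        raise ValueError(f"negative depth at {bad['scaffold']}:{bad['pos']}")
    tracks: dict[str, DepthTrack] = {}
    grouped = dict(tuple(df.groupby("scaffold", sort=False)))
    for scaffold, length in scaffold_lengths.items():
        if scaffold not in grouped:
            raise ParseError(f"depth file {path} has no rows for scaffold {scaffold}")
        sub = grouped[scaffold]
        values = np.zeros(length, dtype=np.float64)
        pos = sub["pos"].to_numpy(dtype=np.int64) - 1
        if pos.min() < 0 or pos.max() >= length:
            raise ParseError(
                f"depth position out of range for scaffold {scaffold} "
                f"(length {length})"
            )
        seen = np.zeros(length, dtype=bool)
        seen[pos] = True
        if not seen.all():
            raise ParseError(
                f"depth file {path} shorter than scaffold {scaffold}: "
                f"{int(seen.sum())} of {length} positions present"
            )
        values[pos] = sub["depth"].to_numpy(dtype=np.float64)
        tracks[scaffold] = DepthTrack(scaffold, values)
    return tracks


def write_depth_tsv(tracks: Iterable[DepthTrack], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#scaffold\tpos\tdepth\n")
        for track in tracks:
            sid = track.scaffold_id
            for i, v in enumerate(track.values, start=1):
                fh.write(f"{sid}\t{i}\t{v:g}\n")


# ---------------------------------------------------------------------------
# GFF3  (gene / transposase / marker features only)
# ---------------------------------------------------------------------------

_GFF_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]
_ID_RE = re.compile(r"(?:^|;)\s*ID=([^;]+)")


def read_gff(path: str | Path) -> list[FeatureRecord]:
    """Read gene/transposase/marker rows from a GFF3 file (1-based inclusive
    converted to internal half-open). Rows of other feature types are ignored."""
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            names=_GFF_COLUMNS,
            dtype=str,
        )
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: malformed GFF3: {exc}") from exc
    incomplete = df[["start", "end", "attributes"]].isna().any(axis=1)
    if incomplete.any():
        raise ParseError(
            f"{path}: row {int(incomplete.idxmax()) + 1}: fewer than 9 columns"
        )
    features: list[FeatureRecord] = []
    for i, row in df.iterrows():
        ftype = row["type"]
        if ftype not in ("gene", "transposase", "marker"):
            continue
        try:
            start, end = int(row["start"]), int(row["end"])
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: row {i + 1}: non-numeric coordinate") from exc
        m = _ID_RE.search(row["attributes"] or "")
        fid = m.group(1) if m else f"{ftype}_{i + 1}"
        strand = row["strand"] if row["strand"] in ("+", "-") else "."
        features.append(
            FeatureRecord(
                scaffold_id=row["seqid"],
                interval=GenomicInterval(row["seqid"], start - 1, end),
                feature_type=ftype,
                feature_id=fid,
                strand=strand,
            )
        )
    return features


def write_gff(features: Iterable[FeatureRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                "\t".join(
                    [
                        f.scaffold_id,
                        "hgtscan",
                        f.feature_type,
                        str(f.interval.start + 1),
                        str(f.interval.end),
                        ".",
                        f.strand,
                        ".",
                        f"ID={f.feature_id}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# FPKM TSV  (gene_id <tab> fpkm)
# ---------------------------------------------------------------------------

def read_fpkm_tsv(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=["gene", "fpkm"]
    )
    if len(df) and (df["fpkm"] < 0).any():
        bad = df[df["fpkm"] < 0].iloc[0]
        raise ValueError(f"negative FPKM for gene {bad['gene']}")
    return dict(zip(df["gene"].astype(str), df["fpkm"].astype(float)))


def write_fpkm_tsv(fpkm: Mapping[str, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene, value in fpkm.items():
            fh.write(f"{gene}\t{value:g}\n")


# ---------------------------------------------------------------------------
# Variant site TSV  (scaffold, 1-based pos, ref, alt, ref_count, alt_count)
# ---------------------------------------------------------------------------

def read_variants_tsv(path: str | Path) -> list[VariantSite]:
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["scaffold", "pos", "ref", "alt", "ref_count", "alt_count"],
    )
    return [
        VariantSite(
            scaffold_id=str(r.scaffold),
            position=int(r.pos) - 1,
            ref_base=str(r.ref),
            alt_base=str(r.alt),
            ref_count=int(r.ref_count),
            alt_count=int(r.alt_count),
        )
        for r in df.itertuples()
    ]


def write_variants_tsv(sites: Iterable[VariantSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#scaffold\tpos\tref\talt\tref_count\talt_count\n")
        for s in sites:
            fh.write(
                f"{s.scaffold_id}\t{s.position + 1}\t{s.ref_base}\t{s.alt_base}\t"
                f"{s.ref_count}\t{s.alt_count}\n"
            )
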