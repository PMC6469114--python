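"""Assembly contiguity and composition statistics.

Nxx/Lxx follow the standard QUAST-style definition: with contigs sorted in
descending length order, Nxx is the length of the first contig at which the
cumulative length reaches xx% of the total, and Lxx is its 1-based rank.
Library yield totals are summed in fixed-point decimal so printed two-decimal
gigabase figures add up exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np

from .tagc import compute_gc

__all__ = ["AssemblyStats", "nxx", "counts_ge", "library_accounting",
           "assembly_stats"]


def nxx(lengths: Sequence[int], x: float) -> tuple[int, int]:
    """(Nxx, Lxx) of a contig length multiset.

    Ties share the qualifying length; Lxx counts through the first qualifying
    contig.
    """
    arr = np.asarray(sorted(lengths, reverse=True), dtype=np.int64)
    if arr.size == 0:
        raise ValueError("empty length set")
    if (arr <= 0).any():
        raise ValueError("contig lengths must be positive")
    if not 0 < x < 100:
        raise ValueError("x must lie strictly between 0 and 100")
    target = x / 100.0 * arr.sum()
    cum = np.cumsum(arr)
    i = int(np.searchsorted(cum, target, side="left"))
    return int(arr[i]), i + 1


def counts_ge(
    lengths: Sequence[int], thresholds: Iterable[int]
) -> dict[int, tuple[int, float]]:
    """Per threshold: contigs at least that long, and the fraction of total
    assembly length they contain."""
    arr = np.asarray(list(lengths), dtype=np.int64)
    total = int(arr.sum())
    out: dict[int, tuple[int, float]] = {}
    for t in thresholds:
        if t <= 0:
            raise ValueError("thresholds must be positive")
        sel = arr[arr >= t]
        out[t] = (int(sel.size), float(sel.sum() / total) if total else 0.0)
    return out


def library_accounting(yields_gb: Iterable[float | str | Decimal]) -> Decimal:
    """Exact decimal sum of per-library yields (gigabases).

    Values are taken at two-decimal fixed point, so printed totals are
    reproduced without binary-float drift.
    """
    total = Decimal("0.00")
    for y in yields_gb:
        d = Decimal(str(y)).quantize(Decimal("0.01"))
        if d < 0:
            raise ValueError(f"negative library yield: {y}")
        total += d
    return total


@dataclass(frozen=True)
class AssemblyStats:
    total_length: int
    n_contigs: int
    n50: int
    n75: int
    l50: int
    l75: int
    gc_percent: float
    counts_ge: dict[int, tuple[int, float]]

    def to_dict(self) -> dict:
        return {
            "total_length": self.total_length,
            "n_contigs": self.n_contigs,
            "n50": self.n50,
            "n75": self.n75,
            "l50": self.l50,
            "l75": self.l75,
            "gc_percent": round(self.gc_percent, 2),
            "counts_ge": {
                str(t): {"count": c, "genome_fraction": round(f, 4)}
                for t, (c, f) in self.counts_ge.items()
            },
        }


def assembly_stats(
    contigs: Sequence[tuple[str, str]],
    thresholds: Iterable[int] = (1000, 50_000),
) -> AssemblyStats:
    """Contiguity and GC summary of an assembly given as (id, sequence) pairs."""
    lengths = [len(seq) for _cid, seq in contigs]
    n50_, l50_ = nxx(lengths, 50)
    n75_, l75_ = nxx(lengths, 75)
    total = sum(lengths)
    # length-weighted GC over unambiguous bases
    gc_weighted = sum(compute_gc(seq) * len(seq) for _cid, seq in contigs)
    return AssemblyStats(
        total_length=total,
        n_contigs=len(lengths),
        n50=n50_,
        n75=n75_,
        l50=l50_,
        l75=l75_,
        gc_percent=100.0 * gc_weighted / total,
        counts_ge=counts_ge(lengths, thresholds),
    )
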