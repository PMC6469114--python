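"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths of the package: anchors are found by
direct per-diagonal character comparison (not k-mer hashing), chaining and
merging are plain Python loops, and Nxx is a linear cumulative scan.
"""

from __future__ import annotations

import numpy as np


def brute_force_blocks(
    query: str,
    ref: str,
    k: int = 21,
    max_gap: int = 500,
    min_block: int = 300,
    m_rep: int = 10,
) -> list[tuple[int, int, int, int, int]]:
    """All similarity blocks as (q0, q1, r0, r1, n_anchors) tuples.

    Anchors are exact k-mer matches found by comparing characters along each
    diagonal; reference k-mers occurring more than m_rep times (counted with
    a plain dictionary) anchor nothing.
    """
    nq, nr = len(query), len(ref)
    if nq < k or nr < k:
        return []

    counts: dict[str, int] = {}
    for j in range(nr - k + 1):
        km = ref[j : j + k]
        if set(km) <= set("ACGT"):
            counts[km] = counts.get(km, 0) + 1

    aq = np.frombuffer(query.encode(), np.uint8)
    ar = np.frombuffer(ref.encode(), np.uint8)
    valid_q = np.isin(aq, np.frombuffer(b"ACGT", np.uint8))
    valid_r = np.isin(ar, np.frombuffer(b"ACGT", np.uint8))

    anchors: list[tuple[int, int]] = []  # (qpos, rpos)
    for d in range(-(nr - k), nq - k + 1):
        qlo, qhi = max(0, d), min(nq, nr + d)
        if qhi - qlo < k:
            continue
        eq = (aq[qlo:qhi] == ar[qlo - d : qhi - d]) & valid_q[qlo:qhi] \
            & valid_r[qlo - d : qhi - d]
        edges = np.diff(np.concatenate([[0], eq.astype(np.int8), [0]]))
        for r_start, r_end in zip(
            np.flatnonzero(edges == 1), np.flatnonzero(edges == -1)
        ):
            if r_end - r_start < k:
                continue
            for q in range(qlo + r_start, qlo + r_end - k + 1):
                km = query[q : q + k]
                if counts.get(km, 0) <= m_rep:
                    anchors.append((q, q - d))

    if not anchors:
        return []

    # chain per diagonal with query gap <= max_gap
    anchors.sort(key=lambda a: (a[0] - a[1], a[0]))
    chains: list[list[int]] = []  # [q0, q_last, r0, n]
    for q, r in anchors:
        d = q - r
        if chains and chains[-1][0] - chains[-1][2] == d \
                and q - chains[-1][1] <= max_gap:
            chains[-1][1] = q
            chains[-1][3] += 1
        else:
            chains.append([q, q, r, 1])

    # merge chains into blocks, in query-position order, same predicate as
    # the implementation: both gaps within max_gap (ref may lag by max_gap)
    spans = sorted(
        [(c[0], c[1] + k, c[2], c[2] + (c[1] - c[0]) + k, c[3]) for c in chains],
        key=lambda s: (s[0], s[2]),
    )
    blocks: list[list[int]] = []
    for q0, q1, r0, r1, n in spans:
        if blocks:
            b = blocks[-1]
            if q0 - b[1] <= max_gap and -max_gap <= r0 - b[3] <= max_gap:
                b[1] = max(b[1], q1)
                b[3] = max(b[3], r1)
                b[4] += n
                continue
        blocks.append([q0, q1, r0, r1, n])
    return [tuple(b) for b in blocks if b[1] - b[0] >= min_block]


def brute_force_nxx(lengths: list[int], x: float) -> tuple[int, int]:
    """Nxx/Lxx by explicit cumulative scan over descending lengths."""
    total = sum(lengths)
    cum = 0
    for rank, length in enumerate(sorted(lengths, reverse=True), start=1):
        cum += length
        if cum >= x / 100.0 * total:
            return length, rank
    raise AssertionError("unreachable for 0 < x < 100")


def brute_force_union(intervals: list[tuple[int, int]], min_run: int = 1) -> int:
    """Union coverage by per-base marking."""
    if not intervals:
        return 0
    hi = max(e for _s, e in intervals)
    covered = np.zeros(hi, dtype=bool)
    for s, e in intervals:
        covered[s:e] = True
    total = 0
    run = 0
    for c in list(covered) + [False]:
        if c:
            run += 1
        else:
            if run >= min_run:
                total += run
            run = 0
    return total
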