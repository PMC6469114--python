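"""Static taxon-annotated GC-coverage (blob) scatter."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .tagc import ScaffoldClassification, ScaffoldRecord

_COLORS = {
    "host": "tab:blue",
    "symbiont": "tab:red",
    "hgt_candidate": "tab:orange",
    "unassigned": "0.6",
}


def tagc_plot(
    records: Sequence[ScaffoldRecord],
    classifications: Sequence[ScaffoldClassification] | None = None,
    path: str | None = None,
):
    """Scatter scaffolds by GC fraction and log depth, coloured by label.

    Marker area scales with scaffold length. Returns the figure; saves to
    ``path`` when given.
    """
    import matplotlib.pyplot as plt

    labels: Mapping[str, str] = {}
    if classifications is not None:
        labels = {c.scaffold_id: c.label for c in classifications}
    fig, ax = plt.subplots(figsize=(6, 4.5))
    max_len = max(r.length for r in records)
    for label in _COLORS:
        rs = [r for r in records if labels.get(r.scaffold_id, "unassigned") == label]
        if not rs:
            continue
        ax.scatter(
            [r.gc_fraction for r in rs],
            [r.mean_depth + 0.5 for r in rs],
            s=[20 + 180 * r.length / max_len for r in rs],
            c=_COLORS[label],
            alpha=0.7,
            label=label,
            edgecolors="none",
        )
    ax.set_yscale("log")
    ax.set_xlabel("GC fraction")
    ax.set_ylabel("mean read depth (x)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
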