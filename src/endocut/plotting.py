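"""Minimal Venn-diagram rendering for 2-3 gene lists."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import Circle

from .codons import VennResult

# circle centres for the classic 2- and 3-set layouts
_LAYOUTS = {
    2: [(-0.35, 0.0), (0.35, 0.0)],
    3: [(-0.35, -0.2), (0.35, -0.2), (0.0, 0.4)],
}
# region label positions keyed by which sets contain the region
_LABELS = {
    2: {(0,): (-0.65, 0.0), (1,): (0.65, 0.0), (0, 1): (0.0, 0.0)},
    3: {
        (0,): (-0.65, -0.3),
        (1,): (0.65, -0.3),
        (2,): (0.0, 0.75),
        (0, 1): (0.0, -0.3),
        (0, 2): (-0.35, 0.2),
        (1, 2): (0.35, 0.2),
        (0, 1, 2): (0.0, 0.0),
    },
}


def plot_venn(result: VennResult, path: str | Path, title: str | None = None) -> None:
    """Draw counts of the exclusive Venn regions of 2 or 3 lists."""
    names = result.list_names
    n = len(names)
    if n not in (2, 3):
        raise ValueError("figure rendering supports 2 or 3 lists")
    fig, ax = plt.subplots(figsize=(5, 5))
    colors = ["tab:blue", "tab:orange", "tab:green"]
    for (x, y), name, color in zip(_LAYOUTS[n], names, colors):
        ax.add_patch(Circle((x, y), 0.55, alpha=0.3, color=color))
        ax.annotate(name, (x, y + 0.6), ha="center", fontsize=10)
    for idx_combo, (x, y) in _LABELS[n].items():
        sig = frozenset(names[i] for i in idx_combo)
        ax.annotate(str(result.region_counts.get(sig, 0)), (x, y), ha="center")
    ax.set_xlim(-1.2, 1.2)
    ax.set_ylim(-1.2, 1.3)
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
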