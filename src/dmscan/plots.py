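"""Sequence-function map rendering.

The map is a grid of amino acid (row) x protein position (column) cells.
Cell color encodes the combined score, diverging around 0 (red above
wild-type, blue below).  A diagonal line in each cell encodes the standard
error, scaled so the largest SE on the plot spans the full cell diagonal;
SEs below 2% of that maximum are not drawn.  Cells holding the wild-type
amino acid are marked with a circle; substitutions never measured are gray.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Optional, Union

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.collections import LineCollection
from matplotlib.colors import TwoSlopeNorm

from .refseq import ReferenceSequence, _aa3

AA_ORDER = list("ACDEFGHIKLMNPQRSTVWY*")

_AA3_TO_1 = {_aa3(aa): aa for aa in AA_ORDER}
_PROTEIN_RE = re.compile(r"^p\.([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})$")

MIN_SE_FRACTION = 0.02  # SEs below 2% of the max are not plotted


def parse_protein_label(label: str):
    """Parse a single-substitution protein label like ``p.Ile117Ter``.

    Returns (wt_aa, position, variant_aa) one-letter codes, or None for
    anything else (wild-type, multi-substitution, nucleotide-only labels).
    """
    m = _PROTEIN_RE.match(label.strip())
    if not m:
        return None
    wt3, pos, var3 = m.groups()
    if wt3 not in _AA3_TO_1 or var3 not in _AA3_TO_1:
        return None
    return _AA3_TO_1[wt3], int(pos), _AA3_TO_1[var3]


def render_sequence_function_map(
    scores: pd.DataFrame,
    ref: ReferenceSequence,
    path: Union[str, Path],
    title: Optional[str] = None,
) -> None:
    """Render combined scores for single amino-acid substitutions to a file.

    ``scores`` must be indexed by protein-level variant labels and contain
    ``score`` and ``SE`` columns; only single-substitution labels are drawn.
    The output format follows the file extension (SVG or PDF recommended).
    """
    if not ref.is_coding:
        raise ValueError("sequence-function maps require a coding reference")
    protein = ref.protein()
    entries = []
    for label, row in scores.iterrows():
        parsed = parse_protein_label(str(label))
        if parsed is None or not np.isfinite(row["score"]):
            continue
        wt_aa, pos, var_aa = parsed
        if 1 <= pos <= len(protein):
            entries.append((pos, var_aa, float(row["score"]), float(row["SE"])))
    if not entries:
        raise ValueError("no scored single amino-acid substitutions to plot")

    n_pos = len(protein)
    n_aa = len(AA_ORDER)
    score_grid = np.full((n_aa, n_pos), np.nan)
    se_grid = np.full((n_aa, n_pos), np.nan)
    for pos, var_aa, score, se in entries:
        i = AA_ORDER.index(var_aa)
        score_grid[i, pos - 1] = score
        se_grid[i, pos - 1] = se

    vmax = np.nanmax(np.abs(score_grid))
    vmax = vmax if vmax > 0 else 1.0
    norm = TwoSlopeNorm(vcenter=0.0, vmin=-vmax, vmax=vmax)
    cmap = plt.get_cmap("RdBu_r").copy()

    fig, ax = plt.subplots(figsize=(max(4.0, 0.35 * n_pos + 1.5), 0.32 * n_aa + 1.2))
    masked = np.ma.masked_invalid(score_grid)
    cmap.set_bad("0.75")  # unmeasured cells gray
    mesh = ax.pcolormesh(
        masked, cmap=cmap, norm=norm, edgecolors="white", linewidth=0.5
    )

    # standard-error diagonals, scaled to the largest SE on the plot
    max_se = np.nanmax(se_grid)
    segments = []
    if max_se and max_se > 0:
        for i in range(n_aa):
            for j in range(n_pos):
                se = se_grid[i, j]
                if not np.isfinite(se) or se < MIN_SE_FRACTION * max_se:
                    continue
                half = 0.5 * se / max_se
                segments.append(
                    [(j + 0.5 - half, i + 0.5 - half), (j + 0.5 + half, i + 0.5 + half)]
                )
    if segments:
        ax.add_collection(LineCollection(segments, colors="black", linewidths=0.8))

    # wild-type cells marked with a circle
    for j, wt_aa in enumerate(protein):
        if wt_aa in AA_ORDER:
            i = AA_ORDER.index(wt_aa)
            ax.plot(j + 0.5, i + 0.5, "o", mfc="none", mec="black", ms=5)

    ax.set_xticks(np.arange(n_pos) + 0.5)
    ax.set_xticklabels(range(1, n_pos + 1), fontsize=7)
    ax.set_yticks(np.arange(n_aa) + 0.5)
    ax.set_yticklabels(AA_ORDER, fontsize=7)
    ax.set_xlabel("position")
    ax.set_ylabel("amino acid")
    ax.invert_yaxis()
    if title:
        ax.set_title(title)
    fig.colorbar(mesh, ax=ax, label="score", shrink=0.8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
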