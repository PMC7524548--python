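"""Export of label maps (SVG, CSV) and metric series (CSV)."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .hexgrid import HexLattice
from .metrics import LabelMap


def labelmap_to_csv(lm: LabelMap, path) -> None:
    pd.DataFrame({"index": np.arange(len(lm.label)), "label": lm.label}).to_csv(
        path, index=False)


def labelmap_to_svg(lm: LabelMap, lattice: HexLattice, path,
                    scale: float = 200.0) -> None:
    """Coloured hex map with region outlines and labels at region centroids."""
    import matplotlib

    cmap = matplotlib.colormaps["hsv"]
    n = max(lm.n_labels, 1)
    # deterministic, well-separated colour order
    order = (np.arange(n) * 0.6180339887) % 1.0
    # hex corner offsets; corner k sits between neighbour directions k and k+1
    ang = np.pi * (2 * np.arange(6) + 1) / 6.0
    rad = lattice.d / np.sqrt(3.0)
    cx = rad * np.cos(ang)
    cy = rad * np.sin(ang)

    minx, miny = lattice.centres.min(axis=0) - lattice.d
    maxx, maxy = lattice.centres.max(axis=0) + lattice.d

    def sx(x):
        return (x - minx) * scale

    def sy(y):
        return (maxy - y) * scale

    out = [f'<svg xmlns="http://www.w3.org/2000/svg" '
           f'width="{sx(maxx):.0f}" height="{sy(miny):.0f}">']
    for h in range(lattice.n_hex):
        x, y = lattice.centres[h]
        col = matplotlib.colors.to_hex(cmap(order[lm.label[h]]))
        pts = " ".join(f"{sx(x + cx[k]):.1f},{sy(y + cy[k]):.1f}" for k in range(6))
        out.append(f'<polygon points="{pts}" fill="{col}" stroke="{col}" stroke-width="0.5"/>')
    # region borders: shared edges between differently labelled hexes
    for h in range(lattice.n_hex):
        x, y = lattice.centres[h]
        for j in range(6):
            nb = lattice.neighbours[h, j]
            if nb >= 0 and nb > h and lm.label[nb] != lm.label[h]:
                x1, y1 = x + cx[j - 1], y + cy[j - 1]
                x2, y2 = x + cx[j], y + cy[j]
                out.append(f'<line x1="{sx(x1):.1f}" y1="{sy(y1):.1f}" '
                           f'x2="{sx(x2):.1f}" y2="{sy(y2):.1f}" '
                           f'stroke="black" stroke-width="1"/>')
    for i in range(lm.n_labels):
        if np.isfinite(lm.centroids[i]).all() and lm.areas[i] > 0:
            x, y = lm.centroids[i]
            name = lm.labels[i] if lm.labels else str(i)
            out.append(f'<text x="{(x - minx) * scale:.1f}" y="{(maxy - y) * scale:.1f}" '
                       f'font-size="10" text-anchor="middle">{name}</text>')
    out.append("</svg>")
    with open(path, "w") as fh:
        fh.write("\n".join(out))
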