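"""Render the PRA functional diagram (radar chart with risk zones).

The diagram shows concentric low/moderate/high annuli with boundaries at
radii 1.5 and 3.5 — chosen so every integer axis score sits strictly inside
its zone — and the patient's closed score polygon on top. SVG output is
byte-reproducible for fixed input (fixed hash salt, no timestamp metadata),
which lets tests diff renderings directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .coding import AxisScoreVector

__all__ = ["DiagramStyle", "render_diagram", "ZONE_BOUNDARIES"]

#: Radii separating the low/moderate and moderate/high annuli.
ZONE_BOUNDARIES = (1.5, 3.5)

_AXIS_LABELS = {
    "bop": "BOP %",
    "pockets": "PD >5 mm",
    "tooth_loss": "Tooth loss",
    "smoking": "Smoking",
    "al_age": "AL/age",
    "diabetic": "Glycemic",
    "dental_systemic": "Dental-systemic",
    "background": "Background",
}


@dataclass(frozen=True)
class DiagramStyle:
    """Visual parameters of the functional diagram."""

    zone_colors: Tuple[str, str, str] = ("#a8d5a2", "#ffe08a", "#f2a297")
    figure_size: Tuple[float, float] = (6.0, 6.0)
    label_flag: bool = True

    def __post_init__(self):
        if len(self.zone_colors) != 3:
            raise ValueError("zone_colors must give exactly three colors "
                             "(low, moderate, high)")


def render_diagram(vector: AxisScoreVector,
                   style: Optional[DiagramStyle] = None,
                   output_path: str | Path = "diagram.svg") -> Path:
    """Write the radar chart for one score vector to ``output_path``.

    The format follows the file suffix (``.svg`` default, ``.png``
    supported). Axis 0 points up and axes proceed clockwise. Returns the
    written path.
    """
    style = style or DiagramStyle()
    path = Path(output_path)
    n = len(vector)
    # clockwise from the top, matching polygon_vertices
    theta = np.pi / 2 - 2 * np.pi * np.arange(n + 1) / n
    radii = np.array(list(vector.scores) + [vector.scores[0]], dtype=float)

    with matplotlib.rc_context({"svg.hashsalt": "periorisk"}):
        fig, ax = plt.subplots(figsize=style.figure_size,
                               subplot_kw={"projection": "polar"})
        lo, hi = ZONE_BOUNDARIES
        ring = np.linspace(0, 2 * np.pi, 144)
        for inner, outer, color in ((0.0, lo, style.zone_colors[0]),
                                    (lo, hi, style.zone_colors[1]),
                                    (hi, 5.0, style.zone_colors[2])):
            ax.fill_between(ring, inner, outer, color=color, zorder=0)
        for k in range(n):
            ax.plot([theta[k], theta[k]], [0, 5], color="0.45",
                    linewidth=0.8, zorder=1)
        ax.plot(theta, radii, color="#1f3b73", linewidth=2.0, zorder=3)
        ax.fill(theta, radii, color="#1f3b73", alpha=0.25, zorder=2)
        ax.plot(theta[:-1], radii[:-1], "o", color="#1f3b73",
                markersize=4, zorder=4)

        ax.set_ylim(0, 5)
        ax.set_yticks([1, 2, 3, 4, 5])
        ax.set_yticklabels(["1", "2", "3", "4", "5"], fontsize=7)
        ax.set_xticks(theta[:-1])
        if style.label_flag:
            names = vector.axis_names or tuple(f"axis {i}" for i in range(n))
            ax.set_xticklabels([_AXIS_LABELS.get(a, a) for a in names],
                               fontsize=8)
        else:
            ax.set_xticklabels([])
        ax.grid(False)
        ax.spines["polar"].set_visible(False)

        if path.suffix.lower() == ".svg":
            fig.savefig(path, format="svg", metadata={"Date": None})
        else:
            fig.savefig(path)
        plt.close(fig)
    return path
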