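"""Optional plotting helpers (requires matplotlib).

Quick visual checks: the MISC cost lines over the interval, and the
MISC+REJ region partition of the triangle.  Styling is intentionally plain.
"""

from __future__ import annotations

from typing import Sequence

from .cost_models import PredictorProfile, misc_line_coefficients
from .triangle import RegionPartition


def plot_misc_lines(profiles: Sequence[PredictorProfile], rho, ax=None):
    """Cost lines rc(rc1) for each predictor over the clinical interval."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for p in profiles:
        slope, intercept = misc_line_coefficients(p, rho)
        ax.plot([0, 1], [float(intercept), float(slope + intercept)], label=p.name)
    ax.set_xlabel("rc1")
    ax.set_ylabel("normalised cost rc")
    ax.legend(fontsize="small")
    return ax


def plot_triangle_partition(partition: RegionPartition, ax=None):
    """Filled polygons of a MISC+REJ region partition, one colour per region."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    cmap = plt.get_cmap("tab20")
    for k, region in enumerate(partition.regions):
        color = cmap(k % 20)
        for i, poly in enumerate(region.polygons):
            xs, ys = zip(*poly.as_float_vertices())
            ax.fill(xs, ys, color=color,
                    label=region.predictor if i == 0 else None)
    ax.plot([0, 1, 0, 0], [0, 0, 1, 0], color="black", lw=1)
    ax.set_xlabel("rc0")
    ax.set_ylabel("rc1")
    ax.set_aspect("equal")
    ax.legend(fontsize="small")
    return ax
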