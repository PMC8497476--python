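"""Phase-diagram rendering (design maps of success/failure regions)."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .pressures import OutcomeClass, boundary_polyline

_COLORS = {
    OutcomeClass.SUCCESS_CONTINUOUS.value: "#2ca25f",
    OutcomeClass.SUCCESS_STEPWISE.value: "#99d8c9",
    OutcomeClass.FAIL_LR_BEFORE_PORT.value: "#de2d26",
    OutcomeClass.FAIL_LR_AFTER_PORT.value: "#fc9272",
}


def plot_phase_diagram(table: pd.DataFrame, axis: str, fixed: dict, out_path: str) -> None:
    """Rasterise a phase-diagram table to an image file.

    Green shades mark geometries predicted to pattern successfully, red
    shades the two failure modes; the black line is the closed-form
    design boundary.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    xs = np.sort(table["x_um"].unique())
    ys = np.sort(table["y_um"].unique())
    classes = list(_COLORS)
    idx = table.pivot(index="y_um", columns="x_um", values="outcome_class")
    z = np.vectorize(classes.index)(idx.values)

    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.pcolormesh(xs, ys, z, cmap=ListedColormap(list(_COLORS.values())), vmin=0, vmax=3, shading="nearest")
    ystar = boundary_polyline(axis, xs, fixed)
    ok = np.isfinite(ystar) & (ystar >= ys.min()) & (ystar <= ys.max())
    ax.plot(xs[ok], ystar[ok], "k-", lw=1.5, label="design boundary")
    ax.set_xlabel("low-rail gap h (μm)")
    ax.set_ylabel("port diameter D (μm)" if axis == "D_vs_h" else "high-rail gap H (μm)")
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
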