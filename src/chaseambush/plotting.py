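"""Landscape panels (heatmaps over the S grid) with gridded CSV companions.

Images are never the test surface: every rendered panel is accompanied by
the numeric grid it was drawn from, so downstream checks read values, not
pixels.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["render_landscape"]

_QUANTITIES = {"E": "mean_E", "P_s": "mean_P_s", "P_w": "mean_P_w", "P_diff": "mean_P_diff", "p": "p"}


def render_landscape(
    sweep: pd.DataFrame,
    quantity: str,
    out_image: str | Path | None = None,
    out_csv: str | Path | None = None,
    panel_keys: tuple[str, ...] = ("sense_s", "sense_w"),
):
    """Pivot a long-format sweep into (S_s x S_w) grids, one per panel.

    Raises if any panel grid has missing cells, naming them.  Returns the
    gridded DataFrame; when ``out_image`` is given a matplotlib figure with
    one heatmap per panel is written alongside.
    """
    if quantity not in _QUANTITIES:
        raise ValueError(f"quantity must be one of {sorted(_QUANTITIES)}")
    col = _QUANTITIES[quantity]
    if col not in sweep.columns:
        raise ValueError(f"sweep table lacks column {col!r}")
    panel_keys = tuple(k for k in panel_keys if k in sweep.columns)

    s_vals = sorted(sweep["S_s"].unique())
    w_vals = sorted(sweep["S_w"].unique())
    panels = list(sweep.groupby(list(panel_keys))) if panel_keys else [((), sweep)]
    grids = []
    for key, df in panels:
        agg = df.groupby(["S_s", "S_w"])[col].mean()
        missing = [
            (float(ss), float(sw)) for ss in s_vals for sw in w_vals if (ss, sw) not in agg.index
        ]
        if missing:
            key_repr = tuple(float(k) for k in (key if isinstance(key, tuple) else (key,)))
            raise ValueError(f"panel {key_repr}: missing cells {missing}")
        g = agg.reset_index()
        if not isinstance(key, tuple):
            key = (key,)
        for name, val in zip(panel_keys, key):
            g[name] = val
        grids.append(g)
    gridded = pd.concat(grids, ignore_index=True)
    if out_csv is not None:
        gridded.to_csv(out_csv, index=False)

    if out_image is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        n = len(panels)
        ncol = int(np.ceil(np.sqrt(n)))
        nrow = int(np.ceil(n / ncol))
        fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 3 * nrow), squeeze=False)
        vmin = gridded[col].min()
        vmax = gridded[col].max()
        for ax, (key, df) in zip(axes.flat, panels):
            mat = (
                df.groupby(["S_s", "S_w"])[col]
                .mean()
                .unstack("S_s")
                .reindex(index=w_vals, columns=s_vals)
            )
            im = ax.imshow(
                mat.to_numpy(),
                origin="lower",
                cmap="BrBG_r",
                vmin=vmin,
                vmax=vmax,
                extent=(min(s_vals), max(s_vals), min(w_vals), max(w_vals)),
                aspect="auto",
            )
            ax.set_title(str(key), fontsize=8)
            ax.set_xlabel("S_s")
            ax.set_ylabel("S_w")
        for ax in axes.flat[n:]:
            ax.axis("off")
        fig.colorbar(im, ax=axes, shrink=0.7, label=quantity)
        fig.savefig(out_image, dpi=120)
        plt.close(fig)
    return gridded
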