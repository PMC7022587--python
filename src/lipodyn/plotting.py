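"""Minimal plotting helpers (matplotlib, Agg-safe)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

_COLOR_RGB = {
    "red": "#d62728",
    "orange": "#ff7f0e",
    "green": "#2ca02c",
    "blue": "#1f77b4",
    "grey": "#bbbbbb",
    "black": "#000000",
}


def plot_pf_chart(chart, path: str | Path | None = None):
    """Render the three-chain residue color chart as stacked bar rows.

    ``chart`` is the DataFrame from :func:`lipodyn.kinetics.build_pf_chart`.
    Returns the matplotlib figure; saves to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = ["dimer_chain_1", "dimer_chain_2", "monomer_chain"]
    fig, ax = plt.subplots(figsize=(max(6, len(chart) / 12), 2.2))
    for y, row in enumerate(rows):
        for _, rec in chart.iterrows():
            ax.add_patch(
                plt.Rectangle(
                    (rec["residue_index"] - 0.5, len(rows) - 1 - y - 0.4),
                    1.0,
                    0.8,
                    color=_COLOR_RGB.get(rec[row], "#bbbbbb"),
                    linewidth=0,
                )
            )
    ax.set_xlim(0.5, len(chart) + 0.5)
    ax.set_ylim(-0.5, len(rows) - 0.5)
    ax.set_yticks(range(len(rows)))
    ax.set_yticklabels(reversed(["dimer chain 1", "dimer chain 2", "monomer chain"]))
    ax.set_xlabel("residue index")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig


def plot_msd_series(series, segments=None, path: str | Path | None = None):
    """MSD versus temperature with optional fitted segment lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.errorbar(series.temperature, series.msd, yerr=series.msd_sigma, fmt="o", ms=3, lw=1)
    if segments is not None:
        for seg in segments.segments:
            t = np.linspace(seg.t_low, seg.t_high, 10)
            sel = (series.temperature >= seg.t_low) & (series.temperature <= seg.t_high)
            anchor = series.msd[sel][0]
            ax.plot(t, anchor + seg.slope * (t - series.temperature[sel][0]), "-", lw=1.5)
    ax.set_xlabel("temperature (K)")
    ax.set_ylabel(r"MSD $\langle u^2\rangle$ ($\mathrm{\AA}^2$)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
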