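"""A single track figure: windowed Fst/ZFst along a contig with region shading."""

from __future__ import annotations

import pandas as pd


def plot_zfst_track(table: pd.DataFrame, contig: str, regions=None, ax=None, column="zfst"):
    """Plot a contrast's windowed ZFst (or fst) along one contig.

    ``table`` is a contrast table from :func:`sweepscan.contrast_table`;
    ``regions`` (optional) are shaded SelectedRegion spans.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 2.5))
    sub = table[table["contig"] == contig]
    mid = (sub["start"] + sub["end"]) / 2.0
    ax.plot(mid / 1e6, sub[column], lw=0.8, color="steelblue")
    for r in regions or []:
        if r.contig == contig:
            ax.axvspan(r.start / 1e6, r.end / 1e6, color="salmon", alpha=0.3)
    ax.set_xlabel(f"{contig} position (Mb)")
    ax.set_ylabel(column)
    return ax
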