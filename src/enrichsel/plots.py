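"""Plot helpers: IFS curves, multiplicity histogram, category bar charts."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from .aggregate import FinalOptimalSet
from .ifs import IFSResult


def plot_ifs_curve(result: IFSResult, path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    sizes = [i for i, _ in result.curve]
    ax.plot(sizes, result.mccs, lw=1)
    ax.axvline(result.optimal_size, color="red", ls="--", lw=0.8)
    ax.set_xlabel("number of features")
    ax.set_ylabel("MCC")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def plot_multiplicity_histogram(final: FinalOptimalSet, path) -> None:
    hist = final.histogram()
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(list(hist.keys()), list(hist.values()))
    ax.set_xlabel("number of optimal feature sets containing the feature")
    ax.set_ylabel("number of features")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def plot_category_bars(summary: pd.DataFrame, column: str, path, top: int = 5) -> None:
    head = summary.sort_values(column, ascending=False).head(top)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(head["category"], head[column])
    ax.set_ylabel(column)
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
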