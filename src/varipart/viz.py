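"""Plots of variance-partition results.

Every figure is built from a plain plot-data object (a DataFrame or the
:class:`~varipart.workflow.BinnedCurve`) that tests can inspect
numerically; rendering is seaborn/matplotlib.  Term colors are assigned
consistently across plot kinds within a run, with the residual always last
and grey.  Axes show percent (fractions × 100).
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns

from .design import is_categorical
from .partition import PartitionTable
from .workflow import BinnedCurve, summarize

__all__ = [
    "term_palette",
    "violin_data",
    "plot_violin",
    "plot_gene_bars",
    "plot_stratified",
    "plot_curve",
]

_RESID_GREY = "#999999"


def term_palette(terms) -> dict[str, str]:
    terms = list(terms)
    others = [t for t in terms if t != "residual"]
    colors = sns.color_palette("Set1", n_colors=max(len(others), 3))
    pal = {t: matplotlib.colors.to_hex(c) for t, c in zip(others, colors)}
    if "residual" in terms:
        pal["residual"] = _RESID_GREY
    return pal


def _save(fig, path) -> str:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(fig)
    return str(path)


def violin_data(table: PartitionTable) -> pd.DataFrame:
    """Long-form percent data with terms ordered by median, residual last."""
    order = list(summarize(table).index)
    df = table.clean() * 100.0
    long = df.melt(var_name="term", value_name="percent")
    long["term"] = pd.Categorical(long["term"], categories=order, ordered=True)
    return long.sort_values("term", kind="stable").reset_index(drop=True)


def plot_violin(table: PartitionTable, path) -> str:
    """Violin+box plot of percent variance explained per term."""
    if len(table.data) < 2:
        raise ValueError("violin plot needs at least 2 genes")
    data = violin_data(table)
    pal = term_palette(data["term"].cat.categories)
    fig, ax = plt.subplots(figsize=(1.2 * data["term"].nunique() + 2, 4))
    sns.violinplot(
        data=data, x="term", y="percent", hue="term", palette=pal, cut=0,
        inner="box", density_norm="width", legend=False, ax=ax,
    )
    ax.set_ylim(0, 100)
    ax.set_ylabel("Variance explained (%)")
    ax.set_xlabel("")
    return _save(fig, path)


def gene_bar_data(table: PartitionTable, genes) -> pd.DataFrame:
    missing = [g for g in genes if g not in table.data.index]
    if missing:
        raise KeyError(f"genes not in table: {missing}")
    return table.data.loc[list(genes)] * 100.0


def plot_gene_bars(table: PartitionTable, genes, path) -> str:
    """Stacked horizontal bars of per-gene fractions (percent).

    Standard rows stack to 100%; varying-coefficient tables are drawn as
    grouped (unstacked) bars with a note that fractions do not sum to 1.
    """
    data = gene_bar_data(table, genes)
    pal = term_palette(data.columns)
    fig, ax = plt.subplots(figsize=(6, 0.5 * len(data) + 1.5))
    if table.sums_to_one:
        left = np.zeros(len(data))
        for t in data.columns:
            ax.barh(data.index, data[t], left=left, color=pal[t], label=t)
            left += data[t].to_numpy()
        ax.set_xlim(0, 100)
    else:
        data.plot.barh(ax=ax, color=[pal[t] for t in data.columns])
        ax.text(
            0.99, 1.02, "fractions do not sum to 1",
            transform=ax.transAxes, ha="right", fontsize=8,
        )
    ax.set_xlabel("Variance explained (%)")
    ax.legend(fontsize=8, bbox_to_anchor=(1.02, 1), loc="upper left")
    return _save(fig, path)


def stratified_data(
    y, metadata: pd.DataFrame, term: str, max_levels: int = 30
) -> pd.DataFrame:
    """One gene's expression against one metadata column.

    Categorical terms with more than ``max_levels`` observed levels are
    subset to levels with at least one replicate.
    """
    if term not in metadata.columns:
        raise KeyError(f"'{term}' not in metadata")
    df = pd.DataFrame({"expression": np.asarray(y, dtype=float)},
                      index=metadata.index)
    df[term] = metadata[term].values
    if is_categorical(metadata[term]):
        df[term] = df[term].astype(str)
        counts = df[term].value_counts()
        if len(counts) > max_levels:
            keep = counts[counts >= 2].index
            df = df[df[term].isin(keep)]
    return df


def plot_stratified(
    y, metadata: pd.DataFrame, term: str, path, fraction: float | None = None
) -> str:
    """Expression of one gene stratified by a metadata column.

    Box/strip plot for categorical terms; scatter with a regression line
    for continuous terms.  ``fraction`` annotates the gene's variance
    fraction for the term.
    """
    df = stratified_data(y, metadata, term)
    fig, ax = plt.subplots(figsize=(6, 4))
    if is_categorical(metadata[term]):
        order = sorted(df[term].unique())
        sns.boxplot(data=df, x=term, y="expression", order=order,
                    color="#cccccc", ax=ax)
        sns.stripplot(data=df, x=term, y="expression", order=order,
                      size=3, color="black", alpha=0.5, ax=ax)
        if len(order) > 12:
            ax.tick_params(axis="x", rotation=90, labelsize=6)
    else:
        sns.regplot(data=df, x=term, y="expression", ax=ax,
                    scatter_kws={"s": 10}, line_kws={"color": "red"})
    if fraction is not None:
        ax.set_title(f"{term}: {100 * fraction:.1f}% of variance")
    return _save(fig, path)


def plot_curve(curve: BinnedCurve, path, xlabel: str = "Variance explained (%)") -> str:
    """Sliding-window points plus logistic smooth from binned_curve()."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(100 * curve.smooth_x, curve.smooth_p, color="tab:blue",
            label="logistic smooth")
    ax.scatter(100 * curve.window_x, curve.window_p, s=18, color="black",
               zorder=3, label=f"windows ({curve.window}/{curve.overlap})")
    ax.axhline(curve.baseline, ls="--", color="grey", label="genome-wide mean")
    ax.set_xlabel(xlabel)
    ax.set_ylabel("P(outcome)")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=8)
    return _save(fig, path)
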