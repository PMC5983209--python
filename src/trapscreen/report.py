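"""Fishtail-plot tables and the expression-vs-sensitivity correlation screen."""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .insertions import ScreenDataset
from .screen_stats import sense_ratio

logger = logging.getLogger(__name__)

FishtailAxis = Literal["total", "sense_fraction"]


def fishtail_table(results: pd.DataFrame, dataset: ScreenDataset,
                   axis: FishtailAxis = "total") -> pd.DataFrame:
    """Build the per-gene scatter table behind a fishtail plot.

    y is the gene's sense ratio in ``dataset`` (the treated screen being
    plotted); x is log10 of the gene's total unique insertion count under the
    default axis convention, the established abundance axis for fishtail
    plots.  ``axis='sense_fraction'`` gives the literal alternative
    log10(sense/total) instead.  Genes with zero insertions (or zero sense
    events under the alternative axis) are excluded; x is undefined for them.
    """
    if not results.index.equals(dataset.counts.index):
        raise ValidationError("results and dataset cover different gene universes")
    rows = []
    for gene_id in dataset.counts.index:
        counts = dataset.gene(gene_id)
        if counts.total == 0:
            continue
        y = sense_ratio(counts)
        if axis == "total":
            x = math.log10(counts.total)
        else:
            if counts.sense == 0:
                continue
            x = math.log10(counts.sense / counts.total)
        rows.append({
            "gene_id": gene_id,
            "x": x,
            "y": y,
            "p_value": results.loc[gene_id, "p_value"],
            "classification": results.loc[gene_id, "classification"],
        })
    return pd.DataFrame(rows, columns=["gene_id", "x", "y", "p_value",
                                       "classification"]).set_index("gene_id")


def plot_fishtail(table: pd.DataFrame, path: str | Path,
                  title: str | None = None) -> None:
    """Render a fishtail scatter (convenience only; tables are the real output)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = table["classification"].map({
        "sensitizer": "tab:red",
        "resistance": "tab:blue",
    }).fillna("0.6")
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(table["x"], table["y"], s=8, c=colors, linewidths=0)
    ax.axhline(0.5, color="k", lw=0.8, ls="--")
    ax.set_xlabel("log10 unique insertions")
    ax.set_ylabel("sense ratio")
    ax.set_ylim(-0.02, 1.02)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def correlate_expression_sensitivity(
    data: pd.DataFrame,
    min_lines: int = 6,
    min_r2: float = 0.2,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-tissue OLS of drug sensitivity (log10 IC50) on gene expression.

    ``data`` needs columns ``cell_line``, ``expression``, ``log10_ic50`` and
    ``tissue``; lines with missing values are dropped per tissue.  Tissue
    clusters with fewer than ``min_lines`` complete lines are excluded from
    consideration.  A cluster is flagged when its slope is positive and
    R^2 >= ``min_r2``; ``significant`` additionally marks regression
    p < ``alpha``.  Clusters with zero expression variance have no defined
    fit and are skipped with a warning.
    """
    required = {"cell_line", "expression", "log10_ic50", "tissue"}
    missing = required - set(data.columns)
    if missing:
        raise ValidationError(f"correlation input missing columns {sorted(missing)}")

    rows = []
    for tissue, sub in data.groupby("tissue", sort=True):
        sub = sub.dropna(subset=["expression", "log10_ic50"])
        n = len(sub)
        if n < min_lines:
            continue
        x = sub["expression"].to_numpy(dtype=float)
        y = sub["log10_ic50"].to_numpy(dtype=float)
        if np.allclose(x, x[0]):
            logger.warning("tissue %r: zero variance in expression, skipped", tissue)
            continue
        fit = stats.linregress(x, y)
        r_squared = fit.rvalue ** 2
        flagged = fit.slope > 0 and r_squared >= min_r2
        rows.append({
            "tissue": tissue,
            "n_lines": n,
            "slope": fit.slope,
            "intercept": fit.intercept,
            "r_squared": r_squared,
            "p_value": fit.pvalue,
            "flagged": flagged,
            "significant": bool(flagged and fit.pvalue < alpha),
        })
    return pd.DataFrame(rows, columns=["tissue", "n_lines", "slope", "intercept",
                                       "r_squared", "p_value", "flagged",
                                       "significant"])
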