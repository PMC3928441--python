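"""Optional matplotlib figures: stability rankings, V series, correlation
scatter plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .genorm import GenormResult


def plot_m_ranking(result: GenormResult, path: str | Path) -> None:
    """Bar chart of final geNorm M values, least stable on the left."""
    order = result.ranking[::-1]
    m = result.m_values.loc[order]
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(range(len(m)), m.to_numpy(), color="steelblue")
    ax.set_xticks(range(len(m)), m.index, rotation=45, ha="right")
    ax.axhline(0.5, color="grey", ls="--", lw=1, label="high-stability band (M < 0.5)")
    ax.set_ylabel("average expression stability M")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_v_series(result: GenormResult, path: str | Path) -> None:
    """Bar chart of pairwise variation V_n/n+1 with the decision cutoff."""
    v = result.v_series
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(range(len(v)), v.to_numpy(), color="darkorange")
    ax.set_xticks(range(len(v)), [f"V{n}/{n + 1}" for n in v.index])
    ax.axhline(result.cutoff, color="grey", ls="--", lw=1, label=f"cutoff {result.cutoff}")
    ax.set_ylabel("pairwise variation V")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_correlation(
    expression: pd.Series, echo_values: pd.Series, label: str, path: str | Path
) -> None:
    """Scatter of normalized expression against one echo index."""
    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.scatter(np.asarray(expression, float), np.asarray(echo_values, float), s=25)
    ax.set_xlabel("normalized expression (a.u.)")
    ax.set_ylabel(label)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
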