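"""Static figure export for the PSA scatter, CEAC and tornado data."""

from __future__ import annotations

import pandas as pd


def _axes():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_ce_plane(scatter: pd.DataFrame, path) -> None:
    """Cost-effectiveness plane: one point per Monte-Carlo draw."""
    plt = _axes()
    fig, ax = plt.subplots(figsize=(6, 5))
    for name, grp in scatter.groupby("strategy", sort=False):
        ax.scatter(grp["effectiveness"], grp["cost"], s=4, alpha=0.4, label=name)
    ax.set_xlabel("effectiveness (GOHAI-scaled years)")
    ax.set_ylabel("cost (EUR)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ceac(ceac: pd.DataFrame, path) -> None:
    """Cost-effectiveness acceptability curves over the WTP grid."""
    plt = _axes()
    fig, ax = plt.subplots(figsize=(6, 4))
    for name, grp in ceac.groupby("strategy", sort=False):
        ax.plot(grp["wtp"], grp["probability"], label=name)
    ax.set_xlabel("willingness to pay (EUR per effectiveness unit)")
    ax.set_ylabel("probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_tornado(tornado: pd.DataFrame, base_icer: float, path) -> None:
    """Horizontal-bar tornado diagram, widest swing on top."""
    plt = _axes()
    df = tornado.sort_values("swing")
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(df) + 1.5))
    lo = df[["icer_low", "icer_high"]].min(axis=1)
    hi = df[["icer_low", "icer_high"]].max(axis=1)
    ax.barh(df["parameter"], hi - lo, left=lo, color="#777fc4")
    ax.axvline(base_icer, color="k", lw=1)
    ax.set_xlabel("ICER (EUR per effectiveness unit)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
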