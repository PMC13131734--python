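"""Minimal diagnostic plots: conditional QQ / fold enrichment and MR panels."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .sumstats_io import SummaryStats  # noqa: E402


def plot_fold_enrichment(curves: pd.DataFrame, path: str) -> None:
    """Fold-enrichment curves per secondary cutoff (reference level 1)."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for cutoff, grp in curves.groupby("cutoff"):
        ax.plot(grp["neglog10_p"], grp["enrichment"], marker="o", label=f"p2 < {cutoff:g}")
    ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel(r"$-\log_{10} p$ (primary)")
    ax.set_ylabel("fold enrichment")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_conditional_qq(
    primary: SummaryStats,
    secondary: SummaryStats,
    cutoffs=(1.0, 0.1, 0.01, 0.001),
    path: str = "conditional_qq.png",
) -> None:
    """Conditional QQ: observed vs expected -log10 p within secondary strata."""
    a = primary.df[["variant_id", "p"]].rename(columns={"p": "p1"})
    b = secondary.df[["variant_id", "p"]].rename(columns={"p": "p2"})
    df = a.merge(b, on="variant_id")
    fig, ax = plt.subplots(figsize=(5, 5))
    for c in cutoffs:
        ps = np.sort(df.loc[df["p2"] <= c, "p1"].to_numpy())
        if len(ps) == 0:
            continue
        exp = -np.log10((np.arange(1, len(ps) + 1) - 0.5) / len(ps))
        ax.plot(exp, -np.log10(ps), lw=1, label=f"p2 < {c:g} (n={len(ps)})")
    lim = ax.get_xlim()[1]
    ax.plot([0, lim], [0, lim], color="grey", lw=0.8, ls="--")
    ax.set_xlabel(r"expected $-\log_{10} p$")
    ax.set_ylabel(r"observed $-\log_{10} p$")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_mr_scatter(pair, results, path: str) -> None:
    """Instrument effects with fitted causal slopes per estimator."""
    bx, sx, by, sy = pair.arrays()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(bx, by, xerr=sx, yerr=sy, fmt="o", ms=4, lw=0.7, color="k", alpha=0.7)
    xs = np.linspace(0, bx.max() * 1.05, 10)
    for res in results:
        intercept = res.egger_intercept if np.isfinite(res.egger_intercept) else 0.0
        ax.plot(xs, intercept + res.beta_causal * xs, lw=1.2, label=res.method)
    ax.set_xlabel("instrument-exposure effect")
    ax.set_ylabel("instrument-outcome effect")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_mr_forest(table: pd.DataFrame, path: str) -> None:
    """Forest plot of odds ratios with 95% CIs per method (and exposure)."""
    fig, ax = plt.subplots(figsize=(5, 0.5 * len(table) + 1.2))
    y = np.arange(len(table))[::-1]
    ax.errorbar(
        table["or"],
        y,
        xerr=[table["or"] - table["or_ci_low"], table["or_ci_high"] - table["or"]],
        fmt="s",
        color="k",
        ms=4,
        lw=1,
    )
    ax.axvline(1.0, color="grey", lw=0.8, ls="--")
    labels = [
        f"{row.exposure} | {row.method}" if "exposure" in table.columns else row.method
        for row in table.itertuples()
    ]
    ax.set_yticks(y)
    ax.set_yticklabels(labels, fontsize=8)
    ax.set_xlabel("odds ratio (95% CI)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
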