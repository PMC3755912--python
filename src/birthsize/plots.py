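"""Figure builders for the association outputs.

Layouts follow the screen's presentation conventions: scatter plots of
birth size against a phenotype with outlier categories coloured (small
yellow / large blue for the wild-type-SD scheme, green / purple for the
quantile scheme) and per-category rho annotations, and category boxplots
whose box band marks the group *mean* (the quartile box and 1.5*IQR
whiskers are standard).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")  # headless rendering; figures are saved, not shown

import matplotlib.pyplot as plt
import numpy as np

from .association import AssociationResult, boxplot_summary, _phenotype_value
from .categories import CategoryAssignment, SCHEME_WT_SD
from .distio import StrainRecord

WT_SD_COLORS = {"small": "#e6c229", "normal": "#b0b0b0", "large": "#2a6fdb"}
QUANTILE_COLORS = {"small": "#3aa655", "normal": "#6e6e6e", "large": "#8e44ad"}

PHENOTYPE_AXIS = {"mean_size": "mean size (fl)",
                  "fitness": "fitness rank (1 = most fit)",
                  "pct_g1": "%G1 DNA content"}


def _colors(scheme: str) -> Mapping[str, str]:
    return WT_SD_COLORS if scheme == SCHEME_WT_SD else QUANTILE_COLORS


def scatter_birth_vs_phenotype(
    records: Sequence[StrainRecord],
    assignments: Sequence[CategoryAssignment],
    phenotype: str,
    results: Sequence[AssociationResult] = (),
    colors: Mapping[str, str] | None = None,
    ax: plt.Axes | None = None,
) -> plt.Figure:
    """Scatter of xb (x axis) vs a phenotype, coloured by category, with
    the overall rho bottom-right and category rhos in matching colours."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    scheme = assignments[0].scheme
    cutoff_q = assignments[0].cutoff_q
    colors = colors or _colors(scheme)
    by_orf = {rec.orf: rec for rec in records}
    for label in ("normal", "small", "large"):  # outliers drawn on top
        xs, ys = [], []
        for a in assignments:
            if a.label != label:
                continue
            rec = by_orf[a.orf]
            v = _phenotype_value(rec, phenotype)
            if v is None:
                continue
            xs.append(rec.params.xb_at(cutoff_q))
            ys.append(v)
        ax.scatter(xs, ys, s=9, c=colors[label], label=label,
                   alpha=0.8 if label == "normal" else 1.0)
    for r in results:
        if r.rho is None:
            continue
        if r.category == "overall":
            ax.annotate(f"ρ = {r.rho:.2f}", xy=(0.97, 0.03),
                        xycoords="axes fraction", ha="right", va="bottom")
        elif r.category in colors:
            y = {"small": 0.97, "large": 0.90}.get(r.category, 0.83)
            ax.annotate(f"ρ = {r.rho:.2f}", xy=(0.03, y),
                        xycoords="axes fraction", ha="left", va="top",
                        color=colors[r.category])
    ax.set_xlabel("birth size $x_b$ (fl)")
    ax.set_ylabel(PHENOTYPE_AXIS.get(phenotype, phenotype))
    ax.set_title(f"{scheme} categories, {round(cutoff_q * 100)}% cutoff")
    ax.legend(frameon=False, fontsize=8)
    return ax.figure


def category_boxplot(
    records: Sequence[StrainRecord],
    assignments: Sequence[CategoryAssignment],
    phenotype: str,
    colors: Mapping[str, str] | None = None,
    ax: plt.Axes | None = None,
) -> plt.Figure:
    """Per-category box summaries with the band at the group mean,
    1.5*IQR whiskers and outlier points as filled circles."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    scheme = assignments[0].scheme
    colors = colors or _colors(scheme)
    by_orf = {rec.orf: rec for rec in records}
    order = ("small", "normal", "large")
    for pos, label in enumerate(order):
        vals = [v for a in assignments if a.label == label
                if (v := _phenotype_value(by_orf[a.orf], phenotype))
                is not None]
        if not vals:
            continue
        s = boxplot_summary(vals)
        ax.bxp([{
            "med": s.mean,  # band drawn at the mean, per the layout
            "q1": s.q1, "q3": s.q3,
            "whislo": s.whisker_low, "whishi": s.whisker_high,
            "fliers": list(s.outliers),
        }], positions=[pos], widths=0.6, showfliers=True,
            boxprops={"color": colors[label]},
            medianprops={"color": "black"},
            flierprops={"marker": "o", "markersize": 3,
                        "markerfacecolor": colors[label]})
    ax.set_xticks(range(len(order)))
    ax.set_xticklabels(order)
    ax.set_ylabel(PHENOTYPE_AXIS.get(phenotype, phenotype))
    ax.set_title(f"{scheme} categories")
    return ax.figure


def save_association_figures(
    records: Sequence[StrainRecord],
    assignments_by_scheme: Mapping[str, Sequence[CategoryAssignment]],
    results: Sequence[AssociationResult],
    out_dir,
) -> list[str]:
    """Scatter (mean size, fitness) and boxplot (%G1) panels per scheme."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for scheme, assignments in assignments_by_scheme.items():
        for phenotype in ("mean_size", "fitness"):
            res = [r for r in results
                   if r.scheme == scheme and r.phenotype == phenotype]
            fig = scatter_birth_vs_phenotype(records, assignments, phenotype,
                                             results=res)
            path = out / f"scatter_{phenotype}_{scheme}.svg"
            fig.savefig(path)
            plt.close(fig)
            paths.append(str(path))
        fig = category_boxplot(records, assignments, "pct_g1")
        path = out / f"boxplot_pct_g1_{scheme}.svg"
        fig.savefig(path)
        plt.close(fig)
        paths.append(str(path))
    return paths
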