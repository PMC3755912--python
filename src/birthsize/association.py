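"""Associations between birth size and per-strain phenotypes.

Per category (small / normal / large / overall) of a labelling scheme,
birth size xb is rank-correlated (Spearman, midrank ties) with mean cell
size, competitive-fitness rank, or %G1 DNA content.  Group comparisons
between categories use Welch's two-sample t test on the means, with a
Mann-Whitney U test alongside as a distribution-free check, plus the
five-number boxplot summaries used for plotting.

Fitness is an ordinal rank (1 = most fit .. 21 = least fit) and is only
ever used in rank-based statistics here.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .distio import StrainRecord
from .categories import CategoryAssignment, LABELS

logger = logging.getLogger(__name__)

PHENOTYPES = ("mean_size", "fitness", "pct_g1")
CATEGORIES = ("small", "normal", "large", "overall")


@dataclass(frozen=True)
class AssociationResult:
    phenotype: str
    scheme: str
    category: str
    cutoff_q: float
    n: int
    rho: float | None
    p_value: float | None
    note: str = ""


@dataclass(frozen=True)
class GroupComparison:
    phenotype: str
    scheme: str
    pair: tuple[str, str]
    cutoff_q: float
    n: tuple[int, int]
    mean_diff: float | None
    welch_t_p: float | None
    mann_whitney_p: float | None
    holm_welch_t_p: float | None = None
    summaries: dict[str, "BoxplotSummary"] = field(default_factory=dict)


@dataclass(frozen=True)
class BoxplotSummary:
    """Five-number summary with mean: quartile box, 1.5*IQR whiskers,
    points beyond the whiskers listed as outliers."""

    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]


def boxplot_summary(values: Sequence[float]) -> BoxplotSummary:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty group")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
    outliers = tuple(float(v) for v in np.sort(arr[(arr < lo_fence)
                                                   | (arr > hi_fence)]))
    return BoxplotSummary(
        n=int(arr.size), mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        median=float(med), q1=float(q1), q3=float(q3),
        whisker_low=float(inside.min()), whisker_high=float(inside.max()),
        outliers=outliers,
    )


def spearman(x: Sequence[float], y: Sequence[float],
             exact: bool = False) -> tuple[float, float]:
    """Spearman rank correlation with midrank tie handling.

    The two-sided p value comes from the large-sample t approximation;
    with ``exact`` and n <= 10 it is computed instead by exhaustive
    permutation of one variable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("rho undefined: a variable is constant")
    if exact:
        if x.size > 10:
            raise ValueError("exact permutation p only for n <= 10")
        res = stats.permutation_test(
            (x, y),
            lambda a, b: stats.spearmanr(a, b).statistic,
            permutation_type="pairings", n_resamples=math.inf,
        )
        rho = stats.spearmanr(x, y).statistic
        return float(rho), float(res.pvalue)
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def welch_p(a: Sequence[float], b: Sequence[float]) -> float | None:
    """Two-sided Welch two-sample t p value; None when undefined
    (both groups constant with unequal means)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 and b.std() == 0:
        return 1.0 if a.mean() == b.mean() else None
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def mann_whitney_p(a: Sequence[float], b: Sequence[float]) -> float | None:
    """Two-sided Mann-Whitney U p value; None when all values are tied."""
    try:
        return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    except ValueError:
        return None


def null_rejection_rate(n_reps: int = 1000, n_per_group: int = 50,
                        alpha: float = 0.05,
                        rng: np.random.Generator | int | None = None) -> float:
    """Type-I calibration of the Welch comparison: fraction of replicates
    rejecting at ``alpha`` when both groups are drawn from the same
    normal distribution (no planted effect)."""
    rng = np.random.default_rng(rng)
    hits = 0
    for _ in range(n_reps):
        p = welch_p(rng.standard_normal(n_per_group),
                    rng.standard_normal(n_per_group))
        if p is not None and p < alpha:
            hits += 1
    return hits / n_reps


def _phenotype_value(rec: StrainRecord, phenotype: str) -> float | None:
    if rec.phenotypes is None:
        return None
    if phenotype == "mean_size":
        return rec.phenotypes.mean_size_published
    if phenotype == "fitness":
        fr = rec.phenotypes.fitness_rank
        return float(fr) if fr is not None else None
    if phenotype == "pct_g1":
        return rec.phenotypes.pct_g1
    raise ValueError(f"unknown phenotype {phenotype!r}")


def _category_members(
    records: Sequence[StrainRecord],
    assignments: Sequence[CategoryAssignment],
) -> tuple[str, float, dict[str, list[StrainRecord]]]:
    by_orf = {rec.orf: rec for rec in records}
    schemes = {a.scheme for a in assignments}
    cutoffs = {a.cutoff_q for a in assignments}
    if len(schemes) != 1 or len(cutoffs) != 1:
        raise ValueError("assignments must come from one scheme and cutoff")
    members: dict[str, list[StrainRecord]] = {lab: [] for lab in LABELS}
    for a in assignments:
        rec = by_orf.get(a.orf)
        if rec is None:
            raise ValueError(f"assignment for unknown strain {a.orf}")
        members[a.label].append(rec)
    return schemes.pop(), cutoffs.pop(), members


def per_category_association(
    records: Sequence[StrainRecord],
    assignments: Sequence[CategoryAssignment],
    phenotype: str,
) -> list[AssociationResult]:
    """Spearman rho of xb vs one phenotype for each category and overall.

    Strains missing the phenotype are dropped pairwise within each cell.
    Cells with fewer than 3 complete pairs, or a constant variable, are
    reported with rho missing rather than omitted.
    """
    scheme, cutoff_q, members = _category_members(records, assignments)
    groups = dict(members)
    groups["overall"] = [rec for lab in LABELS for rec in members[lab]]
    out = []
    for category in CATEGORIES:
        recs = groups[category]
        pairs = [(rec.params.xb_at(cutoff_q), _phenotype_value(rec, phenotype))
                 for rec in recs]
        pairs = [(xb, v) for xb, v in pairs if v is not None]
        if len(pairs) < 3:
            out.append(AssociationResult(phenotype, scheme, category, cutoff_q,
                                         len(pairs), None, None,
                                         note="n < 3"))
            continue
        xs, ys = zip(*pairs)
        try:
            rho, p = spearman(xs, ys)
        except ValueError as exc:
            out.append(AssociationResult(phenotype, scheme, category, cutoff_q,
                                         len(pairs), None, None,
                                         note=str(exc)))
            continue
        out.append(AssociationResult(phenotype, scheme, category, cutoff_q,
                                     len(pairs), rho, p))
    return out


def group_mean_comparison(
    records: Sequence[StrainRecord],
    assignments: Sequence[CategoryAssignment],
    phenotype: str,
    holm: bool = False,
) -> list[GroupComparison]:
    """Welch t and Mann-Whitney U for every category pair and each
    category against the rest, two-sided, with boxplot summaries.

    When both groups have zero variance the t statistic is undefined;
    the Mann-Whitney p is still reported.  ``holm`` adds Holm-adjusted
    Welch p values across the comparisons.
    """
    scheme, cutoff_q, members = _category_members(records, assignments)
    values = {
        lab: np.asarray([v for rec in members[lab]
                         if (v := _phenotype_value(rec, phenotype)) is not None],
                        dtype=float)
        for lab in LABELS
    }
    pairs: list[tuple[str, str]] = list(itertools.combinations(LABELS, 2))
    pairs += [(lab, f"not_{lab}") for lab in LABELS]
    results = []
    for a, b in pairs:
        va = values[a]
        vb = (np.concatenate([values[l] for l in LABELS if l != a])
              if b.startswith("not_") else values[b])
        if va.size < 2 or vb.size < 2:
            results.append(GroupComparison(phenotype, scheme, (a, b), cutoff_q,
                                           (int(va.size), int(vb.size)),
                                           None, None, None))
            continue
        mean_diff = float(va.mean() - vb.mean())
        results.append(GroupComparison(
            phenotype, scheme, (a, b), cutoff_q,
            (int(va.size), int(vb.size)), mean_diff,
            welch_p(va, vb), mann_whitney_p(va, vb),
            summaries={a: boxplot_summary(va), b: boxplot_summary(vb)},
        ))
    if holm:
        ps = [(i, r.welch_t_p) for i, r in enumerate(results)
              if r.welch_t_p is not None]
        if ps:
            order = sorted(range(len(ps)), key=lambda j: ps[j][1])
            m = len(ps)
            adj = {}
            running = 0.0
            for rank, j in enumerate(order):
                i, p = ps[j]
                running = max(running, min(1.0, (m - rank) * p))
                adj[i] = running
            results = [
                GroupComparison(r.phenotype, r.scheme, r.pair, r.cutoff_q,
                                r.n, r.mean_diff, r.welch_t_p,
                                r.mann_whitney_p, adj.get(i),
                                r.summaries)
                for i, r in enumerate(results)
            ]
    return results


def birth_to_budding_increase(xb: float, budding_size: float
                              ) -> tuple[float, int]:
    """Percent size increase from birth (xb) to budding.

    Returns the unrounded percentage and its nearest-integer rounding.
    A budding size below xb yields a negative increase with a warning.
    """
    if xb <= 0:
        raise ValueError("xb must be positive")
    pct = 100.0 * (budding_size - xb) / xb
    if budding_size < xb:
        logger.warning("budding size %.2f fl below birth size %.2f fl: "
                       "negative increase", budding_size, xb)
    return pct, int(round(pct))


def associations_table(results: Sequence[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"phenotype": r.phenotype, "scheme": r.scheme, "cutoff_q": r.cutoff_q,
          "category": r.category, "n": r.n, "rho": r.rho, "p": r.p_value,
          "note": r.note} for r in results]
    )


def comparisons_table(results: Sequence[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"phenotype": r.phenotype, "scheme": r.scheme, "cutoff_q": r.cutoff_q,
          "group_a": r.pair[0], "group_b": r.pair[1],
          "n_a": r.n[0], "n_b": r.n[1], "mean_diff": r.mean_diff,
          "welch_t_p": r.welch_t_p, "mann_whitney_p": r.mann_whitney_p,
          "holm_welch_t_p": r.holm_welch_t_p} for r in results]
    )
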