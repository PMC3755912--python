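"""Small / normal / large birth-size categories.

Two schemes are supported:

* ``wt_sd`` — outliers relative to wild-type replicates: a mutant is
  small when its xb lies strictly more than two SDs below the wild-type
  mean xb, large when strictly more than two SDs above, otherwise
  normal.  Boundary equality maps to normal (the rule is stated with
  strict inequalities).
* ``quantile`` — tail cutoffs over the mutant population itself: strains
  in the bins containing the smallest ``tail`` (default 5%) of xb values
  are small, the largest ``tail`` large.  Because xb is bin-valued,
  every strain sharing a boundary bin is included, so the tails may
  slightly exceed the nominal fraction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .distio import StrainRecord

logger = logging.getLogger(__name__)

SCHEME_WT_SD = "wt_sd"
SCHEME_QUANTILE = "quantile"
LABELS = ("small", "normal", "large")


@dataclass(frozen=True)
class WTReference:
    """Mean and SD of wild-type birth size at one cutoff."""

    mu_wt: float
    sd_wt: float
    n_wt: int
    cutoff_q: float

    def __post_init__(self) -> None:
        if self.n_wt < 2:
            raise ValueError("need >= 2 wild-type replicates")
        if self.sd_wt < 0:
            raise ValueError("sd_wt must be non-negative")

    @property
    def lower(self) -> float:
        return self.mu_wt - 2.0 * self.sd_wt

    @property
    def upper(self) -> float:
        return self.mu_wt + 2.0 * self.sd_wt


@dataclass(frozen=True)
class CategoryAssignment:
    orf: str
    scheme: str
    label: str
    cutoff_q: float

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.scheme not in (SCHEME_WT_SD, SCHEME_QUANTILE):
            raise ValueError(f"unknown scheme {self.scheme!r}")


def _qc_pass(records: Sequence[StrainRecord]) -> list[StrainRecord]:
    out = []
    for rec in records:
        if rec.params is None:
            raise ValueError(f"strain {rec.orf} has no extracted parameters")
        if rec.params.is_pass:
            out.append(rec)
    return out


def wt_reference(records: Sequence[StrainRecord],
                 cutoff: float = 0.20) -> WTReference:
    """Sample mean and SD (n-1 denominator) of wild-type xb at ``cutoff``."""
    q = float(cutoff)
    values = [rec.params.xb_at(q) for rec in _qc_pass(records)
              if rec.is_wild_type]
    if len(values) < 2:
        raise ValueError("need at least 2 qc-pass wild-type replicates")
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1))
    if sd == 0.0:
        logger.warning("wild-type xb replicates are identical (sd = 0): "
                       "every mutant off the wild-type bin becomes an outlier")
    return WTReference(mu_wt=float(arr.mean()), sd_wt=sd, n_wt=arr.size,
                       cutoff_q=q)


def categorize_wt_sd(records: Sequence[StrainRecord],
                     ref: WTReference,
                     include_wildtype: bool = False) -> list[CategoryAssignment]:
    """Assign labels by strict +/- 2 SD thresholds around the wild-type mean.

    Categories are defined over mutants; wild-type replicates are only
    labelled when ``include_wildtype`` is set.
    """
    out = []
    for rec in _qc_pass(records):
        if rec.is_wild_type and not include_wildtype:
            continue
        xb = rec.params.xb_at(ref.cutoff_q)
        if xb < ref.lower:
            label = "small"
        elif xb > ref.upper:
            label = "large"
        else:
            label = "normal"
        out.append(CategoryAssignment(rec.orf, SCHEME_WT_SD, label,
                                      ref.cutoff_q))
    return out


def categorize_quantile(
    records: Sequence[StrainRecord],
    tail: float = 0.05,
    cutoff: float = 0.20,
    include_wildtype: bool = False,
) -> list[CategoryAssignment]:
    """Assign labels by empirical ``tail`` quantiles of the mutant xb pool.

    The quantile is the order statistic at rank ceil(tail * n) with no
    interpolation; bin-level tie inclusion then labels every strain in
    the boundary bin.  Wild-type replicates are excluded from the pool
    (and from the output) unless ``include_wildtype``.
    """
    q = float(cutoff)
    if not 0.0 < tail <= 0.5:
        raise ValueError("tail must be in (0, 0.5]")
    pool = [rec for rec in _qc_pass(records)
            if include_wildtype or not rec.is_wild_type]
    n = len(pool)
    if n < math.ceil(1.0 / tail):
        raise ValueError(f"need >= {math.ceil(1.0 / tail)} strains for "
                         f"tail {tail}")
    xs = np.sort(np.asarray([rec.params.xb_at(q) for rec in pool]))
    k = math.ceil(tail * n)
    low_cut = xs[k - 1]
    high_cut = xs[n - k]
    if tail >= 0.5:
        logger.warning("tail %.2f leaves no normal category", tail)
    out = []
    for rec in pool:
        xb = rec.params.xb_at(q)
        if xb <= low_cut:
            label = "small"
        elif xb >= high_cut:
            label = "large"
        else:
            label = "normal"
        out.append(CategoryAssignment(rec.orf, SCHEME_QUANTILE, label, q))
    return out


def compare_schemes(a: Sequence[CategoryAssignment],
                    b: Sequence[CategoryAssignment]) -> pd.DataFrame:
    """3x3 contingency table of labels under two schemes (same strain set)."""
    la = {x.orf: x.label for x in a}
    lb = {x.orf: x.label for x in b}
    if set(la) != set(lb):
        raise ValueError("assignments cover different strain sets")
    table = pd.DataFrame(0, index=list(LABELS), columns=list(LABELS))
    for orf, lab_a in la.items():
        table.loc[lab_a, lb[orf]] += 1
    table.index.name = "scheme_a"
    table.columns.name = "scheme_b"
    return table


def assignments_table(assignments: Sequence[CategoryAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"orf": a.orf, "scheme": a.scheme, "cutoff_q": a.cutoff_q,
          "label": a.label} for a in assignments]
    )
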