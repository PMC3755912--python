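"""Extraction of the five size-distribution parameters.

For each strain's binned histogram f(x) the module determines

* ``x0`` — start of the cell-size support, after filtering spurious
  low-channel noise;
* ``xd`` — the mode, taken as the maximum daughter size: budding yeast
  divides asymmetrically, so newborn daughters occupy the left-of-mode
  region of an asynchronous size histogram;
* ``xb(q)`` — birth size: the first bin at which the cumulative count
  over the daughter interval [x0, xd] reaches a fraction ``q`` (default
  0.20) of the daughter-interval total;
* ``xm`` — the count-weighted mean size over the support;
* ``xy`` — end of the support (last occupied channel).

Every parameter is a bin value and carries a bin-granularity error bound
x_p +/- (x_{p+1} - x_p) from the local grid interval.

The support was curated visually in the original screen; here the
curation is automated with a deterministic rule (a bin opens the support
when it and the next k-1 bins all hold at least a fraction ``alpha`` of
the histogram's maximum count), complemented by a manual-override table
and an exclusion list so that hand curation can still be expressed as
configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .distio import SizeDistribution, StrainRecord

QC_PASS = "pass"
QC_ABNORMAL = "abnormal_no_daughter_range"
QC_MANUAL_EXCLUDED = "manual_excluded"

DEFAULT_CUTOFFS = (0.10, 0.15, 0.20, 0.25)


class AbnormalProfileError(ValueError):
    """A histogram on which no daughter interval can be defined."""


def validate_cutoff(q: float) -> float:
    if not 0.0 < q < 1.0:
        raise ValueError(f"birth-size cutoff must be in (0, 1), got {q}")
    return float(q)


@dataclass(frozen=True)
class SupportConfig:
    """Automated stand-in for visual support curation.

    alpha: noise threshold as a fraction of the histogram's maximum count.
    k: number of consecutive bins that must clear the threshold for the
       support to open (isolated debris spikes fail this).
    manual_overrides: orf -> (x0, xy) in fl, returned unchanged.
    exclusion_list: orfs removed outright (qc ``manual_excluded``).
    smoothing_window: odd moving-average width for mode finding (1 = off).
    mean_over_support: compute xm over [x0, xy] only (noise excluded);
       set False to average over all channels for sensitivity analysis.
    """

    alpha: float = 0.01
    k: int = 3
    manual_overrides: Mapping[str, tuple[float, float]] = field(
        default_factory=dict)
    exclusion_list: frozenset[str] = frozenset()
    smoothing_window: int = 1
    mean_over_support: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError("alpha must be in [0, 1)")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be odd and >= 1")
        object.__setattr__(self, "exclusion_list",
                           frozenset(self.exclusion_list))


@dataclass
class DistributionParameters:
    """The five parameters of one strain, with error bounds and QC status.

    ``xb`` maps each cutoff q to the birth-size bin; ``err`` maps
    parameter names ('x0', 'xd', 'xb_20', 'xm', 'xy') to the local grid
    interval at that parameter's bin.  Parameters computed before a QC
    failure are retained for diagnostics.
    """

    x0: float | None = None
    xd: float | None = None
    xb: dict[float, float] = field(default_factory=dict)
    xm: float | None = None
    xy: float | None = None
    err: dict[str, float] = field(default_factory=dict)
    qc: str = QC_PASS

    @property
    def is_pass(self) -> bool:
        return self.qc == QC_PASS

    def xb_at(self, q: float) -> float:
        return self.xb[float(q)]


def xb_key(q: float) -> str:
    """Column name for a cutoff, e.g. 0.20 -> 'xb_20'."""
    return f"xb_{round(q * 100):02d}"


def detect_support(dist: SizeDistribution, cfg: SupportConfig,
                   orf: str | None = None) -> tuple[float, float]:
    """Locate the cell-size support [x0, xy], filtering low-channel noise.

    x0 is the smallest bin whose count, and the counts of the next k-1
    bins, all reach alpha times the raw histogram's maximum count; xy is
    the last occupied bin.  A manual override for ``orf`` wins outright.

    Raises AbnormalProfileError when no bin satisfies the x0 rule.
    """
    if orf is not None and orf in cfg.manual_overrides:
        x0, xy = cfg.manual_overrides[orf]
        if x0 >= xy:
            raise ValueError(f"manual override for {orf} has x0 >= xy")
        return float(x0), float(xy)
    counts = dist.counts
    if dist.is_empty:
        raise AbnormalProfileError("all-zero distribution")
    threshold = cfg.alpha * counts.max()
    ok = counts >= threshold if threshold > 0 else counts > 0
    n = dist.n_bins
    start = None
    for i in range(n):
        window = ok[i:i + cfg.k]
        if window.all():
            start = i
            break
    if start is None:
        raise AbnormalProfileError("no bin satisfies the support-start rule")
    last = int(np.flatnonzero(counts > 0)[-1])
    if start >= last:
        raise AbnormalProfileError("support start at or after last occupied bin")
    return float(dist.bin_sizes[start]), float(dist.bin_sizes[last])


def find_mode(dist: SizeDistribution, x0: float, xy: float,
              smoothing_window: int = 1) -> float:
    """Mode of the histogram on [x0, xy]; ties break to the smallest bin.

    With ``smoothing_window`` > 1 (odd) the argmax is taken over a
    moving-average-smoothed copy, approximating by-eye mode reading on
    ragged histograms; the location is still reported on the raw grid.

    Raises AbnormalProfileError when the mode sits at the support start,
    which leaves no daughter interval.
    """
    lo = dist.index_of(x0)
    hi = dist.index_of(xy)
    if lo >= hi:
        raise ValueError("x0 must lie strictly left of xy on the grid")
    counts = dist.counts
    if smoothing_window > 1:
        kernel = np.ones(smoothing_window) / smoothing_window
        counts = np.convolve(counts, kernel, mode="same")
    window = counts[lo:hi + 1]
    xd = float(dist.bin_sizes[lo + int(np.argmax(window))])  # argmax: first max
    if xd == x0:
        raise AbnormalProfileError(
            "mode at support start: daughter interval is empty")
    return xd


def birth_size(dist: SizeDistribution, x0: float, xd: float,
               cutoff: float) -> float:
    """Birth size: first bin where the running daughter-interval sum
    reaches ``cutoff`` times the daughter-interval total.

    Both the running sum and the total include their endpoint bins; the
    comparison is ">=" with no within-bin interpolation — the method
    accepts bin-granularity error instead.
    """
    q = validate_cutoff(cutoff)
    lo = dist.index_of(x0)
    hi = dist.index_of(xd)
    if lo > hi:
        raise ValueError("x0 must not exceed xd")
    daughter = dist.counts[lo:hi + 1]
    total = daughter.sum()
    if total <= 0:
        raise AbnormalProfileError("daughter interval has zero count")
    cum = np.cumsum(daughter)
    t = int(np.searchsorted(cum, q * total))
    return float(dist.bin_sizes[lo + t])


def mean_size(dist: SizeDistribution, x0: float, xy: float,
              over_support: bool = True) -> float:
    """Count-weighted mean size xm = sum x f(x), f renormalised over the
    support so that excluded noise does not weight the average."""
    if over_support:
        lo = dist.index_of(x0)
        hi = dist.index_of(xy)
        counts = dist.counts[lo:hi + 1]
        sizes = dist.bin_sizes[lo:hi + 1]
    else:
        counts = dist.counts
        sizes = dist.bin_sizes
    total = counts.sum()
    if total <= 0:
        raise AbnormalProfileError("no observations in support")
    return float(np.dot(sizes, counts) / total)


def _nearest_bin_index(dist: SizeDistribution, value: float) -> int:
    return int(np.argmin(np.abs(dist.bin_sizes - value)))


def extract_parameters(
    record: StrainRecord,
    cfg: SupportConfig | None = None,
    cutoffs: Iterable[float] = DEFAULT_CUTOFFS,
) -> DistributionParameters:
    """Run the full support -> mode -> birth-size -> mean pipeline for one
    strain, attaching local-grid error bounds and a QC status.

    QC failures do not raise: the stage's failure is recorded in ``qc``
    and parameters from earlier stages are kept for diagnostics.
    """
    cfg = cfg or SupportConfig()
    cutoffs = tuple(validate_cutoff(q) for q in cutoffs)
    dist = record.distribution
    out = DistributionParameters()
    if record.orf in cfg.exclusion_list:
        out.qc = QC_MANUAL_EXCLUDED
        return out

    def err_at(value: float) -> float:
        return dist.bin_interval(_nearest_bin_index(dist, value))

    try:
        x0, xy = detect_support(dist, cfg, orf=record.orf)
    except AbnormalProfileError:
        out.qc = QC_ABNORMAL
        return out
    out.x0, out.xy = x0, xy
    out.err["x0"] = err_at(x0)
    out.err["xy"] = err_at(xy)
    try:
        xd = find_mode(dist, x0, xy, smoothing_window=cfg.smoothing_window)
    except AbnormalProfileError:
        out.qc = QC_ABNORMAL
        return out
    out.xd = xd
    out.err["xd"] = err_at(xd)
    try:
        for q in cutoffs:
            xb = birth_size(dist, x0, xd, q)
            out.xb[q] = xb
            out.err[xb_key(q)] = err_at(xb)
        out.xm = mean_size(dist, x0, xy, over_support=cfg.mean_over_support)
    except AbnormalProfileError:
        out.qc = QC_ABNORMAL
        return out
    out.err["xm"] = err_at(out.xm)
    return out


def extract_panel(
    records: Sequence[StrainRecord],
    cfg: SupportConfig | None = None,
    cutoffs: Iterable[float] = DEFAULT_CUTOFFS,
) -> list[StrainRecord]:
    """Extract parameters for every strain in place; returns the records."""
    for rec in records:
        rec.params = extract_parameters(rec, cfg=cfg, cutoffs=cutoffs)
    return list(records)


def params_table(records: Sequence[StrainRecord],
                 cutoffs: Iterable[float] = DEFAULT_CUTOFFS) -> pd.DataFrame:
    """Flatten extracted parameters to a per-strain table (one row per ORF)."""
    cutoffs = tuple(float(q) for q in cutoffs)
    rows = []
    for rec in records:
        p = rec.params
        if p is None:
            raise ValueError(f"strain {rec.orf} has no extracted parameters")
        row: dict[str, object] = {"orf": rec.orf, "role": rec.role,
                                  "x0": p.x0, "xd": p.xd}
        for q in cutoffs:
            row[xb_key(q)] = p.xb.get(q)
        row["xm"] = p.xm
        row["xy"] = p.xy
        for name, val in p.err.items():
            row[f"err_{name}"] = val
        row["qc"] = p.qc
        rows.append(row)
    return pd.DataFrame(rows)


def qc_summary(records: Sequence[StrainRecord]) -> dict[str, int]:
    """Strain bookkeeping: ingested = pass + abnormal + manually excluded."""
    counts = {"ingested": len(records), QC_PASS: 0, QC_ABNORMAL: 0,
              QC_MANUAL_EXCLUDED: 0}
    for rec in records:
        if rec.params is not None:
            counts[rec.params.qc] += 1
    return counts
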