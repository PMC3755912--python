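"""Shared helpers: random histogram factory and independent oracles."""

from __future__ import annotations

import numpy as np

from birthsize.distio import (ROLE_MUTANT, ROLE_WILD_TYPE, SizeDistribution,
                              StrainRecord)
from birthsize.params import DistributionParameters, QC_PASS


def random_distribution(rng: np.random.Generator) -> SizeDistribution:
    """A random unimodal-ish histogram on a random non-uniform grid."""
    n = int(rng.integers(6, 40))
    start = float(rng.uniform(5, 30))
    intervals = rng.uniform(0.3, 1.3, n - 1)
    bins = start + np.concatenate(([0.0], np.cumsum(intervals)))
    mode_pos = int(rng.integers(1, n))
    base = np.concatenate([
        np.linspace(0.5, 10.0, mode_pos),
        np.linspace(10.0, 0.2, n - mode_pos),
    ])
    counts = rng.poisson(base * rng.uniform(2, 30)).astype(float)
    if counts.sum() == 0:
        counts[mode_pos - 1] = 1.0
    return SizeDistribution(bins, counts)


def brute_force_birth_size(dist: SizeDistribution, x0: float, xd: float,
                           q: float) -> float:
    """Independent oracle: enumerate every candidate bin and test the
    cumulative condition directly against explicit Python sums."""
    bins = list(dist.bin_sizes)
    counts = list(dist.counts)
    lo = bins.index(x0)
    hi = bins.index(xd)
    daughter_total = sum(counts[lo:hi + 1])
    assert daughter_total > 0
    for t in range(lo, hi + 1):
        if sum(counts[lo:t + 1]) >= q * daughter_total:
            return bins[t]
    raise AssertionError("cumulative never reached the threshold")


def midrank(values) -> list[float]:
    """Average ranks with midrank ties, by explicit enumeration."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def pearson(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum()))


def records_with_xb(xb_values, roles=None, cutoff: float = 0.20,
                    prefix: str = "S") -> list[StrainRecord]:
    """Strain records with preset birth sizes, for category-level tests
    that do not need real histograms."""
    bins = np.array([10.0, 11.0, 12.0])
    counts = np.array([1.0, 2.0, 1.0])
    out = []
    for i, xb in enumerate(xb_values):
        role = roles[i] if roles is not None else ROLE_MUTANT
        params = DistributionParameters(
            x0=10.0, xd=11.0, xb={cutoff: float(xb)}, xm=11.0, xy=12.0,
            qc=QC_PASS)
        out.append(StrainRecord(
            orf=f"{prefix}{i:04d}",
            role=role,
            distribution=SizeDistribution(bins, counts),
            params=params))
    return out


def split_half_bins(dist: SizeDistribution) -> SizeDistribution:
    """Refine every bin into two half-spaced bins carrying half the count."""
    bins = dist.bin_sizes
    counts = dist.counts
    d = np.diff(bins)
    new_bins, new_counts = [], []
    for i, x in enumerate(bins):
        step = d[i] if i < d.size else d[-1]
        new_bins += [x, x + step / 2.0]
        new_counts += [counts[i] / 2.0, counts[i] / 2.0]
    return SizeDistribution(np.array(new_bins), np.array(new_counts))
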