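"""Synthetic strain panels with known ground truth.

The generator emulates the statistical structure the birth-size method
assumes about asynchronous budding-yeast cultures measured on a Coulter
channelyzer:

* each strain's size histogram is a two-component lognormal mixture —
  a daughter component (newborns growing from birth size B toward the
  budding size) holding at least half the cells, and a larger mother
  component centred at ``mother_daughter_ratio * B`` — so that daughters
  occupy the left-of-mode region, as asymmetric division produces;
* sizes are binned onto a shared non-uniform channel grid whose
  successive intervals ramp across the 0.385662112-1.203735813 fl range
  seen on the instrument;
* spurious debris counts (Poisson) contaminate the low channels below
  the daughter component's 0.1 percentile, which the support-detection
  step must filter;
* planted mutants scale B by a known multiplier and optionally shift
  %G1 and fitness, so recovery of both parameters and category labels
  can be scored against the truth;
* linked phenotypes follow the generating model: published mean size is
  the analytic mixture mean plus noise, %G1 rises as planted-small
  strains are born smaller, fitness rank worsens for outliers.

All randomness flows from a single seed; identical spec + seed gives
bit-identical panels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .distio import (PhenotypeRecord, ROLE_MUTANT, ROLE_WILD_TYPE,
                     SizeDistribution, StrainRecord, join_panel)

DEFAULT_WT_BIRTH_MEAN = 23.7  # fl
DEFAULT_BUDDING_SIZE = 35.0  # fl


@dataclass(frozen=True)
class PlantedEffect:
    """A mutant with a known birth-size multiplier and phenotype shifts."""

    orf: str
    birth_effect: float = 1.0  # multiplies the true birth size B
    g1_shift: float = 0.0  # percentage points added to %G1
    fitness_shift: int = 0  # ranks added (worsening fitness)

    @property
    def true_label(self) -> str:
        if self.birth_effect < 1.0:
            return "small"
        if self.birth_effect > 1.0:
            return "large"
        return "normal"


@dataclass(frozen=True)
class LinkSpec:
    """How phenotypes are tied to the true birth size.

    %G1 of a planted-small strain is ``g1_baseline + g1_slope *
    (wt_birth_mean - B)`` plus Gaussian noise; unplanted strains sit at
    baseline + noise so they probe type-I behaviour.  Fitness rank is
    1 + Poisson(``fitness_base_lambda``), worsened by
    ``fitness_penalty`` ranks for birth-size outliers; ranks clip to
    [1, 21] and %G1 to [0, 100].
    """

    g1_baseline: float = 50.0  # %G1 of a normal strain
    g1_slope: float = 1.7  # percentage points per fl of birth-size deficit
    g1_noise_sd: float = 3.0
    fitness_base_lambda: float = 2.0
    fitness_penalty: int = 5
    mean_size_noise_sd: float = 0.5  # fl


@dataclass(frozen=True)
class SyntheticPanelSpec:
    """Conditions of a synthetic screen.

    Defaults follow the wild-type numbers the method is calibrated on: a
    23.7 fl mean birth size, budding near 35 fl, mothers ~1.6x their
    daughters' birth size, and at least half of cells being daughters.
    ``wt_birth_cv`` is the cell-to-cell birth-size CV within a strain;
    ``replicate_cv``/``strain_cv`` are the culture-level spreads of
    wild-type replicates and of unperturbed mutants.
    """

    n_mutants: int = 500
    n_wildtype: int = 8
    wt_birth_mean: float = DEFAULT_WT_BIRTH_MEAN
    wt_birth_cv: float = 0.12
    mother_daughter_ratio: float = 1.6
    daughter_fraction: float = 0.55
    budding_ratio: float = DEFAULT_BUDDING_SIZE / DEFAULT_WT_BIRTH_MEAN
    replicate_cv: float = 0.04
    strain_cv: float = 0.05
    cells_per_strain: int = 20_000
    grid_start: float = 8.0  # fl, first channel
    n_bins: int = 80
    grid_interval_min: float = 0.385662112  # fl
    grid_interval_max: float = 1.203735813  # fl
    noise_rate: float = 40.0  # expected spurious low-channel counts / strain
    planted: tuple[PlantedEffect, ...] = ()
    link: LinkSpec = field(default_factory=LinkSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.5 <= self.daughter_fraction < 1.0:
            raise ValueError("daughter_fraction must be in [0.5, 1)")
        if self.mother_daughter_ratio <= 1.0:
            raise ValueError("mother_daughter_ratio must exceed 1")
        if self.budding_ratio <= 1.0:
            raise ValueError("budding_ratio must exceed 1")
        if min(self.n_mutants, self.n_wildtype, self.cells_per_strain,
               self.n_bins) <= 0:
            raise ValueError("counts must be positive")
        if not (0 < self.grid_interval_min <= self.grid_interval_max):
            raise ValueError("invalid grid interval range")
        grid = self.grid()
        lo = self.wt_birth_mean * (1 - 2 * self.wt_birth_cv)
        hi = self.wt_birth_mean * (1 + 2 * self.wt_birth_cv)
        if int(np.count_nonzero((grid >= lo) & (grid <= hi))) < 10:
            raise ValueError("grid too coarse: need >= 10 bins across "
                             "+/- 2 SD of the wild-type birth size")

    def grid(self) -> np.ndarray:
        """Channel sizes: intervals ramp linearly from the minimum to the
        maximum printed instrument interval (deterministic, so closed-form
        checks against the generating model stay reproducible)."""
        intervals = np.linspace(self.grid_interval_min,
                                self.grid_interval_max, self.n_bins - 1)
        return self.grid_start + np.concatenate(([0.0], np.cumsum(intervals)))

    @property
    def daughter_sigma(self) -> float:
        """Log-SD of the daughter component: growth spread from birth to
        budding (ln r / 4, so +/-2 sigma spans one doubling interval)
        combined with the per-cell birth-size CV."""
        return math.hypot(math.log(self.budding_ratio) / 4.0,
                          math.log1p(self.wt_birth_cv))

    @property
    def mother_sigma(self) -> float:
        """Mothers are an age mixture spanning many past cycles, so their
        size spread is wider than the daughters'; the broader right
        component keeps the histogram unimodal with its mode at the
        daughter peak, the shape the left-of-mode partition assumes."""
        return 1.8 * self.daughter_sigma

    def daughter_median(self, b: float) -> float:
        return b * math.sqrt(self.budding_ratio)

    def mother_median(self, b: float) -> float:
        return self.mother_daughter_ratio * b

    def analytic_mean_size(self, b: float) -> float:
        """Expected cell size of the generating mixture for birth size b."""
        w = self.daughter_fraction
        ed = self.daughter_median(b) * math.exp(self.daughter_sigma ** 2 / 2)
        em = self.mother_median(b) * math.exp(self.mother_sigma ** 2 / 2)
        return w * ed + (1 - w) * em


@dataclass(frozen=True)
class GroundTruth:
    """Per-strain generating truth for scoring recovery."""

    df: pd.DataFrame  # orf, role, true_b, true_label, birth_effect,
    #                   g1_shift, fitness_shift, true_mean_size,
    #                   true_g1, true_fitness
    wt_birth_mean: float

    def label_of(self, orf: str) -> str:
        return str(self.df.set_index("orf").loc[orf, "true_label"])


def make_planted_spec(
    n_mutants: int = 500,
    frac_small: float = 0.05,
    small_effect: float = 0.75,
    frac_large: float = 0.05,
    large_effect: float = 1.3,
    g1_shift: float = 0.0,
    fitness_shift: int = 0,
    **overrides,
) -> SyntheticPanelSpec:
    """Convenience spec with the first ``frac_small`` of mutants planted
    small and the next ``frac_large`` planted large."""
    ns = round(frac_small * n_mutants)
    nl = round(frac_large * n_mutants)
    planted = tuple(
        PlantedEffect(_mutant_orf(i), small_effect, g1_shift, fitness_shift)
        for i in range(ns)
    ) + tuple(
        PlantedEffect(_mutant_orf(ns + i), large_effect, 0.0, fitness_shift)
        for i in range(nl)
    )
    return SyntheticPanelSpec(n_mutants=n_mutants, planted=planted,
                              **overrides)


def _mutant_orf(i: int) -> str:
    return f"SYN{i + 1:04d}"


def _wildtype_orf(i: int) -> str:
    return f"WT{i + 1:02d}"


def _bin_edges(grid: np.ndarray) -> np.ndarray:
    mid = (grid[:-1] + grid[1:]) / 2.0
    first = grid[0] - (grid[1] - grid[0]) / 2.0
    last = grid[-1] + (grid[-1] - grid[-2]) / 2.0
    return np.concatenate(([first], mid, [last]))


def _strain_counts(spec: SyntheticPanelSpec, b: float, grid: np.ndarray,
                   edges: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n_d = int(rng.binomial(spec.cells_per_strain, spec.daughter_fraction))
    n_m = spec.cells_per_strain - n_d
    daughters = rng.lognormal(math.log(spec.daughter_median(b)),
                              spec.daughter_sigma, n_d)
    mothers = rng.lognormal(math.log(spec.mother_median(b)),
                            spec.mother_sigma, n_m)
    sizes = np.concatenate([daughters, mothers])
    counts, _ = np.histogram(sizes, bins=edges)
    counts = counts.astype(float)
    if spec.noise_rate > 0:
        cutoff = spec.daughter_median(b) * math.exp(
            spec.daughter_sigma * stats.norm.ppf(0.001))
        low = np.flatnonzero(grid < cutoff)
        if low.size:
            counts[low] += rng.poisson(spec.noise_rate / low.size,
                                       size=low.size)
    return counts


def generate_panel(
    spec: SyntheticPanelSpec,
    seed: int | None = None,
) -> tuple[list[StrainRecord], GroundTruth]:
    """Simulate a full panel (wild-type replicates first, then mutants),
    with linked phenotypes already joined onto the records."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    grid = spec.grid()
    edges = _bin_edges(grid)
    planted = {p.orf: p for p in spec.planted}
    unknown = set(planted) - {_mutant_orf(i) for i in range(spec.n_mutants)}
    if unknown:
        raise ValueError(f"planted orfs outside the panel: {sorted(unknown)}")

    records: list[StrainRecord] = []
    rows = []
    for i in range(spec.n_wildtype):
        orf = _wildtype_orf(i)
        b = spec.wt_birth_mean * math.exp(
            rng.normal(0.0, math.log1p(spec.replicate_cv)))
        counts = _strain_counts(spec, b, grid, edges, rng)
        records.append(StrainRecord(orf, ROLE_WILD_TYPE,
                                    SizeDistribution(grid, counts)))
        rows.append({"orf": orf, "role": ROLE_WILD_TYPE, "true_b": b,
                     "true_label": "normal", "birth_effect": 1.0,
                     "g1_shift": 0.0, "fitness_shift": 0})
    for i in range(spec.n_mutants):
        orf = _mutant_orf(i)
        effect = planted.get(orf, PlantedEffect(orf))
        b = spec.wt_birth_mean * math.exp(
            rng.normal(0.0, math.log1p(spec.strain_cv))) * effect.birth_effect
        counts = _strain_counts(spec, b, grid, edges, rng)
        records.append(StrainRecord(orf, ROLE_MUTANT,
                                    SizeDistribution(grid, counts)))
        rows.append({"orf": orf, "role": ROLE_MUTANT, "true_b": b,
                     "true_label": effect.true_label,
                     "birth_effect": effect.birth_effect,
                     "g1_shift": effect.g1_shift,
                     "fitness_shift": effect.fitness_shift})
    truth = GroundTruth(df=pd.DataFrame(rows),
                        wt_birth_mean=spec.wt_birth_mean)
    phenotypes, truth = phenotype_link(truth, spec.link, spec=spec, rng=rng)
    return join_panel(records, phenotypes), truth


def phenotype_link(
    truth: GroundTruth,
    link: LinkSpec | None = None,
    spec: SyntheticPanelSpec | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[list[PhenotypeRecord], GroundTruth]:
    """Generate phenotypes tied to the generating truth.

    Only planted-small strains carry the %G1-vs-birth-size link (their
    %G1 rises with the birth-size deficit); all other strains sit at
    baseline, so unplanted strains probe false-positive behaviour.
    Birth-size outliers (small or large) take the fitness penalty.
    Returns the records plus the truth updated with the realised values.
    """
    link = link or LinkSpec()
    spec = spec or SyntheticPanelSpec()
    rng = np.random.default_rng(rng)
    out: list[PhenotypeRecord] = []
    realised_g1, realised_fit, realised_mean = [], [], []
    for row in truth.df.itertuples():
        b = float(row.true_b)
        mean_size = spec.analytic_mean_size(b) + rng.normal(
            0.0, link.mean_size_noise_sd)
        g1 = link.g1_baseline
        if row.true_label == "small":
            g1 += link.g1_slope * (truth.wt_birth_mean - b)
        g1 += float(row.g1_shift) + rng.normal(0.0, link.g1_noise_sd)
        g1 = float(np.clip(g1, 0.0, 100.0))
        rank = 1 + int(rng.poisson(link.fitness_base_lambda))
        if row.true_label != "normal":
            rank += link.fitness_penalty
        rank += int(row.fitness_shift)
        rank = int(np.clip(rank, 1, 21))
        out.append(PhenotypeRecord(orf=row.orf,
                                   mean_size_published=float(mean_size),
                                   fitness_rank=rank, pct_g1=g1))
        realised_mean.append(float(mean_size))
        realised_g1.append(g1)
        realised_fit.append(rank)
    df = truth.df.assign(true_mean_size=realised_mean, true_g1=realised_g1,
                         true_fitness=realised_fit)
    return out, replace(truth, df=df)


# --- closed-form reference on the generating mixture ----------------------

def mixture_cdf(x, spec: SyntheticPanelSpec, b: float):
    """CDF of the (unbinned) generating size mixture for birth size b."""
    w = spec.daughter_fraction
    d = stats.lognorm(spec.daughter_sigma,
                      scale=spec.daughter_median(b)).cdf(x)
    m = stats.lognorm(spec.mother_sigma, scale=spec.mother_median(b)).cdf(x)
    return w * d + (1 - w) * m


def mixture_pdf(x, spec: SyntheticPanelSpec, b: float):
    w = spec.daughter_fraction
    d = stats.lognorm(spec.daughter_sigma,
                      scale=spec.daughter_median(b)).pdf(x)
    m = stats.lognorm(spec.mother_sigma, scale=spec.mother_median(b)).pdf(x)
    return w * d + (1 - w) * m


def analytic_birth_size(spec: SyntheticPanelSpec, b: float,
                        cutoff: float = 0.20) -> float:
    """The generating mixture's q-of-daughter-mass point: the size x at
    which the mixture CDF reaches ``cutoff`` times its value at the
    mixture mode — the continuous analogue of the binned birth size."""
    lo = spec.daughter_median(b) * 0.25
    hi = spec.mother_median(b) * 2.0
    res = optimize.minimize_scalar(lambda x: -mixture_pdf(x, spec, b),
                                   bounds=(lo, hi), method="bounded")
    mode = float(res.x)
    target = cutoff * float(mixture_cdf(mode, spec, b))
    return float(optimize.brentq(
        lambda x: mixture_cdf(x, spec, b) - target, lo * 1e-3, mode))
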