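"""Reading, validating and writing binned cell-size panels.

A panel is a bins-by-strains count matrix: one shared grid of Coulter
channelyzer channel sizes (femtoliters, strictly increasing, non-uniform
spacing) and one column of counts per strain, plus an optional per-strain
phenotype table (published mean size, fitness rank, %G1 DNA content).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ROLE_MUTANT = "mutant"
ROLE_WILD_TYPE = "wild_type"


class PanelFormatError(ValueError):
    """Raised when an on-disk panel violates the format contract."""


@dataclass(frozen=True)
class SizeDistribution:
    """One strain's binned size histogram.

    ``bin_sizes`` are representative channel sizes in fl (not edges); the
    interval to the neighbouring channel defines the bin-granularity error
    bound of any parameter read off the histogram.
    """

    bin_sizes: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        bins = np.asarray(self.bin_sizes, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "bin_sizes", bins)
        object.__setattr__(self, "counts", counts)
        if bins.ndim != 1 or counts.ndim != 1 or bins.size != counts.size:
            raise ValueError("bin_sizes and counts must be 1-D and equal length")
        if bins.size < 3:
            raise ValueError("a size distribution needs at least 3 bins")
        if not np.all(np.diff(bins) > 0):
            raise PanelFormatError("bin sizes must be strictly increasing")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return int(self.bin_sizes.size)

    @property
    def total_count(self) -> float:
        return float(self.counts.sum())

    @property
    def is_empty(self) -> bool:
        return self.total_count == 0.0

    def frequencies(self) -> np.ndarray:
        """Counts normalised to sum 1 over the full channel range."""
        total = self.total_count
        if total == 0:
            raise ValueError("cannot normalise an all-zero distribution")
        return self.counts / total

    def bin_interval(self, index: int) -> float:
        """Local grid interval x_{p+1} - x_p at channel ``index``.

        The last channel has no successor; its error bound uses the
        preceding interval instead.
        """
        if index < 0:
            index += self.n_bins
        if index >= self.n_bins - 1:
            return float(self.bin_sizes[-1] - self.bin_sizes[-2])
        return float(self.bin_sizes[index + 1] - self.bin_sizes[index])

    def index_of(self, size: float) -> int:
        idx = int(np.searchsorted(self.bin_sizes, size))
        if idx >= self.n_bins or self.bin_sizes[idx] != size:
            raise KeyError(f"{size} is not a bin of this grid")
        return idx


@dataclass(frozen=True)
class PhenotypeRecord:
    """Published per-strain phenotypes; any field but the ORF may be missing."""

    orf: str
    mean_size_published: float | None = None  # fl
    fitness_rank: int | None = None  # 1 (most fit) .. 21 (least fit)
    pct_g1: float | None = None  # percent of cells with 1C DNA content

    def __post_init__(self) -> None:
        if not self.orf:
            raise ValueError("orf must be non-empty")
        if self.fitness_rank is not None and not 1 <= self.fitness_rank <= 21:
            raise ValueError(f"fitness_rank {self.fitness_rank} outside [1, 21]")
        if self.pct_g1 is not None and not 0 <= self.pct_g1 <= 100:
            raise ValueError(f"pct_g1 {self.pct_g1} outside [0, 100]")


@dataclass
class StrainRecord:
    """One strain of a panel: identity, histogram, phenotypes, parameters."""

    orf: str
    role: str  # ROLE_MUTANT or ROLE_WILD_TYPE
    distribution: SizeDistribution
    phenotypes: PhenotypeRecord | None = None
    params: "object | None" = None  # DistributionParameters, filled by params
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.orf:
            raise ValueError("orf must be non-empty")
        if self.role not in (ROLE_MUTANT, ROLE_WILD_TYPE):
            raise ValueError(f"unknown role {self.role!r}")

    @property
    def is_wild_type(self) -> bool:
        return self.role == ROLE_WILD_TYPE


@dataclass(frozen=True)
class GridReport:
    """Integrity summary of a shared bin grid."""

    n_bins: int
    min_interval: float  # fl
    max_interval: float  # fl


def _read_table(source: str | Path, sheet: str | int | None = None) -> pd.DataFrame:
    path = Path(source)
    suffix = path.suffix.lower()
    if suffix in (".xlsx", ".xlsm"):
        return pd.read_excel(path, sheet_name=sheet if sheet is not None else 0,
                             header=None)
    sep = "\t" if suffix in (".tsv", ".tab", ".txt") else ","
    return pd.read_csv(path, sep=sep, header=None, dtype=str,
                       skip_blank_lines=True)


def read_distribution_matrix(
    source: str | Path,
    layout: str = "bins_in_rows",
    wildtype_ids: Iterable[str] = (),
    sheet: str | int | None = None,
) -> list[StrainRecord]:
    """Read a bins-by-strains count matrix into StrainRecords.

    The canonical layout has bins in rows: first column ``bin_fl`` holds
    the channel sizes, remaining columns one strain each, named by ORF in
    the header row.  ``layout='bins_in_columns'`` accepts the transpose.
    An XLSX source (e.g. a supplementary "asynchronous" sheet with the
    same shape) is read via ``sheet``.

    Strains named in ``wildtype_ids`` get the wild-type role.  All-zero
    strain columns are kept but flagged ``all_zero``.
    """
    if layout not in ("bins_in_rows", "bins_in_columns"):
        raise ValueError(f"unknown layout {layout!r}")
    raw = _read_table(source, sheet=sheet)
    if layout == "bins_in_columns":
        raw = raw.T.reset_index(drop=True)
    header = [str(v).strip() for v in raw.iloc[0]]
    strain_ids = header[1:]
    if len(strain_ids) != len(set(strain_ids)):
        seen: set[str] = set()
        dupes = {s for s in strain_ids if s in seen or seen.add(s)}  # type: ignore[func-returns-value]
        raise PanelFormatError(f"duplicate strain identifiers: {sorted(dupes)}")
    body = raw.iloc[1:]
    try:
        values = body.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise PanelFormatError(f"non-numeric cell in {source}: {exc}") from None
    if np.isnan(values).any():
        raise PanelFormatError(f"non-numeric or empty cell in {source}")
    bins = values[:, 0]
    if not np.all(np.diff(bins) > 0):
        raise PanelFormatError("bin-size column is not strictly increasing")
    wt = set(wildtype_ids)
    records: list[StrainRecord] = []
    for j, orf in enumerate(strain_ids, start=1):
        counts = values[:, j]
        rec = StrainRecord(
            orf=orf,
            role=ROLE_WILD_TYPE if orf in wt else ROLE_MUTANT,
            distribution=SizeDistribution(bins, counts),
        )
        if rec.distribution.is_empty:
            rec.flags.append("all_zero")
            logger.warning("strain %s has an all-zero count column", orf)
        records.append(rec)
    return records


def write_distribution_matrix(records: Sequence[StrainRecord],
                              path: str | Path) -> None:
    """Write records back to the canonical bins-in-rows TSV/CSV layout."""
    if not records:
        raise ValueError("nothing to write")
    bins = records[0].distribution.bin_sizes
    data = {"bin_fl": bins}
    for rec in records:
        if not np.array_equal(rec.distribution.bin_sizes, bins):
            raise PanelFormatError("records do not share a bin grid")
        data[rec.orf] = rec.distribution.counts
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    pd.DataFrame(data).to_csv(path, sep=sep, index=False)


DEFAULT_COLUMN_MAP = {
    "orf": "orf",
    "mean_size": "mean_size",
    "fitness_rank": "fitness_rank",
    "pct_g1": "pct_g1",
}


def read_phenotype_table(
    source: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[PhenotypeRecord]:
    """Read a per-strain phenotype table (TSV/CSV with header).

    ``column_map`` maps the canonical names ``orf``, ``mean_size``,
    ``fitness_rank``, ``pct_g1`` to the file's column names; only ``orf``
    is required.  Blank cells are missing values.  Rows whose fitness or
    %G1 fall outside the valid ranges are rejected with a logged
    diagnostic rather than aborting the read.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    path = Path(source)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    if cmap["orf"] not in df.columns:
        raise PanelFormatError(f"required column {cmap['orf']!r} not found")

    def _get(row: pd.Series, key: str) -> float | None:
        col = cmap.get(key)
        if col is None or col not in df.columns:
            return None
        val = row[col]
        if pd.isna(val) or (isinstance(val, str) and not val.strip()):
            return None
        return float(val)

    records: list[PhenotypeRecord] = []
    for i, row in df.iterrows():
        fitness = _get(row, "fitness_rank")
        try:
            records.append(PhenotypeRecord(
                orf=str(row[cmap["orf"]]).strip(),
                mean_size_published=_get(row, "mean_size"),
                fitness_rank=int(fitness) if fitness is not None else None,
                pct_g1=_get(row, "pct_g1"),
            ))
        except ValueError as exc:
            logger.warning("phenotype row %d rejected: %s", i, exc)
    return records


def write_phenotype_table(records: Sequence[PhenotypeRecord],
                          path: str | Path) -> None:
    rows = [
        {
            "orf": r.orf,
            "mean_size": r.mean_size_published,
            "fitness_rank": r.fitness_rank,
            "pct_g1": r.pct_g1,
        }
        for r in records
    ]
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def join_panel(
    distributions: Sequence[StrainRecord],
    phenotypes: Sequence[PhenotypeRecord],
) -> list[StrainRecord]:
    """Left-join phenotype records onto strain records by ORF.

    Unmatched phenotypes are reported (not errors); a duplicated ORF in
    the phenotype table violates the key contract and is a hard error.
    """
    by_orf: dict[str, PhenotypeRecord] = {}
    for p in phenotypes:
        if p.orf in by_orf:
            raise PanelFormatError(f"duplicate orf in phenotype table: {p.orf}")
        by_orf[p.orf] = p
    joined: list[StrainRecord] = []
    n_match = 0
    for rec in distributions:
        phen = by_orf.pop(rec.orf, None)
        if phen is not None:
            n_match += 1
        joined.append(replace_phenotypes(rec, phen))
    logger.info("join_panel: %d/%d strains matched a phenotype row; "
                "%d phenotype rows unmatched", n_match, len(distributions),
                len(by_orf))
    if by_orf:
        logger.warning("unmatched phenotype orfs: %s",
                       ", ".join(sorted(by_orf)[:10]))
    return joined


def replace_phenotypes(rec: StrainRecord,
                       phen: PhenotypeRecord | None) -> StrainRecord:
    return StrainRecord(orf=rec.orf, role=rec.role,
                        distribution=rec.distribution, phenotypes=phen,
                        params=rec.params, flags=list(rec.flags))


def validate_bin_grid(records: Sequence[StrainRecord]) -> GridReport:
    """Report the shared grid's bin count and extreme successive intervals."""
    if not records:
        raise ValueError("empty panel")
    bins = records[0].distribution.bin_sizes
    for rec in records[1:]:
        if not np.array_equal(rec.distribution.bin_sizes, bins):
            raise PanelFormatError("records do not share a bin grid")
    intervals = np.diff(bins)
    return GridReport(n_bins=int(bins.size),
                      min_interval=float(intervals.min()),
                      max_interval=float(intervals.max()))
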