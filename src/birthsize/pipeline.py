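"""End-to-end orchestration: ingest (or simulate) -> parameters ->
categories -> associations, with a reproducible run manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from . import association, categories, distio, params, synthdata

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration (caught before any stage runs)."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """One pipeline run: either measured input files or a simulation spec.

    Exactly one of ``distributions_path`` / ``simulation`` must be set.
    """

    out_dir: str | Path = "birthsize_run"
    distributions_path: str | Path | None = None
    phenotypes_path: str | Path | None = None
    wildtype_ids: tuple[str, ...] = ()
    column_map: Mapping[str, str] | None = None
    simulation: synthdata.SyntheticPanelSpec | None = None
    support: params.SupportConfig = field(default_factory=params.SupportConfig)
    cutoffs: tuple[float, ...] = params.DEFAULT_CUTOFFS
    category_cutoff: float = 0.20
    schemes: tuple[str, ...] = (categories.SCHEME_WT_SD,
                                categories.SCHEME_QUANTILE)
    tail: float = 0.05
    phenotypes: tuple[str, ...] = association.PHENOTYPES
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        has_files = self.distributions_path is not None
        has_sim = self.simulation is not None
        if has_files == has_sim:
            raise ConfigError("exactly one of distributions_path and "
                              "simulation must be given")
        for s in self.schemes:
            if s not in (categories.SCHEME_WT_SD, categories.SCHEME_QUANTILE):
                raise ConfigError(f"unknown scheme {s!r}")
        if self.category_cutoff not in self.cutoffs:
            raise ConfigError("category_cutoff must be one of cutoffs")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        kwargs = dict(raw)
        if "simulation" in kwargs and kwargs["simulation"] is not None:
            sim = dict(kwargs["simulation"])
            planted = tuple(synthdata.PlantedEffect(**p)
                            for p in sim.pop("planted", []))
            link = synthdata.LinkSpec(**sim.pop("link", {}))
            kwargs["simulation"] = synthdata.SyntheticPanelSpec(
                planted=planted, link=link, **sim)
        if "support" in kwargs and kwargs["support"] is not None:
            sup = dict(kwargs["support"])
            sup["exclusion_list"] = frozenset(sup.get("exclusion_list", ()))
            sup["manual_overrides"] = {
                k: tuple(v) for k, v in sup.get("manual_overrides", {}).items()
            }
            kwargs["support"] = params.SupportConfig(**sup)
        for key in ("wildtype_ids", "cutoffs", "schemes", "phenotypes"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(_jsonable(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in sorted(obj.items())}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj


def _ingest(cfg: RunConfig) -> list[distio.StrainRecord]:
    if cfg.simulation is not None:
        records, _truth = synthdata.generate_panel(cfg.simulation,
                                                   seed=cfg.seed)
        return records
    records = distio.read_distribution_matrix(
        cfg.distributions_path, wildtype_ids=cfg.wildtype_ids)
    if cfg.phenotypes_path is not None:
        phen = distio.read_phenotype_table(cfg.phenotypes_path,
                                           column_map=cfg.column_map)
        records = distio.join_panel(records, phen)
    return records


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Execute all stages, write the output tables and return the manifest.

    Any stage failure writes a FAILED marker (partial outputs are kept)
    and re-raises as StageError with the stage name.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    manifest: dict[str, Any] = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "outputs": {},
        "counts": {},
    }
    stage = "ingest"
    try:
        records = _ingest(cfg)
        manifest["counts"]["ingested"] = len(records)
        manifest["counts"]["wild_type"] = sum(r.is_wild_type for r in records)

        stage = "params"
        params.extract_panel(records, cfg=cfg.support, cutoffs=cfg.cutoffs)
        qc = params.qc_summary(records)
        manifest["counts"].update(
            qc_pass=qc[params.QC_PASS], abnormal=qc[params.QC_ABNORMAL],
            manual_excluded=qc[params.QC_MANUAL_EXCLUDED])
        ptable = params.params_table(records, cutoffs=cfg.cutoffs)
        ppath = out / "params.tsv"
        ptable.to_csv(ppath, sep="\t", index=False)
        manifest["outputs"]["params"] = str(ppath)

        stage = "categorize"
        assignments: dict[str, list[categories.CategoryAssignment]] = {}
        if categories.SCHEME_WT_SD in cfg.schemes:
            ref = categories.wt_reference(records, cutoff=cfg.category_cutoff)
            manifest["wt_reference"] = {"mu_wt": ref.mu_wt, "sd_wt": ref.sd_wt,
                                        "n_wt": ref.n_wt}
            assignments[categories.SCHEME_WT_SD] = categories.categorize_wt_sd(
                records, ref)
        if categories.SCHEME_QUANTILE in cfg.schemes:
            assignments[categories.SCHEME_QUANTILE] = (
                categories.categorize_quantile(records, tail=cfg.tail,
                                               cutoff=cfg.category_cutoff))
        all_assign = [a for sub in assignments.values() for a in sub]
        cpath = out / "categories.tsv"
        categories.assignments_table(all_assign).to_csv(cpath, sep="\t",
                                                        index=False)
        manifest["outputs"]["categories"] = str(cpath)

        stage = "associate"
        assoc_results = []
        comparison_results = []
        for scheme, assign in assignments.items():
            for phenotype in cfg.phenotypes:
                assoc_results.extend(association.per_category_association(
                    records, assign, phenotype))
                comparison_results.extend(association.group_mean_comparison(
                    records, assign, phenotype))
        apath = out / "associations.tsv"
        association.associations_table(assoc_results).to_csv(
            apath, sep="\t", index=False)
        gpath = out / "group_comparisons.tsv"
        association.comparisons_table(comparison_results).to_csv(
            gpath, sep="\t", index=False)
        manifest["outputs"]["associations"] = str(apath)
        manifest["outputs"]["group_comparisons"] = str(gpath)
    except (ValueError, OSError, RuntimeError) as exc:
        failed_marker.write_text(f"stage: {stage}\nerror: {exc}\n")
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
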