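"""End-to-end orchestration: config, staging, logging, result tables.

A run is described by a YAML config (see :class:`RunConfig`). Inputs are
either files (panel directory, study TSVs) or a simulation scenario; every
run writes its resolved configuration, the fitted basis, projection tables,
a Newick dendrogram of projected traits and a machine-readable JSON summary
into one output directory. Runs are deterministic given the seed and never
mutate their inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

import gwasbasis
from gwasbasis.association import cluster_traits
from gwasbasis.basis import build_basis, save_basis
from gwasbasis.harmonise import (MHC_GRCH37, align_to_panel, filter_panel,
                                 intersect_studies, load_panel,
                                 load_summary_stats, read_bed_mask)
from gwasbasis.projection import flag_significant, project_study
from gwasbasis.shrinkage import ShrinkagePrior, compute_weights
from gwasbasis.simulate import (SimulationScenario, simulate_panel,
                                simulate_traits)

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_CONFIG_ERROR = 2
EXIT_DATA_ERROR = 3


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    out: str = "run"
    seed: int = 0
    mode: str = "continuous"
    prior_W: float = 0.04
    tol: float = 1e-3
    maf_min: float = 0.01
    mask: str | None = "mhc"
    overall_fdr: float = 0.01
    component_fdr: float = 0.01
    ssfdr: float = 0.01
    consistency_r2: float = 0.01
    prune_r2: float = 0.1
    n_perm: int = 10_000
    panel: str | None = None
    studies: list = field(default_factory=list)
    project: list = field(default_factory=list)
    simulate: dict | None = None

    def __post_init__(self) -> None:
        for name in ("overall_fdr", "component_fdr", "ssfdr",
                     "consistency_r2", "prune_r2", "tol"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigError(f"{name} must lie in (0, 1), got {v}")
        if self.panel is None and self.simulate is None:
            raise ConfigError("config needs either a panel path or a "
                              "simulate scenario")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _mask_intervals(cfg: RunConfig):
    if cfg.mask is None:
        return []
    if cfg.mask == "mhc":
        return [MHC_GRCH37]
    return read_bed_mask(cfg.mask)


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute harmonise -> shrink -> build -> project -> cluster."""
    out = Path(cfg.out)
    out.mkdir(parents=True, exist_ok=True)
    (out / "resolved_config.yaml").write_text(
        yaml.safe_dump({"gwasbasis_version": gwasbasis.__version__,
                        **asdict(cfg)}, sort_keys=True))
    summary: dict = {"version": gwasbasis.__version__, "seed": cfg.seed}

    if cfg.simulate is not None:
        scenario = SimulationScenario(seed=cfg.seed, **cfg.simulate)
        rng = np.random.default_rng(cfg.seed)
        panel = simulate_panel(scenario, rng)
        studies, _ = simulate_traits(scenario, panel, rng)
    else:
        panel_path = Path(cfg.panel)
        if not panel_path.exists():
            raise ConfigError(f"panel path does not exist: {panel_path}")
        panel = load_panel(panel_path)
        studies = [load_summary_stats(p) for p in cfg.studies]
    if len(studies) < 2:
        raise ConfigError("need at least two basis studies")

    n0 = panel.n_variants
    panel = filter_panel(panel, maf_min=cfg.maf_min,
                         exclude=_mask_intervals(cfg))
    logger.info("panel: %d variants kept of %d after MAF/mask filters",
                panel.n_variants, n0)
    summary["panel_variants"] = panel.n_variants

    aligned = [align_to_panel(ss, panel) if not ss.aligned else ss
               for ss in studies]
    shared = intersect_studies(aligned)
    summary["shared_variants"] = len(shared)
    panel = panel.subset(shared)
    aligned = [_restrict(ss, shared) for ss in aligned]

    prior = ShrinkagePrior(W=cfg.prior_W)
    weights = compute_weights(aligned, panel, prior)
    basis = build_basis(aligned, weights, mode=cfg.mode, tol=cfg.tol)
    save_basis(basis, out / "basis")
    summary["m"] = basis.m
    summary["traits"] = basis.traits

    to_project = []
    for item in cfg.project:
        if isinstance(item, str):
            item = {"path": item}
        ss = load_summary_stats(item["path"])
        ss = align_to_panel(ss, panel)
        ss = _restrict(ss, shared)
        to_project.append((ss, item.get("category", "default")))
    if cfg.simulate is not None and not to_project:
        # project the training traits back for the smoke-level run
        to_project = [(ss, "training") for ss in aligned]

    projections = [project_study(basis, ss, panel, category=cat)
                   for ss, cat in to_project]
    table = flag_significant(projections, cfg.overall_fdr, cfg.component_fdr)
    table.to_csv(out / "projections.tsv", sep="\t", index=False,
                 float_format="%.10g")
    if len(projections) >= 2:
        _, _, nwk = cluster_traits(projections)
        (out / "clusters.nwk").write_text(nwk + "\n")
    summary["projected"] = [pr.trait_id for pr in projections]
    summary["significant_overall"] = sorted(
        {pr.trait_id for pr in projections
         if pr.fdr_overall is not None and pr.fdr_overall < cfg.overall_fdr})
    (out / "summary.json").write_text(json.dumps(summary, indent=1,
                                                 sort_keys=True) + "\n")
    return out


def _restrict(ss, shared):
    from dataclasses import replace
    return replace(ss, data=ss.data.loc[shared])
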