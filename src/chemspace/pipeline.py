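"""Pipeline orchestration: run every analysis stage and write a report bundle.

A :class:`RunConfig` names the inputs (substance table, optional weight and
discovery tables), the analysis window and parameters, and the output
directory.  :func:`run_pipeline` executes the stages in order, writes one
artifact per stage, and records a manifest (parameters, seeds, artifact
list, package version) for reproducibility.  Any stage failure aborts with
a stage-named error; the manifest then carries a FAILED marker for the
stage that broke.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .convergence import backbone, overlap_matrix, ubiquity
from .retrodiction import TAU_SWEEP, read_weight_tables, retro_score_sweep
from .similarity import network_to_json, sce_network, similarity_matrix, write_graphml
from .space import (
    ChemicalSpace,
    combination_counts,
    read_substances,
    year_stats,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


@dataclass
class RunConfig:
    """Inputs and parameters of one pipeline run."""

    substances: str | Path | None = None     # substance table path
    weight_tables: str | Path | None = None  # optional chemist weight tables
    discovery_table: str | Path | None = None
    out_dir: str | Path = "chemspace_out"
    window: tuple[int, int] | None = None
    backbone_threshold: float = 60.0
    ubiquity_sizes: Sequence[int] = tuple(range(5, 100, 5))
    ubiquity_reps: int = 100
    seed: int = 0
    taus: Sequence[float] = tuple(float(t) for t in TAU_SWEEP)
    network_years: Sequence[int] | None = None  # default: every year with data

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "window" in raw and raw["window"] is not None:
            raw["window"] = tuple(raw["window"])
        return cls(**raw)

    def validate(self) -> None:
        for label, p in (
            ("substances", self.substances),
            ("weight_tables", self.weight_tables),
            ("discovery_table", self.discovery_table),
        ):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{label} path does not exist: {p}")
        if self.seed is None:
            raise ValueError("a seed is mandatory for the stochastic stages")


def _read_discovery(path) -> dict[str, int]:
    frame = pd.read_csv(path, sep=None, engine="python")
    return {str(r.element): int(r.year) for r in frame.itertuples(index=False)}


def run_pipeline(config: RunConfig, space: ChemicalSpace | None = None) -> dict:
    """Run all stages on *space* (or the configured substance table).

    Returns the manifest dict; artifacts and ``manifest.json`` are written
    under ``config.out_dir``.  The retrodiction stage runs only when weight
    tables are configured; its absence is noted in the manifest.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "chemspace",
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "backbone_threshold": config.backbone_threshold,
            "ubiquity_sizes": list(config.ubiquity_sizes),
            "ubiquity_reps": config.ubiquity_reps,
            "taus": [float(t) for t in config.taus],
            "window": list(config.window) if config.window else None,
        },
        "artifacts": [],
    }

    def record(stage: str, path: Path, **extra) -> None:
        manifest["artifacts"].append(
            {"stage": stage, "path": path.name, "status": "OK", **extra}
        )

    stage = "load"
    try:
        if space is None:
            if config.substances is None:
                raise ValueError("no substance table configured and no space given")
            space = read_substances(config.substances, window=config.window)
        discovery = (
            _read_discovery(config.discovery_table) if config.discovery_table else None
        )
        logger.info("loaded %d substances over %s", len(space), space.window)

        stage = "stats"
        stats = year_stats(space, discovery)
        p = out / "year_stats.csv"
        stats.to_csv(p, index=False)
        record(stage, p, n_substances=len(space))

        stage = "combinations"
        p = out / "combination_counts.csv"
        combination_counts(space).to_csv(p, index=False)
        record(stage, p)

        stage = "sce"
        years = (
            list(config.network_years) if config.network_years else space.years()
        )
        networks = {}
        net_dir = out / "networks"
        net_dir.mkdir(exist_ok=True)
        for y in years:
            g = sce_network(space, y)
            networks[y] = g
            write_graphml(g, net_dir / f"sce_{y}.graphml")
            network_to_json(space, y, net_dir / f"sce_{y}.json")
        record(stage, net_dir, years=years)

        stage = "similarity_matrix"
        final = years[-1]
        p = out / f"similarity_matrix_{final}.csv"
        similarity_matrix(space, final).to_csv(p)
        record(stage, p, year=final)

        stage = "compare"
        p = out / "overlap_matrix.csv"
        # overlap is defined on the contiguous yearly sequence
        full_years = list(range(min(years), max(years) + 1))
        full_networks = {
            y: networks.get(y) or sce_network(space, y) for y in full_years
        }
        overlap_matrix(full_networks).to_csv(p)
        record(stage, p)

        stage = "backbone"
        edges = backbone(
            full_networks, threshold=config.backbone_threshold,
            end_year=max(full_years),
        )
        p = out / "backbone.csv"
        pd.DataFrame(
            [dataclasses.asdict(e) for e in edges],
            columns=["source", "target", "first_year", "frequency", "ubiquity_percent"],
        ).to_csv(p, index=False)
        record(stage, p, threshold=config.backbone_threshold, n_edges=len(edges))

        stage = "ubiquity"
        ub = ubiquity(
            space, max(full_years), sample_sizes=config.ubiquity_sizes,
            reps=config.ubiquity_reps, seed=config.seed,
        )
        p = out / f"ubiquity_seed{config.seed}.csv"
        ub.to_csv(p, index=False)
        record(stage, p, seed=config.seed, reps=config.ubiquity_reps)

        stage = "retrodict"
        if config.weight_tables:
            tables = read_weight_tables(config.weight_tables)
            frames = []
            for t in tables:
                yr = min(max(t.year, space.window[0] + 1), space.window[1])
                frames.append(retro_score_sweep(space, yr, t, taus=config.taus))
            p = out / "retro_scores.csv"
            pd.concat(frames, ignore_index=True).to_csv(p, index=False)
            record(stage, p, chemists=[t.chemist for t in tables])
        else:
            manifest["artifacts"].append(
                {"stage": stage, "path": None, "status": "SKIPPED",
                 "reason": "no weight tables configured"}
            )
    except Exception as exc:
        manifest["artifacts"].append(
            {"stage": stage, "path": None, "status": "FAILED", "error": str(exc)}
        )
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
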