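"""End-to-end pipeline: preprocess -> ladder -> sweep -> decision -> diagnostics.

Every stochastic stage draws from a sub-stream fanned out deterministically
from the master seed by ``(stage name, level, ...)`` keys, so the whole run
is a pure function of (inputs, config, master seed) and stages can be rerun
independently.  A manifest records the configuration, package version and a
SHA-256 checksum of every output file; rerunning with the same config and
seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .preprocess import preprocess, to_relative_abundance
from .rarefaction import build_ladder, dataset_coverage, rarefy_table
from .sweep import build_model_grid, evaluate_level, min_depth_for_target
from .diagnostics import separability_report
from .tables import AsvTable, ParameterError, write_asv_table

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "sweep_table"]

# stage keys for deterministic seed fan-out
_STAGE_RAREFY = 11
_STAGE_RF = 23
_STAGE_DIAG = 37


def _stage_seed(master_seed: int, stage: int, *extra: int) -> int:
    """Derive a bounded (< 2**31) sub-seed from the master seed and stage keys."""
    h = hashlib.sha256(
        ("/".join(map(str, (master_seed, stage) + extra))).encode()
    ).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of a full depth-benchmarking run."""

    min_asv_total: int = 50
    min_sample_depth: int = 15_000
    ladder_cap: int = 15_000
    n_trees: int = 6000
    mtry_offset_range: int = 3  # offsets -k..+k around the default mtry
    n_runs: int = 3
    gate: str = "median"  # "median" or "best" level summary gates the band
    run_diagnostics: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_asv_total", "min_sample_depth", "ladder_cap", "n_trees"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.n_runs < 1 or self.mtry_offset_range < 0:
            raise ParameterError("bad grid settings")


@dataclass
class PipelineResult:
    table: AsvTable  # the filtered table the models saw
    ladder: list[int]
    full_result: object
    ladder_results: list
    decision: object
    coverage: dict  # per-level dataset coverage (depth -> dict)
    separability: object | None
    records: pd.DataFrame  # all model records, all levels


def sweep_table(
    table: AsvTable, config: PipelineConfig
) -> PipelineResult:
    """Run the full sweep on an already-loaded table (no file I/O)."""
    filtered = preprocess(table, config.min_asv_total, config.min_sample_depth)
    ladder = build_ladder(filtered, cap=config.ladder_cap)
    offsets = range(-config.mtry_offset_range, config.mtry_offset_range + 1)
    grid = build_model_grid(
        filtered.n_asvs,
        offsets=offsets,
        n_runs=config.n_runs,
        base_seed=_stage_seed(config.seed, _STAGE_RF, 0),
        n_trees=config.n_trees,
    )
    logger.info(
        "sweep: %d samples, %d ASVs, ladder %s, grid of %d configs",
        filtered.n_samples, filtered.n_asvs, list(ladder), len(grid),
    )
    full_result = evaluate_level(filtered, grid, depth_level="full")
    coverage = {"full": dataset_coverage(filtered)}
    ladder_results = []
    for level in ladder:
        rarefied = rarefy_table(
            filtered, level, seed=_stage_seed(config.seed, _STAGE_RAREFY, level)
        )
        coverage[level] = dataset_coverage(rarefied)
        ladder_results.append(evaluate_level(rarefied, grid, depth_level=level))
        logger.info(
            "level %d: median kappa %.3f, mean OOB error %.3f",
            level, ladder_results[-1].median_kappa, ladder_results[-1].mean_oob_error,
        )
    decision = min_depth_for_target(full_result, ladder_results, gate=config.gate)
    separability = (
        separability_report(
            filtered, seed=_stage_seed(config.seed, _STAGE_DIAG)
        )
        if config.run_diagnostics
        else None
    )
    records = pd.concat(
        [full_result.to_frame()] + [r.to_frame() for r in ladder_results],
        ignore_index=True,
    )
    return PipelineResult(
        table=filtered,
        ladder=list(ladder),
        full_result=full_result,
        ladder_results=ladder_results,
        decision=decision,
        coverage=coverage,
        separability=separability,
        records=records,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    table: AsvTable, config: PipelineConfig, out_dir: str | Path
) -> PipelineResult:
    """Run the sweep and write the report bundle to ``out_dir``.

    Outputs: filtered table TSVs, per-model records TSV, per-level summary
    TSV, coverage TSV, decision JSON, separability JSON (optional) and a
    manifest JSON with config, version and per-file checksums.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = sweep_table(table, config)

    write_asv_table(
        result.table, out / "filtered_counts.tsv", out / "filtered_metadata.tsv"
    )
    result.records.to_csv(out / "model_records.tsv", sep="\t", index=False)
    result.decision.levels.to_csv(out / "level_summary.tsv", sep="\t", index=False)
    cov_rows = [
        {"depth": depth, **stats} for depth, stats in result.coverage.items()
    ]
    pd.DataFrame(cov_rows).to_csv(out / "coverage.tsv", sep="\t", index=False)
    (out / "depth_decision.json").write_text(
        json.dumps(result.decision.to_dict(), indent=2, default=float) + "\n"
    )
    if result.separability is not None:
        (out / "separability.json").write_text(
            json.dumps(result.separability.to_dict(), indent=2, default=float) + "\n"
        )
    files = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "ampdepth_version": __version__,
        "config": dataclasses.asdict(config),
        "ladder": result.ladder,
        "outputs": {name: _sha256(out / name) for name in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return result
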