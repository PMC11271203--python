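"""Pipeline orchestration: dual regression -> GSR -> causality -> report.

Stages run in acquisition-processing order and every run writes a JSON
manifest with the package version, seed, parameters and SHA-256 hashes of
each stage's inputs and outputs, so identical inputs and seed provably yield
identical results.
"""

from __future__ import annotations

import hashlib
import json
import logging
from importlib.metadata import version, PackageNotFoundError
from pathlib import Path

from . import aggregate as agg_mod
from . import directionality, granger, gsr, io

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _hash_dir(paths) -> dict[str, str]:
    return {p.name: _sha256(p) for p in sorted(paths)}


def _package_version() -> str:
    try:
        return version("restcause")
    except PackageNotFoundError:
        return "unknown"


def run_pipeline(config: io.PipelineConfig) -> dict:
    """Run the enabled stages over TSV inputs and return the manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": _package_version(),
        "config": config.to_dict(),
        "stages": {},
    }

    if config.ts_dir is None:
        raise ValueError("config.ts_dir is required (directory of *_timeseries.tsv)")
    dataset = io.load_dataset(config.ts_dir)
    manifest["stages"]["input"] = {
        "hashes": _hash_dir(Path(config.ts_dir).glob("*_timeseries.tsv"))
    }

    if config.gsr:
        if config.gs_path is None:
            raise ValueError("GSR stage enabled but no gs_path given")
        gs_set = io.read_gs(config.gs_path)
        dataset = gsr.apply_gsr(dataset, gs_set)
        gsr_dir = out_dir / "gsr"
        io.save_dataset(gsr_dir, dataset)
        manifest["stages"]["gsr"] = {
            "hashes": _hash_dir(gsr_dir.glob("*_timeseries.tsv"))
        }

    matrices = None
    if config.gca:
        matrices = granger.fit_all_subjects(dataset, ridge_lambda=config.ridge_lambda)
        mats_dir = out_dir / "mats"
        mats_dir.mkdir(exist_ok=True)
        for m in matrices:
            io.write_matrix(
                mats_dir / f"{m.subject_id}_causality.tsv",
                m.coeffs,
                ridge=m.ridge_lambda,
            )
        manifest["stages"]["gca"] = {"hashes": _hash_dir(mats_dir.glob("*.tsv"))}

    scores = selection = None
    if config.aggregate:
        if matrices is None:
            raise ValueError("aggregate stage requires the gca stage")
        scores = agg_mod.aggregate_matrices(
            matrices, approach=config.approach, component_ids=dataset.component_ids
        )
        selection = agg_mod.select_top(scores, fraction=config.fraction, rule=config.rule)
        logger.info("selection cutoff %s (%d components)",
                    agg_mod.format_cutoff(selection), len(selection.selected))
        agg_dir = out_dir / "agg"
        agg_dir.mkdir(exist_ok=True)
        io.write_matrix(agg_dir / "aggregate.tsv", scores.agg_matrix)
        scores.scores_series().rename_axis("component_id").to_frame().assign(
            rank=lambda f: f["score"].rank(ascending=False, method="first").astype(int)
        ).to_csv(agg_dir / "scores.tsv", sep="\t")
        (agg_dir / "selection.json").write_text(
            json.dumps(
                {
                    "cutoff": selection.cutoff,
                    "rule": selection.rule,
                    "fraction": selection.fraction,
                    "selected": selection.selected,
                },
                indent=2,
            ),
            encoding="utf-8",
        )
        manifest["stages"]["aggregate"] = {"hashes": _hash_dir(agg_dir.glob("*"))}

    if config.report:
        if scores is None or selection is None:
            raise ValueError("report stage requires the aggregate stage")
        edge_table = directionality.build_edge_table(
            selection, scores, fraction=config.fraction, rule=config.rule
        )
        report_dir = out_dir / "report"
        report_dir.mkdir(exist_ok=True)
        edge_table.to_frame().to_csv(report_dir / "edges.tsv", sep="\t", index=False)
        edge_table.to_wide().to_csv(report_dir / "affected_wide.tsv", sep="\t")
        if config.labels_path:
            labels = io.read_labels(config.labels_path)
            summary = {
                "causal": directionality.summarize_by_class(
                    selection.selected, labels, scores=scores.scores_series()
                ).to_dict(orient="index"),
                "affected": directionality.summarize_by_class(
                    edge_table.affected, labels
                ).to_dict(orient="index"),
            }
            (report_dir / "class_summary.json").write_text(
                json.dumps(summary, indent=2), encoding="utf-8"
            )
        manifest["stages"]["report"] = {"hashes": _hash_dir(report_dir.glob("*"))}

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    return manifest
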