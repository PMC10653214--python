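"""End-to-end orchestration: ingest -> featurize -> metric -> cluster -> motifs.

Each stage writes its artifact into the run directory so every number in the
summary is recomputable from persisted intermediates; a manifest records all
resolved parameters, the seed, and library versions.  The single global seed
is fanned out to per-stage sub-seeds by a fixed hash-based derivation.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import math
from pathlib import Path

import numpy as np

from . import __version__
from .affinity import affinity_summary, affinity_vector, read_affinity_table
from .chemio import (
    ActivityLabel,
    filter_c3f6,
    filter_cf,
    read_molecule_table,
    write_molecule_table,
    write_reject_log,
)
from .config import PipelineConfig
from .embed_cluster import kmeans, pca, select_k, tsne
from .errors import ConfigError, DataError
from .featurize import augment_matrix, export_sparse_coo, fingerprint_matrix
from .metric_learning import build_constraints, fit_metric, save_model, transform
from .substructure import SubstructureReport, cluster_motif_report

logger = logging.getLogger(__name__)

__all__ = ["stage_seed", "run_pipeline"]


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage sub-seed from the global seed (stable across runs)."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


def _library_versions() -> dict[str, str]:
    import rdkit
    import sklearn

    return {
        "pfasqsar": __version__,
        "numpy": np.__version__,
        "rdkit": rdkit.__version__,
        "scikit-learn": sklearn.__version__,
    }


def _report_row(r: SubstructureReport) -> dict:
    return {
        "smarts": r.smarts,
        "n_match": r.n_match,
        "n_match_active": r.n_match_active,
        "bioactive_ratio": r.bioactive_ratio,
        "target": r.target,
        "source_cluster": r.source_cluster,
    }


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full workflow described by ``config``.

    Returns the run-artifact directory.  Stage errors propagate with the
    stage name prefixed; artifacts written before the failure are retained.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.seed)  # validated non-None
    target = config.target
    stage_counts: dict[str, dict[str, int]] = {}
    summary: dict = {"target": target, "seed": seed}

    def log_stage(name: str, n_in: int, n_out: int) -> None:
        stage_counts[name] = {"in": n_in, "out": n_out}
        logger.info("stage %-12s in=%d out=%d", name, n_in, n_out)

    stage = "ingest"
    try:
        result = read_molecule_table(config.input.molecules)
        records = result.records
        write_reject_log(result.rejects, outdir / "rejects.log")
        log_stage(stage, len(records) + len(result.rejects), len(records))
        summary["n_records"] = len(records)
        summary["n_rejects"] = len(result.rejects)
        summary["n_duplicate_smiles"] = len(result.duplicate_smiles)

        stage = "filter"
        n_before = len(records)
        if config.filter == "cf":
            records = filter_cf(records)
        elif config.filter == "c3f6":
            records = filter_c3f6(records)
        log_stage(stage, n_before, len(records))
        summary["n_after_filter"] = len(records)
        if not records:
            raise DataError("no records remain after filtering")
        write_molecule_table(records, outdir / "molecules.csv", targets=[target])

        stage = "featurize"
        X = fingerprint_matrix(records, n_bits=config.featurize.n_bits)
        affinity_table = None
        if config.input.affinities is not None:
            affinity_table = read_affinity_table(config.input.affinities)
        if config.featurize.use_affinity:
            assert affinity_table is not None
            values, present = affinity_vector(records, affinity_table, target)
            if not all(present):
                missing = len(present) - sum(present)
                raise DataError(
                    f"featurize: {missing} record(s) lack an affinity for {target!r}; "
                    "co-descriptor augmentation needs full coverage"
                )
            X, used_scale = augment_matrix(
                X, np.asarray(values), scale=config.featurize.affinity_scale
            )
            summary["affinity_scale"] = used_scale
        export_sparse_coo(X, outdir / "descriptors.coo.csv")
        log_stage(stage, len(records), X.shape[0])

        stage = "metric"
        constraints = build_constraints(
            records,
            target,
            max_pairs=config.metric.max_pairs,
            seed=stage_seed(seed, "pairs"),
        )
        model = fit_metric(
            X,
            constraints,
            d_out=min(config.metric.d_out, X.shape[1]),
            margin=config.metric.margin,
            learning_rate=config.metric.learning_rate,
            epochs=config.metric.epochs,
            batch_size=config.metric.batch_size,
            seed=stage_seed(seed, "metric"),
        )
        save_model(model, outdir / "metric_model.json")
        E = transform(model, X)
        log_stage(stage, len(constraints), E.shape[0])
        summary["metric_loss_initial"] = model.loss_trace[0]
        summary["metric_loss_final"] = model.loss_trace[-1]

        stage = "embed"
        n_comp = min(config.embed.pca_components, E.shape[0] - 1, E.shape[1])
        pca_result = pca(E, n_components=n_comp)
        cluster_X = pca_result.scores
        coords = None
        if config.embed.tsne:
            coords = tsne(
                pca_result.scores,
                perplexity=config.embed.perplexity,
                seed=stage_seed(seed, "tsne"),
            )
            if config.cluster.space == "tsne":
                cluster_X = coords
        log_stage(stage, E.shape[0], cluster_X.shape[0])
        summary["pca_components"] = n_comp
        summary["cluster_space"] = config.cluster.space

        stage = "cluster"
        if config.cluster.k is not None:
            assignment = kmeans(
                cluster_X,
                k=config.cluster.k,
                seed=stage_seed(seed, "kmeans"),
                n_init=config.cluster.n_init,
            )
        else:
            grid = config.cluster.k_grid or list(range(5, 61, 5))
            grid = [k for k in grid if 2 <= k <= cluster_X.shape[0]]
            if not grid:
                raise ConfigError("no feasible k in cluster grid")
            assignment = select_k(
                cluster_X,
                grid,
                seed=stage_seed(seed, "kmeans"),
                n_init=config.cluster.n_init,
            )
        log_stage(stage, cluster_X.shape[0], assignment.k)
        summary["k"] = assignment.k
        summary["silhouette"] = assignment.silhouette

        if coords is None:  # fall back to the first two PCs for the map
            coords = pca_result.scores[:, :2]
        with (outdir / "clusters.csv").open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "cluster", "x", "y", "silhouette_overall"])
            for rec, lab, (x, y) in zip(records, assignment.labels, coords):
                writer.writerow(
                    [rec.id, int(lab), f"{x:.6g}", f"{y:.6g}", f"{assignment.silhouette:.6g}"]
                )

        stage = "motifs"
        reports = cluster_motif_report(
            records,
            assignment,
            target,
            top_clusters=config.motif.top_clusters,
            completion_threshold=config.motif.completion_threshold,
            mcs_timeout=config.motif.mcs_timeout,
            seed=stage_seed(seed, "mcs"),
        )
        with (outdir / "motifs.csv").open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(
                fh,
                fieldnames=[
                    "smarts",
                    "n_match",
                    "n_match_active",
                    "bioactive_ratio",
                    "target",
                    "source_cluster",
                ],
            )
            writer.writeheader()
            for r in reports:
                writer.writerow(_report_row(r))
        log_stage(stage, assignment.k, len(reports))
        summary["motifs"] = [_report_row(r) for r in reports]
        # Headline motif: the most general competitive one.  Tiny motifs reach
        # ratio 1.0 by chance and over-specific ones inflate it, so among
        # well-supported reports keep those within 80% of the best ratio and
        # prefer the one with the most labeled matches (ties: higher ratio).
        supported = [
            r
            for r in reports
            if r.n_match >= config.motif.min_support
            and not math.isnan(r.bioactive_ratio)
        ]
        if supported:
            best_ratio = max(r.bioactive_ratio for r in supported)
            competitive = [
                r for r in supported if r.bioactive_ratio >= 0.8 * best_ratio
            ]
            competitive.sort(key=lambda r: (-r.n_match, -r.bioactive_ratio))
            summary["top_motif"] = _report_row(competitive[0])
        else:
            summary["top_motif"] = None

        stage = "affinity"
        if affinity_table is not None:
            asum = affinity_summary(
                affinity_table, target, threshold=config.affinity.threshold
            )
            summary["affinity_summary"] = {
                "fraction_stronger": asum.fraction_stronger,
                "mean": asum.mean,
                "n": asum.n,
                "threshold": asum.threshold,
            }
            log_stage(stage, asum.n, asum.n)
    except Exception as exc:
        exc.args = (f"[stage {stage}] {exc}",)
        raise

    manifest = {
        "config": config.to_dict(),
        "provenance": config.provenance,
        "seed": seed,
        "stage_seeds": {
            s: stage_seed(seed, s) for s in ("pairs", "metric", "tsne", "kmeans", "mcs")
        },
        "versions": _library_versions(),
        "stage_counts": stage_counts,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True), encoding="utf-8"
    )
    _write_text_summary(summary, outdir / "summary.txt")
    return outdir


def _write_text_summary(summary: dict, path: Path) -> None:
    lines = [
        f"records: {summary.get('n_records')} (rejects {summary.get('n_rejects')})",
        f"after filter: {summary.get('n_after_filter')}",
        f"k: {summary.get('k')}  silhouette: {summary.get('silhouette'):.4f}",
    ]
    top = summary.get("top_motif")
    if top:
        lines.append(
            f"top motif ({top['n_match']} labeled matches, "
            f"ratio {top['bioactive_ratio']:.3f}): {top['smarts']}"
        )
    asum = summary.get("affinity_summary")
    if asum:
        lines.append(
            f"affinity: {asum['fraction_stronger'] * 100:.1f}% stronger than "
            f"{asum['threshold']} kcal/mol (mean {asum['mean']:.2f}, n={asum['n']})"
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
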