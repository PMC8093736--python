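"""End-to-end pipeline: records + sites in, report bundle out.

``run_pipeline`` chains the full analysis — diet summary (Table-1 shape),
Schoener/Pianka overlap matrices with the two-triangle report, the
presence and trait GLM sweeps, the Mantel test of overlap against
geographic distance, and the environment PCA associations — and writes a
deterministic bundle of TSV/JSON files plus a run manifest (config echo,
seed, input checksums) from which every number is reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__
from .data_model import (
    GutRecord,
    Site,
    pool_counts,
    read_gut_records,
    read_sites,
    write_gut_records,
    write_sites,
)
from .diet_metrics import MetricsConfig, summaries_to_frame, summarize_population
from .environment_association import (
    correlate_consumption_with_pcs,
    correlate_empty_guts_with_pcs,
    pca_environment,
    regress_metric_on_pcs,
)
from .errors import DietscopeError, ParameterError
from .glm_inference import (
    GlmFit,
    fit_all_presence_glms,
    fit_trait_glm,
    joint_population_test,
    tukey_population_contrasts,
)
from .niche_overlap import (
    correlate_overlap_indices,
    haversine_matrix,
    mantel_test,
    overlap_matrix,
    two_triangle_table,
)
from .synthetic import generate_records, generate_sites, get_preset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline options, defaulting to the conventional analysis choices:
    overlap threshold 0.6, 10,000 Mantel permutations, interaction pruning
    at p > 0.2, PCA retention at 90% cumulative variance."""

    records_path: str | None = None
    sites_path: str | None = None
    preset: str | None = None
    seed: int = 0
    out_dir: str = "dietscope_out"
    dialect: str = "csv"

    iri_variant: str = "hyslop_nv"
    shannon_base: str | float = "e"
    rnw_variant: str = "zero_anchored"
    fo_denominator: str = "all_guts"
    overlap_threshold: float = 0.6
    mantel_permutations: int = 10_000
    mantel_alternative: str = "two_sided"
    glm_coding: str = "numeric_as_paper"
    prune_alpha: float = 0.2
    pca_retain_threshold: float = 0.90
    joint_permutations: int = 199
    run_environment: bool = True
    run_models: bool = True

    def validate(self) -> None:
        if self.preset is None and self.records_path is None:
            raise ParameterError("config must name a preset or a records file")
        if self.preset is not None and self.records_path is not None:
            raise ParameterError("give either a preset or input paths, not both")
        if self.run_environment and self.preset is None and self.sites_path is None:
            raise ParameterError(
                "environment stage requested but no sites file given (and no preset)"
            )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _fit_to_dict(fit: GlmFit | None) -> dict | None:
    if fit is None:
        return None
    d = {
        "response": fit.response,
        "family": fit.family,
        "link": fit.link,
        "population_coding": fit.population_coding,
        "converged": fit.converged,
        "diagnostic": fit.diagnostic,
        "n_used": fit.n_used,
        "interaction_retained": fit.interaction_retained,
        "interaction_p": fit.interaction_p,
        "terms": [dataclasses.asdict(t) for t in fit.terms],
        "dropped_interaction": [dataclasses.asdict(t) for t in fit.dropped_interaction],
    }
    return d


def _json_default(o: Any):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, default=_json_default, allow_nan=True) + "\n")


def load_inputs(config: PipelineConfig) -> tuple[list[GutRecord], list[Site] | None]:
    """Materialise the pipeline inputs from files or a named preset."""
    if config.preset is not None:
        scenario = get_preset(config.preset, seed=config.seed)
        sites = generate_sites(scenario)
        records = generate_records(scenario, sites)
        return records, sites
    records, report = read_gut_records(config.records_path, dialect=config.dialect)
    if report.n_rejected:
        logger.warning("input: rejected %d rows", report.n_rejected)
    sites = read_sites(config.sites_path, dialect=config.dialect) if config.sites_path else None
    return records, sites


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every requested stage and write the report bundle.

    Returns a mapping of artefact name to written path. On any module
    error the partially written bundle is removed and the error
    propagates.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    try:
        records, sites = load_inputs(config)
        if config.preset is not None:
            # echo generated inputs so the bundle is self-contained
            p = out_dir / "records.csv"
            write_gut_records(records, p)
            written["records"] = p
            if sites is not None:
                p = out_dir / "sites.csv"
                write_sites(sites, p)
                written["sites"] = p

        metrics_cfg = MetricsConfig(
            iri_variant=config.iri_variant,  # type: ignore[arg-type]
            shannon_base=config.shannon_base,
            rnw_variant=config.rnw_variant,  # type: ignore[arg-type]
            fo_denominator=config.fo_denominator,  # type: ignore[arg-type]
        )
        matrix = pool_counts(records)
        summaries = summarize_population(records, matrix, metrics_cfg)
        table1 = summaries_to_frame(summaries)
        p = out_dir / "table1.tsv"
        table1.to_csv(p, sep="\t", index=False, float_format="%.6g")
        written["table1"] = p

        schoener = overlap_matrix(matrix, "schoener", config.overlap_threshold)
        pianka = overlap_matrix(matrix, "pianka", config.overlap_threshold)
        table2 = two_triangle_table(schoener, pianka)
        p = out_dir / "table2.tsv"
        table2.to_csv(p, sep="\t", float_format="%.4f")
        written["table2"] = p

        overlap_info: dict[str, Any] = {
            "threshold": config.overlap_threshold,
            "schoener_significant_pairs": int(
                np.triu(schoener.significance_mask.to_numpy(), 1).sum()
            ),
            "pianka_significant_pairs": int(
                np.triu(pianka.significance_mask.to_numpy(), 1).sum()
            ),
        }
        try:
            r, pval = correlate_overlap_indices(schoener, pianka)
            overlap_info["index_correlation"] = {"method": "pearson", "r": r, "p": pval}
        except DietscopeError as exc:
            overlap_info["index_correlation"] = {"error": str(exc)}
        _write_json(out_dir / "overlap.json", overlap_info)
        written["overlap"] = out_dir / "overlap.json"

        if config.run_models:
            models: dict[str, Any] = {
                "presence": {
                    c: _fit_to_dict(f)
                    for c, f in fit_all_presence_glms(
                        records, coding=config.glm_coding, prune_alpha=config.prune_alpha  # type: ignore[arg-type]
                    ).items()
                },
                "traits": {},
                "tukey": {},
            }
            for resp in ("RGL", "GF", "RNW"):
                try:
                    models["traits"][resp] = _fit_to_dict(
                        fit_trait_glm(
                            records, resp, coding=config.glm_coding,  # type: ignore[arg-type]
                            prune_alpha=config.prune_alpha,
                        )
                    )
                except DietscopeError as exc:
                    models["traits"][resp] = {"error": str(exc)}
                try:
                    tk = tukey_population_contrasts(records, resp)  # type: ignore[arg-type]
                    models["tukey"][resp] = {
                        "pairs": tk.pairs,
                        "dropped_populations": tk.dropped_populations,
                    }
                except DietscopeError as exc:
                    models["tukey"][resp] = {"error": str(exc)}
            try:
                joint = joint_population_test(
                    records, n_permutations=config.joint_permutations, seed=config.seed
                )
                models["joint_population_test"] = dataclasses.asdict(joint)
            except DietscopeError as exc:
                models["joint_population_test"] = {"error": str(exc)}
            p = out_dir / "models.json"
            _write_json(p, models)
            written["models"] = p

        if sites is not None:
            dist = haversine_matrix(sites)
            usable = [
                pid for pid in schoener.population_ids
                if not schoener.matrix.loc[pid].isna().all()
            ]
            usable = [pid for pid in usable if pid in dist.index]
            mr = mantel_test(
                dist.loc[usable, usable],
                schoener.matrix.loc[usable, usable],
                n_permutations=config.mantel_permutations,
                seed=config.seed,
                alternative=config.mantel_alternative,  # type: ignore[arg-type]
            )
            _write_json(
                out_dir / "mantel.json",
                {
                    **dataclasses.asdict(mr),
                    "note": "r pairs geographic distance with overlap similarity; "
                    "a negative r means nearer populations overlap more",
                },
            )
            written["mantel"] = out_dir / "mantel.json"

        if config.run_environment and sites is not None:
            pca = pca_environment(sites, retain_threshold=config.pca_retain_threshold)
            env: dict[str, Any] = {
                "retained": pca.retained,
                "explained_variance_ratio": pca.explained_variance_ratio.tolist(),
                "loadings": pca.loadings.round(6).to_dict(),
                "low_power_warning": len(pca.site_ids) < 15,
                "associations": {},
                "correlations": {},
            }
            shannon = {s.population_id: s.shannon_h for s in summaries}
            env["associations"]["shannon_H"] = dataclasses.asdict(
                regress_metric_on_pcs(shannon, pca, "shannon_H")
            )
            env["correlations"]["total_prey"] = correlate_consumption_with_pcs(records, pca)
            env["correlations"]["empty_gut_proportion"] = correlate_empty_guts_with_pcs(
                records, pca
            )
            p = out_dir / "env_assoc.json"
            _write_json(p, env)
            written["env_assoc"] = p

        manifest = {
            "dietscope_version": __version__,
            "seed": config.seed,
            "config": dataclasses.asdict(config),
            "inputs": {
                name: _sha256(Path(p))
                for name, p in [
                    ("records", config.records_path),
                    ("sites", config.sites_path),
                ]
                if p is not None
            },
            "outputs": {k: str(v) for k, v in written.items()},
        }
        p = out_dir / "run_manifest.json"
        _write_json(p, manifest)
        written["manifest"] = p
    except Exception:
        for path in written.values():
            path.unlink(missing_ok=True)
        raise
    return written
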