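"""End-to-end analysis pipeline: align → screen → ordinate → model → index.

The pipeline reads raw landmarks and factors, optionally drops landmarks,
superimposes with GPA, reports specimen outliers and landmark variability,
runs PCA with broken-stick retention, fits the nested model sequence by
RRPP, re-analyzes each habitat separately when a significant habitat main
effect is found (fresh superimposition and PCA per subset), and computes
the sexual-dimorphism index pooled and per subset.  Outputs are TSV tables
plus a JSON manifest recording seeds, options and decisions.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dimorphism import dimorphism_index, dimorphism_table
from .landmark_io import (
    LandmarkDataset,
    attach_factors,
    drop_landmarks,
    read_factor_table,
    read_landmarks,
)
from .ordination import shape_pca
from .shape_models import (
    PermutationSpec,
    compare_models,
    parse_formula,
    subset_reanalysis,
    _model_frame,
)
from .superimposition import flag_specimen_outliers, gpa, landmark_variability

logger = logging.getLogger("morphopipe")

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run (YAML-serializable)."""

    landmarks: str
    format: str = "csv_long"
    factor_table: str | None = None
    drop: list[int] = field(default_factory=list)  # 0-based landmark indices
    tangent: bool = True
    gpa_tol: float = 1e-8
    retention_rule: str = "prefix"
    formulas: list[str] = field(
        default_factory=lambda: [
            "shape ~ logsize",
            "shape ~ logsize + sex",
            "shape ~ logsize + sex + habitat",
            "shape ~ logsize + sex + habitat + sex:habitat",
        ]
    )
    subset_formula: str = "shape ~ logsize + sex + site"
    split_by: str = "habitat"
    subset_mode: str = "auto"  # auto | always | never
    alpha: float = 0.05
    n_perm: int = 10_000
    seed: int = 0
    sex_factor: str = "sex"
    out_dir: str = "morphopipe_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "landmarks" not in raw:
            raise ValueError("config needs a 'landmarks' path")
        return cls(**raw)


def run_pipeline(config: PipelineConfig, ds: LandmarkDataset | None = None) -> dict:
    """Execute the full analysis; returns the in-memory report bundle.

    ``ds`` can be passed directly (e.g. from the simulator) to skip file
    reading.  Each stage aborts with a stage-labeled error; outputs written
    so far are kept and a FAILED marker is left in the output directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "schema_version": SCHEMA_VERSION,
        "package_version": __version__,
        "seed": config.seed,
        "n_perm": config.n_perm,
        "alpha": config.alpha,
        "tangent": config.tangent,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": [],
    }
    bundle: dict = {"manifest": manifest}
    stage = "read"
    try:
        if ds is None:
            ds = read_landmarks(config.landmarks, config.format)
            if config.factor_table:
                ds = attach_factors(ds, read_factor_table(config.factor_table))
        _log_stage(manifest, stage, n=ds.n_specimens, p=ds.n_landmarks)

        if config.drop:
            stage = "drop_landmarks"
            ds = drop_landmarks(ds, config.drop)
            _log_stage(manifest, stage, dropped=config.drop, p=ds.n_landmarks)

        stage = "gpa"
        al = gpa(ds, tol=config.gpa_tol, tangent=config.tangent)
        _log_stage(manifest, stage, iterations=al.iterations, converged=al.converged)
        bundle["aligned"] = al

        stage = "screening"
        outliers = flag_specimen_outliers(al)
        variability = landmark_variability(al)
        pd.DataFrame(
            {"procrustes_distance": outliers.distances,
             "above_q3": outliers.distances.index.isin(outliers.above_q3),
             "extreme": outliers.distances.index.isin(outliers.extreme)}
        ).to_csv(out / "specimen_outliers.tsv", sep="\t")
        variability.variances.sort_values(ascending=False).to_csv(
            out / "landmark_variability.tsv", sep="\t"
        )
        _log_stage(manifest, stage, above_q3=outliers.above_q3,
                   extreme=outliers.extreme)
        bundle["outliers"], bundle["variability"] = outliers, variability

        stage = "pca"
        pca = shape_pca(al, retention=config.retention_rule)
        _write_pca(pca, out / "pca_pooled.tsv")
        _log_stage(manifest, stage, retained=pca.retained,
                   pc1_pct=float(pca.percent_variance[0]))
        bundle["pca"] = pca

        stage = "models"
        perm = PermutationSpec(n_perm=config.n_perm, seed=config.seed)
        data = _model_frame(al)
        comparison = compare_models(
            pca.retained_scores(), data, config.formulas, perm,
            alpha=config.alpha, habitat_term=config.split_by,
        )
        comparison.best_table.to_tsv(out / "anova_pooled.tsv")
        _log_stage(manifest, stage,
                   best_formula=str(comparison.best_formula),
                   common_allometry_rejected=comparison.common_allometry_rejected)
        bundle["comparison"] = comparison

        stage = "subsets"
        habitat_p = _main_effect_p(comparison, config.split_by)
        do_subsets = config.subset_mode == "always" or (
            config.subset_mode == "auto"
            and habitat_p is not None
            and habitat_p < config.alpha
        )
        manifest["subset_trigger"] = {
            "mode": config.subset_mode,
            "split_factor_p": habitat_p,
            "ran": bool(do_subsets),
        }
        subsets = {}
        if do_subsets:
            subsets = subset_reanalysis(
                ds, config.split_by, config.subset_formula, perm,
                tangent=config.tangent,
            )
            for level, res in subsets.items():
                if res.table is not None:
                    res.table.to_tsv(out / f"anova_{_slug(level)}.tsv")
            _log_stage(manifest, stage,
                       levels={k: (v.skipped_reason or "ok")
                               for k, v in subsets.items()})
        bundle["subsets"] = subsets

        stage = "dimorphism"
        indices = {"pooled": dimorphism_index(al, factor=config.sex_factor)}
        for level, res in subsets.items():
            if res.aligned is not None:
                indices[level] = dimorphism_index(res.aligned,
                                                  factor=config.sex_factor)
        dimorphism_table(indices).to_csv(out / "dimorphism.tsv", sep="\t")
        _log_stage(manifest, stage, indices={k: v.index for k, v in indices.items()})
        bundle["dimorphism"] = indices

        manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        manifest["config"] = asdict(config)
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, default=_jsonable)
        return bundle
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage}: {exc}\n", encoding="utf-8")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _main_effect_p(comparison, factor: str) -> float | None:
    """p-value of a factor's main effect in the most complex model containing it."""
    for formula, table in zip(reversed(comparison.formulas),
                              reversed(comparison.tables)):
        if factor in formula.terms:
            return table.term_p(factor)
    return None


def _write_pca(pca, path) -> None:
    k = pca.n_positive
    df = pd.DataFrame(
        {"PC": np.arange(1, k + 1),
         "eigenvalue": pca.eigenvalues[:k],
         "percent_variance": pca.percent_variance[:k],
         "retained": np.arange(1, k + 1) <= pca.retained}
    )
    df.to_csv(path, sep="\t", index=False)


def _log_stage(manifest: dict, stage: str, **info) -> None:
    entry = {"stage": stage, "time": time.strftime("%Y-%m-%dT%H:%M:%S"), **info}
    manifest["stages"].append(entry)
    logger.info("stage %s: %s", stage, info)


def _slug(text: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in text.lower())


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
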