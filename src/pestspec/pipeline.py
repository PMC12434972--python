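"""End-to-end orchestration: simulate -> extract -> select -> train ->
evaluate -> predict-map -> spatial, with a run manifest and a report.

Every stage draws its seed from the single pipeline seed, writes its
outputs under the run directory in standard formats (CSV, GeoTIFF,
GeoJSON, JSON), and records them in ``manifest.json``.  The report is
rendered purely from the manifest and stage outputs — nothing is
recomputed at render time.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from pestspec import geo
from pestspec.cohort import CohortConfig, generate_cohort
from pestspec.features import FeatureTable, build_feature_table, extract_roi_means
from pestspec.indices import registry_manifest
from pestspec.models import (
    SplitSpec,
    evaluate,
    predict_all,
    split_train_test,
    train_model,
)
from pestspec.scene import SceneConfig, generate_scene
from pestspec.selection import anova_filter, sfs_select, spa_select
from pestspec.spatial import analyze_spatial

log = logging.getLogger(__name__)


class SpatialConfig(BaseModel):
    scheme: str = "knn"
    k: int = 8
    band: float | None = None
    permutations: int = Field(default=999, ge=99)
    alpha: float = 0.05


class SelectionConfig(BaseModel):
    anova_p: float = 1e-10
    anova_f_override: float | None = None
    spa_size_range: tuple[int, int] | None = None
    spa_rel_tol: float = 0.01
    spa_cv_folds: int = 5
    sfs_cv_folds: int = 5
    sfs_n_estimators: int = 100
    sfs_n_repeats: int = 10


class PipelineConfig(BaseModel):
    """Validated configuration for a full run (JSON/YAML loadable)."""

    cohort: CohortConfig = CohortConfig()
    scene: SceneConfig = SceneConfig()
    families: list[str] = ["CONV", "RE"]
    methods: list[str] = ["ANOVA", "SPA", "SFS"]
    model_kinds: list[str] = ["RF", "CNN1D", "BPNN"]
    split: SplitSpec = SplitSpec()
    selection: SelectionConfig = SelectionConfig()
    spatial: SpatialConfig = SpatialConfig()
    cv_folds: int = 5
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            return cls.model_validate(yaml.safe_load(text))
        return cls.model_validate(json.loads(text))


class PipelineError(RuntimeError):
    """A stage failure with a machine-readable record."""

    def __init__(self, stage: str, error: Exception):
        self.stage = stage
        self.record = {"stage": stage, "error": str(error), "type": type(error).__name__}
        super().__init__(f"pipeline stage {stage!r} failed: {error}")


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s % 2**31) for s in state]


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, allow_nan=True))


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute every stage; returns (and writes) the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest: dict = {
        "seed": config.seed,
        "stage_seeds": dict(
            zip(["cohort", "scene", "split", "select", "train", "spatial"], seeds)
        ),
        "config": json.loads(config.model_dump_json()),
        "outputs": {},
        "timings": {},
        "metrics": [],
    }

    def _record(name: str, path: Path):
        manifest["outputs"][name] = str(path.relative_to(out))

    def _stage(name):
        class _Ctx:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                log.info("stage %s: start (seed plan %s)", name, manifest["stage_seeds"])
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                manifest["timings"][name] = round(time.perf_counter() - self_inner.t0, 3)
                if exc is not None:
                    err = PipelineError(name, exc)
                    _dump_json(err.record, out / "error.json")
                    raise err from exc
                log.info("stage %s: done in %.1fs", name, manifest["timings"][name])

        return _Ctx()

    # ------------------------------------------------------------ simulate
    with _stage("simulate"):
        cohort = generate_cohort(config.cohort, seed=seeds[0])
        scene = generate_scene(cohort, config.scene, seed=seeds[1])
        scene.trees.to_csv(out / "cohort.csv", index=False)
        geo.write_geotiff(out / "scene.tif", scene.raster, scene.resolution, scene.origin)
        geo.write_rois_geojson(out / "rois.geojson", scene.rois, scene.trees["tree_id"])
        _record("cohort", out / "cohort.csv")
        _record("scene", out / "scene.tif")
        _record("rois", out / "rois.geojson")

    # ------------------------------------------------------------- extract
    with _stage("extract"):
        spectra = extract_roi_means(
            scene.raster,
            scene.rois,
            resolution=scene.resolution,
            origin=scene.origin,
            tree_ids=scene.trees["tree_id"].tolist(),
        )
        labels = pd.Series(
            scene.trees["damage_level"].to_numpy(),
            index=spectra.index,
            name="damage_level",
        )
        table = build_feature_table(spectra, labels)
        table.to_csv(out / "features.csv")
        _dump_json(registry_manifest(), out / "registry.json")
        _record("features", out / "features.csv")
        _record("registry", out / "registry.json")

    # -------------------------------------------------------------- select
    selections: dict[tuple[str, str], list[str]] = {}
    with _stage("select"):
        sel_cfg = config.selection
        for family in config.families:
            fam_table = table.subset(family=family)
            for method in config.methods:
                if method == "ANOVA":
                    res = anova_filter(
                        fam_table, sel_cfg.anova_p, sel_cfg.anova_f_override
                    )
                elif method == "SPA":
                    res = spa_select(
                        fam_table,
                        size_range=sel_cfg.spa_size_range,
                        cv_folds=sel_cfg.spa_cv_folds,
                        rel_tol=sel_cfg.spa_rel_tol,
                        seed=seeds[3],
                    )
                elif method == "SFS":
                    res = sfs_select(
                        fam_table,
                        cv_folds=sel_cfg.sfs_cv_folds,
                        n_repeats=sel_cfg.sfs_n_repeats,
                        n_estimators=sel_cfg.sfs_n_estimators,
                        seed=seeds[3],
                    )
                else:
                    raise ValueError(f"unknown selection method {method!r}")
                selections[(family, method)] = res.selected
                p = out / f"selection_{family}_{method}.json".lower()
                _dump_json(res.to_dict(), p)
                _record(f"selection/{family}/{method}", p)

    # ------------------------------------------------- train + evaluate
    results = {}
    with _stage("train"):
        train_tab, test_tab = split_train_test(
            table, SplitSpec(**{**config.split.model_dump(), "seed": seeds[2]})
        )
        for (family, method), selected in selections.items():
            for kind in config.model_kinds:
                tr = train_tab.subset(features=selected)
                te = test_tab.subset(features=selected)
                model = train_model(kind, tr, cv_folds=config.cv_folds, seed=seeds[4])
                res = evaluate(model, te)
                key = f"{family}-{method}-{kind}"
                results[key] = (model, res)
                row = {
                    "family": family,
                    "selection": method,
                    "model": kind,
                    "n_features": len(selected),
                    "oa": res.oa,
                    "kappa": res.kappa,
                    "recall": res.recall,
                    "f1": res.f1,
                }
                manifest["metrics"].append(row)
                p = out / f"model_{key}.json".lower().replace("*", "s")
                _dump_json(res.to_dict(), p)
                _record(f"model/{key}", p)

    # --------------------------------------------------------- predict-map
    with _stage("predict-map"):
        best_key = max(results, key=lambda k: results[k][1].oa)
        best_model, _ = results[best_key]
        fam, meth, kind = best_key.split("-")
        pred, comp = predict_all(
            best_model, table.subset(features=selections[(fam, meth)])
        )
        pred_df = scene.trees[["tree_id", "x", "y", "damage_level"]].copy()
        pred_df = pred_df.set_index("tree_id")
        pred_df["predicted_level"] = pred
        pred_df.to_csv(out / "predictions.csv")
        comp.to_csv(out / "composition.csv", index=False)
        manifest["best_model"] = best_key
        manifest["composition"] = comp.to_dict(orient="records")
        _record("predictions", out / "predictions.csv")
        _record("composition", out / "composition.csv")

    # -------------------------------------------------------------- spatial
    with _stage("spatial"):
        sp = config.spatial
        points = pred_df[["x", "y"]].to_numpy()
        analysis = analyze_spatial(
            points,
            pred_df["predicted_level"].to_numpy(dtype=float),
            scheme=sp.scheme,
            k=sp.k,
            band=sp.band,
            permutations=sp.permutations,
            alpha=sp.alpha,
            seed=seeds[5],
        )
        sdf = analysis.to_frame(index=pred_df.index)
        sdf.insert(0, "x", pred_df["x"])
        sdf.insert(1, "y", pred_df["y"])
        sdf.to_csv(out / "spatial.csv")
        _dump_json(analysis.global_moran.to_dict(), out / "spatial_global.json")
        manifest["global_moran"] = analysis.global_moran.to_dict()
        manifest["distribution_counts"] = (
            pd.Series(analysis.distribution_type).value_counts().to_dict()
        )
        _record("spatial", out / "spatial.csv")
        _record("spatial_global", out / "spatial_global.json")

    _dump_json(manifest, out / "manifest.json")
    return manifest


def write_report(out_dir, with_figures: bool = True) -> Path:
    """Render ``report.md`` (and figures) from an existing run directory.

    Numbers are read from the manifest and stage outputs only; partial
    runs produce a partial report with a warning banner.
    """
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    lines = ["# Pest-disturbance detection run report", ""]
    stages = set(manifest.get("timings", {}))
    expected = {"simulate", "extract", "select", "train", "predict-map", "spatial"}
    if not expected.issubset(stages):
        lines += ["> **Warning:** partial run — missing stage(s): "
                  + ", ".join(sorted(expected - stages)), ""]
    lines += [f"Seed: {manifest['seed']}", ""]
    metrics = manifest.get("metrics", [])
    if metrics:
        df = pd.DataFrame(metrics)
        df["oa_pct"] = (100 * df["oa"]).map("{:.2f}%".format)
        lines += ["## Model accuracy", "", df.to_markdown(index=False), ""]
        lines += [f"Best model: **{manifest.get('best_model', 'n/a')}**", ""]
    comp = manifest.get("composition")
    if comp:
        lines += ["## Predicted level composition", "",
                  pd.DataFrame(comp).to_markdown(index=False), ""]
    gm = manifest.get("global_moran")
    if gm is not None:
        lines += [
            "## Spatial autocorrelation",
            "",
            f"Global Moran's I = {gm['morans_i']:.4f} "
            f"(E[I] = {gm['expected_i']:.4f}, z = {gm['z_sim']:.2f}, "
            f"pseudo-p = {gm['p_sim']:.4f}, {gm['permutations']} permutations)",
            "",
        ]
        dc = manifest.get("distribution_counts", {})
        if dc:
            lines += ["Distribution types: "
                      + ", ".join(f"{k}: {v}" for k, v in sorted(dc.items())), ""]
    if with_figures and metrics:
        try:
            from pestspec import plots

            figdir = out / "figures"
            figdir.mkdir(exist_ok=True)
            plots.render_run_figures(out, figdir)
            lines += ["Figures written to `figures/`.", ""]
        except Exception as e:  # figures are best-effort
            lines += [f"> Figure rendering failed: {e}", ""]
    path = out / "report.md"
    path.write_text("\n".join(lines))
    return path
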