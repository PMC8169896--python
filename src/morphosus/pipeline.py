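"""End-to-end orchestration: simulate/ingest -> GPA -> tests -> classify ->
mixture -> tree, from a single validated configuration.

Stages whose inputs are absent are skipped (no 3D data means no k-NN
stage); any stage error aborts the run naming the stage.  Outputs are plain
CSV/JSON/Newick artifacts plus a manifest that suffices to re-run the
bundle bit-identically (config, seed, package version).  Logging goes to
standard error only; artifacts never carry timestamps, so identical
config + seed gives byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (
    DEFAULT_VARIANCE_THRESHOLD,
    choose_k,
    crossvalidated_accuracy,
    fit_discriminant,
    knn_status_predict,
    project_specimens,
)
from .dataset_io import MorphometricDataset, assemble_dataset, read_metadata, read_tps, read_xyz_table
from .group_tests import (
    allometry_regression,
    common_slope_test,
    shape_manova,
    size_group_anova,
)
from .population import (
    fit_size_mixture,
    mean_form_distance_matrix,
    neighbor_joining,
    pca_of_group_means,
)
from .superimposition import build_form_matrix, generalized_procrustes, group_mean_shape
from .synthetic import SCENARIO_NAMES, preset_scenario, simulate_3d_classes, simulate_shape_populations

__all__ = ["PipelineConfig", "ResultBundle", "PipelineError", "run_pipeline", "make_report"]

log = logging.getLogger("morphosus")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(name)s %(levelname)s %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


class PipelineError(ValueError):
    pass


_CONFIG_KEYS = {
    "scenario",
    "tps_path",
    "metadata_path",
    "xyz_dir",
    "element",
    "variance_threshold",
    "n_perm",
    "n_iter",
    "max_G",
    "min_n",
    "tree_metric",
    "knn_classes",
    "seed",
    "outdir",
}


@dataclass(frozen=True)
class PipelineConfig:
    """Validated run configuration: exactly one of ``scenario`` or input
    paths; a seed is mandatory."""

    seed: int
    outdir: str
    scenario: str | None = None
    tps_path: str | None = None
    metadata_path: str | None = None
    xyz_dir: str | None = None
    element: str = "M2"
    variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD
    n_perm: int = 999
    n_iter: int = 200
    max_G: int = 5
    min_n: int | None = 4
    tree_metric: str = "form"
    knn_classes: dict[str, str] | None = None

    def __post_init__(self) -> None:
        has_paths = self.tps_path is not None or self.xyz_dir is not None
        if (self.scenario is None) == (not has_paths):
            raise PipelineError("config must name exactly one of: a scenario, or input paths")
        if self.scenario is not None and self.scenario not in SCENARIO_NAMES:
            raise PipelineError(f"unknown scenario {self.scenario!r}")
        if self.tree_metric not in ("form", "shape"):
            raise PipelineError("tree_metric must be 'form' or 'shape'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise PipelineError("config must be a YAML mapping")
        unknown = set(raw) - _CONFIG_KEYS
        if unknown:
            raise PipelineError(f"unknown config keys: {', '.join(sorted(unknown))}")
        if "seed" not in raw:
            raise PipelineError("config must set a seed")
        if "outdir" not in raw:
            raise PipelineError("config must set an outdir")
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        return {
            k: getattr(self, k)
            for k in sorted(_CONFIG_KEYS)
        }


@dataclass
class ResultBundle:
    outdir: Path
    config: PipelineConfig
    artifacts: dict[str, Path] = field(default_factory=dict)
    results: dict[str, Any] = field(default_factory=dict)
    complete: bool = False


def _write_json(path: Path, obj: Any) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def _load_dataset(config: PipelineConfig) -> tuple[MorphometricDataset | None, MorphometricDataset | None]:
    """Return (2D dataset, 3D dataset); either may be absent."""
    if config.scenario is not None:
        scen = preset_scenario(config.scenario, seed=config.seed)
        if scen.truth.template.dimension == 3:
            ds, _ = simulate_3d_classes(scen.truth, scen.n_per_group)
            return None, ds
        ds, _ = simulate_shape_populations(scen.truth, scen.n_per_group)
        return ds, None
    ds2 = ds3 = None
    if config.tps_path:
        if not config.metadata_path:
            raise PipelineError("tps_path requires metadata_path")
        entries = read_tps(config.tps_path)
        meta = read_metadata(config.metadata_path)
        ds2 = assemble_dataset([(sid, cfg) for sid, cfg, _ in entries], meta, config.element)
    if config.xyz_dir:
        files = sorted(Path(config.xyz_dir).glob("*.csv"))
        if not files:
            raise PipelineError(f"no xyz CSVs under {config.xyz_dir}")
        configs = [read_xyz_table(f) for f in files]
        if config.metadata_path:
            meta = read_metadata(config.metadata_path)
        else:
            meta = pd.DataFrame(
                {"specimen_id": [sid for sid, _ in configs], "group": "unknown"}
            ).set_index("specimen_id", drop=False)
        ds3 = assemble_dataset(configs, meta, "calcaneus")
    return ds2, ds3


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            log.info("stage=%s start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage=%s done", name)
            return out
        return wrapper
    return deco


def run_pipeline(config: PipelineConfig) -> ResultBundle:
    """Execute every applicable stage and write the artifact bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = ResultBundle(outdir=outdir, config=config)
    art = bundle.artifacts
    res = bundle.results
    seed = config.seed

    ds2, ds3 = _stage("ingest")(_load_dataset)(config)
    primary = ds2 if ds2 is not None else ds3
    if primary is None:
        raise PipelineError("no input data")

    aligned = _stage("gpa")(generalized_procrustes)(primary)
    form = build_form_matrix(aligned)
    coords = pd.DataFrame(aligned.shape_coordinates, columns=aligned.coordinate_columns())
    coords.insert(0, "specimen_id", aligned.specimen_ids)
    coords.insert(1, "group", aligned.groups)
    coords["centroid_size"] = aligned.centroid_sizes
    art["aligned"] = outdir / "aligned.csv"
    coords.to_csv(art["aligned"], index=False, float_format="%.10g")
    form_df = pd.DataFrame(form.values, columns=form.columns())
    form_df.insert(0, "specimen_id", aligned.specimen_ids)
    art["form"] = outdir / "form.csv"
    form_df.to_csv(art["form"], index=False, float_format="%.10g")

    labels = np.asarray(aligned.groups)
    log_sizes = np.log(aligned.centroid_sizes)
    uniq, counts = np.unique(labels, return_counts=True)
    multi_group = uniq.size >= 2 and counts.min() >= 2

    if multi_group and np.ptp(log_sizes) > 0:
        anova = _stage("size_anova")(size_group_anova)(log_sizes, labels, config.n_perm, seed)
        res["size_anova"] = anova.to_dict()
        art["size_anova"] = outdir / "size_anova.json"
        _write_json(art["size_anova"], res["size_anova"])
        art["boxplot_stats"] = outdir / "boxplot_stats.csv"
        anova.group_summary.to_csv(art["boxplot_stats"], index=False, float_format="%.10g")

    allom = _stage("allometry")(allometry_regression)(
        aligned.shape_coordinates, log_sizes, config.n_perm, seed
    )
    res["allometry"] = allom.to_dict()
    art["allometry"] = outdir / "allometry.json"
    _write_json(art["allometry"], res["allometry"])

    if uniq.size >= 2 and counts.min() >= 3:
        mancova = _stage("common_slope")(common_slope_test)(
            aligned.shape_coordinates, log_sizes, labels, config.n_perm, seed
        )
        res["common_slope"] = mancova.to_dict()
        res["common_slope"]["shared_allometry"] = bool(mancova.p > 0.05)
        art["common_slope"] = outdir / "common_slope.json"
        _write_json(art["common_slope"], res["common_slope"])

    if multi_group:
        manova = _stage("shape_manova")(shape_manova)(
            form.values, labels, config.n_perm, seed
        )
        res["shape_manova"] = manova.to_dict()
        art["shape_manova"] = outdir / "shape_manova.json"
        _write_json(art["shape_manova"], res["shape_manova"])

        report = _stage("classification")(crossvalidated_accuracy)(
            form.values,
            labels,
            n_iter=config.n_iter,
            seed=seed,
            variance_threshold=config.variance_threshold,
            min_n=config.min_n,
        )
        res["classification"] = report.to_dict()
        art["classification"] = outdir / "classification.json"
        _write_json(art["classification"], res["classification"])

        model = fit_discriminant(form.values, labels, config.variance_threshold)
        scores = project_specimens(model, form.values)
        ld_df = pd.DataFrame(scores, columns=[f"LD{i + 1}" for i in range(scores.shape[1])])
        ld_df.insert(0, "specimen_id", aligned.specimen_ids)
        ld_df.insert(1, "group", aligned.groups)
        art["ld_scores"] = outdir / "ld_scores.csv"
        ld_df.to_csv(art["ld_scores"], index=False, float_format="%.10g")

    mixture = _stage("size_mixture")(fit_size_mixture)(log_sizes, config.max_G, seed)
    res["mixture"] = mixture.to_dict()
    art["mixture"] = outdir / "mixture.json"
    _write_json(art["mixture"], res["mixture"])

    if uniq.size >= 2:
        matrix_rows = form.values if config.tree_metric == "form" else aligned.shape_coordinates
        means = group_mean_shape(matrix_rows, labels)
        D, tree_labels = mean_form_distance_matrix(means)
        tree = _stage("tree")(neighbor_joining)(D, tree_labels)
        art["distances"] = outdir / "distances.csv"
        pd.DataFrame(D, index=tree_labels, columns=tree_labels).to_csv(
            art["distances"], float_format="%.10g"
        )
        art["tree"] = outdir / "tree.nwk"
        art["tree"].write_text(tree.newick + "\n")
        res["tree_newick"] = tree.newick
        if uniq.size >= 3:
            ord_df = pca_of_group_means(means)
            art["group_mean_pca"] = outdir / "group_mean_pca.csv"
            ord_df.to_csv(art["group_mean_pca"], float_format="%.10g")

    if ds3 is not None and config.scenario == "three-ecoclasses":
        # k-NN ecophenotype stage: classes are the group labels
        aligned3 = aligned if primary is ds3 else generalized_procrustes(ds3)
        form3 = build_form_matrix(aligned3)
        labels3 = np.asarray(aligned3.groups)
        model3 = fit_discriminant(form3.values, labels3, config.variance_threshold)
        train_scores = project_specimens(model3, form3.values)
        k = choose_k(train_scores.shape[0])
        pred = _stage("knn")(knn_status_predict)(train_scores, labels3, train_scores, k)
        knn_df = pd.DataFrame(
            {
                "specimen_id": aligned3.specimen_ids,
                "true_class": labels3,
                "predicted_class": pred.predicted_class,
                "tie_broken": pred.tie_broken,
            }
        )
        art["knn"] = outdir / "knn.csv"
        knn_df.to_csv(art["knn"], index=False)
        res["knn"] = {
            "k": pred.k,
            "agreement": float(np.mean(knn_df["true_class"] == knn_df["predicted_class"])),
        }

    manifest = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "version": __version__,
        "artifacts": {k: str(v.name) for k, v in art.items()},
        "complete": True,
    }
    art["manifest"] = outdir / "manifest.json"
    _write_json(art["manifest"], manifest)
    bundle.complete = True
    return bundle


def _ascii_tree(newick: str) -> str:
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    return tree.as_ascii_plot(plot_metric="length")


def make_report(bundle: ResultBundle) -> str:
    """One-page markdown summary of a complete bundle; every number comes
    from an artifact file."""
    if not bundle.complete:
        raise PipelineError("bundle is incomplete")
    res = bundle.results
    cfg = bundle.config
    lines = [
        "# morphosus run report",
        "",
        f"seed: {cfg.seed}",
        f"scenario: {cfg.scenario or '(external data)'}",
        "",
    ]
    if "size_anova" in res:
        a = res["size_anova"]
        lines.append(
            f"- size ANOVA: df = {a['df_between']}/{a['df_within']}, "
            f"F = {a['F']:.3f}, p = {a['p']:.4f}"
        )
    if "allometry" in res:
        a = res["allometry"]
        lines.append(f"- allometry: Rsq = {a['Rsq']:.4f}, F = {a['F']:.3f}, p = {a['p']:.4f}")
    if "common_slope" in res:
        a = res["common_slope"]
        shared = "shared" if a["shared_allometry"] else "group-specific"
        lines.append(
            f"- MANCOVA group x size: F = {a['F']:.3f}, p = {a['p']:.4f} ({shared} allometry)"
        )
    if "shape_manova" in res:
        a = res["shape_manova"]
        lines.append(
            f"- shape MANOVA: df = {a['df_between']}/{a['df_within']}, "
            f"F = {a['F']:.3f}, p = {a['p']:.4f}"
        )
    if "classification" in res:
        a = res["classification"]
        per = ", ".join(f"{g}: {v:.1f}%" for g, v in sorted(a["per_group_accuracy"].items()))
        lines.append(
            f"- cross-validated accuracy ({a['fold_scheme']}, {a['n_iterations']} iterations): "
            f"overall {a['overall_accuracy']:.1f}% ({per})"
        )
    if "mixture" in res:
        a = res["mixture"]
        lines.append(
            f"- log-size mixture: G = {a['G']} ({a['family']} variance), "
            f"means = {[round(m, 3) for m in a['means']]}"
        )
    if "knn" in res:
        a = res["knn"]
        lines.append(f"- k-NN ecophenotype (k = {a['k']}): training agreement {100 * a['agreement']:.1f}%")
    if "tree_newick" in res:
        lines += ["", "## Neighbour-joining tree", "", "```", _ascii_tree(res["tree_newick"]).rstrip(), "```"]
    elif "shape_manova" in res:
        # a multi-group run must have produced a tree
        raise PipelineError("missing tree artifact for a multi-group run")
    return "\n".join(lines) + "\n"
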