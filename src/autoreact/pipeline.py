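"""End-to-end pipeline driver.

``run_pipeline`` takes a configuration mapping (or YAML file), executes
simulate -> preprocess -> differential testing -> classification -> ORA
-> visual summaries, writes every stage's table under a run directory and
records a machine-readable manifest (parameters, seed, per-stage shapes).
The whole run is a pure function of (inputs, config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import backward_stepwise_aic, evaluate_classifier, fit_logistic
from .differential import differential_table
from .enrichment import map_analytes_to_genes, ora, parse_gmt, write_gmt
from .preprocess import preprocess_pipeline
from .report import concentration_ellipse, hclust_complete, pca, standardize_columns
from .simdata import (
    BeadArrayDataset,
    SimConfig,
    generate_bead_array,
    generate_gene_sets,
    read_bead_dataset,
    write_bead_dataset,
)

log = logging.getLogger("autoreact")

__all__ = ["run_pipeline", "load_config"]


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _stage(manifest: dict, name: str, **info) -> None:
    manifest["stages"][name] = info
    log.info("stage=%s %s", name, " ".join(f"{k}={v}" for k, v in info.items()))


def run_pipeline(config: dict, out_dir) -> Path:
    """Execute the full analysis described by ``config``.

    Config keys (all optional except one of ``simulate``/``input_dir``):

    - ``seed``: root seed for simulation stages (default 0).
    - ``simulate``: SimConfig field overrides, or ``input_dir``: a dataset
      directory written by :func:`autoreact.simdata.write_bead_dataset`.
    - ``preprocess``: ``exclusion_rule``, ``max_discordance_sd``,
      ``n_anchors``.
    - ``differential``: ``alpha_adj`` (classifier feature threshold,
      default 0.05) and ``alpha_raw`` (ORA query threshold, default 0.05).
    - ``ora``: ``gmt`` — path to a GMT file, or ``synthetic`` (default)
      to score against a generated collection.

    Any stage failure aborts with a stage-named error; the partial run
    directory is kept with a ``FAILED`` marker naming the stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest: dict = {
        "package_version": __version__,
        "seed": seed,
        "config": config,
        "stages": {},
    }
    current = "setup"
    try:
        # --- data ---------------------------------------------------------
        current = "simdata"
        if "input_dir" in config:
            dataset = read_bead_dataset(config["input_dir"])
            _stage(manifest, current, source=str(config["input_dir"]),
                   wells=len(dataset.mfi_rep1), analytes=dataset.mfi_rep1.shape[1])
        else:
            sim_cfg = SimConfig(**{**config.get("simulate", {}), "seed": seed})
            dataset = generate_bead_array(sim_cfg)
            write_bead_dataset(dataset, out / "data")
            _stage(manifest, current, wells=len(dataset.mfi_rep1),
                   analytes=dataset.mfi_rep1.shape[1], truth=len(dataset.truth))

        # --- preprocess ----------------------------------------------------
        current = "preprocess"
        pp = config.get("preprocess", {})
        noise, clean, normalized = preprocess_pipeline(
            dataset,
            max_discordance_sd=float(pp.get("max_discordance_sd", 3.0)),
            exclusion_rule=pp.get("exclusion_rule", "both"),
            n_anchors=int(pp.get("n_anchors", 11)),
        )
        clean.values.to_csv(out / "clean_matrix.tsv", sep="\t")
        normalized.values.to_csv(out / "normalized_matrix.tsv", sep="\t")
        (out / "noise_model.json").write_text(json.dumps({
            "threshold_rep1": noise.threshold_rep1,
            "threshold_rep2": noise.threshold_rep2,
            "outlier_analytes": sorted(noise.outlier_analytes),
            "excluded_analytes": sorted(noise.excluded_analytes),
            "rule": noise.rule,
        }, indent=2))
        _stage(manifest, current, excluded=len(noise.excluded_analytes),
               outliers=len(noise.outlier_analytes),
               kept_analytes=clean.values.shape[1])

        # --- differential --------------------------------------------------
        current = "difftest"
        groups = dataset.groups()
        diff = differential_table(
            normalized.values, clean.values, groups, dataset.analyte_meta
        )
        diff.to_csv(out / "differential.tsv", sep="\t")
        alpha_adj = float(config.get("differential", {}).get("alpha_adj", 0.05))
        alpha_raw = float(config.get("differential", {}).get("alpha_raw", 0.05))
        sig = diff.index[diff["adj_p_value"] < alpha_adj].tolist()
        _stage(manifest, current, analytes=len(diff), significant_adj=len(sig))

        # --- classify ------------------------------------------------------
        current = "classify"
        X = normalized.values.loc[groups.index]
        classify_out: dict = {"features": sig}
        if sig:
            full = fit_logistic(X, groups.to_numpy(), terms=sig)
            reduced = backward_stepwise_aic(X[sig], groups.to_numpy())
            ev_full = evaluate_classifier(X, groups.to_numpy(), sig)
            ev_red = (
                evaluate_classifier(X, groups.to_numpy(), reduced.terms)
                if reduced.terms else None
            )
            classify_out.update({
                "full_model": _model_dump(full),
                "reduced_model": _model_dump(reduced),
                "full_loocv_accuracy": ev_full.loocv_accuracy,
                "full_loocv_auc": ev_full.auc,
                "full_insample_auc": ev_full.insample_auc,
                "reduced_loocv_accuracy": ev_red.loocv_accuracy if ev_red else None,
                "reduced_loocv_auc": ev_red.auc if ev_red else None,
                "reduced_insample_auc": ev_red.insample_auc if ev_red else None,
            })
            roc = pd.DataFrame(ev_full.roc_points, columns=["FPR", "TPR"])
            roc.to_csv(out / "roc_full_loocv.tsv", sep="\t", index=False)
        (out / "classifier.json").write_text(json.dumps(classify_out, indent=2))
        _stage(manifest, current, n_features=len(sig),
               loocv_auc=classify_out.get("full_loocv_auc"))

        # --- enrichment ----------------------------------------------------
        current = "ora"
        gmt_spec = config.get("ora", {}).get("gmt", "synthetic")
        if gmt_spec == "synthetic":
            sets = generate_gene_sets(dataset, seed=seed + 1)
            write_gmt(sets, out / "gene_sets.gmt")
        else:
            sets = parse_gmt(gmt_spec).sets
        universe = sorted(
            {g for gs in dataset.analyte_meta["genes"] for g in gs.split(";")}
        )
        query = map_analytes_to_genes(diff, alpha_raw=alpha_raw)
        if query:
            ora_table = ora(query, universe, sets)
            ora_table.to_csv(out / "ora.tsv", sep="\t")
            n_sig_sets = int((ora_table["adj_p_value"] < 0.05).sum())
        else:
            n_sig_sets = 0
        _stage(manifest, current, query_genes=len(query), sig_sets=n_sig_sets)

        # --- visual summaries ---------------------------------------------
        current = "report"
        pc = pca(normalized.values.loc[groups.index])
        pc.scores.iloc[:, :2].to_csv(out / "pca_scores.tsv", sep="\t")
        ellipses = {
            grp: {k: np.asarray(v).tolist() if not np.isscalar(v) else v
                  for k, v in concentration_ellipse(
                      pc.scores.loc[groups == grp].iloc[:, :2].to_numpy()
                  ).items()}
            for grp in ("case", "control")
        }
        (out / "pca_summary.json").write_text(json.dumps({
            "variance_fraction": pc.variance_fraction[:5].tolist(),
            "ellipses": ellipses,
        }, indent=2))
        heat_cols = diff.index[diff["p_value"] < alpha_raw].tolist()
        if len(heat_cols) >= 2:
            heat = standardize_columns(normalized.values.loc[groups.index, heat_cols])
            row_order = hclust_complete(heat, axis=0).order
            col_order = hclust_complete(heat, axis=1).order
            pd.DataFrame({"row_order": pd.Series(row_order),
                          "col_order": pd.Series(col_order)}).to_csv(
                out / "heatmap_ordering.tsv", sep="\t", index=False)
        _stage(manifest, current,
               pc1=float(pc.variance_fraction[0]), pc2=float(pc.variance_fraction[1]),
               heatmap_analytes=len(heat_cols))
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={current}: {exc}\n")
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


def _model_dump(model) -> dict:
    return {
        "terms": list(model.terms),
        "coefficients": np.asarray(model.coefficients).tolist(),
        "log_likelihood": model.log_likelihood,
        "aic": model.aic,
        "converged": model.converged,
        "separation_flag": model.separation_flag,
    }
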