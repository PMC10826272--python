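"""Reusable simulation studies over the full pipeline.

These functions drive the whole chain — simulate, preprocess, test,
classify — at configurable sizes and return summary numbers.  They are
what the calibration tests and the reproduction script both call, so the
numbers reported anywhere are always recomputed from scratch.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pandas as pd

from .classify import backward_stepwise_aic, evaluate_classifier
from .differential import differential_table, estimate_variance_prior
from .preprocess import preprocess_pipeline
from .simdata import SimConfig, generate_bead_array, null_config

__all__ = [
    "null_pvalues",
    "null_fdr_study",
    "spiked_fdr_study",
    "design_point_study",
    "variance_prior_recovery",
]


def _run_chain(config: SimConfig):
    dataset = generate_bead_array(config)
    _, clean, normalized = preprocess_pipeline(dataset)
    groups = dataset.groups()
    diff = differential_table(normalized.values, clean.values, groups, dataset.analyte_meta)
    return diff, dataset, normalized, groups


def _pipeline_pvalues(config: SimConfig) -> tuple[pd.DataFrame, object]:
    diff, dataset, _, _ = _run_chain(config)
    return diff, dataset


def null_pvalues(n_analytes: int = 2000, seed: int = 0, **overrides) -> np.ndarray:
    """Raw moderated-t p-values from one zero-effect pipeline run."""
    cfg = null_config(SimConfig(seed=seed), n_analytes=n_analytes, **overrides)
    diff, _ = _pipeline_pvalues(cfg)
    return diff["p_value"].to_numpy()


def null_fdr_study(n_runs: int = 100, seed: int = 0, n_analytes: int = 256) -> dict:
    """False-discovery behaviour of BH 0.05 under the global null.

    Every rejection on zero-effect data is false, so the per-run false
    discovery proportion is V / max(R, 1) = 1{R >= 1}; its mean over runs
    estimates the FDR, which BH should hold at or below the nominal 0.05.
    """
    fdp = []
    for r in range(n_runs):
        cfg = null_config(SimConfig(seed=seed + r), n_analytes=n_analytes)
        diff, _ = _pipeline_pvalues(cfg)
        rejected = int((diff["adj_p_value"] < 0.05).sum())
        fdp.append(1.0 if rejected >= 1 else 0.0)
    return {"fdr": float(np.mean(fdp)), "n_runs": n_runs}


def spiked_fdr_study(
    n_runs: int = 100,
    seed: int = 0,
    n_analytes: int = 256,
    n_differential: int = 7,
    effect_range: tuple[float, float] = (0.6, 1.2),
) -> dict:
    """Empirical FDR and recall of BH 0.05 calls on spiked cohorts."""
    v_tot = r_tot = 0
    fdp, recall = [], []
    for r in range(n_runs):
        cfg = replace(
            SimConfig(seed=seed + r),
            n_analytes=n_analytes,
            n_differential=n_differential,
            effect_log2fc_range=effect_range,
        )
        diff, dataset = _pipeline_pvalues(cfg)
        called = set(diff.index[diff["adj_p_value"] < 0.05])
        truth = set(dataset.truth)
        v = len(called - truth)
        fdp.append(v / max(len(called), 1))
        recall.append(len(called & truth) / max(len(truth), 1))
        v_tot += v
        r_tot += len(called)
    return {
        "fdr": float(np.mean(fdp)),
        "mean_recall": float(np.mean(recall)),
        "n_runs": n_runs,
    }


def design_point_study(n_seeds: int = 20, seed: int = 0) -> pd.DataFrame:
    """Full pipeline at the study design point (30 + 30, 256 analytes,
    7 spiked with log2 effects 0.3-1.2).

    Per seed: how many spiked analytes are recovered at adjusted p < 0.05,
    the LOOCV AUC of the model on the selected features after AIC
    backward elimination, and the in-sample AUCs of the full selected
    model and the single best feature.
    """
    rows = []
    for r in range(n_seeds):
        cfg = SimConfig(seed=seed + r)
        diff, dataset, normalized, groups = _run_chain(cfg)
        truth = set(dataset.truth)
        sig = diff.index[diff["adj_p_value"] < 0.05].tolist()
        recovered = len(set(sig) & truth)
        row = {
            "seed": seed + r,
            "n_selected": len(sig),
            "recovered": recovered,
            "loocv_auc": np.nan,
            "insample_auc_full": np.nan,
            "insample_auc_best1": np.nan,
        }
        if sig:
            X = normalized.values.loc[groups.index]
            reduced = backward_stepwise_aic(X[sig], groups.to_numpy())
            terms = reduced.terms or sig
            ev = evaluate_classifier(X, groups.to_numpy(), terms)
            row["loocv_auc"] = ev.auc
            ev_full = evaluate_classifier(X, groups.to_numpy(), sig)
            row["insample_auc_full"] = ev_full.insample_auc
            best1 = [diff.loc[sig, "p_value"].idxmin()]
            ev_b1 = evaluate_classifier(X, groups.to_numpy(), best1)
            row["insample_auc_best1"] = ev_b1.insample_auc
        rows.append(row)
    return pd.DataFrame(rows)


def variance_prior_recovery(
    n_seeds: int = 50,
    seed: int = 0,
    d0: float = 4.0,
    s0_sq: float = 1.0,
    n_analytes: int = 2000,
    df: int = 58,
) -> dict:
    """Recover (d0, s0^2) from variances simulated under the exact model.

    sigma_j^2 ~ d0 * s0^2 / chi2(d0), then s_j^2 ~ sigma_j^2 chi2(df)/df;
    reports the median estimates across seeds.
    """
    d0_hat, s0_hat = [], []
    for r in range(n_seeds):
        rng = np.random.default_rng(seed + r)
        sigma2 = d0 * s0_sq / rng.chisquare(d0, n_analytes)
        s2 = sigma2 * rng.chisquare(df, n_analytes) / df
        d0_est, s0_est = estimate_variance_prior(s2, df)
        d0_hat.append(d0_est)
        s0_hat.append(s0_est)
    return {
        "d0_median": float(np.median(d0_hat)),
        "s0_sq_median": float(np.median(s0_hat)),
        "n_seeds": n_seeds,
    }
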