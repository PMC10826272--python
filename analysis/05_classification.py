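#!/usr/bin/env python
"""Case/control classification from the significant analytes.

Fits a logistic model on the analytes with adjusted p < 0.05, reduces it
by AIC backward elimination, and validates both the full and the reduced
model by leave-one-out cross-validation with ROC/AUC on the held-out
probabilities (in-sample AUCs reported alongside).
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from autoreact.classify import backward_stepwise_aic, evaluate_classifier, fit_logistic
from autoreact.differential import differential_table
from autoreact.preprocess import preprocess_pipeline
from autoreact.simdata import read_bead_dataset


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results/classifier.json"))
    ap.add_argument("--roc-out", type=Path, default=Path("results/roc_loocv.tsv"))
    args = ap.parse_args()

    dataset = read_bead_dataset(args.data)
    _, clean, normalized = preprocess_pipeline(dataset)
    groups = dataset.groups()
    diff = differential_table(
        normalized.values, clean.values, groups, dataset.analyte_meta
    )
    terms = diff.index[diff["adj_p_value"] < 0.05].tolist()
    if not terms:
        raise SystemExit("no analytes at adj p < 0.05; nothing to classify")

    X = normalized.values.loc[groups.index]
    y = groups.to_numpy()
    full = fit_logistic(X, y, terms=terms)
    reduced = backward_stepwise_aic(X[terms], y)
    ev_full = evaluate_classifier(X, y, terms)
    ev_red = evaluate_classifier(X, y, reduced.terms) if reduced.terms else None

    print(f"full model: {len(terms)} analytes, AIC {full.aic:.2f}"
          f"{'  [separation flagged]' if full.separation_flag else ''}")
    print(f"reduced model: {reduced.terms} (AIC {reduced.aic:.2f})")
    print(f"full:    LOOCV accuracy {ev_full.loocv_accuracy:.2f}, "
          f"LOOCV AUC {ev_full.auc:.3f}, in-sample AUC {ev_full.insample_auc:.3f}")
    if ev_red:
        print(f"reduced: LOOCV accuracy {ev_red.loocv_accuracy:.2f}, "
              f"LOOCV AUC {ev_red.auc:.3f}, in-sample AUC {ev_red.insample_auc:.3f}")

    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps({
        "full": {"terms": full.terms, "coefficients": full.coefficients.tolist(),
                 "aic": full.aic, "separation_flag": full.separation_flag,
                 "loocv_accuracy": ev_full.loocv_accuracy, "loocv_auc": ev_full.auc,
                 "insample_auc": ev_full.insample_auc},
        "reduced": {"terms": reduced.terms,
                    "coefficients": reduced.coefficients.tolist(),
                    "aic": reduced.aic,
                    "loocv_accuracy": ev_red.loocv_accuracy if ev_red else None,
                    "loocv_auc": ev_red.auc if ev_red else None,
                    "insample_auc": ev_red.insample_auc if ev_red else None},
    }, indent=2))
    pd.DataFrame(ev_full.roc_points, columns=["FPR", "TPR"]).to_csv(
        args.roc_out, sep="\t", index=False
    )
    print(f"model dump -> {args.out}; ROC points -> {args.roc_out}")


if __name__ == "__main__":
    main()
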