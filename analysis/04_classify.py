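#!/usr/bin/env python
"""Classify phenotypes: random forest vs GRU, with Shapley attribution.

Trains the tabular random forest on the derived feature set and the
GRU on the per-frame sequences for the HL60-vs-HL60d pair, reports
held-out test accuracies and five-fold cross-validation, and writes the
Shapley feature-importance ranking.  All artifacts land in results/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from undulate.classifiers import (RandomForestClassifier, SplitSpec,
                                  cross_validate, feature_importance,
                                  train_gru, train_tabular)
from undulate.config import PipelineConfig
from undulate.features import BASE_FEATURE_NAMES

RESULTS = Path(__file__).resolve().parent.parent / "results"
RUN = RESULTS / "run"
SEED = 1
PAIR = ("HL60", "HL60d")


def main() -> None:
    df = pd.read_csv(RUN / "features.csv")
    sub = df[df["phenotype"].isin(PAIR)].reset_index(drop=True)
    x = sub[BASE_FEATURE_NAMES].to_numpy()
    y = (sub["phenotype"] == PAIR[1]).astype(int).to_numpy()

    rf = train_tabular(x, y, model_kind="random_forest", seed=SEED)
    print(f"Random forest ({PAIR[0]} vs {PAIR[1]}): "
          f"test accuracy {rf.report.accuracy:.3f} "
          f"(TPR {rf.report.tpr:.2f}, FPR {rf.report.fpr:.2f})")

    cv = cross_validate(
        lambda: RandomForestClassifier(n_estimators=200, random_state=0,
                                       n_jobs=1),
        x, y, k=5, seed=SEED)
    print(f"  5-fold CV: {cv['mean']:.3f} +/- {cv['sem']:.3f} (SEM)")

    x_tr, _ = rf.split["train"]
    x_te, _ = rf.split["test"]
    imp = feature_importance(rf.model, x_tr[:80], x_te,
                             feature_names=BASE_FEATURE_NAMES)
    print("  Shapley importance (mean |phi|):")
    for name, value in imp.ranking():
        print(f"    {name:10s} {value:.4f}")

    with np.load(RUN / "sequences.npz", allow_pickle=True) as z:
        seqs, valid, phen = z["sequences"], z["valid"], z["phenotypes"]
    keep = np.isin(phen, PAIR)
    y_seq = (phen[keep] == PAIR[1]).astype(int)
    gru = train_gru(seqs[keep], valid[keep], y_seq, units=32, epochs=40,
                    seed=SEED)
    print(f"GRU on (AR, perimeter, rD, area) sequences: "
          f"test accuracy {gru.report.accuracy:.3f}")

    out = {
        "pair": list(PAIR),
        "rf": rf.report.to_dict(),
        "rf_cv": cv,
        "gru": gru.report.to_dict(),
        "shap_ranking": [[n, float(v)] for n, v in imp.ranking()],
    }
    (RESULTS / "classification.json").write_text(
        json.dumps(out, indent=1, sort_keys=True))
    print("Wrote results/classification.json")


if __name__ == "__main__":
    main()
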