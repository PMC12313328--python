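"""Rare-cell enrichment implied by classifier operating characteristics.

If a target population is present at prior fraction p and a classifier
selects cells with true positive rate TPR and false positive rate FPR,
the selected (sorted) sample contains target cells at the Bayes
precision

    precision = TPR·p / (TPR·p + FPR·(1 − p))

and the fold enrichment is precision / p, bounded above by 1/p (a
perfect classifier) and equal to 1 for an uninformative one
(TPR = FPR).  For rare targets (p ≪ FPR) enrichment ≈ TPR/FPR, so
halving the false positive rate roughly doubles enrichment.
Expected-value accounting throughout; no finite-sample correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class EnrichmentResult:
    prior: float
    tpr: float
    fpr: float
    precision: float
    enrichment: float


def enrichment(tpr: float, fpr: float, prior: float) -> EnrichmentResult:
    """Fold enrichment of a rarity-``prior`` target after sorting."""
    for name, v in (("tpr", tpr), ("fpr", fpr), ("prior", prior)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    denom = tpr * prior + fpr * (1.0 - prior)
    if denom == 0:
        raise ValueError("classifier selects nothing (tpr = fpr = 0)")
    precision = tpr * prior / denom
    fold = precision / prior if prior > 0 else float("inf")
    return EnrichmentResult(prior=prior, tpr=tpr, fpr=fpr,
                            precision=precision, enrichment=fold)


def enrichment_curve(tpr: float, prior: float,
                     fpr_grid: np.ndarray) -> list[EnrichmentResult]:
    """Enrichment as a function of FPR; strictly decreasing in FPR."""
    fpr_grid = np.asarray(fpr_grid, dtype=float)
    if np.any(fpr_grid <= 0) or np.any(fpr_grid > 1):
        raise ValueError("fpr grid must lie in (0, 1]")
    return [enrichment(tpr, float(f), prior) for f in fpr_grid]


def expected_sorted_counts(prior: float, tpr: float, fpr: float,
                           n: float) -> dict[str, float]:
    """Expected composition of the selected sample of n input cells."""
    targets = n * prior * tpr
    non_targets = n * (1.0 - prior) * fpr
    return {"target": targets, "non_target": non_targets,
            "selected": targets + non_targets}
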