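"""Selection-performance metrics for simulation studies.

All rates are computed from the estimated and true support index sets of a
coefficient vector (main effects and GEI effects are scored separately):

* FPR  = false positives / number of non-causal predictors
* TPR  = true positives / number of causal predictors
* FDR  = false positives / number of selected predictors (0 if none selected)
* precision = 1 - FDR
* F1   = harmonic mean of precision and TPR
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable

__all__ = ["SelectionMetrics", "selection_metrics"]


@dataclass(frozen=True)
class SelectionMetrics:
    model_size: int
    fpr: float
    tpr: float
    fdr: float
    precision: float
    f1: float

    def to_dict(self) -> dict:
        return asdict(self)


def selection_metrics(
    estimated: Iterable[int], true: Iterable[int], p: int
) -> SelectionMetrics:
    """Score an estimated support against the true causal set.

    The empty estimated model has FDR 0 by convention (no discoveries means
    no false discoveries) and F1 = 0.  An empty true set (TPR undefined) or
    an all-causal predictor set (FPR undefined) is rejected.
    """
    est = set(int(j) for j in estimated)
    tru = set(int(j) for j in true)
    if not est <= set(range(p)) or not tru <= set(range(p)):
        raise ValueError("support indices must lie in {0, ..., p-1}")
    if len(tru) == 0:
        raise ValueError("TPR undefined: empty true support")
    if len(tru) == p:
        raise ValueError("FPR undefined: every predictor is causal")
    fp = len(est - tru)
    tp = len(est & tru)
    fpr = fp / (p - len(tru))
    tpr = tp / len(tru)
    fdr = fp / len(est) if est else 0.0
    precision = 1.0 - fdr
    if tpr > 0.0 and precision > 0.0:
        f1 = 2.0 / (1.0 / precision + 1.0 / tpr)
    else:
        f1 = 0.0
    return SelectionMetrics(
        model_size=len(est), fpr=fpr, tpr=tpr, fdr=fdr,
        precision=precision, f1=f1,
    )
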