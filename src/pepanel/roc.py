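"""Empirical ROC curves, partial AUC, and operating-point indices.

The panel search ranks markers by the partial area under the empirical ROC
curve restricted to false positive rates below 0.5 (pAUC, in raw area units:
a perfect classifier scores 0.5, chance scores 0.125).  Performance tables
report the full AUC, sensitivity at a 20% FPR, and the full 2x2-derived
index set (sensitivity, specificity, PPV, NPV, LR+, LR-) at the 10%-FPR
operating point.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.metrics import roc_curve

DEFAULT_FPR_CUT = 0.5


@dataclasses.dataclass(frozen=True)
class RocCurve:
    """Ordered (FPR, TPR) vertices of the empirical ROC, from (0,0) to (1,1).

    Tied scores produce diagonal segments, integrated trapezoidally.
    """

    fpr: np.ndarray
    tpr: np.ndarray

    def __post_init__(self) -> None:
        f, t = self.fpr, self.tpr
        if np.any(np.diff(f) < 0) or np.any(np.diff(t) < 0):
            raise ValueError("ROC coordinates must be non-decreasing")


def empirical_roc(scores: np.ndarray, y: np.ndarray) -> RocCurve:
    """Step-function ROC from pooled scores (higher = more case-like)."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to form a ROC curve")
    fpr, tpr, _ = roc_curve(y, np.asarray(scores, dtype=float), drop_intermediate=False)
    if fpr[0] != 0.0 or tpr[0] != 0.0:
        fpr = np.concatenate([[0.0], fpr])
        tpr = np.concatenate([[0.0], tpr])
    return RocCurve(fpr=fpr, tpr=tpr)


def auc(roc: RocCurve) -> float:
    return float(np.trapezoid(roc.tpr, roc.fpr))


def pauc(roc: RocCurve, fpr_cut: float = DEFAULT_FPR_CUT) -> float:
    """Trapezoidal area under the ROC restricted to FPR in [0, fpr_cut].

    Raw units: the maximum attainable value equals ``fpr_cut``.
    """
    if not 0 < fpr_cut <= 1:
        raise ValueError("fpr_cut must be in (0, 1]")
    f, t = roc.fpr, roc.tpr
    if fpr_cut >= f[-1]:
        return float(np.trapezoid(t, f))
    # interpolate the TPR at the cut (linear across any diagonal segment)
    t_cut = float(np.interp(fpr_cut, f, t))
    keep = f <= fpr_cut
    ff = np.concatenate([f[keep], [fpr_cut]])
    tt = np.concatenate([t[keep], [t_cut]])
    return float(np.trapezoid(tt, ff))


def sens_at_fpr(roc: RocCurve, fpr_target: float) -> tuple[float, float]:
    """Sensitivity and achieved specificity at the most permissive threshold
    whose empirical FPR does not exceed ``fpr_target``."""
    if not 0 <= fpr_target <= 1:
        raise ValueError("fpr_target must be in [0, 1]")
    ok = roc.fpr <= fpr_target + 1e-12
    i = int(np.max(np.nonzero(ok)[0]))
    return float(roc.tpr[i]), float(1.0 - roc.fpr[i])


@dataclasses.dataclass
class PerformanceReport:
    """The full LOOCV index set for one interval's final model.

    AUC and sensitivity at FPR 20% summarise the whole curve; the remaining
    indices are evaluated at the 10%-FPR operating point at the interval's
    observed prevalence.
    """

    auc: float
    sens_fpr20: float
    sens: float  # at the FPR-10% operating point
    spec: float  # achieved specificity at that point
    ppv: float
    npv: float
    lr_pos: float
    lr_neg: float
    n_controls: int
    n_cases: int

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def performance_report(
    scores: np.ndarray, y: np.ndarray, operating_fpr: float = 0.10
) -> PerformanceReport:
    """Compute the index set from pooled cross-validated scores."""
    y = np.asarray(y)
    roc = empirical_roc(scores, y)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    sens20, _ = sens_at_fpr(roc, 0.20)
    sens, spec = sens_at_fpr(roc, operating_fpr)
    fpr = 1.0 - spec
    tp = sens * n1
    fn = n1 - tp
    fp = fpr * n0
    tn = n0 - fp
    ppv = tp / (tp + fp) if tp + fp > 0 else np.nan
    npv = tn / (tn + fn) if tn + fn > 0 else np.nan
    lr_pos = sens / fpr if fpr > 0 else np.inf
    lr_neg = (1.0 - sens) / spec if spec > 0 else np.inf
    return PerformanceReport(
        auc=auc(roc),
        sens_fpr20=sens20,
        sens=sens,
        spec=spec,
        ppv=float(ppv),
        npv=float(npv),
        lr_pos=float(lr_pos),
        lr_neg=float(lr_neg),
        n_controls=n0,
        n_cases=n1,
    )
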