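"""Parsimonious LDA panel construction driven by LOOCV partial AUC.

The procedure, per gestational-age window: (1) drop candidate proteins whose
average abundance differs by less than 10% between cases and controls;
(2) rank the survivors by the leave-one-out cross-validated partial AUC
(FPR cut-off 0.5) of a single-marker linear discriminant; (3) grow the panel
greedily through the top-ranked proteins (at most five), accepting an
addition only when it raises the LOOCV pAUC by at least 0.01 raw units;
(4) report the final panel's full LOOCV performance index set.

The LDA score is the classical two-class discriminant with pooled
within-class covariance and class priors proportional to training counts:
higher scores are more case-like.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging

import numpy as np

from .intervals import IntervalDataset
from .roc import (
    DEFAULT_FPR_CUT,
    PerformanceReport,
    empirical_roc,
    pauc,
    performance_report,
)

logger = logging.getLogger(__name__)

MIN_CHANGE = 0.10  # minimal between-group average abundance change kept
MIN_GAIN = 0.01  # minimal pAUC gain to accept an additional panel protein
MAX_PANEL = 5
RIDGE = 1e-6  # x mean diagonal, applied only when the pooled covariance is singular
_VAR_FLOOR = 1e-12


@dataclasses.dataclass
class LdaModel:
    """Fitted two-class linear discriminant on a protein panel."""

    proteins: tuple[str, ...]
    mean_control: np.ndarray
    mean_case: np.ndarray
    weights: np.ndarray  # solves pooled_cov @ w = mean_case - mean_control
    offset_mid: float  # -0.5*(mu0+mu1)@w
    log_prior: float  # log(n_case/n_control)

    @property
    def offset(self) -> float:
        return self.offset_mid + self.log_prior

    @classmethod
    def fit(cls, X: np.ndarray, y: np.ndarray, proteins: tuple[str, ...]) -> "LdaModel":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y)
        X0, X1 = X[y == 0], X[y == 1]
        mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
        n = len(y)
        S = ((X0 - mu0).T @ (X0 - mu0) + (X1 - mu1).T @ (X1 - mu1)) / (n - 2)
        diff = mu1 - mu0
        try:
            w = np.linalg.solve(S, diff)
        except np.linalg.LinAlgError:
            logger.warning("singular pooled covariance; ridge-regularizing")
            S = S + RIDGE * np.mean(np.diag(S)) * np.eye(len(diff))
            w = np.linalg.solve(S, diff)
        return cls(
            proteins,
            mu0,
            mu1,
            w,
            float(-0.5 * (mu0 + mu1) @ w),
            float(np.log(len(X1) / len(X0))),
        )

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_2d(np.asarray(X, dtype=float)) @ self.weights + self.offset


def loocv_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pooled leave-one-patient-out LDA scores for one panel.

    Each patient's score comes from a discriminant fitted on all other
    patients; pre-condition: at least 3 patients per class.  The class-prior
    term is held at the full-data value log(n_case/n_control) across folds:
    priors shift scores monotonically and must not perturb the pooled ROC
    (the per-fold prior varies with the left-out patient's class and would
    bias it pessimistically).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == len(np.asarray(y)) or X.shape == (1, len(np.asarray(y))):
        X = X.reshape(len(np.asarray(y)), -1)
    y = np.asarray(y)
    if (y == 0).sum() < 3 or (y == 1).sum() < 3:
        raise ValueError("need at least 3 patients per class for LOOCV")
    if X.shape[1] == 1:
        return loocv_scores_single(X, y)[:, 0]
    n = len(y)
    scores = np.empty(n)
    idx = np.arange(n)
    proteins = tuple(str(j) for j in range(X.shape[1]))
    log_prior = float(np.log((y == 1).sum() / (y == 0).sum()))
    for i in range(n):
        keep = idx != i
        model = LdaModel.fit(X[keep], y[keep], proteins)
        scores[i] = X[i] @ model.weights + model.offset_mid + log_prior
    return scores


def loocv_scores_single(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorised single-marker LOOCV LDA scores for many proteins at once.

    ``X`` is patients x proteins; returns a matrix of the same shape whose
    column ``p`` holds each patient's held-out discriminant score on protein
    ``p``.  Uses exact leave-one-out downdates of the class sums and pooled
    variance, equivalent to refitting per patient.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    n, _ = X.shape
    m0 = (y == 0)[:, None]
    n0, n1 = int((y == 0).sum()), int((y == 1).sum())
    if n0 < 3 or n1 < 3:
        raise ValueError("need at least 3 patients per class for LOOCV")
    S0 = X[y == 0].sum(axis=0)
    S1 = X[y == 1].sum(axis=0)
    Q0 = (X[y == 0] ** 2).sum(axis=0)
    Q1 = (X[y == 1] ** 2).sum(axis=0)
    SS0 = Q0 - S0**2 / n0
    SS1 = Q1 - S1**2 / n1
    # leave-one-out class means
    mu0 = np.where(m0, (S0 - X) / (n0 - 1), S0 / n0)
    mu1 = np.where(m0, S1 / n1, (S1 - X) / (n1 - 1))
    # leave-one-out within-class sums of squares
    ss0 = np.where(m0, Q0 - X**2 - (S0 - X) ** 2 / (n0 - 1), SS0)
    ss1 = np.where(m0, SS1, Q1 - X**2 - (S1 - X) ** 2 / (n1 - 1))
    s2 = np.maximum((ss0 + ss1) / (n - 3), _VAR_FLOOR)
    return (X - 0.5 * (mu0 + mu1)) * (mu1 - mu0) / s2 + np.log(n1 / n0)


def candidate_filter(
    interval: IntervalDataset, min_change: float = MIN_CHANGE
) -> list[str]:
    """Keep proteins whose average abundance changes by at least ``min_change``
    (10%) between groups, i.e. |mean log2 MoM difference| >= log2(1.1);
    the boundary is inclusive."""
    X = interval.X.to_numpy(dtype=float)
    y = interval.y
    diff = X[y == 1].mean(axis=0) - X[y == 0].mean(axis=0)
    thr = np.log2(1.0 + min_change)
    keep = np.abs(diff) >= thr - 1e-12
    return [p for p, k in zip(interval.X.columns, keep) if k]


@dataclasses.dataclass
class GreedyStep:
    protein: str
    panel: tuple[str, ...]
    pauc: float
    gain: float
    accepted: bool


@dataclasses.dataclass
class SelectionTrace:
    """Audit trail of the panel search for one interval."""

    n_candidates_total: int
    filtered: list[str]
    ranking: list[tuple[str, float]]  # (protein, single-marker LOOCV pAUC)
    steps: list[GreedyStep]


class PanelSelectionModel:
    """Panel development model for one gestational-age interval.

    ``fit()`` runs the full filter/rank/greedy procedure and returns a
    :class:`PanelSelectionResults`; ``bootstrap()`` (see
    :mod:`pepanel.bootstrap`) repeats it inside resamples for honest
    performance estimates.
    """

    def __init__(
        self,
        interval: IntervalDataset,
        fpr_cut: float = DEFAULT_FPR_CUT,
        max_panel: int = MAX_PANEL,
        min_gain: float = MIN_GAIN,
        min_change: float = MIN_CHANGE,
    ):
        self.interval = interval
        self.fpr_cut = fpr_cut
        self.max_panel = max_panel
        self.min_gain = min_gain
        self.min_change = min_change

    # -- pieces -----------------------------------------------------------
    def rank_candidates(self, candidates: list[str]) -> list[tuple[str, float]]:
        """Single-marker LOOCV pAUC ranking, descending; ties broken by
        panel column order for determinism."""
        X = self.interval.X[candidates].to_numpy(dtype=float)
        y = self.interval.y
        scores = loocv_scores_single(X, y)
        paucs = np.array(
            [pauc(empirical_roc(scores[:, j], y), self.fpr_cut) for j in range(len(candidates))]
        )
        order = np.lexsort((np.arange(len(candidates)), -paucs))
        return [(candidates[j], float(paucs[j])) for j in order]

    def _panel_pauc(self, panel: tuple[str, ...]) -> tuple[float, np.ndarray]:
        X = self.interval.X[list(panel)].to_numpy(dtype=float)
        y = self.interval.y
        scores = loocv_scores(X, y)
        return pauc(empirical_roc(scores, y), self.fpr_cut), scores

    # -- the procedure ----------------------------------------------------
    def fit(self) -> "PanelSelectionResults":
        interval = self.interval
        if interval.n_controls < 5 or interval.n_cases < 5:
            raise ValueError("need at least 5 patients per group")
        candidates = candidate_filter(interval, self.min_change)
        if not candidates:
            trace = SelectionTrace(interval.X.shape[1], [], [], [])
            return PanelSelectionResults(self, trace, None, None, None, None)
        ranking = self.rank_candidates(candidates)
        top = ranking[: self.max_panel]
        panel = (top[0][0],)
        current_pauc, scores = self._panel_pauc(panel)
        steps = [GreedyStep(top[0][0], panel, current_pauc, np.nan, True)]
        for prot, _ in top[1:]:
            trial = panel + (prot,)
            trial_pauc, trial_scores = self._panel_pauc(trial)
            gain = trial_pauc - current_pauc
            accepted = gain >= self.min_gain
            steps.append(GreedyStep(prot, trial, trial_pauc, gain, accepted))
            if accepted:
                panel, current_pauc, scores = trial, trial_pauc, trial_scores
        trace = SelectionTrace(interval.X.shape[1], candidates, ranking, steps)
        model = LdaModel.fit(
            interval.X[list(panel)].to_numpy(dtype=float), interval.y, panel
        )
        report = performance_report(scores, interval.y)
        return PanelSelectionResults(self, trace, panel, model, scores, report)


@dataclasses.dataclass
class PanelSelectionResults:
    """Outcome of the panel search: trace, final model and LOOCV indices.

    ``panel`` is None when no candidate survived the 10% filter (a "no
    model" outcome, not an error).
    """

    model_spec: PanelSelectionModel
    trace: SelectionTrace
    panel: tuple[str, ...] | None
    lda: LdaModel | None
    loocv_scores_: np.ndarray | None
    performance: PerformanceReport | None

    @property
    def has_model(self) -> bool:
        return self.panel is not None

    def summary(self) -> str:
        iv = self.model_spec.interval.interval.label
        lines = [f"Panel selection — interval {iv} weeks"]
        lines.append(
            f"  patients: {self.model_spec.interval.n_controls} controls / "
            f"{self.model_spec.interval.n_cases} cases"
        )
        lines.append(
            f"  candidates passing 10% filter: {len(self.trace.filtered)}"
            f" of {self.trace.n_candidates_total}"
        )
        if not self.has_model:
            lines.append("  no model (empty candidate list)")
            return "\n".join(lines)
        lines.append("  panel: " + " + ".join(self.panel))
        p = self.performance
        lines.append(
            f"  LOOCV AUC {p.auc:.2f}; sens@FPR20 {p.sens_fpr20:.2f}; "
            f"sens {p.sens:.2f} / spec {p.spec:.2f} @FPR10; "
            f"PPV {p.ppv:.2f} NPV {p.npv:.2f} LR+ {p.lr_pos:.1f} LR- {p.lr_neg:.2f}"
        )
        return "\n".join(lines)

    def as_dict(self) -> dict:
        return {
            "interval": self.model_spec.interval.interval.label,
            "panel": list(self.panel) if self.panel else [],
            "ranking": [[p, v] for p, v in self.trace.ranking[:20]],
            "steps": [
                {
                    "protein": s.protein,
                    "panel": list(s.panel),
                    "pauc": s.pauc,
                    "gain": None if np.isnan(s.gain) else s.gain,
                    "accepted": s.accepted,
                }
                for s in self.trace.steps
            ],
            "performance": self.performance.as_dict() if self.performance else None,
        }


def best_subset(
    interval: IntervalDataset,
    candidates: list[str],
    max_size: int = 2,
    fpr_cut: float = DEFAULT_FPR_CUT,
) -> tuple[tuple[str, ...], float]:
    """Exhaustively evaluate every panel of size <= max_size by LOOCV pAUC.

    Reference search used to validate the greedy procedure on small inputs;
    not part of the standard pipeline.
    """
    y = interval.y
    best: tuple[tuple[str, ...], float] = ((), -np.inf)
    for k in range(1, max_size + 1):
        for combo in itertools.combinations(candidates, k):
            X = interval.X[list(combo)].to_numpy(dtype=float)
            scores = loocv_scores(X, y)
            v = pauc(empirical_roc(scores, y), fpr_cut)
            if v > best[1]:
                best = (combo, v)
    return best
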