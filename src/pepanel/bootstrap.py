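"""Bootstrap estimation of panel performance with in-loop feature selection.

Naive LOOCV indices for a panel chosen from 1,000+ candidates are optimistic
because the candidates themselves were picked on the same data.  The honest
estimate repeats the *entire* development procedure — 10% filter, pAUC
ranking, greedy panel growth — inside each bootstrap resample of patients
(drawn with replacement, stratified by group so class sizes are preserved),
then evaluates the resulting model only on the out-of-bag patients.  Means
and 95% percentile intervals over (by default) 100 iterations are reported,
along with how often each protein entered the chosen panel — a stability
measure.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import Counter

import numpy as np
import pandas as pd

from .intervals import IntervalDataset
from .roc import empirical_roc, auc as roc_auc, sens_at_fpr
from .selection import (
    MAX_PANEL,
    MIN_CHANGE,
    MIN_GAIN,
    DEFAULT_FPR_CUT,
    PanelSelectionModel,
)

logger = logging.getLogger(__name__)

DEFAULT_B = 100
_MIN_OOB = 3  # minimum out-of-bag patients per class for a usable iteration


@dataclasses.dataclass
class BootstrapIteration:
    panel: tuple[str, ...]
    oob_auc: float
    oob_sens_fpr20: float
    oob_spec: float
    n_oob_controls: int
    n_oob_cases: int


@dataclasses.dataclass
class BootstrapSummary:
    """Aggregated out-of-bag performance and selection stability."""

    B: int
    iterations: list[BootstrapIteration]
    mean: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    selection_counts: Counter
    first_ranked_counts: Counter
    n_redrawn: int
    n_no_model: int

    def summary(self) -> str:
        lines = [f"Bootstrap ({self.B} completed iterations)"]
        for k in ("auc", "sens_fpr20", "spec"):
            lo, hi = self.ci95[k]
            lines.append(f"  {k}: mean {self.mean[k]:.2f} (95% CI {lo:.2f}-{hi:.2f})")
        top = self.selection_counts.most_common(8)
        lines.append(
            "  selection counts: "
            + "; ".join(f"{p}({c})" for p, c in top if c >= max(1, self.B // 20))
        )
        if self.n_redrawn or self.n_no_model:
            lines.append(
                f"  redrawn resamples: {self.n_redrawn} (small out-of-bag or no model)"
            )
        return "\n".join(lines)

    def iteration_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "panel": ["+".join(it.panel) for it in self.iterations],
                "oob_auc": [it.oob_auc for it in self.iterations],
                "oob_sens_fpr20": [it.oob_sens_fpr20 for it in self.iterations],
                "oob_spec": [it.oob_spec for it in self.iterations],
                "n_oob_controls": [it.n_oob_controls for it in self.iterations],
                "n_oob_cases": [it.n_oob_cases for it in self.iterations],
            }
        )

    def as_dict(self) -> dict:
        return {
            "B": self.B,
            "mean": self.mean,
            "ci95": {k: list(v) for k, v in self.ci95.items()},
            "selection_counts": dict(self.selection_counts),
            "n_redrawn": self.n_redrawn,
            "n_no_model": self.n_no_model,
        }


def _subset(interval: IntervalDataset, idx: np.ndarray) -> IntervalDataset:
    return IntervalDataset(
        interval=interval.interval,
        X=interval.X.iloc[idx].reset_index(drop=True),
        patient_id=interval.patient_id[idx],
        group=interval.group[idx],
        source_ga=interval.source_ga[idx],
        severity=None if interval.severity is None else interval.severity[idx],
    )


def bootstrap_evaluate(
    interval: IntervalDataset,
    B: int = DEFAULT_B,
    seed: int = 0,
    fpr_cut: float = DEFAULT_FPR_CUT,
    max_panel: int = MAX_PANEL,
    min_gain: float = MIN_GAIN,
    min_change: float = MIN_CHANGE,
    operating_fpr: float = 0.20,
) -> BootstrapSummary:
    """Run ``B`` completed bootstrap iterations of the full selection pipeline.

    Resampling is with replacement within group (class sizes preserved);
    MoM values are taken as given (normalization is not repeated inside the
    loop).  Resamples leaving fewer than 3 out-of-bag patients in either
    class, or on which no candidate survives the filter, are redrawn and
    logged.  Deterministic given ``seed``.
    """
    if B < 10:
        logger.warning("B=%d is small; aggregate estimates will be unstable", B)
    rng = np.random.default_rng(seed)
    y = interval.y
    controls = np.nonzero(y == 0)[0]
    cases = np.nonzero(y == 1)[0]
    iterations: list[BootstrapIteration] = []
    selection_counts: Counter = Counter()
    first_ranked: Counter = Counter()
    n_redrawn = 0
    n_no_model = 0
    max_attempts = 50 * B
    attempts = 0
    while len(iterations) < B and attempts < max_attempts:
        attempts += 1
        train_idx = np.concatenate(
            [
                rng.choice(controls, size=len(controls), replace=True),
                rng.choice(cases, size=len(cases), replace=True),
            ]
        )
        oob_idx = np.setdiff1d(np.arange(len(y)), np.unique(train_idx))
        n_oob0 = int((y[oob_idx] == 0).sum())
        n_oob1 = int((y[oob_idx] == 1).sum())
        if n_oob0 < _MIN_OOB or n_oob1 < _MIN_OOB:
            n_redrawn += 1
            logger.debug("redraw: out-of-bag too small (%d/%d)", n_oob0, n_oob1)
            continue
        train = _subset(interval, train_idx)
        results = PanelSelectionModel(
            train,
            fpr_cut=fpr_cut,
            max_panel=max_panel,
            min_gain=min_gain,
            min_change=min_change,
        ).fit()
        if not results.has_model:
            n_no_model += 1
            n_redrawn += 1
            logger.debug("redraw: no candidates survived the filter")
            continue
        X_oob = interval.X.iloc[oob_idx][list(results.panel)].to_numpy(dtype=float)
        scores = results.lda.decision_scores(X_oob)
        roc = empirical_roc(scores, y[oob_idx])
        sens, spec = sens_at_fpr(roc, operating_fpr)
        iterations.append(
            BootstrapIteration(
                panel=results.panel,
                oob_auc=roc_auc(roc),
                oob_sens_fpr20=sens,
                oob_spec=spec,
                n_oob_controls=n_oob0,
                n_oob_cases=n_oob1,
            )
        )
        for p in results.panel:
            selection_counts[p] += 1
        first_ranked[results.trace.ranking[0][0]] += 1
    if not iterations:
        raise RuntimeError("no bootstrap iteration completed")
    if len(iterations) < B:
        logger.warning(
            "only %d/%d bootstrap iterations completed after %d attempts",
            len(iterations),
            B,
            attempts,
        )
    arr = {
        "auc": np.array([it.oob_auc for it in iterations]),
        "sens_fpr20": np.array([it.oob_sens_fpr20 for it in iterations]),
        "spec": np.array([it.oob_spec for it in iterations]),
    }
    mean = {k: float(v.mean()) for k, v in arr.items()}
    ci95 = {
        k: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
        for k, v in arr.items()
    }
    return BootstrapSummary(
        B=len(iterations),
        iterations=iterations,
        mean=mean,
        ci95=ci95,
        selection_counts=selection_counts,
        first_ranked_counts=first_ranked,
        n_redrawn=n_redrawn,
        n_no_model=n_no_model,
    )
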