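"""Gestational-age analysis windows and per-patient interval datasets.

Classification operates on five canonical windows — 8-16, 16.1-22, 22.1-28,
28.1-32 and 32.1-36 weeks — with one row per patient per window.  The first
window is closed on both ends ([8, 16]); the rest are half-open on the left
((l, u]), matching the "16.1-22" style labelling of gestational ages recorded
to about a tenth of a week.  Together the windows partition (8, 36].
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .cohort import CovariateTable, LATE_PE
from .normative import MoMMatrix


@dataclasses.dataclass(frozen=True)
class GAInterval:
    label: str
    lower: float
    upper: float
    closed_left: bool = False

    def contains(self, ga: float) -> bool:
        if self.closed_left:
            return self.lower <= ga <= self.upper
        return self.lower < ga <= self.upper

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lower + self.upper)


CANONICAL_INTERVALS: tuple[GAInterval, ...] = (
    GAInterval("8-16", 8.0, 16.0, closed_left=True),
    GAInterval("16.1-22", 16.0, 22.0),
    GAInterval("22.1-28", 22.0, 28.0),
    GAInterval("28.1-32", 28.0, 32.0),
    GAInterval("32.1-36", 32.0, 36.0),
)

COLLAPSE_RULES = ("midpoint", "earliest", "mean")


@dataclasses.dataclass
class IntervalDataset:
    """One window's classification table: one row per patient.

    ``X`` is patients x proteins (log2 MoM), aligned with ``patient_id``,
    ``group`` and ``source_ga`` (the gestational age of the sample that was
    used; NaN when rows are per-patient means).
    """

    interval: GAInterval
    X: pd.DataFrame
    patient_id: np.ndarray
    group: np.ndarray  # 'control' / 'late_pe'
    source_ga: np.ndarray
    severity: np.ndarray | None = None

    @property
    def y(self) -> np.ndarray:
        """Binary labels: 1 = case."""
        return (self.group == LATE_PE).astype(int)

    @property
    def n_controls(self) -> int:
        return int((self.y == 0).sum())

    @property
    def n_cases(self) -> int:
        return int((self.y == 1).sum())

    def attach_severity(self, covariates: CovariateTable) -> None:
        self.severity = np.array(
            [covariates.severity_of(p) for p in self.patient_id], dtype=object
        )

    def subset_outcome(self, outcome: str) -> "IntervalDataset":
        """Restrict cases to one severity ('mild'/'severe'); controls kept.

        ``outcome='all'`` returns self unchanged.
        """
        if outcome == "all":
            return self
        if self.severity is None:
            raise ValueError("severity labels not attached")
        keep = (self.y == 0) | (self.severity == outcome)
        return IntervalDataset(
            interval=self.interval,
            X=self.X.loc[keep].reset_index(drop=True),
            patient_id=self.patient_id[keep],
            group=self.group[keep],
            source_ga=self.source_ga[keep],
            severity=self.severity[keep],
        )


def assign_intervals(
    mom: MoMMatrix,
    intervals: tuple[GAInterval, ...] = CANONICAL_INTERVALS,
    rule: str = "midpoint",
) -> dict[str, IntervalDataset]:
    """Slice the MoM matrix into per-patient interval datasets.

    When a patient has several samples inside one window, ``rule`` picks the
    representative: ``midpoint`` (default) keeps the sample whose GA is
    closest to the window midpoint, ties resolved toward the earlier GA;
    ``earliest`` keeps the first sample; ``mean`` averages the log2 MoM
    vectors (source GA reported as NaN).
    """
    if rule not in COLLAPSE_RULES:
        raise ValueError(f"unknown collapse rule {rule!r}; options {COLLAPSE_RULES}")
    ga = mom.meta["ga_weeks"].to_numpy(dtype=float)
    out: dict[str, IntervalDataset] = {}
    for iv in intervals:
        if iv.closed_left:
            in_iv = (ga >= iv.lower) & (ga <= iv.upper)
        else:
            in_iv = (ga > iv.lower) & (ga <= iv.upper)
        sub_meta = mom.meta.loc[in_iv]
        sub_vals = mom.values.loc[in_iv]
        rows_X, pids, grps, gas = [], [], [], []
        for pid, idx in sub_meta.groupby("patient_id", sort=True).groups.items():
            m = sub_meta.loc[idx]
            if rule == "mean" and len(idx) > 1:
                rows_X.append(sub_vals.loc[idx].mean(axis=0).to_numpy())
                gas.append(np.nan)
            else:
                g = m["ga_weeks"].to_numpy(dtype=float)
                if rule == "earliest" or len(idx) == 1:
                    pick = np.argmin(g)
                else:  # midpoint, ties -> earlier GA (stable argmin on distance)
                    dist = np.abs(g - iv.midpoint)
                    order = np.lexsort((g, dist))
                    pick = order[0]
                rows_X.append(sub_vals.loc[idx[pick]].to_numpy())
                gas.append(float(g[pick]))
            pids.append(pid)
            grps.append(m["group"].iloc[0])
        X_arr = (
            np.asarray(rows_X)
            if rows_X
            else np.empty((0, len(mom.proteins)))
        )
        out[iv.label] = IntervalDataset(
            interval=iv,
            X=pd.DataFrame(X_arr, columns=mom.proteins),
            patient_id=np.asarray(pids, dtype=object),
            group=np.asarray(grps, dtype=object),
            source_ga=np.asarray(gas, dtype=float),
        )
    return out
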