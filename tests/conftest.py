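"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import pytest

from pepanel.cohort import CONTROL, LATE_PE, CohortTable, ProteinPanel
from pepanel.intervals import GAInterval, IntervalDataset

logging.getLogger("pepanel").setLevel(logging.ERROR)


def make_interval(
    n_controls: int,
    n_cases: int,
    n_proteins: int,
    seed: int = 0,
    effects: dict[int, float] | None = None,
    sigma: float = 0.43,
    label: str = "8-16",
) -> IntervalDataset:
    """Directly build a per-patient interval dataset of log2 MoM values.

    Controls draw N(0, sigma^2) per protein; cases additionally shift by the
    given log2 effects.  sigma=0.43 is the total per-sample SD implied by the
    generator defaults (sqrt(0.35^2 + 0.25^2)).
    """
    rng = np.random.default_rng(seed)
    n = n_controls + n_cases
    X = rng.normal(0.0, sigma, size=(n, n_proteins))
    if effects:
        for j, delta in effects.items():
            X[n_controls:, j] += delta
    cols = [f"PROT{j:04d}" for j in range(n_proteins)]
    group = np.array([CONTROL] * n_controls + [LATE_PE] * n_cases, dtype=object)
    pids = np.array([f"C{i}" for i in range(n_controls)] + [f"P{i}" for i in range(n_cases)], dtype=object)
    return IntervalDataset(
        interval=GAInterval(label, 8.0, 16.0, closed_left=True),
        X=pd.DataFrame(X, columns=cols),
        patient_id=pids,
        group=group,
        source_ga=rng.uniform(8.0, 16.0, size=n),
    )


def make_cohort_from_log2(
    meta: pd.DataFrame, log2_values: np.ndarray, prefix: str = "PROT"
) -> CohortTable:
    """Wrap raw log2 values (samples x proteins) into a CohortTable."""
    p = log2_values.shape[1]
    panel = ProteinPanel(columns=tuple(f"{prefix}{j:04d}" for j in range(p)))
    return CohortTable(
        meta=meta.reset_index(drop=True),
        abundance=pd.DataFrame(np.exp2(log2_values), columns=list(panel.columns)),
        panel=panel,
    )


@pytest.fixture
def toy_cohort_csv(tmp_path):
    path = tmp_path / "toy.csv"
    path.write_text(
        "ID,GA,LatePE,ProtA,ProtB,ProtC\n"
        "pt1,12.5,0,100.0,5.5,2000\n"
        "pt2,30.1,1,110.0,6.1,1500\n"
    )
    return path
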