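"""Thresholding, normative spline fits and MoM calibration."""

import numpy as np
import pandas as pd
import pytest

from pepanel.cohort import CohortTable, ProteinPanel
from pepanel.normative import (
    EstimationError,
    NormativeModel,
    compute_mom,
    normalize_cohort,
    threshold_outliers,
)
from pepanel.simulate import SyntheticConfig, generate_cohort

from conftest import make_cohort_from_log2


def _single_protein_cohort(values, ga=None, patients=None):
    n = len(values)
    meta = pd.DataFrame(
        {
            "patient_id": patients if patients is not None else [f"p{i}" for i in range(n)],
            "ga_weeks": ga if ga is not None else np.linspace(8, 36, n),
            "group": ["control"] * n,
        }
    )
    return CohortTable(
        meta=meta,
        abundance=pd.DataFrame({"P0": np.asarray(values, dtype=float)}),
        panel=ProteinPanel(columns=("P0",)),
    )


# -- thresholding ---------------------------------------------------------


def test_constant_column_untouched():
    cohort = _single_protein_cohort(np.full(20, 7.0))
    capped, n = threshold_outliers(cohort)
    assert n == 0
    assert np.array_equal(capped.abundance["P0"].to_numpy(), np.full(20, 7.0))


def test_cap_matches_brute_force_percentile_rule():
    """Only values above 2x the (type 7) 98th percentile are replaced."""
    values = np.concatenate([np.arange(1.0, 100.0), [1000.0]])
    cohort = _single_protein_cohort(values)
    capped, n = threshold_outliers(cohort)
    # brute-force type 7 percentile: linear interpolation of order statistics
    srt = np.sort(values)
    h = 0.98 * (len(srt) - 1)
    lo = int(np.floor(h))
    q98 = srt[lo] + (h - lo) * (srt[lo + 1] - srt[lo])
    cap = 2 * q98
    assert n == 1
    expect = np.where(values > cap, cap, values)
    assert np.allclose(capped.abundance["P0"].to_numpy(), expect)


def test_two_identical_outliers_get_same_cap():
    values = np.concatenate([np.linspace(1, 2, 98), [500.0, 500.0]])
    cohort = _single_protein_cohort(values)
    capped, n = threshold_outliers(cohort)
    out = capped.abundance["P0"].to_numpy()
    assert n == 2
    assert out[-1] == out[-2] < 500.0


def test_thresholding_order_independent_and_idempotent():
    rng = np.random.default_rng(0)
    values = np.exp(rng.normal(2, 1, size=60))
    values[:3] *= 50
    cohort = _single_protein_cohort(values)
    perm = rng.permutation(60)
    cohort_perm = _single_protein_cohort(values[perm], ga=np.linspace(8, 36, 60)[perm])
    once, _ = threshold_outliers(cohort)
    once_perm, _ = threshold_outliers(cohort_perm)
    assert np.allclose(
        np.sort(once.abundance["P0"]), np.sort(once_perm.abundance["P0"])
    )
    twice, n2 = threshold_outliers(once)
    if n2 == 0:  # idempotent when the recomputed cap clears the capped column
        assert np.array_equal(twice.abundance["P0"], once.abundance["P0"])


# -- normative fits -------------------------------------------------------


def test_too_few_controls_is_estimation_error():
    cohort = _single_protein_cohort(np.full(5, 2.0), ga=np.linspace(8, 36, 5))
    with pytest.raises(EstimationError):
        NormativeModel(cohort)


def test_degenerate_constant_fit_is_flat_with_zero_variances():
    cohort = _single_protein_cohort(np.full(30, 8.0))
    res = NormativeModel(cohort).fit()
    fit = res["P0"]
    grid = np.linspace(9, 35, 40)
    assert np.allclose(fit.mean_log2(grid), np.log2(8.0), atol=1e-8)
    assert fit.sigma2_patient == 0.0
    assert fit.sigma2_resid == pytest.approx(0.0, abs=1e-12)


def test_recovers_known_linear_trend():
    """Mean curve within +-0.05 log2 units of a + b*GA (patient SD 0.3),
    averaged over seeds, across 10-36 weeks."""
    a, b = 6.0, 0.05
    errs = []
    grid = np.linspace(10, 36, 27)
    for seed in range(20):
        rng = np.random.default_rng(seed)
        rows_meta, vals = [], []
        for i in range(90):
            k = rng.integers(2, 7)
            ga = np.sort(rng.uniform(8, 40, size=k))
            bi = rng.normal(0, 0.3)
            y = a + b * ga + bi + rng.normal(0, 0.2, size=k)
            for g, v in zip(ga, y):
                rows_meta.append((f"p{i}", g, "control"))
                vals.append(v)
        meta = pd.DataFrame(rows_meta, columns=["patient_id", "ga_weeks", "group"])
        cohort = make_cohort_from_log2(meta, np.asarray(vals)[:, None])
        res = NormativeModel(cohort).fit()
        errs.append(np.abs(res["PROT0000"].mean_log2(grid) - (a + b * grid)).mean())
    assert float(np.mean(errs)) < 0.05


def test_fixed_curve_identifiable_without_random_effect():
    """With sigma_patient = 0 in the generator, permuting patient labels
    leaves the fitted fixed-effect curve essentially unchanged."""
    rng = np.random.default_rng(1)
    n = 120
    ga = rng.uniform(8, 40, size=n)
    y = 5.0 + 0.1 * ga + rng.normal(0, 0.2, size=n)
    patients = [f"p{i % 40}" for i in range(n)]  # samples scattered across GA
    meta = pd.DataFrame({"patient_id": patients, "ga_weeks": ga, "group": "control"})
    cohort = make_cohort_from_log2(meta, y[:, None])
    perm = rng.permutation(n)
    meta2 = meta.copy()
    meta2["patient_id"] = np.asarray(patients, dtype=object)[perm]
    cohort2 = make_cohort_from_log2(meta2, y[:, None])
    grid = np.linspace(9, 39, 50)
    c1 = NormativeModel(cohort).fit()["PROT0000"].mean_log2(grid)
    c2 = NormativeModel(cohort2).fit()["PROT0000"].mean_log2(grid)
    # estimated patient variance sits on the boundary, so GLS weights (and
    # hence the curve) can wiggle slightly between label assignments
    assert np.allclose(c1, c2, atol=0.05)


# -- MoM ------------------------------------------------------------------


def test_mom_zero_and_one_doubling_conventions():
    """Abundance at the predicted mean -> log2 MoM 0; doubled -> 1."""
    cfg = SyntheticConfig(n_controls=30, n_cases=0, n_proteins=2, seed=8)
    cohort, _, _ = generate_cohort(cfg)
    res = NormativeModel(cohort).fit()
    ga = cohort.meta["ga_weeks"].to_numpy()
    pred = res.predicted_mean_log2(ga, list(cohort.panel.columns))
    exact = CohortTable(
        meta=cohort.meta.copy(),
        abundance=pd.DataFrame(np.exp2(pred), columns=list(cohort.panel.columns)),
        panel=cohort.panel,
    )
    mom = compute_mom(exact, res)
    assert np.allclose(mom.values.to_numpy(), 0.0, atol=1e-10)
    doubled = CohortTable(
        meta=cohort.meta.copy(),
        abundance=pd.DataFrame(2 * np.exp2(pred), columns=list(cohort.panel.columns)),
        panel=cohort.panel,
    )
    assert np.allclose(compute_mom(doubled, res).values.to_numpy(), 1.0, atol=1e-10)


def test_control_mom_calibrated_within_ga_bins():
    """Mean control log2 MoM is 0 +- 0.05 in every 2-week bin with >= 50 values."""
    cfg = SyntheticConfig(
        n_controls=150,
        n_cases=0,
        n_proteins=6,
        samples_per_patient=(4, 6),
        sigma_patient=0.15,
        sigma_resid=0.15,
        seed=13,
    )
    cohort, _, _ = generate_cohort(cfg)
    mom, _, _ = normalize_cohort(cohort)
    ga = mom.meta["ga_weeks"].to_numpy()
    vals = mom.values.to_numpy()
    checked = 0
    for lo in np.arange(8, 40, 2.0):
        in_bin = (ga >= lo) & (ga < lo + 2)
        binned = vals[in_bin].ravel()
        if len(binned) >= 50:
            checked += 1
            assert abs(float(binned.mean())) < 0.05, f"bin {lo}-{lo+2}"
    assert checked >= 10


def test_mom_invariant_to_protein_rescaling():
    cfg = SyntheticConfig(n_controls=40, n_cases=10, n_proteins=2, seed=21)
    cohort, _, _ = generate_cohort(cfg)
    mom1, _, _ = normalize_cohort(cohort)
    scaled = CohortTable(
        meta=cohort.meta.copy(),
        abundance=cohort.abundance * [7.0, 1.0],
        panel=cohort.panel,
    )
    mom2, _, _ = normalize_cohort(scaled)
    assert np.allclose(mom1.values.to_numpy(), mom2.values.to_numpy(), atol=1e-5)


def test_extrapolation_is_linear_beyond_fitted_range():
    rng = np.random.default_rng(3)
    n = 80
    ga = np.sort(rng.uniform(12, 30, size=n))
    y = 4.0 + 0.2 * ga + rng.normal(0, 0.1, size=n)
    meta = pd.DataFrame(
        {"patient_id": [f"p{i//2}" for i in range(n)], "ga_weeks": ga, "group": "control"}
    )
    cohort = make_cohort_from_log2(meta, y[:, None])
    fit = NormativeModel(cohort).fit()["PROT0000"]
    lo = fit.knots[0]
    # equally spaced points below the boundary continue the boundary slope
    outside = fit.mean_log2(np.array([lo - 2.0, lo - 1.0, lo]))
    assert outside[2] - outside[1] == pytest.approx(outside[1] - outside[0], abs=1e-9)
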