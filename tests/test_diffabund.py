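"""Moderated-t differential abundance: shrinkage limits, calibration, FCs."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pepanel.cohort import CovariateTable
from pepanel.diffabund import (
    ModeratedTModel,
    cross_interval_summary,
    signed_fc,
    squeeze_var,
)

from conftest import make_interval


def _covariates_for(ds, seed=0, group_dependent=False):
    rng = np.random.default_rng(seed)
    n = len(ds.patient_id)
    bmi = rng.normal(27, 4, n)
    if group_dependent:
        bmi = bmi + 3.0 * ds.y
    data = pd.DataFrame(
        {
            "bmi": bmi,
            "maternal_age": rng.normal(24, 5, n),
            "parity": rng.poisson(1.2, n).astype(float),
            "smoking": (rng.random(n) < 0.2).astype(float),
            "severity": np.where(ds.y == 1, "mild", "none"),
        },
        index=pd.Index(ds.patient_id, name="patient_id"),
    )
    return CovariateTable(data=data)


# -- signed fold change ---------------------------------------------------


@pytest.mark.parametrize(
    "log2fc,expected",
    [(0.0, 1.0), (1.0, 2.0), (-1.0, -2.0), (0.485, 2**0.485)],
)
def test_signed_fc_conventions(log2fc, expected):
    assert signed_fc(log2fc) == pytest.approx(expected)
    assert abs(signed_fc(log2fc)) >= 1.0


def test_signed_fc_display_rounding_matches_1_4():
    assert round(signed_fc(0.485), 1) == 1.4


# -- shrinkage limits -----------------------------------------------------


def _ordinary_t(ds):
    """Per-protein OLS t for the group coefficient, via statsmodels."""
    import statsmodels.api as sm

    X = sm.add_constant(ds.y.astype(float))
    ts = []
    for j in range(ds.X.shape[1]):
        ts.append(sm.OLS(ds.X.iloc[:, j].to_numpy(), X).fit().tvalues[1])
    return np.array(ts)


def test_prior_df_zero_recovers_ordinary_t():
    ds = make_interval(20, 20, 30, seed=1, effects={0: 0.5})
    res = ModeratedTModel(ds, prior_df=0).fit()
    np.testing.assert_allclose(res.table["t"].to_numpy(), _ordinary_t(ds), atol=1e-8)


def test_prior_df_infinite_pools_all_variances():
    ds = make_interval(20, 20, 30, seed=2)
    res = ModeratedTModel(ds, prior_df=np.inf).fit()
    # all posterior variances equal s0^2 => t_j proportional to the raw effect
    t = res.table["t"].to_numpy()
    b = res.table["log2fc"].to_numpy()
    ratio = t / b
    np.testing.assert_allclose(ratio, ratio[0], rtol=1e-10)


def test_moderated_t_between_ordinary_and_pooled():
    ds = make_interval(15, 15, 80, seed=3)
    t_mod = ModeratedTModel(ds).fit().table["t"].to_numpy()
    t_ord = ModeratedTModel(ds, prior_df=0).fit().table["t"].to_numpy()
    t_pool = ModeratedTModel(ds, prior_df=np.inf).fit().table["t"].to_numpy()
    lo = np.minimum(np.abs(t_ord), np.abs(t_pool)) - 1e-9
    hi = np.maximum(np.abs(t_ord), np.abs(t_pool)) + 1e-9
    assert np.all((np.abs(t_mod) >= lo) & (np.abs(t_mod) <= hi))


def test_squeeze_var_recovers_simulated_prior():
    """Variances drawn from a scaled inverse chi-square prior (d0=8) are
    shrunk with an estimated d0 in the right range."""
    rng = np.random.default_rng(4)
    d, d0_true, s0_true = 10, 8.0, 0.04
    sigma2 = s0_true * d0_true / rng.chisquare(d0_true, size=3000)
    s2 = sigma2 * rng.chisquare(d, size=3000) / d
    d0, s0_2, post = squeeze_var(s2, d)
    assert d0 == pytest.approx(d0_true, rel=0.25)
    assert s0_2 == pytest.approx(s0_true, rel=0.10)
    assert np.all((post >= np.minimum(s2, s0_2)) & (post <= np.maximum(s2, s0_2)))


# -- calibration ----------------------------------------------------------


def test_null_pvalues_uniform_and_few_significant():
    """No effects, covariates independent of group: p ~ U(0,1) and the
    q<0.25 & |FC|>1.1 rule flags at most ~5% of proteins on average."""
    fracs = []
    pooled_p = []
    for seed in range(10):
        ds = make_interval(60, 60, 300, seed=seed)
        cov = _covariates_for(ds, seed=seed)
        res = ModeratedTModel(ds, covariates=cov).fit()
        fracs.append(res.table["significant"].mean())
        pooled_p.append(res.table["p"].to_numpy())
    assert stats.kstest(np.concatenate(pooled_p), "uniform").pvalue > 0.01
    assert float(np.mean(fracs)) <= 0.05


def test_adjusted_equals_unadjusted_when_covariates_orthogonal():
    ds = make_interval(20, 20, 10, seed=6)
    # identical covariate pattern in both groups -> exactly orthogonal
    base = _covariates_for(ds, seed=1)
    vals = base.data.iloc[:20].reset_index(drop=True)
    data = pd.concat([vals, vals], ignore_index=True)
    data.index = pd.Index(ds.patient_id, name="patient_id")
    data["severity"] = np.where(ds.y == 1, "mild", "none")
    cov = CovariateTable(data=data)
    adj = ModeratedTModel(ds, covariates=cov).fit().table["log2fc"].to_numpy()
    unadj = ModeratedTModel(ds).fit().table["log2fc"].to_numpy()
    np.testing.assert_allclose(adj, unadj, atol=1e-10)


def test_group_confounded_covariate_changes_the_estimate():
    ds = make_interval(40, 40, 5, seed=8, effects={0: 0.5})
    cov = _covariates_for(ds, seed=2, group_dependent=True)
    adj = ModeratedTModel(ds, covariates=cov).fit().table["log2fc"].to_numpy()
    unadj = ModeratedTModel(ds).fit().table["log2fc"].to_numpy()
    assert not np.allclose(adj, unadj, atol=1e-6)


def test_missing_covariates_drop_patients_with_count():
    ds = make_interval(20, 20, 5, seed=9)
    cov = _covariates_for(ds, seed=3)
    cov.data.iloc[0, 0] = np.nan
    res = ModeratedTModel(ds, covariates=cov).fit()
    assert res.n_dropped_missing_covariates == 1
    assert res.n_patients_used == 39


def test_bh_q_monotone_and_at_least_p():
    ds = make_interval(30, 30, 100, seed=10)
    table = ModeratedTModel(ds).fit().table.sort_values("p")
    assert np.all(table["q"].to_numpy() >= table["p"].to_numpy() - 1e-15)
    assert np.all(np.diff(table["q"].to_numpy()) >= -1e-15)


# -- cross-interval summary ----------------------------------------------


def test_cross_interval_counts_and_clipping():
    ds1 = make_interval(40, 40, 6, seed=11, effects={0: 0.9}, label="8-16")
    ds2 = make_interval(40, 40, 6, seed=12, label="16.1-22")
    results = {
        "8-16": ModeratedTModel(ds1).fit(),
        "16.1-22": ModeratedTModel(ds2).fit(),
    }
    long, heat, n_any = cross_interval_summary(results)
    assert n_any == len(heat)
    assert set(long["interval"]) == {"8-16", "16.1-22"}
    if "PROT0000" in heat.index:  # log2fc 0.9 clipped to 0.4 for display
        assert heat.loc["PROT0000", "8-16"] == pytest.approx(0.4)
    assert heat.to_numpy()[np.isfinite(heat.to_numpy())].max() <= 0.4 + 1e-12


def test_no_significant_proteins_gives_empty_summary():
    ds = make_interval(10, 10, 4, seed=13, sigma=1.5)
    results = {"8-16": ModeratedTModel(ds).fit()}
    _, heat, n_any = cross_interval_summary(results)
    if n_any == 0:
        assert heat.empty


# -- independent oracle ---------------------------------------------------


def test_moderated_t_matches_limma_reference():
    """The in-package empirical-Bayes shrinkage reproduces the reference
    implementation (limma's lmFit/eBayes) on a shared small dataset."""
    ds = make_interval(15, 12, 40, seed=14, effects={0: 0.6, 1: -0.5})
    res = ModeratedTModel(ds).fit()
    import tempfile, os

    with tempfile.TemporaryDirectory() as td:
        ds.X.T.to_csv(os.path.join(td, "expr.csv"))  # proteins x samples
        pd.Series(ds.y).to_csv(os.path.join(td, "y.csv"), index=False)
        script = os.path.join(td, "run.R")
        with open(script, "w") as fh:
            fh.write(
                """
suppressMessages(library(limma))
args <- commandArgs(trailingOnly=TRUE)
expr <- as.matrix(read.csv(file.path(args[1], "expr.csv"), row.names=1, check.names=FALSE))
y <- read.csv(file.path(args[1], "y.csv"))[[1]]
design <- model.matrix(~y)
fit <- eBayes(lmFit(expr, design))
out <- data.frame(t=fit$t[,2], p=fit$p.value[,2], d0=fit$df.prior, s02=fit$s2.prior)
write.csv(out, file.path(args[1], "limma.csv"))
"""
            )
        subprocess.run(["Rscript", script, td], check=True, capture_output=True)
        ref = pd.read_csv(os.path.join(td, "limma.csv"), index_col=0)
    np.testing.assert_allclose(res.table["t"].to_numpy(), ref["t"].to_numpy(), rtol=1e-6)
    np.testing.assert_allclose(res.table["p"].to_numpy(), ref["p"].to_numpy(), rtol=1e-6)
    assert res.d0 == pytest.approx(float(ref["d0"].iloc[0]), rel=1e-4)
    assert res.s0_2 == pytest.approx(float(ref["s02"].iloc[0]), rel=1e-4)
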