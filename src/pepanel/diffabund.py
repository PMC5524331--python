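"""Covariate-adjusted moderated-t differential abundance on log2 MoM.

Per interval and per protein, a linear model ``log2 MoM ~ group + BMI +
smoking + age + parity`` is fitted by least squares.  Residual variances
s^2_g (d degrees of freedom each) are shrunk toward a common value with the
classical empirical-Bayes scheme: assuming s^2_g | sigma^2_g is scaled
chi^2_d and sigma^2_g follows a scaled inverse chi^2 prior with df d0 and
scale s0^2, the posterior variance is

    s~^2_g = (d0 * s0^2 + d * s^2_g) / (d0 + d)

and the moderated t uses s~_g with d0 + d degrees of freedom.  The prior
(d0, s0^2) is estimated by matching the first two moments of log s^2_g under
the scaled-F sampling model (digamma/trigamma closed forms).  Two-sided p
values are BH-adjusted within the interval; a protein is flagged when
q < 0.25 and its linear fold change exceeds 1.1 in magnitude.

Fold changes are reported with the signed-linear convention: FC = 2^b for a
log2 difference b >= 0, and -2^(-b) for b < 0, so |FC| >= 1 always and
negative values denote lower abundance in cases.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .cohort import CovariateTable
from .intervals import IntervalDataset

logger = logging.getLogger(__name__)

Q_THRESHOLD = 0.25
FC_THRESHOLD = 1.1
#: Fig-style display clip for cross-interval log2 fold-change matrices
LOG2FC_CLIP = 0.4

COVARIATE_FIELDS = ("bmi", "smoking", "maternal_age", "parity")


def signed_fc(log2fc: float) -> float:
    """Signed linear fold change: 0 -> 1.0, 1 -> 2.0, -1 -> -2.0."""
    log2fc = float(log2fc)
    return float(2.0**log2fc) if log2fc >= 0 else float(-(2.0 ** (-log2fc)))


def _trigamma_inverse(x: float, tol: float = 1e-8, maxiter: int = 50) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on the inverse scale)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(maxiter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < tol * y:
            break
    return float(y)


def squeeze_var(s2: np.ndarray, df: float) -> tuple[float, float, np.ndarray]:
    """Moment-match the scaled-F model for residual variances.

    Returns ``(d0, s0_2, posterior_var)`` where ``d0`` may be ``inf``
    (complete pooling) when the observed spread of log s^2 is no larger than
    chi-square sampling noise alone.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if not ok.all():
        # guard degenerate zero-variance proteins with the smallest positive value
        floor = s2[ok].min() if ok.any() else 1.0
        s2 = np.where(ok, s2, floor)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) if len(e) > 1 else 0.0
    evar_prior = evar - float(special.polygamma(1, df / 2.0))
    if evar_prior > 0:
        d0 = 2.0 * _trigamma_inverse(evar_prior)
        s0_2 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        post = (d0 * s0_2 + df * s2) / (d0 + df)
    else:
        d0 = np.inf
        s0_2 = float(np.exp(emean))
        post = np.full_like(s2, s0_2)
    return d0, s0_2, post


@dataclasses.dataclass
class DifferentialAbundanceResults:
    """Per-protein moderated-t results for one interval."""

    interval_label: str
    table: pd.DataFrame  # protein, log2fc, fc, t, p, q, significant
    d0: float
    s0_2: float
    residual_df: float
    n_patients_used: int
    n_dropped_missing_covariates: int
    q_threshold: float
    fc_threshold: float

    def significant_proteins(self) -> list[str]:
        return self.table.loc[self.table["significant"], "protein"].tolist()

    def summary(self) -> str:
        t = self.table
        lines = [
            f"Differential abundance — interval {self.interval_label} weeks",
            f"  {self.n_patients_used} patients"
            + (
                f" ({self.n_dropped_missing_covariates} dropped, missing covariates)"
                if self.n_dropped_missing_covariates
                else ""
            ),
            f"  prior df d0 = {self.d0:.2f}, prior variance s0^2 = {self.s0_2:.4f}, "
            f"residual df = {self.residual_df:.0f}",
            f"  significant (q < {self.q_threshold} and |FC| > {self.fc_threshold}): "
            f"{int(t['significant'].sum())} of {len(t)} proteins",
        ]
        return "\n".join(lines)


class ModeratedTModel:
    """Moderated-t differential abundance model for one interval dataset.

    Parameters
    ----------
    interval : IntervalDataset
        One row per patient (log2 MoM).
    covariates : CovariateTable, optional
        When given, the group effect is adjusted for BMI, smoking, maternal
        age and parity; patients with missing covariates are dropped with a
        logged count.  Classification never uses covariates; this model is
        the only consumer.
    prior_df : float, optional
        Override the estimated d0 (0 = ordinary t, inf = complete pooling);
        mainly for validation.
    """

    def __init__(
        self,
        interval: IntervalDataset,
        covariates: CovariateTable | None = None,
        q_threshold: float = Q_THRESHOLD,
        fc_threshold: float = FC_THRESHOLD,
        prior_df: float | None = None,
    ):
        self.interval = interval
        self.covariates = covariates
        self.q_threshold = q_threshold
        self.fc_threshold = fc_threshold
        self.prior_df = prior_df

    def _design(self) -> tuple[np.ndarray, np.ndarray, int]:
        iv = self.interval
        y = iv.y.astype(float)
        cols = [np.ones(len(y)), y]
        names = ["intercept", "group"]
        keep = np.ones(len(y), dtype=bool)
        if self.covariates is not None:
            cov = self.covariates.data.reindex(pd.Index(iv.patient_id))
            mat = cov[list(COVARIATE_FIELDS)].to_numpy(dtype=float)
            keep = np.isfinite(mat).all(axis=1)
            n_drop = int((~keep).sum())
            if n_drop:
                logger.info(
                    "%s: dropping %d/%d patients with missing covariates",
                    iv.interval.label,
                    n_drop,
                    len(keep),
                )
                if keep.sum() < 0.8 * len(keep):
                    logger.warning(
                        "%s: covariates available for fewer than 80%% of patients",
                        iv.interval.label,
                    )
            for j, name in enumerate(COVARIATE_FIELDS):
                cols.append(mat[:, j])
                names.append(name)
        D = np.column_stack(cols)[keep]
        # drop rank-deficient (e.g. constant) covariate columns, never group
        while np.linalg.matrix_rank(D) < D.shape[1]:
            dropped = None
            for j in range(D.shape[1] - 1, 1, -1):
                trial = np.delete(D, j, axis=1)
                if np.linalg.matrix_rank(trial) == trial.shape[1]:
                    dropped = j
                    break
            if dropped is None:
                raise np.linalg.LinAlgError("design matrix irreparably rank-deficient")
            logger.warning("dropping rank-deficient covariate column %s", names[dropped])
            D = np.delete(D, dropped, axis=1)
            del names[dropped]
        return D, keep, int((~keep).sum())

    def fit(self) -> DifferentialAbundanceResults:
        iv = self.interval
        D, keep, n_dropped = self._design()
        Y = iv.X.to_numpy(dtype=float)[keep]
        n, k = D.shape
        if n <= k:
            raise ValueError("too few patients for the design")
        DtD_inv = np.linalg.inv(D.T @ D)
        beta = DtD_inv @ D.T @ Y  # k x P
        resid = Y - D @ beta
        df = n - k
        s2 = (resid**2).sum(axis=0) / df
        if self.prior_df is None:
            d0, s0_2, post = squeeze_var(s2, df)
        else:
            d0 = float(self.prior_df)
            _, s0_2, post_est = squeeze_var(s2, df)
            if d0 == 0:
                post = s2.copy()
            elif np.isinf(d0):
                post = np.full_like(s2, s0_2)
            else:
                post = (d0 * s0_2 + df * s2) / (d0 + df)
        g = 1  # index of the group column
        se = np.sqrt(np.maximum(post, 1e-300) * DtD_inv[g, g])
        log2fc = beta[g]
        tstat = log2fc / se
        df_total = df + d0
        if np.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(tstat))
        else:
            p = 2.0 * stats.t.sf(np.abs(tstat), df_total)
        q = multipletests(p, method="fdr_bh")[1]
        fc = np.array([signed_fc(b) for b in log2fc])
        significant = (q < self.q_threshold) & (np.abs(fc) > self.fc_threshold)
        table = pd.DataFrame(
            {
                "protein": iv.X.columns,
                "log2fc": log2fc,
                "fc": fc,
                "t": tstat,
                "p": p,
                "q": q,
                "significant": significant,
            }
        )
        return DifferentialAbundanceResults(
            interval_label=iv.interval.label,
            table=table,
            d0=d0,
            s0_2=s0_2,
            residual_df=float(df),
            n_patients_used=n,
            n_dropped_missing_covariates=n_dropped,
            q_threshold=self.q_threshold,
            fc_threshold=self.fc_threshold,
        )


def cross_interval_summary(
    results: dict[str, DifferentialAbundanceResults],
    clip: float = LOG2FC_CLIP,
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Combine per-interval results into the cross-gestation overview.

    Returns ``(long_table, heatmap, n_significant_any)``: the concatenated
    per-interval tables, a protein x interval log2 fold-change matrix
    restricted to proteins significant in at least one interval (values
    clipped at +/- ``clip`` for display), and the count of such proteins.
    """
    long = pd.concat(
        [r.table.assign(interval=label) for label, r in results.items()],
        ignore_index=True,
    )
    sig_any = sorted(set().union(*(r.significant_proteins() for r in results.values())))
    heat = pd.DataFrame(index=pd.Index(sig_any, name="protein"))
    for label, r in results.items():
        col = r.table.set_index("protein")["log2fc"].reindex(sig_any)
        heat[label] = col.clip(-clip, clip)
    return long, heat, len(sig_any)
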