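"""Outlier thresholding, normative trajectory fitting and MoM conversion.

Normalization proceeds in the pipeline's fixed order: (1) per-protein data
thresholding — values above twice the 98th percentile of that protein across
all samples are replaced by the cap; (2) log2 transform; (3) per-protein
linear mixed-effects fits on control samples only, modelling log2 abundance
as a cubic B-spline of gestational age (3 interior knots) plus a patient
random intercept; (4) every sample (cases included) is expressed as a
multiple of the mean (MoM): log2 MoM = log2(abundance) minus the fitted
control mean at the sample's gestational age.

A sample whose linear abundance equals the model's predicted geometric mean
therefore has log2 MoM exactly 0 (MoM = 1), and MoM values are invariant to
rescaling a protein's raw column by any positive constant.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
import statsmodels.api as sm

from .cohort import CohortTable

logger = logging.getLogger(__name__)

SPLINE_DEGREE = 3
N_INTERIOR_KNOTS = 3


class EstimationError(RuntimeError):
    pass


def threshold_outliers(cohort: CohortTable) -> tuple[CohortTable, int]:
    """Cap extreme values at 2x the per-protein 98th percentile.

    The percentile uses linear interpolation between order statistics
    (numpy's default, the "type 7" convention).  Returns the thresholded
    cohort and the number of replaced cells.
    """
    vals = cohort.abundance.to_numpy(dtype=float)
    cap = 2.0 * np.percentile(vals, 98, axis=0)
    over = vals > cap[None, :]
    n_replaced = int(over.sum())
    if n_replaced:
        vals = np.where(over, cap[None, :], vals)
    out = CohortTable(
        meta=cohort.meta.copy(),
        abundance=pd.DataFrame(vals, columns=cohort.abundance.columns),
        panel=cohort.panel,
    )
    return out, n_replaced


def _knot_vector(ga: np.ndarray) -> np.ndarray:
    """Clamped cubic knot vector: boundary at the GA range, interior knots at
    the 25th/50th/75th percentiles of control gestational ages."""
    lo, hi = float(np.min(ga)), float(np.max(ga))
    interior = np.percentile(ga, [25, 50, 75])
    # guard against coincident knots on tiny/degenerate GA supports
    interior = np.clip(interior, lo, hi)
    return np.concatenate(
        [[lo] * (SPLINE_DEGREE + 1), interior, [hi] * (SPLINE_DEGREE + 1)]
    )


def _design(ga: np.ndarray, knots: np.ndarray) -> np.ndarray:
    x = np.clip(ga, knots[0], knots[-1])
    return BSpline.design_matrix(x, knots, SPLINE_DEGREE).toarray()


@dataclasses.dataclass
class ProteinFit:
    """Fitted control trajectory for one protein (log2 scale)."""

    protein: str
    knots: np.ndarray
    coef: np.ndarray
    sigma2_patient: float
    sigma2_resid: float
    converged: bool

    def mean_log2(self, ga: np.ndarray) -> np.ndarray:
        """Predicted control mean log2 abundance; linear extrapolation with a
        warning outside the fitted GA range."""
        ga = np.asarray(ga, dtype=float)
        lo, hi = self.knots[0], self.knots[-1]
        spline = BSpline(self.knots, self.coef, SPLINE_DEGREE, extrapolate=False)
        deriv = spline.derivative()
        out = np.empty_like(ga)
        inside = (ga >= lo) & (ga <= hi)
        out[inside] = spline(ga[inside])
        if (~inside).any():
            logger.warning(
                "%s: %d gestational age(s) outside fitted range [%.1f, %.1f]; "
                "extrapolating linearly",
                self.protein,
                int((~inside).sum()),
                lo,
                hi,
            )
            below = ga < lo
            above = ga > hi
            out[below] = spline(lo) + deriv(lo) * (ga[below] - lo)
            out[above] = spline(hi) + deriv(hi) * (ga[above] - hi)
        return out


class NormativeModel:
    """Per-protein normative trajectory model over the control samples.

    Parameters
    ----------
    cohort : CohortTable
        Full cohort; only control samples enter the fit.  Thresholding is the
        caller's responsibility (see :func:`threshold_outliers`).
    """

    def __init__(self, cohort: CohortTable):
        controls = cohort.controls()
        ga = controls.meta["ga_weeks"].to_numpy(dtype=float)
        if len(controls.meta) < 10 or len(np.unique(ga)) < 3:
            raise EstimationError(
                "need >= 10 control samples spanning >= 3 distinct gestational ages"
            )
        self.cohort = cohort
        self.controls = controls
        self.knots = _knot_vector(ga)
        self._X = _design(ga, self.knots)
        self._groups = controls.meta["patient_id"].to_numpy()

    def fit(self, proteins: list[str] | None = None) -> "NormativeResults":
        """REML-fit every protein; OLS fallback (random variance 0) when the
        mixed fit fails to converge, with a logged warning."""
        cols = list(proteins) if proteins is not None else list(self.cohort.panel.columns)
        fits = {}
        n_fallback = 0
        log2v = np.log2(self.controls.abundance[cols].to_numpy(dtype=float))
        for j, name in enumerate(cols):
            fit = self._fit_one(name, log2v[:, j])
            if not fit.converged:
                n_fallback += 1
            fits[name] = fit
        if n_fallback:
            logger.warning(
                "mixed-effects fit fell back to fixed-effects-only for %d/%d proteins",
                n_fallback,
                len(cols),
            )
        return NormativeResults(model=self, fits=fits)

    def _fit_one(self, name: str, y: np.ndarray) -> ProteinFit:
        X = self._X
        if np.ptp(y) < 1e-12:
            # degenerate constant column: flat curve, zero variances
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            return ProteinFit(name, self.knots, coef, 0.0, 0.0, True)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                md = sm.MixedLM(y, X, groups=self._groups)
                res = md.fit(reml=True, maxiter=200)
            if not np.all(np.isfinite(res.fe_params)):
                raise np.linalg.LinAlgError("non-finite fixed effects")
            # guard against silent optimizer failure: the mixed fixed-effect
            # curve must not fit grossly worse than plain least squares
            ols_coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss_ols = float(np.sum((y - X @ ols_coef) ** 2))
            rss_mix = float(np.sum((y - X @ np.asarray(res.fe_params)) ** 2))
            if rss_mix > 2.0 * rss_ols + 1e-9:
                raise np.linalg.LinAlgError("mixed fit diverged")
            sigma2_patient = float(np.asarray(res.cov_re)[0, 0])
            sigma2_resid = float(res.scale)
            converged = bool(getattr(res, "converged", True))
            if not converged:
                raise np.linalg.LinAlgError("MixedLM did not converge")
            return ProteinFit(
                name, self.knots, np.asarray(res.fe_params), sigma2_patient, sigma2_resid, True
            )
        except Exception:
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ coef
            dof = max(len(y) - X.shape[1], 1)
            return ProteinFit(
                name, self.knots, coef, 0.0, float(resid @ resid / dof), False
            )


@dataclasses.dataclass
class NormativeResults:
    """Fitted normative curves for a set of proteins."""

    model: NormativeModel
    fits: dict[str, ProteinFit]

    def __getitem__(self, protein: str) -> ProteinFit:
        return self.fits[protein]

    def predicted_mean_log2(self, ga: np.ndarray, proteins: list[str]) -> np.ndarray:
        """Matrix of predicted control mean log2 values, samples x proteins.

        The spline basis is shared (knots depend only on control GAs), so the
        in-range prediction is a single design-matrix product.
        """
        ga = np.asarray(ga, dtype=float)
        knots = self.model.knots
        lo, hi = knots[0], knots[-1]
        C = np.column_stack([self.fits[p].coef for p in proteins])
        inside = (ga >= lo) & (ga <= hi)
        out = np.empty((len(ga), len(proteins)))
        if inside.any():
            out[inside] = _design(ga[inside], knots) @ C
        if (~inside).any():
            for k, p in enumerate(proteins):
                out[~inside, k] = self.fits[p].mean_log2(ga[~inside])
        return out

    def to_dict(self) -> dict:
        return {
            p: {
                "knots": f.knots.tolist(),
                "coef": f.coef.tolist(),
                "sigma2_patient": f.sigma2_patient,
                "sigma2_resid": f.sigma2_resid,
                "converged": f.converged,
            }
            for p, f in self.fits.items()
        }


@dataclasses.dataclass
class MoMMatrix:
    """log2 multiples-of-the-mean with sample metadata carried alongside."""

    values: pd.DataFrame  # samples x proteins, log2 MoM
    meta: pd.DataFrame  # patient_id, ga_weeks, group

    @property
    def proteins(self) -> list[str]:
        return list(self.values.columns)


def compute_mom(cohort: CohortTable, results: NormativeResults) -> MoMMatrix:
    """Express every sample (cases and controls) as log2 MoM."""
    proteins = list(cohort.panel.columns)
    missing = [p for p in proteins if p not in results.fits]
    if missing:
        raise EstimationError(f"no normative model for protein(s) {missing[:5]}")
    ga = cohort.meta["ga_weeks"].to_numpy(dtype=float)
    pred = results.predicted_mean_log2(ga, proteins)
    log2v = np.log2(cohort.abundance.to_numpy(dtype=float))
    return MoMMatrix(
        values=pd.DataFrame(log2v - pred, columns=proteins),
        meta=cohort.meta.copy(),
    )


def normalize_cohort(
    cohort: CohortTable,
) -> tuple[MoMMatrix, NormativeResults, int]:
    """Convenience front-end: threshold -> fit normative curves -> MoM."""
    capped, n_replaced = threshold_outliers(cohort)
    results = NormativeModel(capped).fit()
    mom = compute_mom(capped, results)
    return mom, results, n_replaced
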