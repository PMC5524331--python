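"""Cohort data model and plain-CSV I/O.

The pipeline's native input is a wide sample table: one row per blood draw
with columns ``ID`` (patient identifier), ``GA`` (gestational age, decimal
weeks), ``LatePE`` (1 = late-onset preeclampsia, 0 = normal pregnancy) and
one column per protein holding relative fluorescence units.  A companion
covariate table (one row per patient) and a two-column protein-to-term
annotation map are optional side inputs.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

CONTROL = "control"
LATE_PE = "late_pe"

#: mandatory metadata columns of the wide sample table, in file order
META_COLUMNS = ("ID", "GA", "LatePE")

GA_MIN_WEEKS = 4.0
GA_MAX_WEEKS = 43.0


class CohortFormatError(ValueError):
    """The file does not have the expected wide-table layout."""


class CohortValidationError(ValueError):
    """The file parses but violates a domain invariant."""


@dataclasses.dataclass(frozen=True)
class ProteinPanel:
    """The measured protein panel: column keys plus display symbols.

    ``columns`` are the unique machine keys (CSV headers); ``symbols`` maps
    each key to a human-readable symbol (defaults to the key itself) and
    ``genes`` optionally to a gene identifier.
    """

    columns: tuple[str, ...]
    symbols: Mapping[str, str] = dataclasses.field(default_factory=dict)
    genes: Mapping[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.columns)) != len(self.columns):
            raise CohortValidationError("protein column keys must be unique")

    def symbol(self, column: str) -> str:
        return self.symbols.get(column, column)

    def __len__(self) -> int:
        return len(self.columns)

    def __iter__(self):
        return iter(self.columns)


@dataclasses.dataclass
class CohortTable:
    """Validated longitudinal cohort: sample metadata + abundance matrix.

    ``meta`` has one row per sample with columns ``patient_id``, ``ga_weeks``
    and ``group`` (``control``/``late_pe``); ``abundance`` is the aligned
    samples x proteins matrix of strictly positive relative fluorescence
    units.  Both share the same integer range index.
    """

    meta: pd.DataFrame
    abundance: pd.DataFrame
    panel: ProteinPanel

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if list(self.abundance.columns) != list(self.panel.columns):
            raise CohortValidationError("abundance columns do not match panel")
        if len(self.meta) != len(self.abundance):
            raise CohortValidationError("meta and abundance row counts differ")
        vals = self.abundance.to_numpy(dtype=float)
        bad = ~np.isfinite(vals) | (vals <= 0)
        if bad.any():
            cells = [
                f"(row {i}, {self.abundance.columns[j]})"
                for i, j in zip(*np.nonzero(bad))
            ][:20]
            raise CohortValidationError(
                "non-positive or non-finite abundance at " + ", ".join(cells)
            )
        ga = self.meta["ga_weeks"].to_numpy(dtype=float)
        if ((ga < GA_MIN_WEEKS) | (ga > GA_MAX_WEEKS)).any():
            raise CohortValidationError(
                f"gestational ages must lie in [{GA_MIN_WEEKS}, {GA_MAX_WEEKS}] weeks"
            )
        if self.meta.duplicated(["patient_id", "ga_weeks"]).any():
            raise CohortValidationError("(patient id, GA) pairs must be unique")
        ngroups = self.meta.groupby("patient_id")["group"].nunique()
        if (ngroups > 1).any():
            offenders = ngroups.index[ngroups > 1].tolist()
            raise CohortValidationError(
                f"group label not constant within patient(s): {offenders}"
            )

    # -- convenience ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.meta)

    @property
    def n_proteins(self) -> int:
        return len(self.panel)

    def patients(self, group: str | None = None) -> list:
        m = self.meta if group is None else self.meta[self.meta["group"] == group]
        return m["patient_id"].drop_duplicates().tolist()

    def subset(self, mask: np.ndarray) -> "CohortTable":
        """Row-subset (boolean or index mask) preserving the panel."""
        meta = self.meta.loc[mask].reset_index(drop=True)
        abundance = self.abundance.loc[mask].reset_index(drop=True)
        return CohortTable(meta=meta, abundance=abundance, panel=self.panel)

    def controls(self) -> "CohortTable":
        return self.subset((self.meta["group"] == CONTROL).to_numpy())

    def to_frame(self) -> pd.DataFrame:
        """Back to the wide on-disk layout (ID, GA, LatePE, proteins...)."""
        out = pd.DataFrame(
            {
                "ID": self.meta["patient_id"].to_numpy(),
                "GA": self.meta["ga_weeks"].to_numpy(),
                "LatePE": (self.meta["group"] == LATE_PE).astype(int).to_numpy(),
            }
        )
        return pd.concat([out, self.abundance.reset_index(drop=True)], axis=1)


def read_cohort(path) -> CohortTable:
    """Read and validate a wide-format sample table.

    Expects the header ``ID,GA,LatePE,<protein>,...``; LatePE must be 0 or 1.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(f"{path}: missing mandatory column(s) {missing}")
    protein_cols = [c for c in df.columns if c not in META_COLUMNS]
    if not protein_cols:
        raise CohortFormatError(f"{path}: no protein columns found")
    late = df["LatePE"]
    if not late.isin([0, 1]).all():
        bad = sorted(set(late[~late.isin([0, 1])].tolist()))
        raise CohortValidationError(f"{path}: LatePE values must be 0/1, found {bad}")
    meta = pd.DataFrame(
        {
            "patient_id": df["ID"],
            "ga_weeks": df["GA"].astype(float),
            "group": np.where(late.astype(int) == 1, LATE_PE, CONTROL),
        }
    )
    panel = ProteinPanel(columns=tuple(protein_cols))
    return CohortTable(
        meta=meta.reset_index(drop=True),
        abundance=df[protein_cols].astype(float).reset_index(drop=True),
        panel=panel,
    )


def write_cohort(cohort: CohortTable, path) -> None:
    cohort.to_frame().to_csv(path, index=False, float_format="%.17g")


#: covariate CSV columns
COVARIATE_COLUMNS = ("ID", "BMI", "AGE", "PARITY", "SMOKING", "SEVERITY")
SEVERITIES = ("none", "mild", "severe")


@dataclasses.dataclass
class CovariateTable:
    """Per-patient covariates used only by the adjusted differential analysis.

    One row per patient, indexed by patient id, columns ``bmi``,
    ``maternal_age``, ``parity``, ``smoking``, ``severity``; patients missing
    from the source file carry NaN covariates and are flagged in ``missing``.
    """

    data: pd.DataFrame
    missing: tuple = ()

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise CohortValidationError(f"duplicate patient id(s) in covariates: {dups}")

    def complete_patients(self) -> list:
        req = ["bmi", "maternal_age", "parity", "smoking"]
        ok = self.data[req].notna().all(axis=1)
        return self.data.index[ok].tolist()

    def severity_of(self, patient_id) -> str:
        v = self.data.at[patient_id, "severity"] if patient_id in self.data.index else None
        return v if isinstance(v, str) else "none"


def read_covariates(path, cohort: CohortTable | None = None) -> CovariateTable:
    """Read the covariate CSV; optionally align to a cohort's patients.

    Patients present in the cohort but absent from the file get NaN covariates
    and are listed in ``missing`` (adjusted analyses drop them with a logged
    count); duplicated ids are an error.
    """
    df = pd.read_csv(path)
    missing_cols = [c for c in COVARIATE_COLUMNS if c not in df.columns and c != "SEVERITY"]
    if missing_cols:
        raise CohortFormatError(f"{path}: missing covariate column(s) {missing_cols}")
    out = pd.DataFrame(
        {
            "bmi": df["BMI"].astype(float),
            "maternal_age": df["AGE"].astype(float),
            "parity": df["PARITY"].astype(float),
            "smoking": df["SMOKING"].astype(float),
            "severity": df["SEVERITY"] if "SEVERITY" in df.columns else "none",
        }
    )
    out.index = pd.Index(df["ID"], name="patient_id")
    if out.index.has_duplicates:
        dups = out.index[out.index.duplicated()].tolist()
        raise CohortValidationError(f"{path}: duplicate patient id(s) {dups}")
    missing: tuple = ()
    if cohort is not None:
        want = pd.Index(cohort.patients(), name="patient_id")
        missing = tuple(p for p in want if p not in out.index)
        out = out.reindex(want)
        out["severity"] = out["severity"].fillna("none")
    bad_sev = set(out["severity"].dropna()) - set(SEVERITIES)
    if bad_sev:
        raise CohortValidationError(f"{path}: unknown severity value(s) {sorted(bad_sev)}")
    return CovariateTable(data=out, missing=missing)


def write_matrix(values: pd.DataFrame, meta: pd.DataFrame, path) -> None:
    """Write a samples x proteins matrix with ID/GA columns preserved.

    Floats are written at full (repr) precision so the read side round-trips
    bit-identically.
    """
    out = pd.DataFrame(
        {"ID": meta["patient_id"].to_numpy(), "GA": meta["ga_weeks"].to_numpy()}
    )
    out = pd.concat([out, values.reset_index(drop=True)], axis=1)
    try:
        out.to_csv(path, index=False, float_format="%.17g")
    except OSError as exc:  # surface path context
        raise OSError(f"failed writing matrix to {path}: {exc}") from exc


def read_matrix(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inverse of :func:`write_matrix`: returns (values, meta)."""
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("ID", "GA"):
        if col not in df.columns:
            raise CohortFormatError(f"{path}: missing column {col}")
    meta = pd.DataFrame({"patient_id": df["ID"], "ga_weeks": df["GA"].astype(float)})
    values = df[[c for c in df.columns if c not in ("ID", "GA")]]
    return values, meta


def read_annotation(path) -> dict[str, set[str]]:
    """Two-column CSV ``protein_symbol,term_id`` -> mapping term -> proteins."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise CohortFormatError(f"{path}: expected two columns protein_symbol,term_id")
    prot_col, term_col = df.columns[:2]
    terms: dict[str, set[str]] = {}
    for prot, term in zip(df[prot_col], df[term_col]):
        terms.setdefault(str(term), set()).add(str(prot))
    return terms
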