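"""End-to-end orchestration: normalize -> intervals -> select + bootstrap ->
differential abundance -> enrichment, with a machine-readable report bundle.

Defaults reproduce the published procedure verbatim: pAUC FPR cut-off 0.5,
panels of at most 5 proteins, +0.01 pAUC gain rule, 10% abundance-change
filter, 100 bootstrap iterations, q < 0.25 and |FC| > 1.1 for differential
abundance, and >= 3 hits with q < 0.1 for term enrichment.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import yaml

from . import bootstrap as bs
from . import diffabund, enrichment, intervals as iv_mod, normative
from .cohort import (
    CohortTable,
    CovariateTable,
    read_annotation,
    read_cohort,
    read_covariates,
    write_matrix,
)
from .selection import PanelSelectionModel

logger = logging.getLogger(__name__)

OUTCOMES = ("all", "mild", "severe")


@dataclasses.dataclass
class PipelineConfig:
    cohort_path: str = ""
    covariates_path: str | None = None
    annotation_path: str | None = None
    out_dir: str = "pepanel_out"
    fpr_cut: float = 0.5
    max_panel: int = 5
    min_gain: float = 0.01
    min_change: float = 0.10
    bootstrap_iterations: int = 100
    q_da: float = 0.25
    fc_da: float = 1.1
    q_enrich: float = 0.1
    min_hits: int = 3
    collapse_rule: str = "midpoint"
    run_bootstrap: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def run_all(
    config: PipelineConfig,
    cohort: CohortTable | None = None,
    covariates: CovariateTable | None = None,
    annotation: enrichment.AnnotationMap | None = None,
) -> dict:
    """Run the whole pipeline and write the report bundle under ``out_dir``.

    Inputs may be passed in-memory (as from the synthetic generator) or read
    from the configured paths.  Returns the bundle dict that is also written
    as ``report.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cohort is None:
        cohort = read_cohort(config.cohort_path)
    if covariates is None and config.covariates_path:
        covariates = read_covariates(config.covariates_path, cohort)
    if annotation is None and config.annotation_path:
        annotation = enrichment.AnnotationMap(terms=read_annotation(config.annotation_path))

    logger.info("normalizing %d samples x %d proteins", cohort.n_samples, cohort.n_proteins)
    mom, norm_results, n_capped = normative.normalize_cohort(cohort)
    logger.info("thresholding replaced %d cells", n_capped)
    write_matrix(mom.values, mom.meta, out / "log2_mom.csv")
    with open(out / "normative_models.json", "w") as fh:
        json.dump(norm_results.to_dict(), fh)

    datasets = iv_mod.assign_intervals(mom, rule=config.collapse_rule)
    have_severity = covariates is not None and (
        covariates.data["severity"].isin(["mild", "severe"]).any()
    )
    if covariates is not None:
        for ds in datasets.values():
            ds.attach_severity(covariates)
    outcomes = OUTCOMES if have_severity else ("all",)
    if not have_severity:
        logger.info("no severity labels available; skipping mild/severe analyses")

    bundle: dict = {
        "config": dataclasses.asdict(config),
        "n_capped": n_capped,
        "intervals": {},
        "selection": {},
        "bootstrap": {},
        "differential_abundance": {},
        "enrichment": {},
    }
    selection_rows = []
    for label, ds in datasets.items():
        bundle["intervals"][label] = {
            "n_controls": ds.n_controls,
            "n_cases": ds.n_cases,
        }
        for outcome in outcomes:
            sub = ds.subset_outcome(outcome)
            if sub.n_controls < 5 or sub.n_cases < 5:
                logger.info("%s/%s: too few patients, skipped", label, outcome)
                continue
            key = f"{label}/{outcome}"
            results = PanelSelectionModel(
                sub,
                fpr_cut=config.fpr_cut,
                max_panel=config.max_panel,
                min_gain=config.min_gain,
                min_change=config.min_change,
            ).fit()
            bundle["selection"][key] = results.as_dict()
            if results.has_model:
                row = {
                    "outcome": outcome,
                    "interval": label,
                    "n": f"{sub.n_controls}/{sub.n_cases}",
                    "predictors": "+".join(results.panel),
                }
                row.update(results.performance.as_dict())
                selection_rows.append(row)
            if config.run_bootstrap:
                summary = bs.bootstrap_evaluate(
                    sub,
                    B=config.bootstrap_iterations,
                    seed=config.seed,
                    fpr_cut=config.fpr_cut,
                    max_panel=config.max_panel,
                    min_gain=config.min_gain,
                    min_change=config.min_change,
                )
                bundle["bootstrap"][key] = summary.as_dict()
                summary.iteration_frame().to_csv(
                    out / f"bootstrap_{label.replace('.', '_')}_{outcome}.csv", index=False
                )

    if selection_rows:
        import pandas as pd

        pd.DataFrame(selection_rows).to_csv(out / "selection_performance.csv", index=False)

    da_results: dict[str, diffabund.DifferentialAbundanceResults] = {}
    for label, ds in datasets.items():
        if ds.n_controls < 5 or ds.n_cases < 5:
            continue
        da_results[label] = diffabund.ModeratedTModel(
            ds,
            covariates=covariates,
            q_threshold=config.q_da,
            fc_threshold=config.fc_da,
        ).fit()
    if da_results:
        long, heat, n_any = diffabund.cross_interval_summary(da_results)
        long.to_csv(out / "differential_abundance.csv", index=False)
        heat.to_csv(out / "da_heatmap_log2fc.csv")
        bundle["differential_abundance"] = {
            "n_significant_any_interval": n_any,
            "per_interval": {
                label: {
                    "n_significant": int(r.table["significant"].sum()),
                    "d0": r.d0 if r.d0 != float("inf") else "inf",
                    "s0_2": r.s0_2,
                }
                for label, r in da_results.items()
            },
        }
        if annotation is not None:
            for label, r in da_results.items():
                res = enrichment.enrich(
                    r.significant_proteins(),
                    annotation,
                    min_hits=config.min_hits,
                    q_threshold=config.q_enrich,
                )
                bundle["enrichment"][label] = {
                    "n_enriched": int(res.table["enriched"].sum()) if len(res.table) else 0,
                    "terms": res.enriched_terms(),
                }
                res.table.to_csv(
                    out / f"enrichment_{label.replace('.', '_')}.csv", index=False
                )

    with open(out / "report.json", "w") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True)
    return bundle
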