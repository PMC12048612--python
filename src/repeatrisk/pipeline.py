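"""End-to-end pipeline orchestrator.

Runs the full analysis sequence on one cohort table: category
association screens per case group and age stratum, the b/c split-point
scan, age-stratified and pooled two-allele risk models with
relative-risk surfaces, and any configured phenotype regression
families.  Stage failures are captured per stage; the report is always
emitted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .association import AnalysisConfig, run_category_association, split_point_scan
from .riskmodel import CagRiskModel, fit_age_models, relative_risk_surface

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    case_groups: tuple[str, ...] = ("MDD", "ANX")
    strata: tuple[str, ...] = ("all", "older", "younger")
    phenotype_outcomes: tuple[str, ...] = ()
    phenotype_covariates: tuple[str, ...] = ("status", "eICV", "coil")
    seed: int = 0


@dataclass
class PipelineReport:
    """Per-stage result tables plus provenance."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    scalars: dict[str, float] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)
    failed: dict[str, str] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables.items():
            table.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        meta = {
            "schema_version": SCHEMA_VERSION,
            "scalars": self.scalars,
            "skipped": self.skipped,
            "failed": self.failed,
            "provenance": self.provenance,
            "tables": sorted(self.tables),
        }
        (out / "report.json").write_text(json.dumps(meta, indent=2, sort_keys=True))

    @classmethod
    def load(cls, out_dir) -> "PipelineReport":
        out = Path(out_dir)
        meta = json.loads((out / "report.json").read_text())
        tables = {
            name: pd.read_csv(out / f"{name}.tsv", sep="\t")
            for name in meta["tables"]
        }
        return cls(
            tables=tables,
            scalars=meta["scalars"],
            skipped=meta["skipped"],
            failed=meta["failed"],
            provenance=meta["provenance"],
        )


def run_pipeline(
    cohort: pd.DataFrame, config: Optional[PipelineConfig] = None
) -> PipelineReport:
    """Run the full analysis sequence on a validated cohort table."""
    config = config or PipelineConfig()
    report = PipelineReport(
        provenance={
            "version": __version__,
            "schema_version": SCHEMA_VERSION,
            "seed": config.seed,
            "n_subjects": int(len(cohort)),
            "case_groups": list(config.case_groups),
        }
    )

    # 1. category association screens
    assoc_frames = []
    for case_group in config.case_groups:
        if case_group not in set(cohort["group"]):
            report.skipped[f"association_{case_group}"] = "case group absent"
            continue
        for stratum in config.strata:
            key = f"association_{case_group}_{stratum}"
            try:
                screen = run_category_association(
                    cohort,
                    config=config.analysis,
                    case_group=case_group,
                    stratum=stratum,
                    omnibus_seed=config.seed,
                )
                assoc_frames.append(screen.to_frame())
                report.scalars[f"omnibus_p_{case_group}_{stratum}"] = screen.omnibus_p
            except Exception as exc:  # noqa: BLE001 - stage isolation
                report.failed[key] = str(exc)
    if assoc_frames:
        report.tables["association"] = pd.concat(assoc_frames, ignore_index=True)

    # 2. split-point scan (older stratum, per case group)
    scan_frames = []
    for case_group in config.case_groups:
        if case_group not in set(cohort["group"]):
            continue
        try:
            scan_frames.append(
                split_point_scan(
                    cohort,
                    config=config.analysis,
                    case_group=case_group,
                    stratum="older",
                )
            )
        except Exception as exc:  # noqa: BLE001
            report.failed[f"split_scan_{case_group}"] = str(exc)
    if scan_frames:
        report.tables["split_scan"] = pd.concat(scan_frames, ignore_index=True)

    # 3. risk models (pooled patients vs CON) + surfaces
    try:
        present = [g for g in config.case_groups if g in set(cohort["group"])]
        models = fit_age_models(
            cohort, age_split=config.analysis.age_split, case_groups=present
        )
        fit_rows = []
        for stratum, res in (
            ("younger", models.younger),
            ("older", models.older),
            ("pooled", models.pooled),
        ):
            for term in res.params.index:
                fit_rows.append(
                    {
                        "stratum": stratum,
                        "term": term,
                        "coef": float(res.params[term]),
                        "se": float(res.bse[term]),
                        "p": float(res.pvalues[term]),
                        "deviance": res.deviance,
                        "converged": res.converged,
                    }
                )
        report.tables["risk_fits"] = pd.DataFrame(fit_rows)
        surfaces = []
        for stratum, res in (("younger", models.younger), ("older", models.older)):
            surf = relative_risk_surface(res, extrapolate=True)
            surf.insert(0, "stratum", stratum)
            surfaces.append(surf)
        report.tables["surfaces"] = pd.concat(surfaces, ignore_index=True)
    except Exception as exc:  # noqa: BLE001
        report.failed["risk_models"] = str(exc)

    # 4. phenotype regressions
    if not config.phenotype_outcomes:
        report.skipped["phenotypes"] = "no phenotype outcomes configured"
    else:
        from .phenoreg import fit_phenotype_model

        present = [c for c in config.phenotype_outcomes if c in cohort.columns]
        if not present:
            report.skipped["phenotypes"] = "phenotype columns absent from cohort"
        else:
            try:
                df = cohort.copy()
                if "status" in config.phenotype_covariates and "status" not in df:
                    df["status"] = (df["group"] != "CON").astype(int)
                covs = [c for c in config.phenotype_covariates if c in df.columns]
                report.tables["phenotypes"] = fit_phenotype_model(
                    df, present, extra_covariates=covs
                )
            except Exception as exc:  # noqa: BLE001
                report.failed["phenotypes"] = str(exc)
    return report
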