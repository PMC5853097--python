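"""End-to-end orchestration: load or simulate a cohort, derive ratios,
run the univariate table, densities and C-statistics, FDA, seafood
correlations, and the subtype-exclusion sensitivity rerun.

The univariate table follows a fixed canonical row order (the 11
measured fatty acids followed by the 4 derived measures) and records,
for every analyte, which branch of the test-selection tree fired — so
each routing decision is auditable from the report alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_data import (
    ANALYTES,
    DISPLAY_NAMES,
    CohortTable,
    compute_derived_table,
    exclude_subtypes,
)
from .density import c_statistic, kde_fit, kde_interval
from .multivariate import FdaModel, fda_fit, pls_regress, seafood_correlation
from .synthetic import SyntheticPanelSpec, generate_cohort
from .univariate import PowerSpec, TestDecision, min_sample_size, multiplicity_correct, select_and_test

__all__ = ["AnalysisReport", "run_full_analysis", "univariate_table", "write_report"]

log = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = "1"

DEFAULT_CONFIG = {
    "alpha_gate": 0.05,
    "correction": "bonferroni",
    "coverage": 0.95,
    "ridge": 1e-8,
    "sensitivity_exclude": ("Aspergers", "PDD_NOS"),
    "power": {"d": 0.5, "alpha": 0.1, "power": 0.8, "sided": "two"},
    "severity_labels": (),       # PLS targets; empty = skip
    "pls_components": 2,
}


@dataclass
class AnalysisReport:
    """Everything the pipeline computed, plus per-section error flags."""

    table3: pd.DataFrame
    decisions: list[TestDecision]
    fda: FdaModel | None
    table4: pd.DataFrame | None
    sensitivity: pd.DataFrame | None
    power_note: dict
    pls: dict
    metadata: dict
    errors: dict = field(default_factory=dict)

    def summary(self) -> dict:
        """Compact machine-readable summary of the headline numbers."""
        t3 = self.table3
        out = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "n_asd": int(t3["n_asd"].iloc[0]),
            "n_neu": int(t3["n_neu"].iloc[0]),
            "min_p_raw": float(t3["p_value"].min()),
            "min_p_adjusted": float(t3["p_adjusted"].min()),
            "max_univariate_c": float(t3["c_statistic"].max()),
            "power_note": self.power_note,
            "errors": {k: str(v) for k, v in self.errors.items()},
        }
        if self.fda is not None:
            out["fda_c_statistic"] = float(self.fda.score_c_statistic.c_statistic)
        return out


def univariate_table(
    table: CohortTable,
    alpha_gate: float = 0.05,
    correction: str = "bonferroni",
    coverage: float = 0.95,
) -> tuple[pd.DataFrame, list[TestDecision]]:
    """One row per analyte: routed test, centrals, KDE intervals,
    raw and adjusted p, and both C-statistic variants."""
    rows = []
    decisions = []
    for analyte in ANALYTES:
        x = table.analyte_values(analyte, "ASD")
        y = table.analyte_values(analyte, "NEU")
        dec = select_and_test(x, y, alpha_gate=alpha_gate, analyte=analyte)
        decisions.append(dec)
        log.info(
            "%s: route=%s -> %s (p=%.4g)", analyte, dec.route, dec.final_test, dec.p_value
        )
        ci_asd = kde_interval(kde_fit(x), coverage)
        ci_neu = kde_interval(kde_fit(y), coverage)
        c_pdf = c_statistic(x, y, method="pdf_integral")
        c_emp = c_statistic(x, y, method="empirical")
        rows.append(
            {
                "analyte": analyte,
                "measurement": DISPLAY_NAMES[analyte],
                "test": dec.final_test,
                "route": dec.route,
                "central_asd": dec.central_asd,
                "ci_asd_lo": ci_asd[0],
                "ci_asd_hi": ci_asd[1],
                "central_neu": dec.central_neu,
                "ci_neu_lo": ci_neu[0],
                "ci_neu_hi": ci_neu[1],
                "p_value": dec.p_value,
                "c_statistic": c_pdf.c_statistic,
                "c_statistic_empirical": c_emp.c_statistic,
                "n_asd": dec.n_asd,
                "n_neu": dec.n_neu,
                "note": dec.note,
            }
        )
    df = pd.DataFrame(rows)
    df["p_adjusted"] = multiplicity_correct(df["p_value"].to_numpy(), correction)
    return df, decisions


def run_full_analysis(source, config: dict | None = None, seed: int | None = None) -> AnalysisReport:
    """Run the whole analysis on a :class:`CohortTable` or a
    :class:`SyntheticPanelSpec` (which is first realized with ``seed``).

    Deterministic given source, config and seed.  Sections that cannot
    run (e.g. seafood correlations without seafood data) are flagged in
    ``report.errors`` instead of aborting the rest.
    """
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    if isinstance(source, SyntheticPanelSpec):
        table = generate_cohort(source, seed=seed)
    elif isinstance(source, CohortTable):
        table = compute_derived_table(source)
    else:
        raise TypeError("source must be a CohortTable or SyntheticPanelSpec")
    counts = table.cohort_counts()
    if min(counts.values()) < 3:
        raise ValueError(f"need at least 3 records per cohort, got {counts}")

    errors: dict[str, str] = {}
    table3, decisions = univariate_table(
        table, cfg["alpha_gate"], cfg["correction"], cfg["coverage"]
    )

    fda = None
    try:
        fda = fda_fit(table, variables=ANALYTES, ridge=cfg["ridge"])
    except Exception as exc:  # keep partial report
        errors["fda"] = str(exc)

    table4 = None
    try:
        table4 = seafood_correlation(table)
        if table4.isna().all().all():
            table4 = None
            errors["table4"] = "no seafood data"
    except Exception as exc:
        errors["table4"] = str(exc)

    sensitivity = None
    try:
        reduced = exclude_subtypes(table, set(cfg["sensitivity_exclude"]))
        sensitivity, _ = univariate_table(
            reduced, cfg["alpha_gate"], cfg["correction"], cfg["coverage"]
        )
    except Exception as exc:
        errors["sensitivity"] = str(exc)

    pls = {}
    for label in cfg["severity_labels"]:
        try:
            m = pls_regress(
                table, ANALYTES, label, n_components=cfg["pls_components"], loo=True
            )
            pls[label] = {"r_squared": m.r_squared, "r_squared_loo": m.r_squared_loo}
        except Exception as exc:
            errors[f"pls:{label}"] = str(exc)

    p = PowerSpec(**cfg["power"])
    power_note = {
        "d": p.d,
        "alpha": p.alpha,
        "power": p.power,
        "sided": p.sided,
        "min_n_per_group": min_sample_size(p),
    }
    metadata = {
        "provenance": table.provenance,
        "seed": seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in cfg.items()
        },
        "counts": counts,
    }
    return AnalysisReport(
        table3=table3,
        decisions=decisions,
        fda=fda,
        table4=table4,
        sensitivity=sensitivity,
        power_note=power_note,
        pls=pls,
        metadata=metadata,
        errors=errors,
    )


def write_report(report: AnalysisReport, outdir) -> Path:
    """Write table3.csv, table4.csv, fda_scores.csv, sensitivity.csv and
    a JSON summary into ``outdir``; returns the summary path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.table3.to_csv(outdir / "table3.csv", index=False)
    if report.table4 is not None:
        report.table4.to_csv(outdir / "table4.csv", index_label="analyte")
    if report.sensitivity is not None:
        report.sensitivity.to_csv(outdir / "sensitivity.csv", index=False)
    if report.fda is not None:
        scores = pd.DataFrame(
            {
                "cohort": ["ASD"] * len(report.fda.scores_asd)
                + ["NEU"] * len(report.fda.scores_neu),
                "score": np.concatenate(
                    [report.fda.scores_asd, report.fda.scores_neu]
                ),
            }
        )
        scores.to_csv(outdir / "fda_scores.csv", index=False)
    summary = report.summary()
    summary["metadata"] = report.metadata
    path = outdir / "report.json"
    path.write_text(json.dumps(summary, indent=2, default=str))
    return path
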