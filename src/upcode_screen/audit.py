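"""Step Two: auditor decision support for flagged providers.

Two cross-validation views per outlier, rendered as descriptive
comparisons only — never verdicts:

* a fraud-variable dashboard: where the provider sits, as a percentile of
  the provider population, on average cost, share of CC DRGs, degree of
  specialization, number of visits and the upcoding index;
* a casemix comparison: the provider's patients/discharges against the
  whole population on age, length of stay, comorbidity, total cost,
  cost/LOS and cost/comorbidity, on a log scale (log(x + 1), since LOS
  and comorbidity can be 0), with the distribution means reported.

The percentile convention is the strict rank divided by the population
size: the population minimum sits at 0 and the maximum of N distinct
values at (N - 1)/N.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .aggregation import HospitalProfile, PatientSummary
from .comorbidity import WeightTable, score_hdc
from .hdc_core import Cohort

__all__ = [
    "FRAUD_VARIABLES",
    "CASEMIX_VARIABLES",
    "CasemixSummary",
    "AuditReport",
    "percentile_position",
    "fraud_dashboard",
    "casemix_comparison",
    "build_audit_report",
]

#: the five provider-level fraud-related variables of the dashboard
FRAUD_VARIABLES = ("avg_cost", "pct_cc", "specialization", "n_visits", "upcoding_index")

#: casemix variables: (name, level); level is "patient" or "hdc"
CASEMIX_VARIABLES = (
    ("age", "patient"),
    ("los", "hdc"),
    ("comorbidity", "hdc"),
    ("total_cost", "patient"),
    ("cost_per_los", "hdc"),
    ("cost_per_comorbidity", "hdc"),
)


@dataclass(frozen=True)
class CasemixSummary:
    """Log-scale comparison of one variable: outlier vs whole population."""

    variable: str
    outlier_mean_log: float
    population_mean_log: float
    outlier_quartiles: tuple[float, float, float]
    population_quartiles: tuple[float, float, float]
    n_outlier: int
    n_population: int

    @property
    def shift(self) -> float:
        """Difference of log means (outlier minus population)."""
        return self.outlier_mean_log - self.population_mean_log


@dataclass(frozen=True)
class AuditReport:
    """Dashboard percentiles plus casemix summaries for flagged providers."""

    fraud_table: pd.DataFrame  # variables x outliers, percentile fractions
    casemix: dict[str, dict[str, CasemixSummary]]  # outlier -> variable -> summary

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.fraud_table.to_csv(out / "fraud_dashboard.csv")
        rows = []
        for hid, per_var in self.casemix.items():
            for var, s in per_var.items():
                rows.append(
                    {
                        "hospital_id": hid,
                        "variable": var,
                        "outlier_mean_log": s.outlier_mean_log,
                        "population_mean_log": s.population_mean_log,
                        "shift": s.shift,
                        "n_outlier": s.n_outlier,
                        "n_population": s.n_population,
                    }
                )
        pd.DataFrame(rows).to_csv(out / "casemix_comparison.csv", index=False)


def percentile_position(value: float, population: Sequence[float]) -> float:
    """Fraction of population values strictly below ``value``.

    Lies in [0, 1): the minimum maps to 0 and, with N distinct values,
    the maximum to (N - 1)/N.
    """
    pop = np.asarray(population, dtype=float)
    if pop.size == 0:
        raise ValueError("population must be non-empty")
    return float(np.count_nonzero(pop < value) / pop.size)


def fraud_dashboard(
    profiles: Sequence[HospitalProfile],
    outlier_ids: Sequence[str],
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Percentile positions of each outlier on the five fraud variables.

    Returns a variables x outliers table of fractions in [0, 1); when
    ``out_dir`` is given, also writes one density plot per variable with
    vertical lines at each outlier's value.
    """
    by_id = {p.hospital_id: p for p in profiles}
    unknown = [o for o in outlier_ids if o not in by_id]
    if unknown:
        raise KeyError(f"unknown outlier id(s): {unknown}")
    table = pd.DataFrame(
        {
            o: [
                percentile_position(
                    by_id[o].scalar(v), [p.scalar(v) for p in profiles]
                )
                for v in FRAUD_VARIABLES
            ]
            for o in outlier_ids
        },
        index=list(FRAUD_VARIABLES),
    )
    if out_dir is not None:
        _plot_dashboard(profiles, outlier_ids, by_id, Path(out_dir))
    return table


def _plot_dashboard(profiles, outlier_ids, by_id, out: Path) -> None:
    import matplotlib.pyplot as plt

    out.mkdir(parents=True, exist_ok=True)
    for v in FRAUD_VARIABLES:
        pop = [p.scalar(v) for p in profiles]
        fig, ax = plt.subplots(figsize=(6, 3.5))
        ax.hist(pop, bins=30, density=True, color="lightgrey", edgecolor="white")
        for o in outlier_ids:
            ax.axvline(by_id[o].scalar(v), label=o)
        ax.set_xlabel(v)
        ax.set_ylabel("density")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(out / f"dashboard_{v}.png", dpi=120)
        plt.close(fig)


def _log_values(
    variable: str,
    level: str,
    hospital_id: str | None,
    patients: Sequence[PatientSummary],
    cohort: Cohort,
    ci_by_event: dict[str, int],
) -> np.ndarray:
    """Log-scale sample of one casemix variable.

    ``hospital_id=None`` gives the whole population.  HDC-level variables
    attribute each discharge to its hospital; patient-level variables use
    patients with at least one discharge there.  LOS 0 is treated as 1 in
    ratio denominators, and cost/comorbidity divides by comorbidity + 1.
    """
    if level == "patient":
        if hospital_id is None:
            subset = list(patients)
        else:
            pids = {r.patient_id for r in cohort.records if r.hospital_id == hospital_id}
            subset = [p for p in patients if p.patient_id in pids]
        raw = {
            "age": [p.age_first for p in subset],
            "total_cost": [p.total_cost for p in subset],
        }[variable]
    else:
        recs = [
            r
            for r in cohort.records
            if hospital_id is None or r.hospital_id == hospital_id
        ]
        if variable == "los":
            raw = [r.los for r in recs]
        elif variable == "comorbidity":
            raw = [ci_by_event[r.event_id] for r in recs]
        elif variable == "cost_per_los":
            raw = [r.cost / max(r.los, 1) for r in recs]
        elif variable == "cost_per_comorbidity":
            raw = [r.cost / (ci_by_event[r.event_id] + 1) for r in recs]
        else:
            raise ValueError(f"unknown HDC-level variable {variable!r}")
    arr = np.asarray(raw, dtype=float)
    return np.log(arr + 1.0)


def casemix_comparison(
    outlier_id: str,
    patients: Sequence[PatientSummary],
    cohort: Cohort,
    weights: WeightTable,
    out_dir: str | Path | None = None,
) -> dict[str, CasemixSummary]:
    """Compare one provider's casemix with the whole population.

    For each casemix variable, returns the log-scale means of the
    provider's and the population's distributions (the vertical lines of
    the comparison plots) plus quartiles; optionally writes the plots.
    Comorbidity is clipped at 0 for the log scale (negative combined
    scores are rare and the plots compare burden, not protective codes).
    """
    if not any(r.hospital_id == outlier_id for r in cohort.records):
        raise ValueError(f"hospital {outlier_id!r} has no attributable discharges")
    ci_by_event = {
        r.event_id: max(score_hdc(r, weights), 0) for r in cohort.records
    }
    summaries: dict[str, CasemixSummary] = {}
    for variable, level in CASEMIX_VARIABLES:
        out_vals = _log_values(variable, level, outlier_id, patients, cohort, ci_by_event)
        pop_vals = _log_values(variable, level, None, patients, cohort, ci_by_event)
        summaries[variable] = CasemixSummary(
            variable=variable,
            outlier_mean_log=float(out_vals.mean()),
            population_mean_log=float(pop_vals.mean()),
            outlier_quartiles=tuple(np.percentile(out_vals, [25, 50, 75])),
            population_quartiles=tuple(np.percentile(pop_vals, [25, 50, 75])),
            n_outlier=out_vals.size,
            n_population=pop_vals.size,
        )
    if out_dir is not None:
        _plot_casemix(outlier_id, patients, cohort, ci_by_event, Path(out_dir))
    return summaries


def _plot_casemix(outlier_id, patients, cohort, ci_by_event, out: Path) -> None:
    import matplotlib.pyplot as plt

    out.mkdir(parents=True, exist_ok=True)
    for variable, level in CASEMIX_VARIABLES:
        out_vals = _log_values(variable, level, outlier_id, patients, cohort, ci_by_event)
        pop_vals = _log_values(variable, level, None, patients, cohort, ci_by_event)
        fig, ax = plt.subplots(figsize=(6, 3.5))
        ax.hist(pop_vals, bins=40, density=True, alpha=0.5, color="tab:red", label="population")
        ax.hist(out_vals, bins=40, density=True, alpha=0.5, color="tab:blue", label=outlier_id)
        ax.axvline(pop_vals.mean(), color="tab:red", ls="--")
        ax.axvline(out_vals.mean(), color="tab:blue", ls="--")
        ax.set_xlabel(f"log({variable} + 1)")
        ax.set_ylabel("density")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(out / f"casemix_{outlier_id}_{variable}.png", dpi=120)
        plt.close(fig)


def build_audit_report(
    profiles: Sequence[HospitalProfile],
    patients: Sequence[PatientSummary],
    cohort: Cohort,
    weights: WeightTable,
    outlier_ids: Sequence[str],
    out_dir: str | Path | None = None,
) -> AuditReport:
    """Dashboard plus casemix comparison for every flagged provider."""
    fraud_table = fraud_dashboard(profiles, outlier_ids, out_dir=out_dir)
    casemix = {
        o: casemix_comparison(o, patients, cohort, weights, out_dir=out_dir)
        for o in outlier_ids
    }
    report = AuditReport(fraud_table=fraud_table, casemix=casemix)
    if out_dir is not None:
        report.save(out_dir)
    return report
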