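"""Patient- and hospital-level aggregation of a discharge cohort.

Two derived datasets feed the screening pipeline:

* the *patients* dataset — one row per qualifying patient, with age at
  first hospitalization, summed comorbidity index and cost/LOS totals;
* the *hospitals* dataset — one row per provider, carrying the behavioral
  feature vector: the relative frequencies with which the provider codes
  each disease-related DRG (the ``r`` vector), plus scalar indexes
  (average cost, average LOS, volume, specialization, share of
  complication-bearing DRGs, upcoding index, average cost per patient).

The upcoding index implemented here is the hospital's CC share among
disease-family DRGs divided by the population's CC share: 1 means
population-typical coding, values above 1 a CC-heavier coding style.  It
is an interpretable, scale-free ratio isolated in a single function so a
different operationalization can be substituted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .comorbidity import WeightTable, score_hdc
from .hdc_core import Cohort, CohortConfig, HDCRecord

__all__ = [
    "PatientSummary",
    "HospitalProfile",
    "FeatureMatrix",
    "SCALAR_FEATURES",
    "build_patients",
    "patients_to_frame",
    "drg_mix",
    "upcoding_index",
    "build_hospitals",
    "profiles_to_frame",
]

#: scalar features appended after the r components, in matrix column order
SCALAR_FEATURES = (
    "avg_cost",
    "avg_los",
    "n_episodes",
    "n_visits",
    "specialization",
    "pct_cc",
    "upcoding_index",
    "avg_cost_per_patient",
)


@dataclass(frozen=True)
class PatientSummary:
    patient_id: str
    age_first: int
    n_events: int
    total_ci: int
    total_cost: float
    total_los: int

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ValueError(f"patient {self.patient_id}: n_events < 1")
        if self.total_cost < 0 or self.total_los < 0:
            raise ValueError(f"patient {self.patient_id}: negative totals")

    @property
    def mean_los(self) -> float:
        return self.total_los / self.n_events


@dataclass(frozen=True)
class HospitalProfile:
    """Behavioral feature vector of one provider."""

    hospital_id: str
    ownership: str
    r: np.ndarray  # aligned with CohortConfig.drg_family_ordered
    n_episodes: int  # disease-related hospitalizations (DRG in family)
    n_visits: int  # all hospitalizations in the cohort window
    n_patients: int  # distinct patients seen
    avg_cost: float  # total cost / n_visits
    avg_los: float  # total LOS / n_visits
    specialization: float  # n_episodes / n_visits
    pct_cc: float  # CC-DRG share among disease episodes
    upcoding_index: float
    avg_cost_per_patient: float

    def scalar(self, name: str) -> float:
        return float(getattr(self, name))


@dataclass(frozen=True)
class FeatureMatrix:
    """Hospitals x features numeric matrix with a recorded column order."""

    unit_ids: tuple[str, ...]
    feature_names: tuple[str, ...]
    values: np.ndarray
    standardized: bool = False
    center: np.ndarray | None = None
    scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.unit_ids), len(self.feature_names)):
            raise ValueError("values shape inconsistent with ids/names")
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains missing values")

    def select(self, names: Sequence[str]) -> "FeatureMatrix":
        idx = [self.feature_names.index(n) for n in names]
        return replace(
            self,
            feature_names=tuple(names),
            values=self.values[:, idx],
            center=None if self.center is None else self.center[idx],
            scale=None if self.scale is None else self.scale[idx],
        )

    def standardize(self) -> "FeatureMatrix":
        """Z-score each column; constant columns are dropped with a warning.

        Distance-based steps (PFA, k-means, local distances) require
        commensurable columns, so standardization always precedes them.
        """
        if self.standardized:
            return self
        center = self.values.mean(axis=0)
        scale = self.values.std(axis=0)
        keep = scale > 1e-12
        if not keep.all():
            dropped = [n for n, k in zip(self.feature_names, keep) if not k]
            warnings.warn(f"dropping constant feature(s): {dropped}", stacklevel=2)
        z = (self.values[:, keep] - center[keep]) / scale[keep]
        return FeatureMatrix(
            unit_ids=self.unit_ids,
            feature_names=tuple(n for n, k in zip(self.feature_names, keep) if k),
            values=z,
            standardized=True,
            center=center[keep],
            scale=scale[keep],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.unit_ids), columns=list(self.feature_names))


def build_patients(cohort: Cohort, weights: WeightTable) -> list[PatientSummary]:
    """One summary per qualifying patient.

    Age is taken from the chronologically first hospitalization; per-HDC
    comorbidity scores are summed into ``total_ci``.
    """
    by_patient: dict[str, list[HDCRecord]] = {}
    for r in cohort.records:
        by_patient.setdefault(r.patient_id, []).append(r)
    out = []
    for pid in sorted(by_patient):
        recs = sorted(by_patient[pid], key=lambda r: (r.admission_date, r.event_id))
        out.append(
            PatientSummary(
                patient_id=pid,
                age_first=recs[0].age,
                n_events=len(recs),
                total_ci=sum(score_hdc(r, weights) for r in recs),
                total_cost=float(sum(r.cost for r in recs)),
                total_los=sum(r.los for r in recs),
            )
        )
    return out


def patients_to_frame(patients: Sequence[PatientSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in patients],
            "age_first": [p.age_first for p in patients],
            "n_events": [p.n_events for p in patients],
            "total_ci": [p.total_ci for p in patients],
            "total_cost": [p.total_cost for p in patients],
            "total_los": [p.total_los for p in patients],
            "mean_los": [p.mean_los for p in patients],
        }
    )


def drg_mix(episodes: Sequence[HDCRecord], drg_family: Sequence[str]) -> np.ndarray:
    """Relative DRG frequencies of one provider over the disease family.

    Episodes with DRGs outside the family are excluded from numerator and
    denominator; the result lies on the probability simplex.
    """
    if not drg_family:
        raise ValueError("drg_family must be non-empty")
    family = list(drg_family)
    counts = np.zeros(len(family))
    index = {d: i for i, d in enumerate(family)}
    total = 0
    for r in episodes:
        i = index.get(r.drg_code)
        if i is not None:
            counts[i] += 1
            total += 1
    if total == 0:
        raise ValueError("no disease-related episodes: DRG mix undefined")
    return counts / total


def upcoding_index(
    episodes: Sequence[HDCRecord],
    population_episodes: Sequence[HDCRecord],
    config: CohortConfig,
) -> float:
    """Hospital CC share over population CC share among family DRGs.

    Stand-in operationalization of the upcoding-tendency construct:
    1 = population-typical coding, >1 = CC-heavier.  Kept behind this one
    function so an alternative formula can replace it.
    """
    def cc_share(recs: Sequence[HDCRecord]) -> tuple[int, int]:
        fam = config.drg_family
        cc = config.cc_drg_codes
        n_fam = sum(1 for r in recs if r.drg_code in fam)
        n_cc = sum(1 for r in recs if r.drg_code in cc)
        return n_cc, n_fam

    h_cc, h_fam = cc_share(episodes)
    if h_fam == 0:
        raise ValueError("hospital has no disease-family episodes")
    p_cc, p_fam = cc_share(population_episodes)
    if p_fam == 0 or p_cc == 0:
        raise ValueError("population CC share is zero: upcoding index undefined")
    return (h_cc / h_fam) / (p_cc / p_fam)


def build_hospitals(
    cohort: Cohort,
    patients: Sequence[PatientSummary],
    weights: WeightTable,
) -> tuple[list[HospitalProfile], FeatureMatrix]:
    """Aggregate the cohort per provider and assemble the feature matrix.

    Hospitals with zero disease-related episodes are excluded with a
    warning (their DRG mix is undefined).  The matrix columns are the r
    components (``r_<drg>`` in sorted family order) followed by
    :data:`SCALAR_FEATURES`; it is returned unstandardized.
    """
    config = cohort.config
    fam = config.drg_family_ordered
    cc = config.cc_drg_codes
    by_hospital: dict[str, list[HDCRecord]] = {}
    for r in cohort.records:
        by_hospital.setdefault(r.hospital_id, []).append(r)

    family_records = [r for r in cohort.records if r.drg_code in config.drg_family]
    pop_cc = sum(1 for r in family_records if r.drg_code in cc)
    pop_fam = len(family_records)
    if pop_fam and pop_cc == 0:
        raise ValueError("population CC share is zero: upcoding index undefined")

    profiles: list[HospitalProfile] = []
    for hid in sorted(by_hospital):
        recs = by_hospital[hid]
        episodes = [r for r in recs if r.drg_code in config.drg_family]
        if not episodes:
            warnings.warn(
                f"hospital {hid}: no disease-related episodes, excluded", stacklevel=2
            )
            continue
        n_visits = len(recs)
        n_episodes = len(episodes)
        n_cc = sum(1 for r in episodes if r.drg_code in cc)
        total_cost = float(sum(r.cost for r in recs))
        n_patients = len({r.patient_id for r in recs})
        profiles.append(
            HospitalProfile(
                hospital_id=hid,
                ownership=recs[0].ownership,
                r=drg_mix(episodes, fam),
                n_episodes=n_episodes,
                n_visits=n_visits,
                n_patients=n_patients,
                avg_cost=total_cost / n_visits,
                avg_los=sum(r.los for r in recs) / n_visits,
                specialization=n_episodes / n_visits,
                pct_cc=n_cc / n_episodes,
                upcoding_index=(n_cc / n_episodes) / (pop_cc / pop_fam),
                avg_cost_per_patient=total_cost / n_patients,
            )
        )

    names = tuple(f"r_{d}" for d in fam) + SCALAR_FEATURES
    values = np.array(
        [list(p.r) + [p.scalar(s) for s in SCALAR_FEATURES] for p in profiles]
    )
    fm = FeatureMatrix(
        unit_ids=tuple(p.hospital_id for p in profiles),
        feature_names=names,
        values=values,
    )
    return profiles, fm


def profiles_to_frame(
    profiles: Sequence[HospitalProfile], drg_family: Sequence[str] | None = None
) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {
            "hospital_id": p.hospital_id,
            "ownership": p.ownership,
            "n_episodes": p.n_episodes,
            "n_visits": p.n_visits,
            "n_patients": p.n_patients,
            "avg_cost": p.avg_cost,
            "avg_los": p.avg_los,
            "specialization": p.specialization,
            "pct_cc": p.pct_cc,
            "upcoding_index": p.upcoding_index,
            "avg_cost_per_patient": p.avg_cost_per_patient,
        }
        if drg_family is not None:
            row.update({f"r_{d}": v for d, v in zip(drg_family, p.r)})
        rows.append(row)
    return pd.DataFrame(rows)
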