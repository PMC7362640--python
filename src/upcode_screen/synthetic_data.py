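"""Synthetic hospital-discharge claims with known ground truth.

The generator emulates the structure of a regional administrative
database around one index disease (heart failure by default): a
population of providers partitioned into behavior *archetype groups*
that differ in DRG mix, coding of complications, cost level, length of
stay, specialization and volume, plus a small planted minority of
deviants:

* **upcoders** — identical to their group except that each non-CC
  disease episode is relabeled to its CC-paired DRG with probability
  ``delta`` (with the corresponding tariff consequence).  This is the
  "cautious fraudster" construct: no extreme volumes or costs, only a
  shifted coding style.
* **complex-casemix providers** — treat genuinely sicker patients
  (higher comorbidity rates, longer stays), the benign explanation an
  auditor should be able to recognize.

Disease DRGs come in CC/non-CC pairs (``HF01``/``HF01C``...).  Each
archetype group concentrates a fixed mass of its DRG mix on its own
disjoint block of pairs, which separates groups far beyond the
hospital-level sampling noise and makes cluster recovery well-posed.
Every quantity is drawn from one seeded generator, so output is
reproducible byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .comorbidity import WeightTable
from .hdc_core import CohortConfig, HDCRecord

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate",
    "expected_profiles",
    "default_cohort_config",
]

#: primary diagnosis used for disease episodes (heart failure, ICD-9-CM)
DISEASE_PRIMARY_CODE = "4280"
DISEASE_PREFIX = "428"
#: primary diagnoses for non-disease stays (none match the 428 prefix)
OTHER_PRIMARY_CODES = ("486", "5990", "5589", "7802", "8208")
N_OTHER_DRGS = 8


class SimConfig(BaseModel):
    """Study conditions of the synthetic population.

    Defaults mimic the scale of a three-year regional heart-failure
    extraction, scaled down in event count: 183 hospitals in 6 behavior
    groups, 18 CC/non-CC DRG pairs (36 r components + 8 scalar features =
    44 features), ~60-100 disease episodes per hospital (~35k events in
    total), and 10 planted deviants (8 upcoders at ``delta=0.4``, 2
    complex-casemix providers).
    """

    model_config = ConfigDict(frozen=True)

    n_hospitals: int = 183
    n_groups: int = 6
    group_proportions: tuple[float, ...] | None = None
    n_planted_upcoders: int = 8
    n_planted_complex: int = 2
    delta: float = 0.4  # minimum P(relabel non-CC episode to its CC pair)
    delta_spread: float = 0.0  # per-upcoder delta ~ U(delta, delta + delta_spread)
    # optionally, upcoders game only a random subset of DRG pairs: each pair
    # is targeted with this probability, with the per-pair relabeling
    # probability scaled up so the aggregate CC shift stays delta * (1 - p)
    target_pair_frac: float = 1.0

    n_drg_pairs: int = 18
    preferred_mass: float = 0.6  # group mix mass on its own pair block
    mix_concentration: float = 400.0  # Dirichlet concentration around group mix

    # group archetype ranges, interpolated across groups
    cc_base_range: tuple[float, float] = (0.15, 0.35)
    cc_jitter_sd: float = 0.04  # hospital-level spread of the CC probability
    los_base_range: tuple[float, float] = (5.0, 10.0)
    specialization_range: tuple[float, float] = (0.55, 0.30)
    hf_episodes_range: tuple[float, float] = (60.0, 100.0)

    # patient model
    age_mean: float = 76.0
    age_sd: float = 10.0
    volume_cv: float = 0.06  # hospital-level spread of patient volume
    comorbidity_rate: float = 1.2  # Poisson rate of extra coded conditions
    hf_events_per_patient: float = 1.5
    cross_hospital_prob: float = 0.05

    # cost/LOS model
    base_tariff: float = 2800.0
    tariff_growth: float = 1.06  # tariff of pair i = base * growth**i
    cc_premium: float = 0.35
    cost_noise_sd: float = 0.30  # lognormal sigma on cost
    los_sigma: float = 0.45  # lognormal sigma on LOS
    los_comorbidity_slope: float = 0.06  # log-LOS increase per coded condition

    # planted complex-casemix effect
    complex_los_factor: float = 1.5
    complex_comorbidity_factor: float = 1.8

    window_start: date = date(2013, 1, 1)
    window_end: date = date(2015, 12, 31)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        if self.n_groups > self.n_hospitals:
            raise ValueError("more behavior groups than hospitals")
        if self.n_drg_pairs < self.n_groups:
            raise ValueError("need at least one DRG pair per group")
        if not 0 <= self.delta <= 1:
            raise ValueError("delta must be in [0, 1]")
        if self.delta_spread < 0 or self.delta + self.delta_spread > 1:
            raise ValueError("delta + delta_spread must stay in [0, 1]")
        if self.n_planted_upcoders + self.n_planted_complex > self.n_hospitals:
            raise ValueError("more planted deviants than hospitals")
        if self.group_proportions is not None:
            if len(self.group_proportions) != self.n_groups:
                raise ValueError("group_proportions length must equal n_groups")
            if any(p <= 0 for p in self.group_proportions):
                raise ValueError("group_proportions must be positive")
        if not 0 < self.target_pair_frac <= 1:
            raise ValueError("target_pair_frac must be in (0, 1]")
        for name in ("preferred_mass", "cross_hospital_prob"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        positive = (
            "mix_concentration", "cc_jitter_sd", "volume_cv",
            "age_sd", "comorbidity_rate", "hf_events_per_patient",
            "base_tariff", "tariff_growth", "cost_noise_sd", "los_sigma",
            "complex_los_factor", "complex_comorbidity_factor",
        )
        if any(getattr(self, name) <= 0 for name in positive):
            raise ValueError("rate/scale parameters must be > 0")
        if not self.window_start < self.window_end:
            raise ValueError("window_start must precede window_end")
        return self

    # --- derived structure -------------------------------------------------

    @property
    def pair_codes(self) -> tuple[tuple[str, str], ...]:
        """(non-CC, CC) DRG code pairs."""
        return tuple(
            (f"HF{i + 1:02d}", f"HF{i + 1:02d}C") for i in range(self.n_drg_pairs)
        )

    @property
    def tariffs(self) -> np.ndarray:
        return self.base_tariff * self.tariff_growth ** np.arange(self.n_drg_pairs)

    def group_blocks(self) -> list[np.ndarray]:
        """Disjoint pair blocks (one per group) carrying the preferred mass."""
        return [b for b in np.array_split(np.arange(self.n_drg_pairs), self.n_groups)]

    def group_mix(self, g: int) -> np.ndarray:
        """Archetype DRG-pair mix of group g."""
        mix = np.full(self.n_drg_pairs, 0.0)
        block = self.group_blocks()[g]
        rest = self.n_drg_pairs - block.size
        if rest == 0:
            mix[block] = 1.0 / block.size
        else:
            mix[:] = (1 - self.preferred_mass) / rest
            mix[block] = self.preferred_mass / block.size
        return mix

    def _interp(self, lo_hi: tuple[float, float]) -> np.ndarray:
        return np.linspace(lo_hi[0], lo_hi[1], self.n_groups)

    @property
    def group_cc_base(self) -> np.ndarray:
        return self._interp(self.cc_base_range)

    @property
    def group_los_base(self) -> np.ndarray:
        return self._interp(self.los_base_range)

    @property
    def group_specialization(self) -> np.ndarray:
        return self._interp(self.specialization_range)

    @property
    def group_hf_episodes(self) -> np.ndarray:
        return self._interp(self.hf_episodes_range)


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure: behavior group and deviant type per hospital."""

    group: dict[str, int]
    deviant_type: dict[str, str]  # hospital -> "upcoder" | "complex"

    @property
    def upcoders(self) -> frozenset[str]:
        return frozenset(h for h, t in self.deviant_type.items() if t == "upcoder")

    @property
    def complex_casemix(self) -> frozenset[str]:
        return frozenset(h for h, t in self.deviant_type.items() if t == "complex")

    @property
    def deviants(self) -> frozenset[str]:
        return frozenset(self.deviant_type)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"group": self.group, "deviant_type": self.deviant_type}, indent=2)
        )

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        raw = json.loads(Path(path).read_text())
        return cls(group={k: int(v) for k, v in raw["group"].items()},
                   deviant_type=dict(raw["deviant_type"]))


def default_cohort_config(config: SimConfig) -> CohortConfig:
    """Cohort definition matching the generator's coding scheme."""
    family = frozenset(c for pair in config.pair_codes for c in pair)
    cc = frozenset(pair[1] for pair in config.pair_codes)
    return CohortConfig(
        disease_codes=frozenset({DISEASE_PREFIX}),
        drg_family=family,
        cc_drg_codes=cc,
        window_start=config.window_start,
        window_end=config.window_end,
    )


def expected_profiles(config: SimConfig) -> dict[int, dict]:
    """Closed-form per-group expectations used as oracles in tests.

    For each group: the archetype DRG-pair mass, the r vector over the
    sorted DRG family implied by splitting each pair by the CC
    probability, the CC share (and its upcoded counterpart
    ``p + E[delta] (1 - p)`` at the mean relabeling probability
    ``delta + delta_spread / 2``), and the specialization fraction.
    """
    out: dict[int, dict] = {}
    fam_order = sorted(c for pair in config.pair_codes for c in pair)
    for g in range(config.n_groups):
        mix = config.group_mix(g)
        p = float(config.group_cc_base[g])
        r_map = {}
        for i, (plain, cc_code) in enumerate(config.pair_codes):
            r_map[plain] = mix[i] * (1 - p)
            r_map[cc_code] = mix[i] * p
        out[g] = {
            "pair_mass": mix,
            "r": np.array([r_map[c] for c in fam_order]),
            "pct_cc": p,
            "pct_cc_upcoder": p + (config.delta + config.delta_spread / 2) * (1 - p),
            "specialization": float(config.group_specialization[g]),
        }
    return out


def _sample_conditions(
    rng: np.random.Generator, n: int, condition_prefixes: list[str]
) -> list[str]:
    """Draw n distinct condition codes (first prefix of each condition)."""
    n = min(n, len(condition_prefixes))
    idx = rng.choice(len(condition_prefixes), size=n, replace=False)
    return [condition_prefixes[i] for i in idx]


def simulate(
    config: SimConfig, weights: WeightTable | None = None
) -> tuple[list[HDCRecord], GroundTruth]:
    """Generate HDC records and the planted ground truth.

    Reproducible under ``config.seed``; every hospital has at least one
    disease-related episode.  Upcoder hospitals differ from their group
    only through the ``delta`` relabeling of non-CC episodes and the
    tariff consequence of the relabeled DRG.
    """
    if weights is None:
        weights = WeightTable.load_default()
    rng = np.random.default_rng(config.seed)
    n_h = config.n_hospitals
    hospital_ids = [f"H{i + 1:03d}" for i in range(n_h)]

    # group assignment
    if config.group_proportions is None:
        groups = np.arange(n_h) % config.n_groups
    else:
        props = np.asarray(config.group_proportions, dtype=float)
        props = props / props.sum()
        sizes = np.floor(props * n_h).astype(int)
        while sizes.sum() < n_h:
            sizes[int(np.argmax(props * n_h - sizes))] += 1
        groups = np.repeat(np.arange(config.n_groups), sizes)
    rng.shuffle(groups)

    # planted deviants, stratified round-robin over groups: cautious
    # fraudsters are scattered across peer groups, never concentrated in one
    n_dev = config.n_planted_upcoders + config.n_planted_complex
    members = {g: list(np.flatnonzero(groups == g)) for g in range(config.n_groups)}
    group_cycle = rng.permutation(config.n_groups)
    deviant_type: dict[str, str] = {}
    for j in range(n_dev):
        g = int(group_cycle[j % config.n_groups])
        pool = [i for i in members[g] if hospital_ids[i] not in deviant_type]
        if not pool:  # tiny group exhausted; fall back to any untouched hospital
            pool = [i for i in range(n_h) if hospital_ids[i] not in deviant_type]
        i = int(pool[rng.integers(0, len(pool))])
        deviant_type[hospital_ids[i]] = (
            "upcoder" if j < config.n_planted_upcoders else "complex"
        )

    ownership = rng.choice(["public", "private"], size=n_h, p=[0.6, 0.4])
    tariffs = config.tariffs
    pair_codes = config.pair_codes
    other_drgs = [f"X{j + 1:02d}" for j in range(N_OTHER_DRGS)]
    condition_prefixes = [prefixes[0] for prefixes, _ in weights.entries.values()]
    n_days = (config.window_end - config.window_start).days

    records: list[HDCRecord] = []
    truth_group: dict[str, int] = {}
    event_counter = 0
    patient_counter = 0

    def new_event_id() -> str:
        nonlocal event_counter
        event_counter += 1
        return f"E{event_counter:06d}"

    for i, hid in enumerate(hospital_ids):
        g = int(groups[i])
        truth_group[hid] = g
        dtype = deviant_type.get(hid)
        is_upcoder = dtype == "upcoder"
        is_complex = dtype == "complex"
        # fraud intensity varies by fraudster; all lie at or above `delta`.
        # each fraudster games its own subset of DRG pairs, with the per-pair
        # relabeling probability scaled so the aggregate shift stays delta_h
        if is_upcoder:
            delta_h = config.delta + config.delta_spread * float(rng.random())
            targeted = rng.random(config.n_drg_pairs) < config.target_pair_frac
            if not targeted.any():
                targeted[int(rng.integers(0, config.n_drg_pairs))] = True
            delta_pair = min(1.0, delta_h / config.target_pair_frac)
        else:
            targeted = None
            delta_pair = 0.0

        mix_h = rng.dirichlet(config.mix_concentration * config.group_mix(g))
        p_cc_h = float(
            np.clip(rng.normal(config.group_cc_base[g], config.cc_jitter_sd), 0.02, 0.90)
        )
        cost_mult_h = float(rng.lognormal(0.0, 0.04))
        spec_g = float(config.group_specialization[g])
        ci_rate_h = config.comorbidity_rate * (
            config.complex_comorbidity_factor if is_complex else 1.0
        )
        los_base_h = float(config.group_los_base[g]) * (
            config.complex_los_factor if is_complex else 1.0
        )

        mean_patients = config.group_hf_episodes[g] / config.hf_events_per_patient
        n_patients = max(1, int(round(mean_patients * rng.lognormal(0.0, config.volume_cv))))
        for _ in range(n_patients):
            patient_counter += 1
            pid = f"P{patient_counter:06d}"
            age = int(np.clip(round(rng.normal(config.age_mean, config.age_sd)), 18, 105))
            n_hf = 1 + int(rng.poisson(config.hf_events_per_patient - 1.0))
            n_other = int(rng.poisson(n_hf * (1.0 / spec_g - 1.0)))
            for ev in range(n_hf + n_other):
                is_hf = ev < n_hf
                # a small share of non-disease stays happen elsewhere
                if not is_hf and rng.random() < config.cross_hospital_prob and n_h > 1:
                    other = int(rng.integers(0, n_h - 1))
                    ev_hid = hospital_ids[other if other < i else other + 1]
                    ev_own = ownership[other if other < i else other + 1]
                else:
                    ev_hid, ev_own = hid, ownership[i]

                age_factor = max(0.2, 1.0 + 0.02 * (age - 70))
                n_cond = int(rng.poisson(ci_rate_h * age_factor))
                secondary = _sample_conditions(rng, n_cond, condition_prefixes)

                if is_hf:
                    pair = int(rng.choice(config.n_drg_pairs, p=mix_h))
                    cc = bool(rng.random() < p_cc_h)
                    if not cc and is_upcoder and ev_hid == hid and targeted[pair]:
                        cc = bool(rng.random() < delta_pair)
                    drg = pair_codes[pair][1] if cc else pair_codes[pair][0]
                    base_cost = tariffs[pair] * (1 + config.cc_premium if cc else 1.0)
                    primary = DISEASE_PRIMARY_CODE
                    los_loc = np.log(los_base_h) + config.los_comorbidity_slope * n_cond
                else:
                    drg = other_drgs[int(rng.integers(0, N_OTHER_DRGS))]
                    base_cost = 2000.0
                    primary = OTHER_PRIMARY_CODES[int(rng.integers(0, len(OTHER_PRIMARY_CODES)))]
                    los_loc = np.log(4.0) + config.los_comorbidity_slope * n_cond

                los = min(int(round(rng.lognormal(los_loc, config.los_sigma))), 365)
                cost = float(base_cost * cost_mult_h * rng.lognormal(0.0, config.cost_noise_sd))
                admission = config.window_start + timedelta(days=int(rng.integers(0, n_days + 1 - los)))
                records.append(
                    HDCRecord(
                        event_id=new_event_id(),
                        patient_id=pid,
                        hospital_id=ev_hid,
                        admission_date=admission,
                        discharge_date=admission + timedelta(days=los),
                        age=age,
                        diagnosis_codes=tuple([primary] + secondary),
                        procedure_codes=(),
                        drg_code=drg,
                        cost=round(cost, 2),
                        ownership=str(ev_own),
                    )
                )
    return records, GroundTruth(group=truth_group, deviant_type=deviant_type)
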