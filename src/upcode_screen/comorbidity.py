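"""Per-discharge comorbidity scoring and per-patient summation.

The score is a weighted count of distinct chronic conditions coded on a
discharge: each condition in the weight table is matched by diagnosis-code
prefix against every diagnosis position of the HDC, counts at most once
per discharge no matter how many of its codes appear, and contributes its
integer weight (weights may be negative).  Per-patient scores are the
plain sum of the per-discharge scores — no normalization by number of
admissions is applied.

The shipped default table is the combined comorbidity score (Gagne et al.
2011); it lives in an editable YAML data file so alternative weightings
(e.g. Charlson) can be swapped in without touching code.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .hdc_core import HDCRecord

__all__ = ["WeightTable", "score_hdc", "patient_comorbidity"]


@dataclass(frozen=True)
class WeightTable:
    """Condition name -> (diagnosis-code prefixes, integer weight)."""

    entries: Mapping[str, tuple[tuple[str, ...], int]]
    provenance: str = ""

    def __post_init__(self) -> None:
        for name, (prefixes, weight) in self.entries.items():
            if not prefixes:
                raise ValueError(f"condition {name!r}: empty prefix set")
            if not isinstance(weight, int) or isinstance(weight, bool):
                raise ValueError(f"condition {name!r}: weight {weight!r} not an integer")

    @classmethod
    def from_mapping(cls, conditions: Mapping[str, Mapping], provenance: str = "") -> "WeightTable":
        entries = {
            name: (tuple(str(p) for p in spec["prefixes"]), int(spec["weight"]))
            for name, spec in conditions.items()
        }
        return cls(entries=entries, provenance=provenance)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "WeightTable":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_mapping(raw["conditions"], provenance=raw.get("provenance", ""))

    @classmethod
    def load_default(cls) -> "WeightTable":
        """The shipped combined-comorbidity-score table."""
        ref = resources.files("upcode_screen.data") / "combined_comorbidity_score.yaml"
        raw = yaml.safe_load(ref.read_text())
        return cls.from_mapping(raw["conditions"], provenance=raw.get("provenance", ""))

    def matched_conditions(self, diagnosis_codes: Iterable[str]) -> set[str]:
        codes = tuple(diagnosis_codes)
        return {
            name
            for name, (prefixes, _) in self.entries.items()
            if any(code.startswith(p) for code in codes for p in prefixes)
        }


def score_hdc(record: HDCRecord, weights: WeightTable) -> int:
    """Comorbidity index of one discharge.

    All diagnosis positions (primary and secondary) are scanned; each
    condition counts once.  Codes matching no condition contribute 0.
    """
    matched = weights.matched_conditions(record.diagnosis_codes)
    return sum(weights.entries[name][1] for name in matched)


def patient_comorbidity(per_hdc_scores: Iterable[int]) -> int:
    """Sum of a patient's per-discharge scores (empty -> 0)."""
    return sum(per_hdc_scores)
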