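"""EWGSOP2 reference-standard classification.

Sarcopenia is confirmed by the joint presence of low muscle *strength* and low
muscle *quantity*.  Strength may be probed with handgrip dynamometry (HG) or
the five-times sit-to-stand test (5STS); quantity with appendicular skeletal
mass (ASM) or the skeletal muscle index (SMI = ASM / height**2).  The four
resulting criterion combinations each define a reference standard.

All cutoffs are strict inequalities; a value exactly equal to its cutoff is
classified *not low*.

Cutoffs (sex-specific where applicable):

==========  ================  ================
measure     men               women
==========  ================  ================
handgrip    < 27 kg           < 16 kg
5STS        > 15 s            > 15 s
ASM         < 20 kg           < 15 kg
SMI         < 7 kg/m^2        < 5.5 kg/m^2
==========  ================  ================

ASM/SMI are taken as inputs (typically from bioimpedance analysis via a
population-validated conversion); a user-supplied callable may be plugged in
via :func:`asm_from_impedance` for raw-impedance workflows.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable

import pandas as pd

__all__ = [
    "GRIP_CUTOFF_KG",
    "FIVESTS_CUTOFF_S",
    "ASM_CUTOFF_KG",
    "SMI_CUTOFF_KG_M2",
    "FRAILTY_CRITERIA",
    "RISK_FACTORS",
    "SarcopeniaCriterion",
    "ParticipantRecord",
    "MissingDataError",
    "low_muscle_strength",
    "low_muscle_quantity",
    "sarcopenia_reference",
    "frailty_phenotype",
    "reference_labels",
    "asm_from_impedance",
]

GRIP_CUTOFF_KG = {"male": 27.0, "female": 16.0}
FIVESTS_CUTOFF_S = 15.0
ASM_CUTOFF_KG = {"male": 20.0, "female": 15.0}
SMI_CUTOFF_KG_M2 = {"male": 7.0, "female": 5.5}

#: Fried phenotype components; frailty = at least 3 of 5 present.
FRAILTY_CRITERIA = (
    "slowness",
    "exhaustion",
    "weight_loss",
    "weakness",
    "low_activity",
)

#: Health-related risk factors carried as booleans on each record.
RISK_FACTORS = (
    "education_low",
    "socioeconomic_low",
    "comorbidity_2plus",
    "smoking",
    "polypharmacy_5plus",
    "self_perceived_health_low",
    "depression",
    "falls_2plus",
    "hospitalized",
)


class MissingDataError(ValueError):
    """A measurement required by the requested classification is absent."""


class SarcopeniaCriterion(enum.Enum):
    """The four strength x quantity combinations of the reference standard."""

    HG_ASM = ("HG", "ASM")
    HG_SMI = ("HG", "SMI")
    FIVESTS_ASM = ("5STS", "ASM")
    FIVESTS_SMI = ("5STS", "SMI")

    @property
    def strength_test(self) -> str:
        return self.value[0]

    @property
    def quantity_measure(self) -> str:
        return self.value[1]

    @classmethod
    def parse(cls, name: str) -> "SarcopeniaCriterion":
        """Parse CLI-style names like ``hg_asm`` or ``5sts_smi``."""
        key = name.strip().lower().replace("+", "_").replace("-", "_")
        mapping = {
            "hg_asm": cls.HG_ASM,
            "hg_smi": cls.HG_SMI,
            "5sts_asm": cls.FIVESTS_ASM,
            "5sts_smi": cls.FIVESTS_SMI,
        }
        try:
            return mapping[key]
        except KeyError:
            raise ValueError(
                f"unknown criterion {name!r}; expected one of {sorted(mapping)}"
            ) from None

    @property
    def label(self) -> str:
        return {"HG": "hg", "5STS": "5sts"}[self.strength_test] + "_" + self.quantity_measure.lower()


@dataclass
class ParticipantRecord:
    """One cohort member: demographics, reference measurements, booleans.

    Continuous measurements may be ``None`` (missing); an operation that needs
    a missing field raises :class:`MissingDataError` naming it.  When both
    ``asm_kg`` and ``smi_kg_m2`` are present they are cross-checked against
    ``asm / height**2`` at 2% tolerance (warning on mismatch).
    """

    participant_id: str
    sex: str
    age_years: float | None = None
    height_m: float | None = None
    weight_kg: float | None = None
    handgrip_kg: float | None = None
    fivests_s: float | None = None
    asm_kg: float | None = None
    smi_kg_m2: float | None = None
    risk_factors: dict[str, bool] = field(default_factory=dict)
    frailty_criteria: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        for name in ("age_years", "height_m", "weight_kg", "handgrip_kg",
                     "fivests_s", "asm_kg", "smi_kg_m2"):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v <= 0):
                raise ValueError(f"{name} must be positive and finite, got {v}")
        if self.asm_kg is not None and self.smi_kg_m2 is not None and self.height_m:
            implied = self.asm_kg / self.height_m**2
            if abs(implied - self.smi_kg_m2) > 0.02 * implied:
                warnings.warn(
                    f"participant {self.participant_id}: smi_kg_m2="
                    f"{self.smi_kg_m2:.2f} disagrees with asm/height^2="
                    f"{implied:.2f} by more than 2%",
                    UserWarning,
                    stacklevel=2,
                )

    @property
    def bmi(self) -> float | None:
        if self.height_m and self.weight_kg:
            return self.weight_kg / self.height_m**2
        return None


def _require(value, field_name: str, pid: str = "?"):
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise MissingDataError(
            f"participant {pid}: missing {field_name!r} required for classification"
        )
    return value


def low_muscle_strength(record: ParticipantRecord, test: str) -> bool:
    """Low strength under handgrip (``"HG"``) or five-times sit-to-stand (``"5STS"``)."""
    if test == "HG":
        grip = _require(record.handgrip_kg, "handgrip_kg", record.participant_id)
        return grip < GRIP_CUTOFF_KG[record.sex]
    if test == "5STS":
        t = _require(record.fivests_s, "fivests_s", record.participant_id)
        return t > FIVESTS_CUTOFF_S
    raise ValueError(f"unknown strength test {test!r}; expected 'HG' or '5STS'")


def low_muscle_quantity(record: ParticipantRecord, measure: str) -> bool:
    """Low quantity under appendicular mass (``"ASM"``) or muscle index (``"SMI"``)."""
    if measure == "ASM":
        asm = _require(record.asm_kg, "asm_kg", record.participant_id)
        return asm < ASM_CUTOFF_KG[record.sex]
    if measure == "SMI":
        smi = _require(record.smi_kg_m2, "smi_kg_m2", record.participant_id)
        return smi < SMI_CUTOFF_KG_M2[record.sex]
    raise ValueError(f"unknown quantity measure {measure!r}; expected 'ASM' or 'SMI'")


def sarcopenia_reference(
    record: ParticipantRecord, criterion: SarcopeniaCriterion
) -> bool:
    """Confirmed sarcopenia: low strength AND low quantity under *criterion*."""
    return low_muscle_strength(record, criterion.strength_test) and low_muscle_quantity(
        record, criterion.quantity_measure
    )


def frailty_phenotype(record: ParticipantRecord) -> tuple[bool, int]:
    """Fried phenotype: ``(frail, count)`` where frail means >= 3 of 5 criteria."""
    missing = [c for c in FRAILTY_CRITERIA if c not in record.frailty_criteria]
    if missing:
        raise MissingDataError(
            f"participant {record.participant_id}: missing frailty criteria {missing}"
        )
    count = sum(bool(record.frailty_criteria[c]) for c in FRAILTY_CRITERIA)
    return count >= 3, count


# -- vectorized cohort-table interface ---------------------------------------

_STRENGTH_COL = {"HG": "handgrip_kg", "5STS": "fivests_s"}
_QUANTITY_COL = {"ASM": "asm_kg", "SMI": "smi_kg_m2"}


def reference_labels(
    cohort: pd.DataFrame, criterion: SarcopeniaCriterion
) -> pd.Series:
    """Reference-standard labels for a cohort table.

    Returns a nullable-boolean Series aligned with *cohort*; rows missing a
    needed measurement get ``<NA>`` (they are excluded from that criterion's
    analysis, not from the cohort).
    """
    scol = _STRENGTH_COL[criterion.strength_test]
    qcol = _QUANTITY_COL[criterion.quantity_measure]
    for col in ("sex", scol, qcol):
        if col not in cohort.columns:
            raise MissingDataError(f"cohort table lacks required column {col!r}")
    sex = cohort["sex"]
    if criterion.strength_test == "HG":
        cuts = sex.map(GRIP_CUTOFF_KG).astype(float)
        low_strength = cohort[scol] < cuts
    else:
        low_strength = cohort[scol] > FIVESTS_CUTOFF_S
    qcuts = sex.map(ASM_CUTOFF_KG if criterion.quantity_measure == "ASM" else SMI_CUTOFF_KG_M2)
    low_quantity = cohort[qcol] < qcuts.astype(float)
    labels = (low_strength & low_quantity).astype("boolean")
    labels[cohort[scol].isna() | cohort[qcol].isna()] = pd.NA
    return labels


def asm_from_impedance(
    record_raw: dict,
    converter: Callable[[dict], float],
) -> float:
    """Hook for user-supplied ASM estimation from raw bioimpedance values.

    *converter* receives the raw record dict and returns ASM in kg.  The
    package ships no built-in impedance equation; supply a population-
    validated one.
    """
    asm = float(converter(record_raw))
    if not math.isfinite(asm) or asm <= 0:
        raise ValueError(f"converter returned implausible ASM {asm!r}")
    return asm
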