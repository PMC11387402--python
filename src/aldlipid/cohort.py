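"""Clinical stratification of ALD cohorts.

Male patients are grouped by the presence of cerebral ALD (CALD), adrenal
insufficiency (AI), and severity of spinal cord disease (EDSS > 6 =
severe). Because new symptoms can still appear in younger patients, the
asymptomatic reference strata additionally have age-restricted variants
(> 55 years), by which age CALD and new-onset AI are rare. Women are
stratified only above age 40 (spinal cord disease is rare before the 4th
decade) into mild (EDSS <= 6) and severe (EDSS > 6).

Boundary conventions: "> 55" is strict; EDSS exactly 6 is mild.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PatientRecord",
    "Stratum",
    "stratify_males",
    "stratify_females",
    "hct_series",
    "records_from_frame",
]

EDSS_SEVERE_THRESHOLD = 6.0
MALE_AGE_CUTOFF = 55.0
FEMALE_AGE_MIN = 40.0


@dataclass(frozen=True)
class PatientRecord:
    """Clinical attributes of one patient driving stratification."""

    patient_id: str
    sex: str
    age: float
    cald: bool = False
    adrenal_insufficiency: bool = False
    edss: float | None = None
    hct: bool = False
    months_post_hct: float | None = None
    xci_fraction: float | None = None
    sample_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"{self.patient_id}: sex must be male/female")
        if self.age < 0:
            raise ValueError(f"{self.patient_id}: negative age")
        if self.edss is not None and not 0 <= self.edss <= 10:
            raise ValueError(f"{self.patient_id}: EDSS {self.edss} outside [0, 10]")
        if self.xci_fraction is not None and not 0 <= self.xci_fraction <= 1:
            raise ValueError(f"{self.patient_id}: XCI fraction outside [0, 1]")


@dataclass
class Stratum:
    """A named analysis group with its membership predicate description."""

    name: str
    description: str
    members: tuple[str, ...]
    ages: tuple[float, ...] = ()

    @property
    def n(self) -> int:
        return len(self.members)

    @property
    def mean_age(self) -> float:
        return float(np.mean(self.ages)) if self.ages else float("nan")

    @property
    def age_range(self) -> tuple[float, float]:
        if not self.ages:
            return (float("nan"), float("nan"))
        return (min(self.ages), max(self.ages))

    def summary(self) -> dict:
        lo, hi = self.age_range
        return {
            "stratum": self.name,
            "n": self.n,
            "mean_age": self.mean_age,
            "age_min": lo,
            "age_max": hi,
        }


def _stratum(name: str, desc: str, members: Sequence[PatientRecord]) -> Stratum:
    return Stratum(
        name,
        desc,
        tuple(p.patient_id for p in members),
        tuple(p.age for p in members),
    )


def stratify_males(records: Iterable[PatientRecord]) -> dict[str, Stratum]:
    """Male contrast strata: CALD, AI, and spinal-cord-severity groupings.

    Patients without an EDSS score are excluded (with a log message) from
    the spinal-cord contrast only.
    """
    males = [p for p in records if p.sex == "male"]
    with_edss = [p for p in males if p.edss is not None]
    dropped = [p.patient_id for p in males if p.edss is None]
    if dropped:
        logger.warning(
            "spinal-cord contrast: %d male patient(s) without EDSS excluded: %s",
            len(dropped),
            dropped,
        )
    strata = {
        "CALD": _stratum("CALD", "cerebral ALD present", [p for p in males if p.cald]),
        "noCALD_all": _stratum(
            "noCALD_all", "no cerebral ALD, all ages", [p for p in males if not p.cald]
        ),
        "noCALD_gt55": _stratum(
            "noCALD_gt55",
            f"no cerebral ALD and age > {MALE_AGE_CUTOFF:g}",
            [p for p in males if not p.cald and p.age > MALE_AGE_CUTOFF],
        ),
        "AI": _stratum(
            "AI",
            "adrenal insufficiency present",
            [p for p in males if p.adrenal_insufficiency],
        ),
        "noAI_all": _stratum(
            "noAI_all",
            "no adrenal insufficiency, all ages",
            [p for p in males if not p.adrenal_insufficiency],
        ),
        "noAI_gt55": _stratum(
            "noAI_gt55",
            f"no adrenal insufficiency and age > {MALE_AGE_CUTOFF:g}",
            [
                p
                for p in males
                if not p.adrenal_insufficiency and p.age > MALE_AGE_CUTOFF
            ],
        ),
        "mild_gt55": _stratum(
            "mild_gt55",
            f"EDSS <= {EDSS_SEVERE_THRESHOLD:g} and age > {MALE_AGE_CUTOFF:g}",
            [
                p
                for p in with_edss
                if p.edss <= EDSS_SEVERE_THRESHOLD and p.age > MALE_AGE_CUTOFF
            ],
        ),
        "severe": _stratum(
            "severe",
            f"EDSS > {EDSS_SEVERE_THRESHOLD:g}, any age",
            [p for p in with_edss if p.edss > EDSS_SEVERE_THRESHOLD],
        ),
    }
    return strata


def stratify_females(
    records: Iterable[PatientRecord],
    age_min: float = FEMALE_AGE_MIN,
    rule: str = "edss",
) -> dict[str, Stratum]:
    """Female mild/severe strata among women above ``age_min``.

    ``rule="edss"`` (default): severe = EDSS > 6, mild = EDSS <= 6.
    ``rule="presence"``: severe = any spinal cord disease (EDSS > 0).
    """
    if rule not in ("edss", "presence"):
        raise ValueError(f"unknown female severity rule {rule!r}")
    females = [p for p in records if p.sex == "female"]
    eligible = [p for p in females if p.age > age_min]
    with_edss = [p for p in eligible if p.edss is not None]
    dropped = [p.patient_id for p in eligible if p.edss is None]
    if dropped:
        logger.warning(
            "female contrast: %d patient(s) without EDSS excluded: %s",
            len(dropped),
            dropped,
        )
    if rule == "edss":
        severe = [p for p in with_edss if p.edss > EDSS_SEVERE_THRESHOLD]
        mild = [p for p in with_edss if p.edss <= EDSS_SEVERE_THRESHOLD]
        desc = f"EDSS > {EDSS_SEVERE_THRESHOLD:g}"
    else:
        severe = [p for p in with_edss if p.edss > 0]
        mild = [p for p in with_edss if p.edss == 0]
        desc = "spinal cord disease present (EDSS > 0)"
    return {
        "mild": _stratum("mild", f"age > {age_min:g}, not ({desc})", mild),
        "severe": _stratum("severe", f"age > {age_min:g}, {desc}", severe),
    }


def hct_series(
    records: Iterable[PatientRecord],
    measurements: pd.DataFrame,
) -> dict[str, pd.DataFrame]:
    """Per-patient post-transplant biomarker trajectories.

    ``measurements`` is long-format with columns ``patient_id``,
    ``months_post_hct``, ``value``. Trajectories are keyed by patient and
    sorted by months; a patient with follow-up but no baseline (0 months)
    is retained and logged.
    """
    required = {"patient_id", "months_post_hct", "value"}
    if not required <= set(measurements.columns):
        raise ValueError(f"measurements must have columns {sorted(required)}")
    hct_ids = {p.patient_id for p in records if p.hct}
    if not hct_ids:
        raise ValueError("no HCT patients in the cohort")
    out: dict[str, pd.DataFrame] = {}
    for pid, grp in measurements.groupby("patient_id", sort=True):
        if pid not in hct_ids:
            logger.warning("measurements for non-HCT patient %s ignored", pid)
            continue
        traj = grp.sort_values("months_post_hct").reset_index(drop=True)
        if not (traj["months_post_hct"] == 0).any():
            logger.warning("patient %s has follow-up but no baseline sample", pid)
        out[str(pid)] = traj[["months_post_hct", "value"]]
    return out


def group_means(trajectories: Mapping[str, pd.DataFrame]) -> pd.Series:
    """Cross-patient mean value at each sampled timepoint."""
    stacked = pd.concat(trajectories.values(), ignore_index=True)
    return stacked.groupby("months_post_hct")["value"].mean()


def records_from_frame(frame: pd.DataFrame) -> list[PatientRecord]:
    """Build patient records from a metadata table (see io module schema)."""
    records = []
    for _, row in frame.iterrows():
        edss = row.get("edss")
        xci = row.get("xci_fraction")
        months = row.get("months_post_hct")
        records.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                sex=str(row["sex"]),
                age=float(row["age"]),
                cald=bool(row.get("cald", False)),
                adrenal_insufficiency=bool(row.get("adrenal_insufficiency", False)),
                edss=None if pd.isna(edss) else float(edss),
                hct=bool(row.get("hct", False)),
                months_post_hct=None if pd.isna(months) else float(months),
                xci_fraction=None if pd.isna(xci) else float(xci),
                sample_ids=tuple(
                    str(row["sample_id"]).split(";") if "sample_id" in row else ()
                ),
            )
        )
    return records
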