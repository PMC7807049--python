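"""Growth-curve arithmetic, passage classification, beta-gal percentages.

Population doubling (PD) of one passage is log2(harvested/seeded);
cumulative PD (cPD) is its running sum across passages. The early (E)
passage of a donor is the one whose cPD is closest to six; the senescent
(S) passage is the first one whose growth falls below a configurable
threshold rate (default: less than one doubling in 7 days; a
"failed to double in two weeks" rule is also provided).

The histochemical SA-beta-galactosidase stain is the benchmark standard:
per well, the percentage of blue-stained (positive) cells among at least
200 counted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BGAL_MIN_COUNT = 200


def population_doubling(seeded: float, harvested: float) -> float:
    """PD = log2(harvested / seeded); both counts must be positive."""
    if seeded <= 0 or harvested <= 0:
        raise ValueError(f"counts must be positive (seeded={seeded}, harvested={harvested})")
    return math.log2(harvested / seeded)


@dataclass
class PassageRecord:
    passage: int
    seeded: float
    harvested: float
    days: float

    @property
    def pd(self) -> float:
        return population_doubling(self.seeded, self.harvested)


@dataclass
class GrowthCurve:
    """Per-passage seeding/harvest records of one donor culture."""

    records: list[PassageRecord]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("growth curve has no passages")
        for r in self.records:
            if r.days <= 0:
                raise ValueError(f"non-positive culture duration at passage {r.passage}")

    @property
    def pds(self) -> np.ndarray:
        return np.array([r.pd for r in self.records])

    @property
    def cpds(self) -> np.ndarray:
        return np.cumsum(self.pds)

    @property
    def pd_rates(self) -> np.ndarray:
        """Population doublings per day."""
        return self.pds / np.array([r.days for r in self.records])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "passage": [r.passage for r in self.records],
                "seeded": [r.seeded for r in self.records],
                "harvested": [r.harvested for r in self.records],
                "days": [r.days for r in self.records],
                "pd": self.pds,
                "cpd": self.cpds,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, meta: dict | None = None) -> "GrowthCurve":
        records = [
            PassageRecord(int(row.passage), float(row.seeded), float(row.harvested), float(row.days))
            for row in frame.itertuples()
        ]
        return cls(records, dict(meta or {}))


# -- senescence rules -------------------------------------------------------


def rule_less_than_1pd_in_7_days(record: PassageRecord) -> bool:
    """Senescent when the passage achieved < 1 PD per 7 days of culture."""
    return record.pd / record.days * 7.0 < 1.0


def rule_failed_to_double_in_14_days(record: PassageRecord) -> bool:
    """Senescent when the passage failed to double within two weeks."""
    return record.pd / record.days * 14.0 < 1.0


SENESCENCE_RULES = {
    "lt1pd_7d": rule_less_than_1pd_in_7_days,
    "no_double_14d": rule_failed_to_double_in_14_days,
}


def classify_passages(
    curve: GrowthCurve,
    early_target_cpd: float = 6.0,
    senescent_rule="lt1pd_7d",
) -> tuple[int, int | None]:
    """Pick the early and senescent passage indices of a growth curve.

    Returns ``(e_index, s_index)`` as positions into ``curve.records``.
    E is the passage whose cPD is closest to ``early_target_cpd`` (ties
    break to the earlier passage). S is the first passage satisfying the
    senescence rule (a key of ``SENESCENCE_RULES`` or a callable); when
    no passage satisfies it, S is ``None`` and a warning is issued.
    """
    if len(curve.records) < 2:
        raise ValueError("need at least 2 passages to classify")
    rule = SENESCENCE_RULES[senescent_rule] if isinstance(senescent_rule, str) else senescent_rule
    cpds = curve.cpds
    e_index = int(np.argmin(np.abs(cpds - early_target_cpd)))  # argmin keeps first on ties
    s_index: int | None = None
    for i, record in enumerate(curve.records):
        if rule(record):
            s_index = i
            break
    if s_index is None:
        warnings.warn("no passage satisfies the senescence rule; S undefined", stacklevel=2)
    return e_index, s_index


# -- beta-galactosidase staining --------------------------------------------


@dataclass
class BgalCount:
    """Positive/total cell counts of one stained well."""

    positive: int
    total: int
    well: str = ""

    def __post_init__(self) -> None:
        if self.total < 1:
            raise ValueError("total count must be >= 1")
        if not 0 <= self.positive <= self.total:
            raise ValueError(
                f"positive count {self.positive} outside [0, {self.total}]"
            )


def bgal_percentage(count: BgalCount) -> float:
    """Percentage of beta-gal positive cells; warns when the well is undercounted."""
    if count.total < BGAL_MIN_COUNT:
        warnings.warn(
            f"undercounted well {count.well!r}: {count.total} cells "
            f"(< {BGAL_MIN_COUNT})",
            stacklevel=2,
        )
    return 100.0 * count.positive / count.total
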