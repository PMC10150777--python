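"""Sample and family containers.

A cohort is carried as a pandas DataFrame of samples (one row per
individual, PED-like columns) plus a list of :class:`Family` objects that
index into it.  The DataFrame is the interchange surface; Family is the
unit the segregation-coding logic operates on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: columns every sample sheet must carry
SAMPLE_COLUMNS = [
    "family_id",
    "sample_id",
    "father",
    "mother",
    "sex",
    "affected",
    "tp53_status",
    "onset_age_months",
    "surv_time",
    "surv_event",
]


@dataclass
class SampleRecord:
    """One individual: pedigree links, cancer status and survival."""

    sample_id: str
    family_id: str
    father: str | None = None
    mother: str | None = None
    sex: str = "U"
    affected: bool = False
    tp53_status: str = "wildtype"  # "variant" | "wildtype"
    onset_age_months: float | None = None
    surv_time: float | None = None
    surv_event: int | None = None


@dataclass
class Family:
    """A sequenced family: member IDs partitioned by cancer status."""

    family_id: str
    members: list[str] = field(default_factory=list)
    affected: set[str] = field(default_factory=set)
    unaffected: set[str] = field(default_factory=set)

    @property
    def is_singleton(self) -> bool:
        return len(self.members) == 1

    def __post_init__(self):
        overlap = self.affected & self.unaffected
        if overlap:
            raise ValueError(f"samples both affected and unaffected: {sorted(overlap)}")


def families_from_samples(samples: pd.DataFrame) -> list[Family]:
    """Assemble Family objects from a sample sheet.

    Raises ``ValueError`` on duplicate sample IDs or parent references to
    unknown samples (unknown parents are allowed only as NA/"0").
    """
    if samples["sample_id"].duplicated().any():
        dup = samples.loc[samples["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample ID: {dup}")
    known = set(samples["sample_id"])
    for col in ("father", "mother"):
        for i, val in samples[col].items():
            if pd.isna(val) or val in ("0", "", None):
                continue
            if val not in known:
                raise ValueError(
                    f"row {i}: unknown {col} ID {val!r} for sample "
                    f"{samples.at[i, 'sample_id']!r}"
                )
    fams = []
    for fid, grp in samples.groupby("family_id", sort=True):
        aff = set(grp.loc[grp["affected"].astype(bool), "sample_id"])
        fams.append(
            Family(
                family_id=str(fid),
                members=list(grp["sample_id"]),
                affected=aff,
                unaffected=set(grp["sample_id"]) - aff,
            )
        )
    return fams
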