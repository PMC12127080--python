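"""Panel data model and policy schedule.

A *panel* is a long-format :class:`pandas.DataFrame` with one record per
individual per survey wave.  Required columns:

========================  =======  =======================================
column                    type     meaning
========================  =======  =======================================
``individual_id``         str      unique person identifier
``region_id``             str      region of permanent residence
``wave``                  int      calendar year of the survey wave
outcome column(s)         int      event outcomes coded 0 / 1000
                                   (linear probability per 1,000 persons)
covariate columns         numeric  named control variables
``weight`` (optional)     float    positive observation weight
========================  =======  =======================================

The per-1,000 coding makes ordinary least-squares coefficients read
directly as "events per 1,000 persons", matching how regional
policy-evaluation studies report linear probability models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("individual_id", "region_id", "wave")


@dataclass(frozen=True)
class PolicySchedule:
    """Region -> adoption-year mapping for a staggered rollout.

    Regions absent from ``adoption`` are never treated.  ``regions`` is
    the full universe of regions (used for placebo reassignment); it
    defaults to the adopting regions only.
    """

    adoption: Mapping[str, int]
    regions: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "adoption", dict(self.adoption))
        regions = tuple(self.regions) if len(self.regions) else tuple(sorted(self.adoption))
        object.__setattr__(self, "regions", regions)
        missing = set(self.adoption) - set(regions)
        if missing:
            raise ValueError(f"adopting regions not in region universe: {sorted(missing)}")

    @property
    def treated_regions(self) -> tuple[str, ...]:
        return tuple(sorted(self.adoption))

    @property
    def never_treated_regions(self) -> tuple[str, ...]:
        return tuple(r for r in self.regions if r not in self.adoption)

    def cohorts(self) -> dict[int, list[str]]:
        """Adoption year -> sorted list of regions adopting that year."""
        out: dict[int, list[str]] = {}
        for region, year in sorted(self.adoption.items()):
            out.setdefault(int(year), []).append(region)
        return dict(sorted(out.items()))

    def cohort_sizes(self) -> dict[int, int]:
        return {year: len(rs) for year, rs in self.cohorts().items()}

    def adoption_year(self, region: str) -> int | None:
        return self.adoption.get(region)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"region_id": r, "adoption_year": self.adoption.get(r, pd.NA)}
            for r in self.regions
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PolicySchedule":
        adoption = {
            str(row.region_id): int(row.adoption_year)
            for row in frame.itertuples()
            if pd.notna(row.adoption_year)
        }
        return cls(adoption=adoption, regions=tuple(frame["region_id"].astype(str)))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PolicySchedule":
        return cls.from_frame(pd.read_csv(path))


def validate_panel(
    panel: pd.DataFrame,
    outcome_columns: Sequence[str] = ("cancer",),
) -> pd.DataFrame:
    """Check the panel contract; returns the panel unchanged.

    Raises ``ValueError`` on a missing required column, a duplicated
    (individual, wave) key, an outcome value outside {0, 1000}, or a
    non-positive weight.
    """
    for col in REQUIRED_COLUMNS:
        if col not in panel.columns:
            raise ValueError(f"panel missing required column {col!r}")
    dup = panel.duplicated(subset=["individual_id", "wave"])
    if dup.any():
        raise ValueError(
            f"{int(dup.sum())} duplicated (individual_id, wave) records"
        )
    for col in outcome_columns:
        if col not in panel.columns:
            raise ValueError(f"panel missing outcome column {col!r}")
        bad = ~panel[col].isin((0, 1000))
        if bad.any():
            raise ValueError(f"outcome {col!r} has values outside {{0, 1000}}")
    if "weight" in panel.columns and (panel["weight"] <= 0).any():
        raise ValueError("observation weights must be positive")
    return panel


def build_treatment_indicator(
    panel: pd.DataFrame,
    schedule: PolicySchedule,
    name: str = "cetp_post",
    treated_name: str = "treated",
) -> pd.DataFrame:
    """Attach the treat x post indicator and the ever-treated dummy.

    ``name`` is 1 iff the record's region is a pilot and the wave year is
    at or after its adoption year (inclusive boundary).  Regions in the
    panel but absent from the schedule are treated as never treated and
    logged.  Returns a copy.
    """
    panel = panel.copy()
    known = set(schedule.regions) | set(schedule.adoption)
    unknown = sorted(set(panel["region_id"].unique()) - known)
    if unknown:
        logger.info(
            "%d panel regions missing from schedule treated as never-treated: %s",
            len(unknown), unknown[:10],
        )
    adoption = panel["region_id"].map(schedule.adoption)
    treated = adoption.notna()
    post = treated & (panel["wave"] >= adoption.fillna(np.inf))
    panel[treated_name] = treated.astype(int)
    panel[name] = post.astype(int)
    return panel


def write_panel(panel: pd.DataFrame, path) -> None:
    """Write a panel to CSV or Parquet, chosen by file extension."""
    path = str(path)
    if path.endswith(".parquet"):
        panel.to_parquet(path, index=False)
    else:
        panel.to_csv(path, index=False)


def read_panel(path) -> pd.DataFrame:
    path = str(path)
    if path.endswith(".parquet"):
        return pd.read_parquet(path)
    return pd.read_csv(path)
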