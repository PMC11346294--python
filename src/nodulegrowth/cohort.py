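"""Longitudinal nodule records: domain types, table I/O and the inclusion filter.

The analysis unit is a :class:`NoduleSeries` — one nodule followed over
repeated CT scans, each scan contributing a segmented volume (mm³) and,
optionally, a mean attenuation (HU). Times are stored in months since the
nodule's first scan, so every series starts at t = 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .errors import (
    CohortValidationError,
    ParameterError,
    ParseError,
    SchemaError,
)

DAYS_PER_MONTH = 30.4375

REQUIRED_COLUMNS = ("nodule_id", "malignancy", "morphology", "time_months", "volume_mm3")
ALL_COLUMNS = (
    "nodule_id",
    "malignancy",
    "morphology",
    "histology",
    "stage",
    "time_months",
    "volume_mm3",
    "attenuation_hu",
)


class Malignancy(str, Enum):
    BENIGN = "benign"
    MALIGNANT = "malignant"


class Morphology(str, Enum):
    SOLID = "solid"
    PART_SOLID = "part_solid"
    NON_SOLID = "non_solid"
    UNKNOWN = "unknown"


class ExclusionReason(str, Enum):
    TOO_FEW_SCANS = "too_few_scans"
    NON_INCREASING = "non_increasing"
    NON_POSITIVE_VOLUME = "non_positive_volume"


@dataclass(frozen=True)
class ScanObservation:
    """One CT scan of one nodule.

    Parameters
    ----------
    time_months
        Months since the nodule's baseline scan (t0 = 0).
    volume_mm3
        Segmented nodule volume in mm³; must be positive.
    attenuation_hu
        Mean attenuation in Hounsfield Units; typically negative for lung
        nodules. ``None`` marks a scan without attenuation data.
    """

    time_months: float
    volume_mm3: float
    attenuation_hu: float | None = None

    def __post_init__(self):
        if not math.isfinite(self.time_months) or self.time_months < 0:
            raise CohortValidationError(
                f"time_months must be finite and >= 0, got {self.time_months}"
            )
        if not math.isfinite(self.volume_mm3) or self.volume_mm3 <= 0:
            raise CohortValidationError(
                f"volume_mm3 must be finite and > 0, got {self.volume_mm3}"
            )
        if self.attenuation_hu is not None and not math.isfinite(self.attenuation_hu):
            object.__setattr__(self, "attenuation_hu", None)


@dataclass(frozen=True)
class NoduleSeries:
    """One nodule's longitudinal record plus its labels."""

    nodule_id: str
    malignancy: Malignancy
    observations: tuple[ScanObservation, ...]
    morphology: Morphology = Morphology.UNKNOWN
    histology: str | None = None
    stage: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "malignancy", Malignancy(self.malignancy))
        object.__setattr__(self, "morphology", Morphology(self.morphology))
        obs = tuple(self.observations)
        object.__setattr__(self, "observations", obs)
        if not obs:
            raise CohortValidationError(f"{self.nodule_id}: series has no observations")
        times = [o.time_months for o in obs]
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            raise CohortValidationError(
                f"{self.nodule_id}: observation times must be strictly increasing"
            )
        if times[0] != 0.0:
            raise CohortValidationError(
                f"{self.nodule_id}: first observation must be at time 0 (got {times[0]})"
            )

    @property
    def times(self) -> np.ndarray:
        return np.array([o.time_months for o in self.observations], dtype=float)

    @property
    def volumes(self) -> np.ndarray:
        return np.array([o.volume_mm3 for o in self.observations], dtype=float)

    @property
    def attenuations(self) -> np.ndarray:
        """Attenuations with missing values as NaN."""
        return np.array(
            [math.nan if o.attenuation_hu is None else o.attenuation_hu for o in self.observations],
            dtype=float,
        )

    def __len__(self) -> int:
        return len(self.observations)

    def with_volumes(self, volumes: Iterable[float]) -> "NoduleSeries":
        """Copy of the series with volumes replaced (times/labels unchanged)."""
        volumes = list(volumes)
        if len(volumes) != len(self.observations):
            raise ParameterError("replacement volumes must match the number of observations")
        obs = tuple(
            ScanObservation(o.time_months, v, o.attenuation_hu)
            for o, v in zip(self.observations, volumes)
        )
        return NoduleSeries(
            self.nodule_id, self.malignancy, obs, self.morphology, self.histology, self.stage
        )


@dataclass(frozen=True)
class Cohort:
    """A collection of nodule series with unique ids."""

    series: tuple[NoduleSeries, ...]
    provenance: str = ""

    def __post_init__(self):
        object.__setattr__(self, "series", tuple(self.series))
        ids = [s.nodule_id for s in self.series]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate nodule_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.series)

    def __iter__(self) -> Iterator[NoduleSeries]:
        return iter(self.series)

    def get(self, nodule_id: str) -> NoduleSeries:
        for s in self.series:
            if s.nodule_id == nodule_id:
                return s
        raise KeyError(nodule_id)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(s.nodule_id for s in self.series)


@dataclass
class ExclusionLog:
    """Outcome of the inclusion filter: every input nodule is either retained
    or excluded with a reason; later-scan anomalies are flagged, not excluded."""

    retained: tuple[str, ...] = ()
    excluded: dict[str, ExclusionReason] = field(default_factory=dict)
    flags: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "retained": list(self.retained),
            "excluded": {k: v.value for k, v in self.excluded.items()},
            "flags": dict(self.flags),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _table_sep(path: str | Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("csv", "tsv"):
            raise ParameterError(f"unknown table dialect {dialect!r} (use 'csv' or 'tsv')")
        return "\t" if dialect == "tsv" else ","
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_cohort(path: str | Path, dialect: str | None = None) -> Cohort:
    """Read a long-format cohort table (one row per scan) into a :class:`Cohort`.

    Required columns: nodule_id, malignancy, morphology, time_months,
    volume_mm3. Optional: histology, stage, attenuation_hu. Times are re-based
    per nodule so the earliest scan is at 0 months.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        sep=_table_sep(path, dialect),
        dtype={"nodule_id": str},
        float_precision="round_trip",
    )
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r} in {path}")

    for col in ("time_months", "volume_mm3"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based plus header line
            raise ParseError(f"non-numeric or missing {col} at line {row} of {path}")
        df[col] = numeric
    if "attenuation_hu" in df.columns:
        df["attenuation_hu"] = pd.to_numeric(df["attenuation_hu"], errors="coerce")

    series = []
    for nodule_id, grp in df.groupby("nodule_id", sort=True):
        grp = grp.sort_values("time_months")
        times = grp["time_months"].to_numpy(dtype=float)
        if len(np.unique(times)) != len(times):
            raise CohortValidationError(f"duplicate (nodule_id, time) for nodule {nodule_id!r}")
        times = times - times[0]
        if (grp["volume_mm3"] <= 0).any():
            raise CohortValidationError(f"non-positive volume for nodule {nodule_id!r}")
        hu = (
            grp["attenuation_hu"].to_numpy(dtype=float)
            if "attenuation_hu" in grp.columns
            else np.full(len(grp), np.nan)
        )
        obs = tuple(
            ScanObservation(t, v, None if math.isnan(h) else h)
            for t, v, h in zip(times, grp["volume_mm3"], hu)
        )

        def _opt(col: str) -> str | None:
            if col not in grp.columns:
                return None
            val = grp[col].iloc[0]
            return None if pd.isna(val) or val == "" else str(val)

        series.append(
            NoduleSeries(
                nodule_id=str(nodule_id),
                malignancy=str(grp["malignancy"].iloc[0]),
                observations=obs,
                morphology=str(grp["morphology"].iloc[0]),
                histology=_opt("histology"),
                stage=_opt("stage"),
            )
        )
    return Cohort(series=tuple(series), provenance=str(path))


def cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    """Long-format DataFrame view of a cohort (one row per scan)."""
    rows = []
    for s in sorted(cohort.series, key=lambda s: s.nodule_id):
        for o in s.observations:
            rows.append(
                {
                    "nodule_id": s.nodule_id,
                    "malignancy": s.malignancy.value,
                    "morphology": s.morphology.value,
                    "histology": s.histology,
                    "stage": s.stage,
                    "time_months": o.time_months,
                    "volume_mm3": o.volume_mm3,
                    "attenuation_hu": o.attenuation_hu,
                }
            )
    return pd.DataFrame(rows, columns=list(ALL_COLUMNS))


def write_cohort(cohort: Cohort, path: str | Path, dialect: str | None = None) -> None:
    """Write a cohort as a long-format table readable by :func:`read_cohort`.

    Rows are ordered by (nodule_id, time) so output is deterministic.
    """
    path = Path(path)
    # %.17g round-trips float64 exactly, so read(write(C)) is bit-identical
    cohort_to_frame(cohort).to_csv(
        path, sep=_table_sep(path, dialect), index=False, float_format="%.17g"
    )


def inclusion_filter(
    cohort: Cohort,
    min_scans: int = 3,
    require_increase: bool = True,
    min_fold_increase: float = 1.0,
) -> tuple[Cohort, ExclusionLog]:
    """Apply the study inclusion criteria: at least ``min_scans`` follow-ups and,
    when ``require_increase``, strictly increasing volumes across the first
    ``min_scans`` scans with an overall fold-change of at least
    ``min_fold_increase``.

    Later (beyond the first ``min_scans``) non-monotone points do not exclude a
    nodule; they are flagged in the log.
    """
    if min_scans < 2:
        raise ParameterError(f"min_scans must be >= 2, got {min_scans}")
    retained, excluded, flags = [], {}, {}
    for s in cohort.series:
        if len(s) < min_scans:
            excluded[s.nodule_id] = ExclusionReason.TOO_FEW_SCANS
            continue
        v = s.volumes
        head = v[:min_scans]
        if require_increase:
            if np.any(np.diff(head) <= 0) or head[-1] / head[0] < min_fold_increase:
                excluded[s.nodule_id] = ExclusionReason.NON_INCREASING
                continue
            if np.any(np.diff(v[min_scans - 1 :]) <= 0):
                flags[s.nodule_id] = "non_monotone_after_first_%d_scans" % min_scans
        retained.append(s)
    log = ExclusionLog(
        retained=tuple(s.nodule_id for s in retained), excluded=excluded, flags=flags
    )
    return Cohort(series=tuple(retained), provenance=cohort.provenance), log


def days_to_months(days: float) -> float:
    return days / DAYS_PER_MONTH


def months_to_days(months: float) -> float:
    return months * DAYS_PER_MONTH
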