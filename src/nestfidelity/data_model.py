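"""Domain records and deterministic preprocessing.

Converts raw nest-encounter and nest-visit tables into the two analysis
units used by the models:

* :class:`EncounterPair` — one individual observed nesting in two
  consecutive years, with the Euclidean dispersal distance between the two
  nest locations and the fate of the previous year's nest (possibly
  unknown).
* :class:`ExposureInterval` — one span between two checks of a monitored
  nest, with its length in days and a binary survived/failed outcome.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Fate",
    "VisitStatus",
    "NestEncounter",
    "EncounterPair",
    "ExposureInterval",
    "YearCovariates",
    "PreprocessSummary",
    "euclidean_distance",
    "spring_index",
    "pair_consecutive",
    "build_exposure_intervals",
    "floor_distances",
    "read_encounters_csv",
    "read_visits_csv",
    "read_years_csv",
    "pairs_to_frame",
    "intervals_to_frame",
    "write_preprocess_summary",
    "MAX_NEST_AGE",
    "DEFAULT_DISTANCE_FLOOR_M",
]

#: Average exposure period of a nest in days (laying + incubation); nest
#: survival is daily survival raised to this power, and the missing-fate
#: submodel integrates daily survival from the last check through this age.
MAX_NEST_AGE = 28

#: Floor applied to dispersal distances before the log transform, in meters.
#: Below GPS accuracy, so observed 0 m movements stay in the likelihood
#: without producing log(0).
DEFAULT_DISTANCE_FLOOR_M = 1.0


class Fate(str, Enum):
    """Fate of a nesting attempt."""

    SUCCESS = "success"
    FAIL = "fail"
    UNKNOWN = "unknown"


class VisitStatus(str, Enum):
    """Status recorded at a nest visit."""

    ALIVE = "alive"
    FAILED = "failed"
    HATCHED = "hatched"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class NestEncounter:
    """One individual observed on a nest in one year.

    ``last_check_age`` is the nest age in days at the final check of the
    attempt; it drives the missing-fate submodel when the fate is unknown.
    """

    individual_id: str
    year: int
    easting: float
    northing: float
    fate: Fate = Fate.UNKNOWN
    init_day: int | None = None
    last_check_age: int | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.easting) and math.isfinite(self.northing)):
            raise ValueError(
                f"non-finite UTM coordinates for {self.individual_id}/{self.year}"
            )
        if self.easting < 0 or self.northing < 0:
            raise ValueError("UTM coordinates must be non-negative meters")
        if self.last_check_age is not None and self.last_check_age > MAX_NEST_AGE:
            raise ValueError(f"last_check_age > {MAX_NEST_AGE}")


@dataclass(frozen=True)
class EncounterPair:
    """One consecutive-year re-encounter of a marked individual.

    Fields follow the fidelity model's covariates: dispersal distance in
    meters, previous-year nest fate (0 success, 1 fail, None missing),
    flood indicator for the previous year, and the spring timing index of
    the current year. ``prev_last_check_age`` is carried for imputation of
    a missing previous fate.
    """

    individual_id: str
    year_j: int
    dispersal_m: float
    prev_fate: int | None
    flood_prev: int
    spring_index: float
    prev_last_check_age: int | None = None

    def __post_init__(self) -> None:
        if self.dispersal_m < 0 or not math.isfinite(self.dispersal_m):
            raise ValueError("dispersal_m must be finite and >= 0")
        if self.flood_prev not in (0, 1):
            raise ValueError("flood_prev must be 0 or 1")
        if self.prev_fate not in (0, 1, None):
            raise ValueError("prev_fate must be 0, 1 or None")


@dataclass(frozen=True)
class ExposureInterval:
    """One nest-check interval: the unit of the survival likelihood."""

    nest_id: str
    individual_id: str
    year: int
    length_days: int
    outcome: int
    age_start: int

    def __post_init__(self) -> None:
        if self.length_days < 1:
            raise ValueError("length_days must be >= 1")
        if self.outcome not in (0, 1):
            raise ValueError("outcome must be 0 or 1")


@dataclass(frozen=True)
class YearCovariates:
    """Year-level covariates: flood indicator and spring timing index."""

    year: int
    flood: int
    mean_init_day: float
    spring_index: float = 0.0


@dataclass
class PreprocessSummary:
    """Counts of records retained and dropped during preprocessing."""

    n_encounters: int = 0
    n_pairs: int = 0
    n_dropped_gap: int = 0
    n_missing_prev_fate: int = 0
    n_nests: int = 0
    n_intervals: int = 0
    n_censored_nests: int = 0
    notes: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {k: v for k, v in self.__dict__.items()}, indent=2, sort_keys=True
        )


# ---------------------------------------------------------------------------
# Deterministic preprocessing operations
# ---------------------------------------------------------------------------


def euclidean_distance(
    p1: tuple[float, float], p2: tuple[float, float]
) -> float:
    """Euclidean distance in meters between two same-zone UTM points."""
    e1, n1 = p1
    e2, n2 = p2
    if not all(math.isfinite(v) for v in (e1, n1, e2, n2)):
        raise ValueError("non-finite coordinate")
    return math.hypot(e2 - e1, n2 - n1)


def spring_index(mean_init_by_year: Mapping[int, float]) -> dict[int, float]:
    """Early–late spring index: each year's mean nest initiation date minus
    the long-term mean over all years. Positive values are late springs;
    the indices sum to zero by construction.
    """
    if not mean_init_by_year:
        raise ValueError("need at least one year with a mean initiation date")
    grand = float(np.mean(list(mean_init_by_year.values())))
    return {yr: float(v) - grand for yr, v in mean_init_by_year.items()}


def pair_consecutive(
    encounters: Sequence[NestEncounter],
    year_covariates: Mapping[int, YearCovariates] | None = None,
    summary: PreprocessSummary | None = None,
) -> list[EncounterPair]:
    """Form one :class:`EncounterPair` per individual per pair of
    consecutive years in which it was encountered with valid coordinates.

    Pairing keys on calendar-year arithmetic (year j requires year j−1
    observed), never on encounter order; gaps of two or more years break a
    run and the skipped transitions are counted in ``summary``.
    Covariates (flood of year j−1, spring index of year j) are attached
    from ``year_covariates`` when given, else zero.
    """
    by_ind: dict[str, dict[int, NestEncounter]] = {}
    for enc in encounters:
        by_ind.setdefault(enc.individual_id, {})[enc.year] = enc

    pairs: list[EncounterPair] = []
    n_gap = 0
    for ind, by_year in by_ind.items():
        for year in sorted(by_year):
            prev = by_year.get(year - 1)
            if prev is None:
                if (year - 2) in by_year or any(y < year for y in by_year):
                    n_gap += 1
                continue
            cur = by_year[year]
            dist = euclidean_distance(
                (prev.easting, prev.northing), (cur.easting, cur.northing)
            )
            if prev.fate is Fate.UNKNOWN:
                prev_fate: int | None = None
            else:
                prev_fate = 1 if prev.fate is Fate.FAIL else 0
            if year_covariates is not None:
                ycov = year_covariates.get(year)
                pcov = year_covariates.get(year - 1)
                flood_prev = pcov.flood if pcov is not None else 0
                s_j = ycov.spring_index if ycov is not None else 0.0
            else:
                flood_prev, s_j = 0, 0.0
            pairs.append(
                EncounterPair(
                    individual_id=ind,
                    year_j=year,
                    dispersal_m=dist,
                    prev_fate=prev_fate,
                    flood_prev=flood_prev,
                    spring_index=s_j,
                    prev_last_check_age=prev.last_check_age,
                )
            )
    if summary is not None:
        summary.n_encounters += len(encounters)
        summary.n_pairs += len(pairs)
        summary.n_dropped_gap += n_gap
        summary.n_missing_prev_fate += sum(p.prev_fate is None for p in pairs)
    return pairs


def build_exposure_intervals(
    visits: Iterable[tuple],
    censor_unknown_fate_nests: bool = True,
    summary: PreprocessSummary | None = None,
) -> tuple[list[ExposureInterval], set[str]]:
    """Turn nest visit histories into exposure intervals.

    ``visits`` holds tuples ``(nest_id, individual_id, year, visit_age,
    status)`` sorted by age within nest. Each adjacent pair of visits
    yields one interval; the outcome is 1 if the nest was alive or hatched
    at the interval's end and 0 if it had failed. Visits after a terminal
    event emit nothing. Nests whose final status never resolves to hatched
    or failed are censored: with ``censor_unknown_fate_nests`` (default,
    matching the convention of dropping whole unknown-fate nests) none of
    their intervals are kept, otherwise their alive→alive intervals are
    retained and the nest is flagged.

    Returns ``(intervals, censored_nest_ids)``.
    """
    by_nest: dict[str, list[tuple]] = {}
    for v in visits:
        by_nest.setdefault(v[0], []).append(v)

    intervals: list[ExposureInterval] = []
    censored: set[str] = set()
    for nest_id, vs in by_nest.items():
        ages = [v[3] for v in vs]
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError(f"non-monotone visit ages for nest {nest_id}")
        nest_iv: list[ExposureInterval] = []
        terminal = False
        resolved = False
        for (nid, ind, year, a0, s0), (_, _, _, a1, s1) in zip(vs, vs[1:]):
            if terminal:
                break
            s1 = VisitStatus(s1)
            if s1 is VisitStatus.UNKNOWN:
                break
            outcome = 0 if s1 is VisitStatus.FAILED else 1
            nest_iv.append(
                ExposureInterval(
                    nest_id=nid,
                    individual_id=ind,
                    year=year,
                    length_days=int(a1 - a0),
                    outcome=outcome,
                    age_start=int(a0),
                )
            )
            if s1 in (VisitStatus.FAILED, VisitStatus.HATCHED):
                terminal = True
                resolved = True
        if not resolved:
            censored.add(nest_id)
            if censor_unknown_fate_nests:
                nest_iv = []
        intervals.extend(nest_iv)

    if summary is not None:
        summary.n_nests += len(by_nest)
        summary.n_intervals += len(intervals)
        summary.n_censored_nests += len(censored)
    return intervals, censored


def floor_distances(
    distances: np.ndarray, floor_m: float = DEFAULT_DISTANCE_FLOOR_M
) -> np.ndarray:
    """Floor dispersal distances at ``floor_m`` meters so the log transform
    stays finite for observed 0 m movements."""
    return np.maximum(np.asarray(distances, dtype=float), floor_m)


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------


def read_encounters_csv(path: str | Path) -> list[NestEncounter]:
    df = pd.read_csv(path)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            NestEncounter(
                individual_id=str(row.individual_id),
                year=int(row.year),
                easting=float(row.easting),
                northing=float(row.northing),
                fate=Fate(row.fate),
                init_day=None if pd.isna(row.init_day) else int(row.init_day),
                last_check_age=(
                    None
                    if pd.isna(row.last_check_age)
                    else int(row.last_check_age)
                ),
            )
        )
    return out


def read_visits_csv(path: str | Path) -> list[tuple]:
    df = pd.read_csv(path)
    return [
        (
            str(r.nest_id),
            str(r.individual_id),
            int(r.year),
            int(r.visit_age),
            str(r.status),
        )
        for r in df.itertuples(index=False)
    ]


def read_years_csv(path: str | Path) -> dict[int, YearCovariates]:
    df = pd.read_csv(path)
    s_idx = spring_index(
        {int(r.year): float(r.mean_init_day) for r in df.itertuples(index=False)}
    )
    return {
        int(r.year): YearCovariates(
            year=int(r.year),
            flood=int(r.flood),
            mean_init_day=float(r.mean_init_day),
            spring_index=s_idx[int(r.year)],
        )
        for r in df.itertuples(index=False)
    }


def pairs_to_frame(pairs: Sequence[EncounterPair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "individual_id": [p.individual_id for p in pairs],
            "year_j": [p.year_j for p in pairs],
            "dispersal_m": [p.dispersal_m for p in pairs],
            "prev_fate": [
                np.nan if p.prev_fate is None else p.prev_fate for p in pairs
            ],
            "flood_prev": [p.flood_prev for p in pairs],
            "spring_index": [p.spring_index for p in pairs],
            "prev_last_check_age": [
                np.nan if p.prev_last_check_age is None else p.prev_last_check_age
                for p in pairs
            ],
        }
    )


def pairs_from_frame(df: pd.DataFrame) -> list[EncounterPair]:
    out = []
    for r in df.itertuples(index=False):
        out.append(
            EncounterPair(
                individual_id=str(r.individual_id),
                year_j=int(r.year_j),
                dispersal_m=float(r.dispersal_m),
                prev_fate=None if pd.isna(r.prev_fate) else int(r.prev_fate),
                flood_prev=int(r.flood_prev),
                spring_index=float(r.spring_index),
                prev_last_check_age=(
                    None
                    if pd.isna(r.prev_last_check_age)
                    else int(r.prev_last_check_age)
                ),
            )
        )
    return out


def intervals_to_frame(intervals: Sequence[ExposureInterval]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "nest_id": [iv.nest_id for iv in intervals],
            "individual_id": [iv.individual_id for iv in intervals],
            "year": [iv.year for iv in intervals],
            "length_days": [iv.length_days for iv in intervals],
            "outcome": [iv.outcome for iv in intervals],
            "age_start": [iv.age_start for iv in intervals],
        }
    )


def intervals_from_frame(df: pd.DataFrame) -> list[ExposureInterval]:
    return [
        ExposureInterval(
            nest_id=str(r.nest_id),
            individual_id=str(r.individual_id),
            year=int(r.year),
            length_days=int(r.length_days),
            outcome=int(r.outcome),
            age_start=int(r.age_start),
        )
        for r in df.itertuples(index=False)
    ]


def write_preprocess_summary(summary: PreprocessSummary, path: str | Path) -> None:
    Path(path).write_text(summary.to_json())
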