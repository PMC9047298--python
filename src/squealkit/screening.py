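"""Squeal inclusion rules: duration, background-noise rating, artifacts.

A candidate squeal enters the analysis only if
  * it lasts at least 0.3 s,
  * the mean of its per-rater background-noise scores (each 0, 1 or 2;
    0 = low noise) is at most 1.00 — a mean of exactly 1.00 is included,
  * no audible artifact (e.g. slight overdrive) was flagged.

Rating means are compared as exact rationals: three raters produce
means on a 1/3 grid, and a float comparison at the 1.00 boundary would
be fragile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["SquealRecord", "screen", "SquealScreener"]


@dataclass(frozen=True)
class SquealRecord:
    """Metadata for one candidate squeal."""

    clip_id: str
    pig_id: str
    phase: str  # "pre" or "post" surgery
    duration: float  # seconds
    ratings: tuple  # per-rater noise scores, each in {0, 1, 2}
    artifact: bool = False

    def __post_init__(self) -> None:
        if self.phase not in ("pre", "post"):
            raise ValueError(f"phase must be 'pre' or 'post', got {self.phase!r}")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        ratings = tuple(int(r) for r in self.ratings)
        if not ratings or any(r not in (0, 1, 2) for r in ratings):
            raise ValueError("ratings must be a nonempty tuple of scores in {0,1,2}")
        object.__setattr__(self, "ratings", ratings)

    @property
    def mean_rating(self) -> Fraction:
        return Fraction(sum(self.ratings), len(self.ratings))


def screen(
    records: list[SquealRecord],
    min_dur_s: float = 0.3,
    max_mean_rating: float = 1.0,
) -> tuple[list[SquealRecord], list[tuple[SquealRecord, str]]]:
    """Partition records into (included, excluded-with-reason).

    Rules are evaluated in order duration -> rating -> artifact, and the
    first failing rule labels the exclusion.  The two output lists are a
    disjoint cover of the input, in input order.

    Raises
    ------
    ValueError
        If the record list is empty.
    """
    if not records:
        raise ValueError("no records to screen")
    max_rating = Fraction(max_mean_rating).limit_denominator(10**6)
    included: list[SquealRecord] = []
    excluded: list[tuple[SquealRecord, str]] = []
    for rec in records:
        if rec.duration < min_dur_s:
            excluded.append((rec, "duration"))
        elif rec.mean_rating > max_rating:
            excluded.append((rec, "noise"))
        elif rec.artifact:
            excluded.append((rec, "artifact"))
        else:
            included.append(rec)
    return included, excluded


def records_to_frame(records: list[SquealRecord]) -> pd.DataFrame:
    """Tabulate records as a DataFrame (ratings joined as 'r1;r2;r3')."""
    return pd.DataFrame(
        {
            "clip_id": [r.clip_id for r in records],
            "pig_id": [r.pig_id for r in records],
            "phase": [r.phase for r in records],
            "duration": [r.duration for r in records],
            "ratings": [";".join(map(str, r.ratings)) for r in records],
            "artifact": [r.artifact for r in records],
        }
    )


def frame_to_records(frame: pd.DataFrame) -> list[SquealRecord]:
    """Inverse of :func:`records_to_frame`."""
    return [
        SquealRecord(
            clip_id=str(row.clip_id),
            pig_id=str(row.pig_id),
            phase=str(row.phase),
            duration=float(row.duration),
            ratings=tuple(int(x) for x in str(row.ratings).split(";")),
            artifact=bool(row.artifact),
        )
        for row in frame.itertuples(index=False)
    ]


class SquealScreener(TransformerMixin, BaseEstimator):
    """Transformer applying the squeal inclusion rules to a record list.

    ``transform`` returns the included records; the exclusions of the
    most recent call are kept in ``exclusions_`` as (record, reason)
    pairs.

    Parameters
    ----------
    min_dur_s : float
        Minimum squeal duration in seconds (default 0.3).
    max_mean_rating : float
        Maximum admissible mean noise rating (default 1.00, inclusive).
    """

    def __init__(self, min_dur_s: float = 0.3, max_mean_rating: float = 1.0):
        self.min_dur_s = min_dur_s
        self.max_mean_rating = max_mean_rating

    def fit(self, X=None, y=None):
        return self

    def transform(self, X: list[SquealRecord]) -> list[SquealRecord]:
        included, excluded = screen(
            list(X), min_dur_s=self.min_dur_s, max_mean_rating=self.max_mean_rating
        )
        self.exclusions_ = excluded
        return included
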