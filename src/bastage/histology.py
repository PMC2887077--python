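"""Ordinal histology scoring and threshold-based group assignment.

Liver biopsies taken at diagnosis of biliary atresia are graded by a
pathologist for portal inflammation (0-3, H&E) and staged for fibrosis
(0-3, trichrome).  The *differential score* of a biopsy is

    differential = inflammation_grade - fibrosis_stage

and a biopsy is called inflammation-predominant when the differential
reaches a positive threshold (default 2), fibrosis-predominant when it
reaches the negative threshold, and "mixed" otherwise.  The predominant
biopsies form the labelled seed set from which the molecular signature
is derived; grading itself is pathologist work and an input contract.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import pandas as pd

INFLAMMATION = "inflammation"
FIBROSIS = "fibrosis"
MIXED = "mixed"

VALID_SCORES = (0, 1, 2, 3)


class HistologyError(ValueError):
    """Invalid histology score or group-assignment input."""


@dataclass(frozen=True)
class HistologyScore:
    """Pathologist scores for one biopsy: both values must be in 0..3."""

    subject_id: str
    inflammation_grade: int
    fibrosis_stage: int

    def __post_init__(self) -> None:
        for field in ("inflammation_grade", "fibrosis_stage"):
            value = getattr(self, field)
            if not isinstance(value, (int,)) or isinstance(value, bool):
                raise HistologyError(
                    f"{field} must be an integer, got {value!r} "
                    f"for subject {self.subject_id!r}"
                )
            if value not in VALID_SCORES:
                raise HistologyError(
                    f"{field} must be in 0..3, got {value} "
                    f"for subject {self.subject_id!r}"
                )


@dataclass(frozen=True)
class HistologyGroup:
    """Group assignment for one biopsy at a given differential threshold."""

    subject_id: str
    inflammation_grade: int
    fibrosis_stage: int
    differential: int
    label: str
    threshold_used: int


class GroupCounts(NamedTuple):
    n_inflammation: int
    n_fibrosis: int
    n_mixed: int


def differential_score(score: HistologyScore) -> int:
    """Signed differential: inflammation grade minus fibrosis stage.

    Positive values indicate inflammation-predominant histology,
    negative values fibrosis-predominant.
    """
    return score.inflammation_grade - score.fibrosis_stage


def assign_histology_groups(
    scores: Iterable[HistologyScore], threshold: int = 2
) -> tuple[list[HistologyGroup], GroupCounts]:
    """Label each biopsy inflammation / fibrosis / mixed by differential score.

    Parameters
    ----------
    scores
        Histology scores, one per subject; subject IDs must be unique.
    threshold
        Positive differential threshold in {1, 2, 3}.  A subject is
        inflammation-predominant iff differential >= threshold and
        fibrosis-predominant iff differential <= -threshold.

    Returns
    -------
    (groups, counts)
        Per-subject :class:`HistologyGroup` records in input order and
        the cohort tally (n_inflammation, n_fibrosis, n_mixed).
    """
    if threshold not in (1, 2, 3):
        raise HistologyError(f"threshold must be in {{1, 2, 3}}, got {threshold!r}")
    scores = list(scores)
    if not scores:
        raise HistologyError("empty score list")
    ids = [s.subject_id for s in scores]
    dupes = [sid for sid, k in Counter(ids).items() if k > 1]
    if dupes:
        raise HistologyError(f"duplicate subject IDs: {sorted(dupes)}")

    groups: list[HistologyGroup] = []
    tally = Counter()
    for score in scores:
        diff = differential_score(score)
        if diff >= threshold:
            label = INFLAMMATION
        elif diff <= -threshold:
            label = FIBROSIS
        else:
            label = MIXED
        tally[label] += 1
        groups.append(
            HistologyGroup(
                subject_id=score.subject_id,
                inflammation_grade=score.inflammation_grade,
                fibrosis_stage=score.fibrosis_stage,
                differential=diff,
                label=label,
                threshold_used=threshold,
            )
        )
    counts = GroupCounts(tally[INFLAMMATION], tally[FIBROSIS], tally[MIXED])
    return groups, counts


def scores_from_table(samples: pd.DataFrame) -> list[HistologyScore]:
    """Build :class:`HistologyScore` records from a sample table.

    Expects columns ``sample_id``, ``inflammation_grade``, ``fibrosis_stage``.
    """
    required = {"sample_id", "inflammation_grade", "fibrosis_stage"}
    missing = required - set(samples.columns)
    if missing:
        raise HistologyError(f"sample table missing columns: {sorted(missing)}")
    return [
        HistologyScore(
            subject_id=str(row.sample_id),
            inflammation_grade=int(row.inflammation_grade),
            fibrosis_stage=int(row.fibrosis_stage),
        )
        for row in samples.itertuples(index=False)
    ]


def groups_to_frame(groups: Iterable[HistologyGroup]) -> pd.DataFrame:
    """Tabulate group assignments for the group-assignment CSV."""
    return pd.DataFrame(
        [
            {
                "subject_id": g.subject_id,
                "inflammation_grade": g.inflammation_grade,
                "fibrosis_stage": g.fibrosis_stage,
                "differential": g.differential,
                "label": g.label,
                "threshold_used": g.threshold_used,
            }
            for g in groups
        ]
    )
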