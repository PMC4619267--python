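"""Five-state event histories from raw benefit-spell records.

The state space is

====  ==========================  =========================================
code  label                       definition
====  ==========================  =========================================
1     work                        no registered benefit
2     partial_sick_leave          sick-leave benefit graded 20-99 %
3     sick_leave                  full (100 %) sick-leave benefit
4     work_assessment_allowance   intermediate benefit before disability
5     disability_pension          absorbing
====  ==========================  =========================================

Raw registry spells are messy: they may overlap in time, contain
non-genuine one-day spells, and show no-benefit gaps right before a
disability pension is granted.  :func:`clean_spells` and
:func:`build_history` apply the cleaning rules (newest registration wins,
one-day spells discarded, pre-disability gaps attributed to the most
recent benefit, work = absence of benefits, disability absorbing) and
produce tiled, gap-free histories on ``[0, C)`` in integer days.

All intervals are half-open ``[start, stop)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

WORK = 1
PARTIAL_SICK_LEAVE = 2
SICK_LEAVE = 3
WORK_ASSESSMENT = 4
DISABILITY = 5

STATES = (1, 2, 3, 4, 5)
TRANSIENT_STATES = (1, 2, 3, 4)
N_STATES = 5

STATE_LABELS = {
    WORK: "work",
    PARTIAL_SICK_LEAVE: "partial_sick_leave",
    SICK_LEAVE: "sick_leave",
    WORK_ASSESSMENT: "work_assessment_allowance",
    DISABILITY: "disability_pension",
}

BENEFIT_TO_STATE = {
    "partial_sick_leave": PARTIAL_SICK_LEAVE,
    "sick_leave": SICK_LEAVE,
    "work_assessment_allowance": WORK_ASSESSMENT,
    "disability_pension": DISABILITY,
}

#: columns of the raw benefit-spell CSV schema
RECORD_COLUMNS = (
    "person_id",
    "benefit_type",
    "grading",
    "start",
    "stop",
    "registration_order",
    "diagnosis_code",
)

#: columns of the long-format transition-row schema (covariates appended)
TRANSITION_ROW_COLUMNS = (
    "person_id",
    "from_state",
    "to_state",
    "entry",
    "exit",
    "status",
    "weight",
)


def reachable_states(h: int) -> tuple[int, ...]:
    """Destination states considered reachable from transient state ``h``."""
    if h == DISABILITY:
        return ()
    return tuple(j for j in STATES if j != h)


class SchemaError(ValueError):
    """Raised when an input table violates the documented schema."""


class TieBreakError(ValueError):
    """Overlapping spells of one person share a registration order."""


class ExclusionError(ValueError):
    """Person must be excluded from the analysis (e.g. disabled at baseline)."""


@dataclass(frozen=True)
class BenefitRecord:
    """One raw registry spell, before cleaning.

    ``grading`` is the percent of full benefit; partial sick leave is graded
    20-99 %, all other benefits carry 100.
    """

    person_id: str
    benefit_type: str
    start: int
    stop: int
    registration_order: int
    grading: int = 100
    diagnosis_code: str | None = None

    def __post_init__(self) -> None:
        if self.benefit_type not in BENEFIT_TO_STATE:
            raise SchemaError(f"unknown benefit_type {self.benefit_type!r}")
        if self.stop <= self.start:
            raise SchemaError(
                f"spell for {self.person_id!r} has stop <= start "
                f"({self.start}, {self.stop})"
            )
        if not 20 <= self.grading <= 100:
            raise SchemaError(f"grading {self.grading} outside [20, 100]")
        partial = self.benefit_type == "partial_sick_leave"
        if partial != (self.grading < 100):
            raise SchemaError(
                "partial_sick_leave must be graded 20-99 %, other benefits 100 %"
            )

    @property
    def state(self) -> int:
        return BENEFIT_TO_STATE[self.benefit_type]

    @property
    def duration(self) -> int:
        return self.stop - self.start


class Episode(NamedTuple):
    """One sojourn in a state; half-open day interval [entry, exit)."""

    state: int
    entry: int
    exit: int


@dataclass
class CleaningReport:
    """Counters a reviewer of the cleaning step would ask about."""

    n_input: int = 0
    n_clipped: int = 0
    n_discarded_one_day: int = 0
    n_overlaps_resolved: int = 0
    n_fragments_discarded: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


@dataclass
class EventHistory:
    """A person's cleaned trajectory through the five states on ``[0, C)``.

    Episodes tile ``[0, censor_time)`` without gaps or overlaps, consecutive
    episodes are in different states, and any disability episode is last and
    extends to the censoring time.
    """

    person_id: str
    censor_time: int
    episodes: list[Episode]
    covariates: dict[str, float] | None = None
    baseline_day: int = 0

    def __post_init__(self) -> None:
        self.validate()

    @property
    def initial_state(self) -> int:
        return self.episodes[0].state

    def validate(self) -> None:
        eps = self.episodes
        if not eps:
            raise ValueError("history must contain at least one episode")
        if eps[0].entry != 0 or eps[-1].exit != self.censor_time:
            raise ValueError("episodes must span [0, C)")
        for a, b in zip(eps, eps[1:]):
            if a.exit != b.entry:
                raise ValueError("episodes must tile [0, C) without gaps")
            if a.state == b.state:
                raise ValueError("consecutive episodes must change state")
        for ep in eps:
            if ep.exit <= ep.entry:
                raise ValueError("episodes must have positive length")
        for ep in eps[:-1]:
            if ep.state == DISABILITY:
                raise ValueError("disability must be the final episode")
        if eps[0].state == DISABILITY:
            raise ExclusionError(
                f"person {self.person_id!r} is on disability pension at baseline"
            )

    def state_at(self, t: float) -> int:
        """State occupied at time ``t`` (right-continuous step function)."""
        if not 0 <= t < self.censor_time:
            raise ValueError(f"t={t} outside [0, {self.censor_time})")
        for ep in self.episodes:
            if ep.entry <= t < ep.exit:
                return ep.state
        raise AssertionError("unreachable: episodes tile [0, C)")

    def transitions(self) -> list[tuple[int, int, int]]:
        """Realized ``(from, to, time)`` transitions."""
        return [
            (a.state, b.state, b.entry)
            for a, b in zip(self.episodes, self.episodes[1:])
        ]


# ---------------------------------------------------------------------------
# spell cleaning
# ---------------------------------------------------------------------------


def _subtract_interval(
    start: int, stop: int, claimed: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Fragments of [start, stop) not covered by the disjoint ``claimed`` set."""
    fragments = []
    cur = start
    for c0, c1 in sorted(claimed):
        if c1 <= cur or c0 >= stop:
            continue
        if c0 > cur:
            fragments.append((cur, min(c0, stop)))
        cur = max(cur, c1)
        if cur >= stop:
            break
    if cur < stop:
        fragments.append((cur, stop))
    return fragments


def clean_spells(
    records: Iterable[BenefitRecord],
    baseline_day: int,
    end_day: int,
    tie_break=None,
    report: CleaningReport | None = None,
) -> list[BenefitRecord]:
    """Clean raw benefit spells.

    Rules, applied per person:

    1. clip spells to the study window ``[baseline_day, end_day)``;
    2. discard spells of duration <= 1 day;
    3. where spells overlap, the newest registration (highest
       ``registration_order``) claims the overlapped days; the older spell
       survives only as its non-overlapped fragments;
    4. re-apply the one-day rule to fragments (so cleaning is idempotent).

    ``tie_break`` may be a callable ``record -> sortable`` used to order
    overlapping spells with identical registration order; without it such
    ties raise :class:`TieBreakError`.
    """
    if baseline_day >= end_day:
        raise ValueError("baseline_day must be < end_day")
    rep = report if report is not None else CleaningReport()

    by_person: dict[str, list[BenefitRecord]] = {}
    for rec in records:
        rep.n_input += 1
        by_person.setdefault(rec.person_id, []).append(rec)

    out: list[BenefitRecord] = []
    for pid in by_person:
        clipped: list[BenefitRecord] = []
        for rec in by_person[pid]:
            start = max(rec.start, baseline_day)
            stop = min(rec.stop, end_day)
            if (start, stop) != (rec.start, rec.stop):
                rep.n_clipped += 1
            if stop - start <= 0:
                continue
            if stop - start <= 1:
                rep.n_discarded_one_day += 1
                continue
            clipped.append(replace(rec, start=start, stop=stop))

        # detect unresolvable registration-order ties among overlapping spells
        if tie_break is None:
            for i, a in enumerate(clipped):
                for b in clipped[i + 1 :]:
                    if (
                        a.registration_order == b.registration_order
                        and a.start < b.stop
                        and b.start < a.stop
                    ):
                        raise TieBreakError(
                            f"person {pid!r}: overlapping spells share "
                            f"registration_order {a.registration_order}"
                        )

        def _order(rec: BenefitRecord):
            key = [rec.registration_order]
            if tie_break is not None:
                key.append(tie_break(rec))
            return tuple(key)

        claimed: list[tuple[int, int]] = []
        resolved: list[BenefitRecord] = []
        for rec in sorted(clipped, key=_order, reverse=True):
            fragments = _subtract_interval(rec.start, rec.stop, claimed)
            if fragments != [(rec.start, rec.stop)]:
                rep.n_overlaps_resolved += 1
            for s, t in fragments:
                if t - s <= 1:
                    rep.n_fragments_discarded += 1
                    continue
                resolved.append(replace(rec, start=s, stop=t))
            claimed.append((rec.start, rec.stop))

        out.extend(resolved)

    out.sort(key=lambda r: (str(r.person_id), r.start, r.registration_order))
    return out


# ---------------------------------------------------------------------------
# history construction
# ---------------------------------------------------------------------------


def build_history(
    records: Sequence[BenefitRecord],
    baseline_day: int,
    end_day: int,
    covariates: Mapping[str, float] | None = None,
    person_id: str | None = None,
) -> EventHistory:
    """Assemble one person's cleaned spells into an :class:`EventHistory`.

    Days with no benefit become work (state 1), except a no-benefit gap
    immediately preceding a disability spell, which is attributed to the most
    recently received benefit.  Disability is absorbing: once entered the
    history stays in state 5 until the censoring time.

    Raises :class:`ExclusionError` if the person is on disability pension at
    baseline.
    """
    C = end_day - baseline_day
    if C <= 0:
        raise ValueError("baseline_day must be < end_day")
    recs = sorted(records, key=lambda r: r.start)
    if recs:
        pids = {r.person_id for r in recs}
        if len(pids) > 1:
            raise ValueError(f"records belong to multiple persons: {sorted(pids)}")
        pid = recs[0].person_id
    else:
        if person_id is None:
            raise ValueError("person_id required when the record list is empty")
        pid = person_id

    segments: list[Episode] = []
    for rec in recs:
        s, t = rec.start - baseline_day, rec.stop - baseline_day
        if s < 0 or t > C:
            raise ValueError(
                f"person {pid!r}: cleaned spell [{rec.start}, {rec.stop}) "
                "outside the study window"
            )
        if segments and s < segments[-1].exit:
            raise ValueError(f"person {pid!r}: records overlap after cleaning")
        segments.append(Episode(rec.state, s, t))

    # fill no-benefit gaps; pre-disability gaps go to the preceding benefit
    filled: list[Episode] = []
    cursor = 0
    last_benefit_state: int | None = None
    for seg in segments:
        if seg.entry > cursor:
            if seg.state == DISABILITY and last_benefit_state is not None:
                gap_state = last_benefit_state
            else:
                gap_state = WORK
            filled.append(Episode(gap_state, cursor, seg.entry))
        filled.append(seg)
        last_benefit_state = seg.state
        cursor = seg.exit
    if cursor < C:
        filled.append(Episode(WORK, cursor, C))

    # absorb at first disability entry
    absorbed: list[Episode] = []
    for ep in filled:
        if ep.state == DISABILITY:
            if ep.entry == 0:
                raise ExclusionError(
                    f"person {pid!r} is on disability pension at baseline"
                )
            absorbed.append(Episode(DISABILITY, ep.entry, C))
            break
        absorbed.append(ep)

    # merge adjacent same-state episodes
    merged: list[Episode] = []
    for ep in absorbed:
        if merged and merged[-1].state == ep.state:
            merged[-1] = Episode(ep.state, merged[-1].entry, ep.exit)
        else:
            merged.append(ep)

    return EventHistory(
        person_id=pid,
        censor_time=C,
        episodes=merged,
        covariates=dict(covariates) if covariates is not None else None,
        baseline_day=baseline_day,
    )


def build_cohort(
    records: Iterable[BenefitRecord],
    baseline_day: int,
    end_day: int,
    covariate_table: pd.DataFrame | None = None,
    censor_times: Mapping[str, int] | None = None,
) -> tuple[list[EventHistory], list[tuple[str, str]]]:
    """Build histories for a whole cohort of cleaned records.

    Persons appearing in ``covariate_table`` but with no spells get a pure
    work history.  Excluded persons (disability at baseline) are reported in
    the second return value as ``(person_id, reason)`` pairs, not silently
    dropped.  ``censor_times`` optionally overrides the administrative end
    of follow-up per person (days since baseline).
    """
    by_person: dict[str, list[BenefitRecord]] = {}
    for rec in records:
        by_person.setdefault(str(rec.person_id), []).append(rec)

    person_ids = list(by_person)
    if covariate_table is not None:
        for pid in covariate_table.index.astype(str):
            if pid not in by_person:
                person_ids.append(pid)

    histories: list[EventHistory] = []
    exclusions: list[tuple[str, str]] = []
    for pid in person_ids:
        cov = None
        if covariate_table is not None:
            if pid not in covariate_table.index.astype(str):
                exclusions.append((pid, "no covariate row"))
                continue
            cov = covariate_table.loc[pid].to_dict()
        end = end_day
        if censor_times is not None and pid in censor_times:
            end = baseline_day + int(censor_times[pid])
        try:
            histories.append(
                build_history(
                    [
                        replace(r, stop=min(r.stop, end))
                        for r in by_person.get(pid, [])
                        if r.start < end
                    ],
                    baseline_day,
                    end,
                    covariates=cov,
                    person_id=pid,
                )
            )
        except ExclusionError as err:
            log.warning("excluding person %s: %s", pid, err)
            exclusions.append((pid, str(err)))
    return histories, exclusions


# ---------------------------------------------------------------------------
# counting-process representation
# ---------------------------------------------------------------------------


def to_transition_rows(
    histories: Iterable[EventHistory],
    covariate_cols: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Long-format ("stacked") transition rows for per-transition hazard fits.

    Each non-absorbing episode ``(h, s, t)`` yields one row per reachable
    destination ``j`` with ``status`` 1 only on the realized destination
    (0 everywhere when the episode ends by censoring).  Default weight is 1.
    """
    rows: list[dict] = []
    for hist in histories:
        cov = hist.covariates or {}
        if covariate_cols is not None:
            missing = [c for c in covariate_cols if c not in cov]
            if missing:
                raise KeyError(
                    f"person {hist.person_id!r} lacks covariates {missing}"
                )
        eps = hist.episodes
        for i, ep in enumerate(eps):
            if ep.state == DISABILITY:
                continue
            dest = eps[i + 1].state if i + 1 < len(eps) else None
            for j in reachable_states(ep.state):
                row = {
                    "person_id": hist.person_id,
                    "from_state": ep.state,
                    "to_state": j,
                    "entry": ep.entry,
                    "exit": ep.exit,
                    "status": int(dest == j),
                    "weight": 1.0,
                }
                if covariate_cols is not None:
                    for c in covariate_cols:
                        row[c] = cov[c]
                rows.append(row)
    cols = list(TRANSITION_ROW_COLUMNS) + list(covariate_cols or ())
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows, columns=cols)


def count_transitions(histories: Iterable[EventHistory]) -> np.ndarray:
    """5x5 matrix of realized transition counts (row = from, col = to).

    Row 5 is identically zero because disability is absorbing.
    """
    counts = np.zeros((N_STATES, N_STATES), dtype=int)
    for hist in histories:
        for h, j, _t in hist.transitions():
            counts[h - 1, j - 1] += 1
    return counts


# ---------------------------------------------------------------------------
# covariate recoding and IO
# ---------------------------------------------------------------------------

#: binary questionnaire items where a missing answer is recoded to "no"
RECODE_TO_NO = ("married", "higher_education", "ia_agreement")


def recode_covariates(
    table: pd.DataFrame, to_no: Sequence[str] = RECODE_TO_NO
) -> pd.DataFrame:
    """Recode missing answers on selected binary items to the "no" category.

    A ``<col>_missing`` indicator is added for every recoded column so the
    information is not lost.  Other columns are left untouched.
    """
    out = table.copy()
    for col in to_no:
        if col not in out.columns:
            continue
        missing = out[col].isna()
        out[f"{col}_missing"] = missing.astype(int)
        out[col] = out[col].fillna(0).astype(int)
    return out


def read_benefit_records(path) -> list[BenefitRecord]:
    """Read the benefit-spell CSV (one spell per line, documented schema)."""
    df = pd.read_csv(path, dtype={"person_id": str, "diagnosis_code": str})
    missing = set(RECORD_COLUMNS[:-1]) - set(df.columns)  # diagnosis optional
    if missing:
        raise SchemaError(f"benefit-record CSV lacks columns {sorted(missing)}")
    records = []
    for i, r in enumerate(df.itertuples(index=False)):
        try:
            records.append(
                BenefitRecord(
                    person_id=str(r.person_id),
                    benefit_type=str(r.benefit_type),
                    grading=int(r.grading),
                    start=int(r.start),
                    stop=int(r.stop),
                    registration_order=int(r.registration_order),
                    diagnosis_code=(
                        None
                        if not hasattr(r, "diagnosis_code")
                        or pd.isna(r.diagnosis_code)
                        else str(r.diagnosis_code)
                    ),
                )
            )
        except (SchemaError, ValueError) as err:
            raise SchemaError(f"row {i}: {err}") from err
    return records


def write_benefit_records(records: Iterable[BenefitRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "person_id": r.person_id,
                "benefit_type": r.benefit_type,
                "grading": r.grading,
                "start": r.start,
                "stop": r.stop,
                "registration_order": r.registration_order,
                "diagnosis_code": r.diagnosis_code,
            }
            for r in records
        ],
        columns=RECORD_COLUMNS,
    ).to_csv(path, index=False)


def read_covariate_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"person_id": str})
    if "person_id" not in df.columns:
        raise SchemaError("covariate CSV lacks a person_id column")
    return df.set_index("person_id")


def histories_to_frame(histories: Iterable[EventHistory]) -> pd.DataFrame:
    """Cleaned-history CSV layout: person, state, entry, exit."""
    rows = [
        {
            "person_id": h.person_id,
            "state": ep.state,
            "entry": ep.entry,
            "exit": ep.exit,
        }
        for h in histories
        for ep in h.episodes
    ]
    return pd.DataFrame(rows, columns=["person_id", "state", "entry", "exit"])


def histories_from_frame(
    frame: pd.DataFrame,
    covariate_table: pd.DataFrame | None = None,
) -> list[EventHistory]:
    """Rebuild histories from the cleaned-history CSV layout."""
    out = []
    for pid, grp in frame.groupby("person_id", sort=True):
        grp = grp.sort_values("entry")
        eps = [
            Episode(int(r.state), int(r.entry), int(r.exit))
            for r in grp.itertuples(index=False)
        ]
        cov = None
        if covariate_table is not None:
            cov = covariate_table.loc[str(pid)].to_dict()
        out.append(
            EventHistory(
                person_id=str(pid),
                censor_time=eps[-1].exit,
                episodes=eps,
                covariates=cov,
            )
        )
    return out
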