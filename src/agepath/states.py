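"""Multimorbidity state classification and per-participant timelines.

Health states count the number of distinct disorder *domains* present
(physical, psychological, cognitive): none, single, dual, triple, plus an
absorbing death state.  Domains accumulate monotonically — a domain once
present never clears — so state paths are non-decreasing in disorder count
until death.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import pandas as pd

DOMAINS = ("physical", "psychological", "cognitive")

#: epsilon (years) separating synthetic sub-jumps when several domains share
#: one onset date; the transition graph has no multi-level jumps.
TIE_EPSILON = 1.0 / 365.25


class HealthState(IntEnum):
    NO_CONDITION = 1
    SINGLE = 2
    DUAL = 3
    TRIPLE = 4
    DEATH = 5


def classify_state(domain_flags) -> HealthState:
    """Map the set of disorder domains present to a health state.

    The mapping depends only on the cardinality of the subset, so it is
    invariant to which particular domains are held.
    """
    flags = set(domain_flags)
    unknown = flags - set(DOMAINS)
    if unknown:
        raise ValueError(f"unknown disorder domains: {sorted(unknown)}")
    return HealthState(1 + len(flags))


@dataclass
class StateTimeline:
    """Ordered health-state occupancy for one participant."""

    id: object
    baseline_age: float
    entries: list = field(default_factory=list)  # [(age, HealthState), ...]
    death_age: float | None = None
    censor_age: float | None = None
    onset_ages: dict = field(default_factory=dict)  # domain -> first-onset age

    @property
    def baseline_state(self) -> HealthState:
        return self.entries[0][1]

    def validate(self) -> None:
        ages = [a for a, _ in self.entries]
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError(f"timeline ages not strictly increasing for id={self.id}")
        states = [s for _, s in self.entries]
        if any(int(t) != int(s) + 1 for s, t in zip(states, states[1:]) if t != HealthState.DEATH):
            raise ValueError(f"timeline skips states for id={self.id}")


def build_timeline(
    record,
    baseline_age: float | None = None,
    censor_age: float | None = None,
) -> StateTimeline:
    """Build a state timeline from per-domain first-onset ages and death age.

    ``record`` is a mapping (e.g. a DataFrame row) with keys ``id``,
    ``chronological_age``, ``onset_age_physical``, ``onset_age_psychological``,
    ``onset_age_cognitive`` (NaN/None when absent), ``death_age`` and
    ``censor_age``.  Onsets at or before the baseline age define the baseline
    state; later onsets each add one domain.  Onsets sharing one recorded age
    are ordered physical -> psychological -> cognitive with a one-day epsilon
    between the synthetic sub-jumps.
    """
    get = record.get if hasattr(record, "get") else record.__getitem__
    pid = get("id")
    if baseline_age is None:
        baseline_age = float(get("chronological_age"))
    if censor_age is None:
        censor_age = get("censor_age")
    censor_age = float(censor_age)
    death_age = get("death_age")
    death_age = None if death_age is None or (isinstance(death_age, float) and np.isnan(death_age)) else float(death_age)

    if baseline_age < 0 or censor_age < baseline_age:
        raise ValueError(f"invalid baseline/censor ages for id={pid}")

    onsets = {}
    for d in DOMAINS:
        v = get(f"onset_age_{d}")
        if v is not None and not (isinstance(v, float) and np.isnan(v)):
            v = float(v)
            if v < 0:
                raise ValueError(f"negative onset age for id={pid}, domain={d}")
            if death_age is not None and v > death_age:
                raise ValueError(f"onset after death for id={pid}, domain={d}")
            onsets[d] = v

    end_age = min(censor_age, death_age) if death_age is not None else censor_age
    baseline_domains = {d for d, a in onsets.items() if a <= baseline_age}
    entries = [(baseline_age, classify_state(baseline_domains))]

    # later onsets, domain-order tie-break with epsilon sub-jumps
    later = sorted(
        ((a, DOMAINS.index(d), d) for d, a in onsets.items() if baseline_age < a <= end_age),
    )
    held = set(baseline_domains)
    last_age = baseline_age
    for age, _, dom in later:
        held.add(dom)
        jump_age = max(age, last_age + TIE_EPSILON)
        entries.append((jump_age, classify_state(held)))
        last_age = jump_age
    if death_age is not None and death_age <= censor_age:
        entries.append((max(death_age, last_age + TIE_EPSILON), HealthState.DEATH))

    tl = StateTimeline(
        id=pid,
        baseline_age=baseline_age,
        entries=entries,
        death_age=death_age if (death_age is not None and death_age <= censor_age) else None,
        censor_age=censor_age,
        onset_ages=onsets,
    )
    tl.validate()
    return tl


def timelines_from_table(table: pd.DataFrame) -> list[StateTimeline]:
    """Vector convenience: one timeline per row of a cohort table."""
    return [build_timeline(row) for _, row in table.iterrows()]


def make_panel(timelines, scheme: str = "event-dates"):
    """Convert timelines to interval-censored panel observations.

    Under the ``event-dates`` scheme each participant contributes a row at
    baseline, at each onset age, and at the end of follow-up; death is
    flagged as exactly observed.  Participants whose only transition is
    no-condition -> death are excluded (that direct edge is not in the
    transition graph) and counted in the returned report.

    Returns ``(panel, report)`` where ``panel`` is a long-format DataFrame
    with columns (id, time, age, state, exact_death) — ``time`` is years
    since baseline — and ``report`` records exclusion counts.
    """
    if scheme != "event-dates":
        raise ValueError(f"unknown panel scheme: {scheme!r}")
    rows = []
    n_excluded = 0
    for tl in timelines:
        states = [s for _, s in tl.entries]
        if (
            states[0] == HealthState.NO_CONDITION
            and len(states) == 2
            and states[1] == HealthState.DEATH
        ):
            n_excluded += 1
            continue
        for age, state in tl.entries:
            rows.append((tl.id, age - tl.baseline_age, age, int(state), state == HealthState.DEATH))
        if tl.death_age is None and tl.censor_age > tl.entries[-1][0]:
            last_state = tl.entries[-1][1]
            rows.append((tl.id, tl.censor_age - tl.baseline_age, tl.censor_age, int(last_state), False))
    panel = pd.DataFrame(rows, columns=["id", "time", "age", "state", "exact_death"])
    report = {"n_input": len(list(timelines)), "n_excluded_none_to_death": n_excluded}
    report["n_retained"] = report["n_input"] - n_excluded
    return panel, report


def landmark_exclude(timelines, window_years: float = 5.0):
    """Drop participants with any onset or death within the landmark window.

    Sensitivity design against reverse causation: events in the first
    ``window_years`` of follow-up disqualify the participant; survivors keep
    their original baseline.
    """
    if window_years < 0:
        raise ValueError("landmark window must be non-negative")
    if window_years == 0:
        return list(timelines)
    kept = []
    for tl in timelines:
        cutoff = tl.baseline_age + window_years
        event_ages = [a for a, s in tl.entries[1:]]
        if any(a < cutoff for a in event_ages):
            continue
        if tl.death_age is not None and tl.death_age < cutoff:
            continue
        kept.append(tl)
    return kept
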