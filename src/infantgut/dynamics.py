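"""Longitudinal community-state series and directional transition analysis.

Each infant's samples are mapped to named community states (each PAM cluster
is named after the family with the highest mean abundance among its members,
e.g. Staphylococcaceae / Enterobacteriaceae / Bifidobacteriaceae), and
transitions are counted between consecutive *observed* samples — days without
a sample are bridged, with the gap length recorded alongside each counted
transition.  No run-length smoothing is applied by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .community import ClusterSolution
from .profiles import AbundanceTable, SampleMetadata

__all__ = [
    "StateSeries",
    "TransitionMatrix",
    "assign_states",
    "assign_states_dominance",
    "transition_counts",
    "directionality",
]


@dataclass
class StateSeries:
    """One subject's ordered (day, state) observations."""

    subject_id: str
    days: list[int]
    states: list[str]

    def __post_init__(self) -> None:
        if len(self.days) != len(self.states):
            raise ValueError("days and states length mismatch")
        if any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise ValueError(f"days not strictly increasing for {self.subject_id}")


@dataclass
class TransitionMatrix:
    """Counts of state transitions over consecutive observed samples."""

    states: list[str]
    counts: pd.DataFrame  # from (index) x to (columns)
    per_subject: dict[str, pd.DataFrame] = field(default_factory=dict)
    gaps: list[tuple[str, int, int, int]] = field(default_factory=list)
    # (subject, day_from, day_to, gap_days)

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


def _name_clusters(
    table: AbundanceTable, solution: ClusterSolution
) -> dict[int, str]:
    """Name each cluster by its members' top mean family; ambiguity is an error."""
    names: dict[int, str] = {}
    for c in sorted(set(solution.assignment.values())):
        members = solution.members(c)
        means = table.data.loc[members].mean(axis=0)
        names[c] = str(means.idxmax())
    if len(set(names.values())) != len(names):
        raise ValueError(
            f"two clusters share a top family ({names}); pass an explicit state_naming"
        )
    return names


def assign_states(
    table: AbundanceTable,
    meta: SampleMetadata,
    solution: ClusterSolution,
    state_naming: Mapping[int, str] | None = None,
) -> dict[str, StateSeries]:
    """Per-subject state series from a clustering solution.

    Clusters are named by their dominant mean family unless ``state_naming``
    maps cluster indices to labels explicitly.  Only samples present in both
    the metadata (with a day) and the assignment are used.
    """
    missing = [s for s in table.sample_ids if s not in solution.assignment]
    if missing:
        raise ValueError(f"samples missing from cluster assignment: {missing[:5]}")
    naming = dict(state_naming) if state_naming else _name_clusters(table, solution)
    md = meta.data
    md = md[md["sample_id"].isin(table.sample_ids)].copy()
    md["day"] = pd.to_numeric(md["day"], errors="coerce")
    md = md.dropna(subset=["day"])
    out: dict[str, StateSeries] = {}
    for subject, grp in md.groupby("subject_id", sort=True):
        grp = grp.sort_values("day")
        days = [int(d) for d in grp["day"]]
        states = [naming[solution.assignment[s]] for s in grp["sample_id"]]
        out[str(subject)] = StateSeries(str(subject), days, states)
    return out


def assign_states_dominance(
    table: AbundanceTable,
    meta: SampleMetadata,
    min_dominance: float = 0.0,
    families: Sequence[str] | None = None,
) -> dict[str, StateSeries]:
    """Alternative per-sample rule: state = argmax family abundance.

    Samples whose top family (restricted to ``families`` when given) falls
    below ``min_dominance`` are labelled ``"NT"`` and skipped by
    :func:`transition_counts`.
    """
    data = table.data if families is None else table.data[list(families)]
    top = data.idxmax(axis=1)
    frac = data.max(axis=1)
    md = meta.data.copy()
    md = md[md["sample_id"].isin(table.sample_ids)]
    md["day"] = pd.to_numeric(md["day"], errors="coerce")
    md = md.dropna(subset=["day"])
    out: dict[str, StateSeries] = {}
    for subject, grp in md.groupby("subject_id", sort=True):
        grp = grp.sort_values("day")
        days, states = [], []
        for _, row in grp.iterrows():
            s = row["sample_id"]
            days.append(int(row["day"]))
            states.append(str(top[s]) if frac[s] >= min_dominance else "NT")
        out[str(subject)] = StateSeries(str(subject), days, states)
    return out


def transition_counts(series: Mapping[str, StateSeries] | Sequence[StateSeries]) -> TransitionMatrix:
    """Count transitions between consecutive observed samples per subject.

    ``NT`` observations carry no state and are skipped; the transition is
    counted between the two nearest observed samples around the gap, with the
    day gap logged.  Self-pairs land on the diagonal.  The total count equals
    the summed (observed - 1) over subjects.
    """
    if isinstance(series, Mapping):
        series = list(series.values())
    observed = [
        [(d, s) for d, s in zip(ss.days, ss.states) if s != "NT"] for ss in series
    ]
    if all(len(obs) < 2 for obs in observed):
        raise ValueError("no subject has two or more observed samples")
    states = sorted({s for obs in observed for _, s in obs})
    zero = pd.DataFrame(0, index=states, columns=states)
    counts = zero.copy()
    per_subject: dict[str, pd.DataFrame] = {}
    gaps: list[tuple[str, int, int, int]] = []
    for ss, obs in zip(series, observed):
        sub = zero.copy()
        for (d1, s1), (d2, s2) in zip(obs, obs[1:]):
            sub.loc[s1, s2] += 1
            gaps.append((ss.subject_id, d1, d2, d2 - d1))
        counts += sub
        per_subject[ss.subject_id] = sub
    return TransitionMatrix(states, counts, per_subject, gaps)


def directionality(
    matrix: TransitionMatrix, order: Sequence[str]
) -> tuple[float, bool]:
    """Fraction of off-diagonal transitions that move forward along ``order``.

    ``order`` lists the states from earliest to best-adapted (e.g.
    Staphylococcaceae < Enterobacteriaceae < Bifidobacteriaceae).  Returns
    (fraction, defined); with no off-diagonal transitions the fraction is NaN
    and ``defined`` is False.
    """
    order = list(order)
    unknown = set(matrix.states) - set(order)
    if unknown:
        raise ValueError(f"states outside declared order: {sorted(unknown)}")
    rank = {s: i for i, s in enumerate(order)}
    forward = off_diag = 0
    for s1 in matrix.states:
        for s2 in matrix.states:
            if s1 == s2:
                continue
            c = int(matrix.counts.loc[s1, s2])
            off_diag += c
            if rank[s2] > rank[s1]:
                forward += c
    if off_diag == 0:
        return float("nan"), False
    return forward / off_diag, True


def series_to_grid(series: Mapping[str, StateSeries], abbrev: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Subjects × days grid of state labels ('' where no sample was provided)."""
    all_days = sorted({d for ss in series.values() for d in ss.days})
    grid = pd.DataFrame("", index=sorted(series), columns=all_days)
    for subject, ss in series.items():
        for d, s in zip(ss.days, ss.states):
            grid.loc[subject, d] = abbrev.get(s, s) if abbrev else s
    grid.index.name = "subject_id"
    return grid
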