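"""The retrieval-dependency statistic.

For each participant and condition, the six directed retrieval trials per event
are paired into six 2x2 contingency tables — one for each pair of trials that
shares a cue element (e.g. cue animal -> object and cue animal -> location) or a
retrieval target (e.g. cue object -> animal and cue location -> animal). Each
table classifies every event by the joint outcome of its two trials.

The observed proportion of *joint* retrieval in a table is the proportion of
events falling in the concordant cells (correct-correct plus
incorrect-incorrect). The *independent model* predicts that proportion from the
participant's marginal accuracies P1, P2 on the table's two directed pairs as
``P1*P2 + (1-P1)*(1-P2)``, i.e. what concordance would look like if the two
trials succeeded independently at the participant's own accuracy level.
Averaging both proportions over the six tables and subtracting gives

    dependency = mean_tables(P_joint_data) - mean_tables(P_joint_independent)

Positive dependency means the event's trials succeed or fail together more
than the participant's accuracy alone predicts — the signature of holistic
(all-or-none) event retrieval. The statistic is bounded in [-1, 1] and is 0 by
construction for a participant at floor or at ceiling, which is why ceiling
performers are excluded upstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .trial_data import (
    DEFAULT_ROLES,
    RESPONSE_CORRECT,
    RESPONSE_MISSING,
    ParticipantDataset,
    TrialDataError,
    directed_pairs,
)

__all__ = [
    "ContingencyTable",
    "DependencyResult",
    "table_definitions",
    "build_contingency_tables",
    "joint_retrieval_data",
    "independent_model_joint",
    "dependency",
    "dependency_from_outcomes",
    "outcome_matrix",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 event counts for the joint outcome of two directed retrieval trials.

    ``counts`` is a 2x2 integer array indexed [pair_1 outcome, pair_2 outcome]
    with 0 = correct and 1 = incorrect, so ``counts[0, 0]`` is the
    correct-correct cell and ``counts[1, 1]`` incorrect-incorrect.
    """

    table_kind: str  # "common_cue" | "common_target"
    shared_role: str
    pair_1: tuple[str, str]
    pair_2: tuple[str, str]
    counts: np.ndarray
    n_events: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (2, 2) or (counts < 0).any():
            raise ValueError("counts must be a 2x2 array of nonnegative integers")
        if counts.sum() != self.n_events:
            raise ValueError(
                f"counts sum {counts.sum()} != n_events {self.n_events}"
            )
        object.__setattr__(self, "counts", counts)

    @property
    def marginal_p1(self) -> float:
        """Participant accuracy on pair_1 across the table's events."""
        return float(self.counts[0].sum() / self.n_events)

    @property
    def marginal_p2(self) -> float:
        """Participant accuracy on pair_2 across the table's events."""
        return float(self.counts[:, 0].sum() / self.n_events)


@dataclass(frozen=True)
class TableDetail:
    table_kind: str
    shared_role: str
    p_data: float
    p_independent: float
    marginal_p1: float
    marginal_p2: float


@dataclass(frozen=True)
class DependencyResult:
    """Per-participant dependency: joint-retrieval proportions and their difference."""

    participant_id: str
    condition_id: str | None
    p_joint_data: float
    p_joint_independent: float
    dependency: float
    per_table: tuple[TableDetail, ...]
    n_events: int


def table_definitions(
    roles: Sequence[str] = DEFAULT_ROLES,
) -> list[tuple[str, str, tuple[str, str], tuple[str, str]]]:
    """The six (kind, shared_role, pair_1, pair_2) table layouts.

    Three common-cue tables (for each role X: trials X->Y and X->Z) and three
    common-target tables (for each role X: trials Y->X and Z->X). Every
    directed pair appears in exactly one table of each kind.
    """
    a, b, c = roles
    others = {a: (b, c), b: (a, c), c: (a, b)}
    defs = []
    for x in roles:
        y, z = others[x]
        defs.append(("common_cue", x, (x, y), (x, z)))
    for x in roles:
        y, z = others[x]
        defs.append(("common_target", x, (y, x), (z, x)))
    return defs


def outcome_matrix(
    dataset: ParticipantDataset, condition: str | None = None
) -> tuple[np.ndarray, list[int]]:
    """Boolean (n_events, 6) correctness matrix, columns in canonical pair order.

    Rows follow sorted event ids (returned alongside); requires complete
    six-trial events with missing responses already scored.
    """
    sub = dataset._scope(condition)
    if (sub["response"] == RESPONSE_MISSING).any():
        raise TrialDataError("missing responses must be scored before the dependency analysis")
    if condition is None and sub["condition_id"].nunique() > 1:
        raise TrialDataError(
            "dataset spans multiple conditions; pass the condition to analyse"
        )
    pairs = directed_pairs(dataset.roles)
    col = {p: j for j, p in enumerate(pairs)}
    events = sorted(sub["event_id"].unique())
    row = {e: i for i, e in enumerate(events)}
    mat = np.full((len(events), 6), -1, dtype=np.int8)
    for _, r in sub.iterrows():
        mat[row[r["event_id"]], col[(r["cue_role"], r["target_role"])]] = (
            1 if r["response"] == RESPONSE_CORRECT else 0
        )
    if (mat < 0).any():
        i, j = np.argwhere(mat < 0)[0]
        raise TrialDataError(
            f"participant {dataset.participant_id!r}: event {events[i]} lacks the "
            f"{pairs[j][0]}->{pairs[j][1]} trial"
        )
    return mat.astype(bool), events


def build_contingency_tables(
    dataset: ParticipantDataset, condition: str | None = None
) -> list[ContingencyTable]:
    """The six per-participant contingency tables for one condition."""
    mat, events = outcome_matrix(dataset, condition)
    pairs = directed_pairs(dataset.roles)
    col = {p: j for j, p in enumerate(pairs)}
    tables = []
    for kind, shared, p1, p2 in table_definitions(dataset.roles):
        x = mat[:, col[p1]]
        y = mat[:, col[p2]]
        counts = np.array(
            [
                [int((x & y).sum()), int((x & ~y).sum())],
                [int((~x & y).sum()), int((~x & ~y).sum())],
            ]
        )
        tables.append(ContingencyTable(kind, shared, p1, p2, counts, len(events)))
    return tables


def joint_retrieval_data(table: ContingencyTable) -> float:
    """Observed proportion of concordant events: (CC + II) / n_events."""
    if table.n_events == 0:
        raise ValueError("empty contingency table (n_events = 0)")
    return float((table.counts[0, 0] + table.counts[1, 1]) / table.n_events)


def independent_model_joint(p1: float, p2: float) -> float:
    """Expected concordance if the two trials are independent: p1*p2 + (1-p1)(1-p2)."""
    if not (0.0 <= p1 <= 1.0 and 0.0 <= p2 <= 1.0):
        raise ValueError(f"marginal probabilities must lie in [0, 1], got {p1}, {p2}")
    return p1 * p2 + (1.0 - p1) * (1.0 - p2)


def dependency(
    dataset: ParticipantDataset, condition: str | None = None
) -> DependencyResult:
    """Per-participant dependency score for one condition.

    Averages observed and independent-model concordance over the six tables;
    their difference is the dependency statistic.
    """
    tables = build_contingency_tables(dataset, condition)
    details = []
    for t in tables:
        p_data = joint_retrieval_data(t)
        p_ind = independent_model_joint(t.marginal_p1, t.marginal_p2)
        details.append(
            TableDetail(t.table_kind, t.shared_role, p_data, p_ind, t.marginal_p1, t.marginal_p2)
        )
    p_joint_data = float(np.mean([d.p_data for d in details]))
    p_joint_ind = float(np.mean([d.p_independent for d in details]))
    return DependencyResult(
        participant_id=dataset.participant_id,
        condition_id=condition,
        p_joint_data=p_joint_data,
        p_joint_independent=p_joint_ind,
        dependency=p_joint_data - p_joint_ind,
        per_table=tuple(details),
        n_events=tables[0].n_events,
    )


# Column-index pairs of the six tables in the canonical directed-pair ordering
# [(A,B),(A,C),(B,A),(B,C),(C,A),(C,B)]: three common-cue then three common-target.
_TABLE_COLS = ((0, 1), (2, 3), (4, 5), (2, 4), (0, 5), (1, 3))


def dependency_from_outcomes(correct: np.ndarray) -> np.ndarray:
    """Vectorised dependency from a boolean outcome array.

    ``correct`` has shape ``(..., n_events, 6)`` with the last axis in the
    canonical directed-pair order of :func:`eventdep.trial_data.directed_pairs`.
    Returns dependency scores of shape ``(...)``. This is the fast path used by
    simulation studies; it computes exactly the same statistic as
    :func:`dependency`.
    """
    x = np.asarray(correct, dtype=float)
    if x.ndim < 2 or x.shape[-1] != 6:
        raise ValueError("expected shape (..., n_events, 6)")
    dep = np.zeros(x.shape[:-2], dtype=float)
    for i, j in _TABLE_COLS:
        a = x[..., i]
        b = x[..., j]
        p11 = (a * b).mean(axis=-1)
        p00 = ((1 - a) * (1 - b)).mean(axis=-1)
        p1 = a.mean(axis=-1)
        p2 = b.mean(axis=-1)
        dep += (p11 + p00) - (p1 * p2 + (1 - p1) * (1 - p2))
    return dep / len(_TABLE_COLS)


def dependency_table(
    results: Sequence[DependencyResult], accuracies: Sequence[float] | None = None
) -> pd.DataFrame:
    """Tidy per-participant export of dependency results."""
    rows = []
    for i, r in enumerate(results):
        rows.append(
            {
                "participant_id": r.participant_id,
                "condition_id": r.condition_id,
                "p_joint_data": r.p_joint_data,
                "p_joint_indep": r.p_joint_independent,
                "dependency": r.dependency,
                "accuracy": accuracies[i] if accuracies is not None else np.nan,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "condition_id",
            "p_joint_data",
            "p_joint_indep",
            "dependency",
            "accuracy",
        ],
    )
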