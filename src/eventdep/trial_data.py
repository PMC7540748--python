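"""Trial-level data model, long-format I/O, missing-response scoring and exclusions.

The unit of data is the *retrieval trial*: one directed cue->target test of a
pairwise association within a three-element event (e.g. cue the animal, retrieve
the location). A complete participant/condition dataset contains exactly six
trials per event — every ordered pair of the three element roles — which is the
structure the dependency analysis requires.

The on-disk format is a long-format CSV with one row per trial and header
columns ``participant_id, condition_id, event_id, cue_role, target_role,
response, block, trial_index`` (the last two optional). Responses are the
strings ``correct`` / ``incorrect`` / ``missing``; a ``response_map`` can
translate other encodings (``1/0/NA`` and the like) at load time.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "DEFAULT_ROLES",
    "RESPONSE_LEVELS",
    "StudyConfig",
    "ParticipantDataset",
    "Exclusion",
    "TrialDataError",
    "directed_pairs",
    "load_trials",
    "save_trials",
    "score_missing",
    "accuracy",
    "apply_exclusions",
    "write_exclusion_report",
]

#: Canonical element roles. Any ordered triple of distinct labels is accepted
#: (person/object/location designs fit the same analysis).
DEFAULT_ROLES: tuple[str, str, str] = ("animal", "object", "location")

RESPONSE_CORRECT = "correct"
RESPONSE_INCORRECT = "incorrect"
RESPONSE_MISSING = "missing"
RESPONSE_LEVELS = (RESPONSE_CORRECT, RESPONSE_INCORRECT, RESPONSE_MISSING)

REQUIRED_COLUMNS = (
    "participant_id",
    "condition_id",
    "event_id",
    "cue_role",
    "target_role",
    "response",
)
OPTIONAL_COLUMNS = ("block", "trial_index")


class TrialDataError(ValueError):
    """Malformed or incomplete trial-level data."""


def directed_pairs(roles: Sequence[str] = DEFAULT_ROLES) -> list[tuple[str, str]]:
    """The six ordered cue->target role pairs, in canonical order."""
    _validate_roles(roles)
    return [(c, t) for c, t in itertools.permutations(roles, 2)]


def _validate_roles(roles: Sequence[str]) -> None:
    if len(roles) != 3 or len(set(roles)) != 3:
        raise TrialDataError(f"exactly three distinct element roles required, got {roles!r}")


@dataclass(frozen=True)
class StudyConfig:
    """Analysis-level configuration: design size, chance level, exclusion rules.

    Parameters
    ----------
    n_events
        Events per condition (15 or 30 in the reference experiments).
    chance_level
        Guessing probability of the forced-choice test (0.25 for 4AFC).
    ceiling_threshold
        Participants at or above this accuracy are excluded (dependency is
        mathematically bounded at ceiling). Inclusive, as in ">= 95%".
    floor_threshold
        Participants at or below this accuracy are excluded (near-chance
        responding); ``None`` disables the floor rule. Inclusive ("<= 30%").
    exclusion_scope
        ``"overall"`` pools trials across conditions before computing the
        accuracy used for exclusion; ``"condition_mean"`` averages the
        per-condition accuracies (the two-condition within-subject regime).
    """

    n_events: int = 15
    chance_level: float = 0.25
    ceiling_threshold: float = 0.95
    floor_threshold: float | None = 0.30
    exclusion_scope: str = "overall"
    roles: tuple[str, str, str] = DEFAULT_ROLES

    def __post_init__(self) -> None:
        _validate_roles(self.roles)
        if not 0.0 < self.chance_level < 1.0:
            raise TrialDataError("chance_level must lie strictly inside (0, 1)")
        if not 0.0 < self.ceiling_threshold <= 1.0:
            raise TrialDataError("ceiling_threshold must lie in (0, 1]")
        if self.floor_threshold is not None and not (
            0.0 < self.floor_threshold < self.ceiling_threshold
        ):
            raise TrialDataError("need 0 < floor_threshold < ceiling_threshold")
        if self.exclusion_scope not in ("overall", "condition_mean"):
            raise TrialDataError(
                f"exclusion_scope must be 'overall' or 'condition_mean', got {self.exclusion_scope!r}"
            )

    def to_dict(self) -> dict:
        return {
            "n_events": self.n_events,
            "chance_level": self.chance_level,
            "ceiling_threshold": self.ceiling_threshold,
            "floor_threshold": self.floor_threshold,
            "exclusion_scope": self.exclusion_scope,
            "roles": list(self.roles),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudyConfig":
        d = dict(d)
        if "roles" in d:
            d["roles"] = tuple(d["roles"])
        return cls(**d)


@dataclass(frozen=True)
class ParticipantDataset:
    """All retrieval trials of one participant, as a validated long table.

    ``trials`` holds one row per directed retrieval trial with the canonical
    columns; within every (condition, event) the six ordered role pairs each
    appear exactly once.
    """

    participant_id: str
    trials: pd.DataFrame
    roles: tuple[str, str, str] = DEFAULT_ROLES

    def __post_init__(self) -> None:
        _validate_roles(self.roles)
        object.__setattr__(self, "trials", self.trials.reset_index(drop=True))

    @property
    def conditions(self) -> list[str]:
        return sorted(self.trials["condition_id"].unique())

    def n_events(self, condition: str | None = None) -> int:
        sub = self._scope(condition)
        return sub["event_id"].nunique()

    def _scope(self, condition: str | None) -> pd.DataFrame:
        if condition is None:
            return self.trials
        sub = self.trials[self.trials["condition_id"] == condition]
        if sub.empty:
            raise TrialDataError(
                f"participant {self.participant_id!r}: no trials in condition {condition!r}"
            )
        return sub

    def validate_complete(self) -> None:
        """Check the six-trials-per-event invariant; raise naming the offender."""
        expected = set(directed_pairs(self.roles))
        for (cond, event), grp in self.trials.groupby(["condition_id", "event_id"], sort=False):
            got = set(zip(grp["cue_role"], grp["target_role"]))
            if len(grp) != 6 or got != expected:
                missing = sorted(expected - got)
                extra = sorted(got - expected)
                raise TrialDataError(
                    f"participant {self.participant_id!r}, condition {cond!r}, event {event}: "
                    f"expected the 6 directed role pairs, got {len(grp)} trials"
                    + (f"; missing pairs {missing}" if missing else "")
                    + (f"; unexpected pairs {extra}" if extra else "")
                )


@dataclass(frozen=True)
class Exclusion:
    participant_id: str
    accuracy: float
    reason: str  # "ceiling" or "floor"


def _normalise_frame(df: pd.DataFrame, path: str, roles: Sequence[str],
                     response_map: Mapping[str, str] | None) -> pd.DataFrame:
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise TrialDataError(f"{path}: missing required columns {missing_cols}")
    for col in OPTIONAL_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA

    df = df.copy()
    for col in ("participant_id", "condition_id", "cue_role", "target_role"):
        df[col] = df[col].astype(str).str.strip()
    if response_map:
        df["response"] = df["response"].astype(str).str.strip().map(
            lambda v: response_map.get(v, v)
        )
    else:
        df["response"] = df["response"].astype(str).str.strip()

    # row-level validation, reporting 1-based data row numbers (header = row 1)
    event_num = pd.to_numeric(df["event_id"], errors="coerce")
    bad = event_num.isna() | (event_num < 1) | (event_num != event_num.round())
    if bad.any():
        row = int(df.index[bad][0]) + 2
        raise TrialDataError(f"{path}: row {row}: event_id {df.loc[bad].iloc[0]['event_id']!r} "
                             "is not a positive integer")
    df["event_id"] = event_num.astype(int)

    role_set = set(roles)
    for col in ("cue_role", "target_role"):
        bad = ~df[col].isin(role_set)
        if bad.any():
            row = int(df.index[bad][0]) + 2
            raise TrialDataError(
                f"{path}: row {row}: {col} {df.loc[bad].iloc[0][col]!r} not in {sorted(role_set)}"
            )
    bad = df["cue_role"] == df["target_role"]
    if bad.any():
        row = int(df.index[bad][0]) + 2
        raise TrialDataError(f"{path}: row {row}: cue_role equals target_role")

    bad = ~df["response"].isin(RESPONSE_LEVELS)
    if bad.any():
        row = int(df.index[bad][0]) + 2
        raise TrialDataError(
            f"{path}: row {row}: response {df.loc[bad].iloc[0]['response']!r} "
            f"not in {list(RESPONSE_LEVELS)} (use response_map for other encodings)"
        )

    dup_key = ["participant_id", "condition_id", "event_id", "cue_role", "target_role"]
    dups = df.duplicated(dup_key, keep=False)
    if dups.any():
        first = df.loc[dups, dup_key].iloc[0].to_dict()
        raise TrialDataError(f"{path}: duplicate trial rows for {first}")
    return df


def load_trials(
    path: str | Path,
    *,
    roles: Sequence[str] = DEFAULT_ROLES,
    response_map: Mapping[str, str] | None = None,
) -> list[ParticipantDataset]:
    """Read a long-format trial CSV into validated per-participant datasets.

    Raises :class:`TrialDataError` naming the row and field for malformed rows,
    the (condition, event) for incomplete events, and the key for duplicates.
    """
    _validate_roles(roles)
    path = Path(path)
    if not path.exists():
        raise TrialDataError(f"{path}: no such file")
    try:
        # keep_default_na=False so encodings like "NA" reach the response_map intact
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise TrialDataError(f"{path}: empty input file") from None
    if df.empty:
        raise TrialDataError(f"{path}: no trial rows")
    df = _normalise_frame(df, str(path), roles, response_map)

    datasets = []
    for pid, grp in df.groupby("participant_id", sort=True):
        ds = ParticipantDataset(pid, grp.reset_index(drop=True), tuple(roles))
        ds.validate_complete()
        datasets.append(ds)
    return datasets


def save_trials(datasets: Iterable[ParticipantDataset], path: str | Path) -> None:
    """Write datasets back to the long-format CSV dialect (round-trips with load)."""
    frames = [ds.trials for ds in datasets]
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=REQUIRED_COLUMNS + OPTIONAL_COLUMNS
    )
    cols = list(REQUIRED_COLUMNS) + [c for c in OPTIONAL_COLUMNS if c in out.columns]
    out[cols].to_csv(path, index=False)


def score_missing(dataset: ParticipantDataset) -> tuple[ParticipantDataset, float]:
    """Count missing responses as incorrect.

    Time-outs are scored as retrieval failures, matching the forced-choice
    scoring rule of the task. Returns the rescored dataset together with the
    participant's missing proportion for reporting; trial count is unchanged.
    """
    trials = dataset.trials
    is_missing = trials["response"] == RESPONSE_MISSING
    prop = float(is_missing.mean()) if len(trials) else 0.0
    if is_missing.any():
        trials = trials.copy()
        trials.loc[is_missing, "response"] = RESPONSE_INCORRECT
    return replace(dataset, trials=trials), prop


def accuracy(dataset: ParticipantDataset, condition: str | None = None) -> float:
    """Proportion correct in the given condition (or overall).

    Missing responses must already have been scored (:func:`score_missing`).
    """
    sub = dataset._scope(condition)
    if sub.empty:
        raise TrialDataError(f"participant {dataset.participant_id!r}: empty accuracy scope")
    if (sub["response"] == RESPONSE_MISSING).any():
        raise TrialDataError(
            f"participant {dataset.participant_id!r}: score_missing must be applied "
            "before computing accuracy"
        )
    return float((sub["response"] == RESPONSE_CORRECT).mean())


def exclusion_accuracy(dataset: ParticipantDataset, config: StudyConfig) -> float:
    """The accuracy the exclusion rule is applied to, per the configured scope."""
    if config.exclusion_scope == "condition_mean":
        accs = [accuracy(dataset, c) for c in dataset.conditions]
        return float(sum(accs) / len(accs))
    return accuracy(dataset)


def apply_exclusions(
    datasets: Sequence[ParticipantDataset], config: StudyConfig
) -> tuple[list[ParticipantDataset], list[Exclusion]]:
    """Partition participants into included and excluded-with-reason.

    Thresholds are inclusive: accuracy >= ceiling_threshold excludes with
    reason ``ceiling``; accuracy <= floor_threshold (when a floor rule is
    configured) excludes with reason ``floor``. The partition is exhaustive
    and disjoint, and the operation is idempotent.
    """
    included: list[ParticipantDataset] = []
    excluded: list[Exclusion] = []
    for ds in datasets:
        acc = exclusion_accuracy(ds, config)
        if acc >= config.ceiling_threshold:
            excluded.append(Exclusion(ds.participant_id, acc, "ceiling"))
        elif config.floor_threshold is not None and acc <= config.floor_threshold:
            excluded.append(Exclusion(ds.participant_id, acc, "floor"))
        else:
            included.append(ds)
    return included, excluded


def write_exclusion_report(exclusions: Sequence[Exclusion], path: str | Path) -> None:
    pd.DataFrame(
        [{"participant_id": e.participant_id, "accuracy": e.accuracy, "reason": e.reason}
         for e in exclusions],
        columns=["participant_id", "accuracy", "reason"],
    ).to_csv(path, index=False)
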