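"""Trial-to-session aggregation.

Each subject contributes several trials per session; downstream statistics
operate on one score per subject per session.  Three aggregation rules are
supported: the session average of all trials (Avg), the highest trial value
(Hv) and the lowest trial value (Lv, used only for hop contact time, where
shorter is better).

For reactive hops the two set-level summaries act as the session's two
"trials": the set peak force is the single highest force over all valid
hops of the set, and the set average contact time (ACT) is the mean contact
time of the valid hops.  Hops flagged invalid (heel contact) contribute to
neither.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    ConfigError,
    Dataset,
    DegenerateSetError,
    InsufficientDataError,
    Test,
    Variable,
)

logger = logging.getLogger("retestkit")


class AggregationRule(str, enum.Enum):
    AVG = "avg"
    HIGHEST = "highest"
    LOWEST = "lowest"


def validate_rule(variable: Variable, rule: AggregationRule) -> None:
    """Lv applies only to contact time; Hv never does (short contacts win)."""
    if rule is AggregationRule.LOWEST and variable is not Variable.HOP_CONTACT_TIME:
        raise ConfigError(f"rule 'lowest' is only valid for hop_contact_time, not {variable.value}")
    if rule is AggregationRule.HIGHEST and variable is Variable.HOP_CONTACT_TIME:
        raise ConfigError("rule 'highest' is not valid for hop_contact_time")


@dataclass(frozen=True)
class SessionScore:
    subject_id: str
    session_id: str
    variable: Variable
    rule: AggregationRule
    score: float
    n_trials_used: int


@dataclass
class ScoreMatrix:
    """Complete n-subjects x k-sessions matrix of session scores.

    Subjects missing any requested session are dropped (with a logged
    warning) before construction, so ``values`` never has missing cells.
    """

    variable: Variable
    rule: AggregationRule
    subjects: list[str]
    sessions: list[str]
    values: np.ndarray  # shape (n, k)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, k = self.values.shape
        if n != len(self.subjects) or k != len(self.sessions):
            raise ValueError("matrix shape does not match subject/session lists")
        if n < 2 or k < 2:
            raise InsufficientDataError(
                f"need at least 2 subjects and 2 sessions, got {n} x {k}"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("score matrix contains non-finite values")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# Hop-set summarisation
# ---------------------------------------------------------------------------

def hop_set_summary(hops: pd.DataFrame) -> tuple[float, float]:
    """Summarise one subject-session-set of hops.

    Returns ``(set_peak_force, set_avg_contact_time)``: the highest peak
    force over valid hops and the mean contact time of valid hops.  Raises
    :class:`DegenerateSetError` when no hop in the set is valid.
    """
    valid = hops[hops["valid"].astype(bool)]
    if valid.empty:
        ident = ""
        if len(hops):
            row = hops.iloc[0]
            ident = f" (subject {row['subject_id']}, session {row['session_id']}, set {row['set_index']})"
        raise DegenerateSetError(f"no valid hops in set{ident}")
    return float(valid["peak_force"].max()), float(valid["contact_time"].mean())


def hop_sets_to_trials(dataset: Dataset) -> pd.DataFrame:
    """Collapse hop-level records to set-level trial rows.

    Each (subject, session, set) yields two trial rows -- one
    ``hop_peak_force`` and one ``hop_contact_time`` -- with the set index as
    the trial index, ready to be merged with the ordinary trial table.
    """
    if dataset.hops.empty:
        return pd.DataFrame(columns=dataset.trials.columns)
    rows = []
    for (subj, sess, set_idx), grp in dataset.hops.groupby(
        ["subject_id", "session_id", "set_index"], sort=True
    ):
        peak, act = hop_set_summary(grp)
        rows.append((subj, sess, Test.REACTIVE_HOPS.value,
                     Variable.HOP_PEAK_FORCE.value, int(set_idx), peak))
        rows.append((subj, sess, Test.REACTIVE_HOPS.value,
                     Variable.HOP_CONTACT_TIME.value, int(set_idx), act))
    return pd.DataFrame(rows, columns=["subject_id", "session_id", "test",
                                       "variable", "trial_index", "value"])


# ---------------------------------------------------------------------------
# Session scores
# ---------------------------------------------------------------------------

def session_score(
    values: Sequence[float],
    rule: AggregationRule,
    subject_id: str = "",
    session_id: str = "",
    variable: Variable | None = None,
) -> SessionScore:
    """Collapse the trial values of one subject-session to a single score."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise InsufficientDataError("session_score requires at least one trial value")
    if rule is AggregationRule.AVG:
        score = float(arr.mean())
    elif rule is AggregationRule.HIGHEST:
        score = float(arr.max())
    elif rule is AggregationRule.LOWEST:
        score = float(arr.min())
    else:  # pragma: no cover
        raise ConfigError(f"unknown rule {rule!r}")
    return SessionScore(subject_id, session_id, variable, rule, score, int(arr.size))


def session_scores(dataset: Dataset, variable: Variable, rule: AggregationRule) -> pd.DataFrame:
    """Per subject x session scores for one variable under one rule.

    Hop variables are first collapsed from hop level to set-level trials.
    Returns a frame with columns ``subject_id, session_id, score,
    n_trials_used``.
    """
    validate_rule(variable, rule)
    trials = dataset.trials
    if variable in (Variable.HOP_PEAK_FORCE, Variable.HOP_CONTACT_TIME) and not dataset.hops.empty:
        trials = pd.concat([trials, hop_sets_to_trials(dataset)], ignore_index=True)
    sub = trials[trials["variable"] == variable.value]
    rows = []
    for (subj, sess), grp in sub.groupby(["subject_id", "session_id"], sort=True):
        s = session_score(grp["value"].to_numpy(), rule, subj, sess, variable)
        rows.append((subj, sess, s.score, s.n_trials_used))
    return pd.DataFrame(rows, columns=["subject_id", "session_id", "score", "n_trials_used"])


def build_matrix(
    scores: pd.DataFrame,
    variable: Variable,
    rule: AggregationRule,
    sessions: Sequence[str],
) -> ScoreMatrix:
    """Pivot session scores into a complete n x k :class:`ScoreMatrix`.

    ``sessions`` is the ordered subset of the session order to analyse
    (the full design, or one pair such as ``("S1", "S3")``).  Subjects
    lacking any requested session are excluded with a logged warning.
    """
    sessions = list(sessions)
    if len(sessions) < 2:
        raise InsufficientDataError("a comparison needs at least 2 sessions")
    wide = scores.pivot(index="subject_id", columns="session_id", values="score")
    missing_sessions = [s for s in sessions if s not in wide.columns]
    if missing_sessions:
        raise InsufficientDataError(f"no scores for session(s) {missing_sessions}")
    wide = wide[sessions]
    incomplete = wide.index[wide.isna().any(axis=1)]
    if len(incomplete):
        logger.warning(
            "excluding %d subject(s) incomplete in sessions %s: %s",
            len(incomplete), sessions, list(incomplete),
        )
        wide = wide.drop(index=incomplete)
    if len(wide) < 2:
        raise InsufficientDataError(
            f"fewer than 2 subjects complete in sessions {sessions}"
        )
    return ScoreMatrix(variable, rule, list(wide.index), sessions, wide.to_numpy())


def matrix_from_dataset(
    dataset: Dataset,
    variable: Variable,
    rule: AggregationRule,
    sessions: Sequence[str] | None = None,
) -> ScoreMatrix:
    """Convenience: aggregate and pivot in one step."""
    scores = session_scores(dataset, variable, rule)
    return build_matrix(scores, variable, rule, sessions or dataset.session_order)
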