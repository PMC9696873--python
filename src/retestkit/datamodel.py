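"""Data model and I/O for trial-level strength/power test measurements.

The canonical input is a long-format CSV: one row per trial of one variable
(e.g. the peak knee-extension torque of trial 2 in session S1 of subject
``sub03``).  Reactive-hop data are carried separately at the hop level (one
row per hop, with a validity flag for heel contacts) and are summarised to
set-level "trials" by :mod:`retestkit.aggregation`.

Units are metadata only: every variable is analysed in its native unit
(Nm, kg, cm, W/kg, kN, s) and no conversion is ever performed.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("retestkit")


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class RetestKitError(Exception):
    """Base class for all package errors."""


class SchemaError(RetestKitError):
    """A required column is missing or a label is not recognised."""


class ParseError(RetestKitError):
    """A cell could not be parsed; the message cites the offending file line."""


class IntegrityError(RetestKitError):
    """A dataset invariant is violated (duplicate keys, negative values...)."""


class InsufficientDataError(RetestKitError):
    """Fewer complete subjects or sessions than an analysis requires."""


class DegenerateSetError(RetestKitError):
    """A hop set contains no valid hops."""


class UndefinedStatisticError(RetestKitError):
    """A statistic is undefined for the given input (e.g. ICC of a constant
    matrix, CV with a non-positive subject mean)."""


class ConfigError(RetestKitError):
    """Invalid configuration value."""


# ---------------------------------------------------------------------------
# Enumerations
# ---------------------------------------------------------------------------

class Test(str, enum.Enum):
    """The four performance tests of the nine-week test battery."""

    KNEE_EXTENSION_MVC = "knee_extension_mvc"
    HANDGRIP_MVC = "handgrip_mvc"
    CMJ = "cmj"
    REACTIVE_HOPS = "reactive_hops"


class Variable(str, enum.Enum):
    """Scalar outcome variables, one or two per test."""

    PEAK_TORQUE = "peak_torque"            # Nm, knee extension MVC
    GRIP_FORCE = "grip_force"              # kg, handgrip MVC
    JUMP_HEIGHT = "jump_height"            # cm, countermovement jump
    PEAK_POWER = "peak_power"              # W/kg, countermovement jump
    HOP_PEAK_FORCE = "hop_peak_force"      # kN, reactive hops (per-set max)
    HOP_CONTACT_TIME = "hop_contact_time"  # s, reactive hops (per-set mean)


UNITS: Mapping[Variable, str] = {
    Variable.PEAK_TORQUE: "Nm",
    Variable.GRIP_FORCE: "kg",
    Variable.JUMP_HEIGHT: "cm",
    Variable.PEAK_POWER: "W/kg",
    Variable.HOP_PEAK_FORCE: "kN",
    Variable.HOP_CONTACT_TIME: "s",
}

VARIABLE_TEST: Mapping[Variable, Test] = {
    Variable.PEAK_TORQUE: Test.KNEE_EXTENSION_MVC,
    Variable.GRIP_FORCE: Test.HANDGRIP_MVC,
    Variable.JUMP_HEIGHT: Test.CMJ,
    Variable.PEAK_POWER: Test.CMJ,
    Variable.HOP_PEAK_FORCE: Test.REACTIVE_HOPS,
    Variable.HOP_CONTACT_TIME: Test.REACTIVE_HOPS,
}

#: Display rounding (decimal places) for values in a variable's native unit.
UNIT_DECIMALS: Mapping[Variable, int] = {
    Variable.PEAK_TORQUE: 1,
    Variable.GRIP_FORCE: 1,
    Variable.JUMP_HEIGHT: 1,
    Variable.PEAK_POWER: 1,
    Variable.HOP_PEAK_FORCE: 2,
    Variable.HOP_CONTACT_TIME: 3,
}

TRIAL_COLUMNS = ["subject_id", "session_id", "test", "variable", "trial_index", "value"]
HOP_COLUMNS = [
    "subject_id", "session_id", "set_index", "hop_index",
    "contact_time", "peak_force", "valid",
]
MAX_HOPS_PER_SET = 10


# ---------------------------------------------------------------------------
# Records and Dataset
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialRecord:
    """One scalar measurement of one trial (or one hop-set summary)."""

    subject_id: str
    session_id: str
    test: Test
    variable: Variable
    trial_index: int
    value: float

    def __post_init__(self) -> None:
        if self.trial_index < 1:
            raise IntegrityError(f"trial_index must be >= 1, got {self.trial_index}")
        if not np.isfinite(self.value) or self.value < 0:
            raise IntegrityError(
                f"value must be a nonnegative finite number, got {self.value!r}"
            )


@dataclass(frozen=True)
class HopRecord:
    """One reactive hop: contact time, peak force and a heel-contact flag."""

    subject_id: str
    session_id: str
    set_index: int
    hop_index: int
    contact_time: float
    peak_force: float
    valid: bool = True

    def __post_init__(self) -> None:
        if self.set_index < 1:
            raise IntegrityError(f"set_index must be >= 1, got {self.set_index}")
        if self.hop_index < 1:
            raise IntegrityError(f"hop_index must be >= 1, got {self.hop_index}")
        if not self.contact_time > 0:
            raise IntegrityError(f"contact_time must be > 0, got {self.contact_time}")
        if not self.peak_force > 0:
            raise IntegrityError(f"peak_force must be > 0, got {self.peak_force}")


@dataclass
class Dataset:
    """Validated trial- and hop-level data plus the session ordering.

    ``trials`` has columns ``subject_id, session_id, test, variable,
    trial_index, value``; ``hops`` has columns ``subject_id, session_id,
    set_index, hop_index, contact_time, peak_force, valid``.  Either frame
    may be empty.  ``session_order`` lists every session label in
    chronological order (lexical by default).
    """

    trials: pd.DataFrame
    hops: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=HOP_COLUMNS))
    session_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.session_order:
            labels = set(self.trials["session_id"]) | set(self.hops["session_id"])
            self.session_order = sorted(labels)
        self.validate()

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_records(
        cls,
        records: Iterable[TrialRecord] = (),
        hops: Iterable[HopRecord] = (),
        session_order: Sequence[str] | None = None,
    ) -> "Dataset":
        trials = pd.DataFrame(
            [
                (r.subject_id, r.session_id, r.test.value, r.variable.value,
                 r.trial_index, r.value)
                for r in records
            ],
            columns=TRIAL_COLUMNS,
        )
        hops_df = pd.DataFrame(
            [
                (h.subject_id, h.session_id, h.set_index, h.hop_index,
                 h.contact_time, h.peak_force, h.valid)
                for h in hops
            ],
            columns=HOP_COLUMNS,
        )
        return cls(trials, hops_df, list(session_order) if session_order else [])

    def validate(self) -> None:
        t = self.trials
        if len(t):
            bad = ~t["variable"].isin([v.value for v in Variable])
            if bad.any():
                raise SchemaError(
                    f"unknown variable label(s): {sorted(t.loc[bad, 'variable'].unique())}"
                )
            bad = ~t["test"].isin([x.value for x in Test])
            if bad.any():
                raise SchemaError(
                    f"unknown test label(s): {sorted(t.loc[bad, 'test'].unique())}"
                )
            if (t["value"] < 0).any() or not np.isfinite(t["value"]).all():
                raise IntegrityError("trial values must be nonnegative finite numbers")
            if (t["trial_index"] < 1).any():
                raise IntegrityError("trial_index must be >= 1")
            key = ["subject_id", "session_id", "test", "variable", "trial_index"]
            dup = t.duplicated(key)
            if dup.any():
                first = t.loc[dup, key].iloc[0].tolist()
                raise IntegrityError(f"duplicate trial key {tuple(first)}")
        h = self.hops
        if len(h):
            if not (h["contact_time"] > 0).all():
                raise IntegrityError("hop contact_time must be > 0")
            if not (h["peak_force"] > 0).all():
                raise IntegrityError("hop peak_force must be > 0")
            counts = h.groupby(["subject_id", "session_id", "set_index"]).size()
            if (counts > MAX_HOPS_PER_SET).any():
                where = counts[counts > MAX_HOPS_PER_SET].index[0]
                raise IntegrityError(
                    f"more than {MAX_HOPS_PER_SET} hops in set {where}"
                )
            dup = h.duplicated(["subject_id", "session_id", "set_index", "hop_index"])
            if dup.any():
                raise IntegrityError("duplicate hop key")
        labels = set(t["session_id"]) | set(h["session_id"])
        missing = labels - set(self.session_order)
        if missing:
            raise IntegrityError(f"session id(s) {sorted(missing)} not in session_order")

    # -- convenience ---------------------------------------------------------

    @property
    def subjects(self) -> list[str]:
        subj = set(self.trials["subject_id"]) | set(self.hops["subject_id"])
        return sorted(subj)

    def variables(self) -> list[Variable]:
        return [Variable(v) for v in sorted(self.trials["variable"].unique())]

    def with_sessions(self, session_order: Sequence[str]) -> "Dataset":
        return Dataset(self.trials.copy(), self.hops.copy(), list(session_order))


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _numeric_column(raw: pd.Series, name: str) -> pd.Series:
    """Parse a column to float, citing the 1-based file line on failure."""
    out = pd.to_numeric(raw, errors="coerce")
    bad = out.isna() & raw.notna()
    if bad.any():
        # +2: one for the header row, one for 0- to 1-based indexing.
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise ParseError(
            f"could not parse {name!r} value {raw[bad].iloc[0]!r} on line {line}"
        )
    if out.isna().any():
        line = int(np.flatnonzero(out.isna().to_numpy())[0]) + 2
        raise ParseError(f"missing {name!r} value on line {line}")
    return out


def _apply_schema(df: pd.DataFrame, required: Sequence[str],
                  schema: Mapping[str, str] | None) -> pd.DataFrame:
    schema = dict(schema or {})
    rename = {schema.get(c, c): c for c in required}
    missing = [src for src in rename if src not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    return df.rename(columns=rename)[list(required)].copy()


def read_trials(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    session_order: Sequence[str] | None = None,
    expected_trials: int | None = None,
) -> Dataset:
    """Read a long-format trial CSV into a validated :class:`Dataset`.

    ``schema`` maps canonical column names to the file's column names, e.g.
    ``{"value": "peak_torque_Nm"}``.  Session order is inferred by lexical
    sort of the distinct session labels unless given.  If ``expected_trials``
    is set, subject-session groups deviating from that trial count are
    logged as warnings (never errors: the design tolerates miscounts).
    """
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    df = _apply_schema(raw, TRIAL_COLUMNS, schema)
    df["value"] = _numeric_column(df["value"], "value")
    idx = _numeric_column(df["trial_index"], "trial_index")
    if not (idx == idx.round()).all():
        raise ParseError("trial_index must be an integer")
    df["trial_index"] = idx.astype(int)
    ds = Dataset(df, session_order=list(session_order) if session_order else [])
    if expected_trials is not None:
        counts = df.groupby(["subject_id", "session_id", "variable"]).size()
        off = counts[counts != expected_trials]
        for key, n in off.items():
            logger.warning("expected %d trials, found %d for %s", expected_trials, n, key)
    return ds


def read_hops(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    session_order: Sequence[str] | None = None,
) -> Dataset:
    """Read a hop-level CSV (one row per hop) into a :class:`Dataset`."""
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    df = _apply_schema(raw, HOP_COLUMNS, schema)
    for col in ("contact_time", "peak_force"):
        df[col] = _numeric_column(df[col], col)
    for col in ("set_index", "hop_index"):
        df[col] = _numeric_column(df[col], col).astype(int)
    df["valid"] = df["valid"].str.strip().str.lower().isin(["true", "1", "yes", "t"])
    empty = pd.DataFrame(columns=TRIAL_COLUMNS)
    return Dataset(empty, df, list(session_order) if session_order else [])


def write_trials(dataset: Dataset, path: str | Path) -> None:
    """Write the trial table back to CSV (full precision; exact round-trip)."""
    dataset.trials.to_csv(path, index=False)


def write_hops(dataset: Dataset, path: str | Path) -> None:
    dataset.hops.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Report writer
# ---------------------------------------------------------------------------

def _comparison_label(comparison: Sequence[str], session_order: Sequence[str]) -> str:
    if list(comparison) == list(session_order):
        return "all"
    return "-".join(comparison)


def write_report_table(result_rows: Sequence, path: str | Path, layout: str) -> None:
    """Write reliability or sensitivity results as a wide per-variable table.

    One output row per variable x rule; within a row, one column block per
    session comparison ordered all sessions first, then the pairs in
    chronological order.  ``layout`` is ``"reliability"`` (ICC with 95% CI,
    CV%) or ``"sensitivity"`` (SEm (SEm%), SWC, MD (MD%)).  Values are
    rounded to report conventions; full-precision values live in the
    machine-readable sidecar written by the pipeline.
    """
    if layout not in ("reliability", "sensitivity"):
        raise ConfigError(f"unknown layout {layout!r}")
    expected = {"reliability": "cv_pct", "sensitivity": "sem"}[layout]
    for row in result_rows:
        if not hasattr(row, expected):
            raise ConfigError(
                f"row {row!r} does not match the {layout!r} layout; "
                "mixed layouts are not supported"
            )

    frame = _layout_frame(result_rows, layout)
    frame.to_csv(path, index=False)


def _fmt(x: float, nd: int) -> str:
    return f"{x:.{nd}f}"


def _layout_frame(rows: Sequence, layout: str) -> pd.DataFrame:
    groups: dict[tuple[str, str], list] = {}
    comparisons: list[str] = []
    for r in rows:
        groups.setdefault((r.variable.value, r.rule.value), []).append(r)
        if r.label not in comparisons:
            comparisons.append(r.label)
    comparisons.sort(key=lambda c: (c != "all", c))

    out_rows = []
    for (variable, rule), rs in groups.items():
        var = Variable(variable)
        nd = UNIT_DECIMALS[var]
        rec: dict[str, str] = {"variable": variable, "unit": UNITS[var], "rule": rule}
        for label in comparisons:
            match = [r for r in rs if r.label == label]
            if not match:
                continue
            r = match[0]
            if layout == "reliability":
                rec[f"{label} ICC (95% CI)"] = (
                    f"{r.icc.estimate:.3f} ({r.icc.ci_low:.3f}-{r.icc.ci_high:.3f})"
                )
                rec[f"{label} CV%"] = _fmt(r.cv_pct, 1)
            else:
                rec[f"{label} SEm (SEm%)"] = f"{_fmt(r.sem, nd)} ({_fmt(r.sem_pct, 1)}%)"
                rec[f"{label} SWC"] = _fmt(r.swc, nd)
                rec[f"{label} MD (MD%)"] = f"{_fmt(r.md, nd)} ({_fmt(r.md_pct, 1)}%)"
        out_rows.append(rec)

    if not out_rows:  # header-only file
        cols = ["variable", "unit", "rule"]
        if layout == "reliability":
            cols += ["all ICC (95% CI)", "all CV%"]
        else:
            cols += ["all SEm (SEm%)", "all SWC", "all MD (MD%)"]
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(out_rows)
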