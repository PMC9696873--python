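"""Full-analysis orchestration: gates -> aggregation -> reliability and
sensitivity for every variable x rule x session comparison.

The default analysis mirrors the three-session design: the all-sessions
comparison plus each pair (S1-S2, S1-S3, S2-S3), with the Avg and Hv rules
for every variable except hop contact time, which uses Avg and Lv.  Each
comparison's matrix is built independently, so pair results never depend on
scores outside the pair.  Human-readable tables are rounded to report
conventions (ICC 3 decimals, percentages 1 decimal, unit values at the
variable's precision) with significance markers (* = S1-S2, # = S1-S3,
& = S2-S3 bias); full-precision values go to machine-readable sidecars.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import pandas as pd
import yaml

from . import datamodel
from .aggregation import AggregationRule, matrix_from_dataset, validate_rule
from .datamodel import (
    ConfigError,
    Dataset,
    InsufficientDataError,
    Test,
    UNIT_DECIMALS,
    Variable,
    VARIABLE_TEST,
    write_report_table,
)
from .reliability import (
    DEFAULT_ALPHA,
    GateResult,
    ReliabilityResult,
    analyze_reliability,
    distribution_gates,
)
from .sensitivity import (
    DEFAULT_SWC_MULTIPLIER,
    SensitivityResult,
    analyze_sensitivity,
)

logger = logging.getLogger("retestkit")

#: Default aggregation rules per variable (Lv only for contact time).
DEFAULT_RULES: Mapping[Variable, tuple[AggregationRule, ...]] = {
    Variable.PEAK_TORQUE: (AggregationRule.AVG, AggregationRule.HIGHEST),
    Variable.GRIP_FORCE: (AggregationRule.AVG, AggregationRule.HIGHEST),
    Variable.JUMP_HEIGHT: (AggregationRule.AVG, AggregationRule.HIGHEST),
    Variable.PEAK_POWER: (AggregationRule.AVG, AggregationRule.HIGHEST),
    Variable.HOP_PEAK_FORCE: (AggregationRule.AVG, AggregationRule.HIGHEST),
    Variable.HOP_CONTACT_TIME: (AggregationRule.AVG, AggregationRule.LOWEST),
}

_PAIR_MARKERS = {"S1-S2": "*", "S1-S3": "#", "S2-S3": "&"}


@dataclass
class RunConfig:
    """Analysis settings; see the packaged YAML example for the file form."""

    trials_path: str | Path | None = None
    hops_path: str | Path | None = None
    variables: Sequence[Variable] | None = None
    rules: Mapping[Variable, Sequence[AggregationRule]] | None = None
    session_order: Sequence[str] | None = None
    comparisons: Sequence[Sequence[str]] | None = None
    alpha: float = DEFAULT_ALPHA
    swc_multiplier: float = DEFAULT_SWC_MULTIPLIER
    cv_method: Literal["per_subject", "pooled"] = "per_subject"
    levene_center: Literal["mean", "median"] = "mean"
    sd_pool_method: Literal["per_session", "centered_cells"] = "per_session"
    schema: Mapping[str, str] | None = None
    out_dir: str | Path | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "variables" in kwargs and kwargs["variables"]:
            kwargs["variables"] = [Variable(v) for v in kwargs["variables"]]
        if "rules" in kwargs and kwargs["rules"]:
            kwargs["rules"] = {
                Variable(v): [AggregationRule(r) for r in rs]
                for v, rs in kwargs["rules"].items()
            }
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**kwargs)


@dataclass
class RunReport:
    """Everything one run computed, in analysis order."""

    reliability: list[ReliabilityResult] = field(default_factory=list)
    sensitivity: list[SensitivityResult] = field(default_factory=list)
    gates: dict[tuple[str, str], list[GateResult]] = field(default_factory=dict)
    session_order: list[str] = field(default_factory=list)

    def reliability_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.reliability:
            rows.append({
                "variable": r.variable.value, "rule": r.rule.value,
                "comparison": r.label, "n_subjects": r.n_subjects,
                "icc": r.icc.estimate, "icc_ci_low": r.icc.ci_low,
                "icc_ci_high": r.icc.ci_high, "icc_form": r.icc.form,
                "classification": r.icc.classification, "cv_pct": r.cv_pct,
                "bias_f": r.bias.f_stat, "bias_p": r.bias.p_value,
                "bias_significant": r.bias.significant,
                **{f"mean_{s}": m for s, m in zip(r.comparison, r.session_means)},
                **{f"sd_{s}": sd for s, sd in zip(r.comparison, r.session_sds)},
            })
        return pd.DataFrame(rows)

    def sensitivity_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.sensitivity:
            rows.append({
                "variable": r.variable.value, "rule": r.rule.value,
                "comparison": r.label, "icc": r.icc_estimate,
                "sd_pooled": r.pooled.sd_pooled, "mean_pooled": r.pooled.mean_pooled,
                "sem": r.sem, "sem_pct": r.sem_pct, "swc": r.swc,
                "md": r.md, "md_pct": r.md_pct, "sensitive": r.sensitive,
            })
        return pd.DataFrame(rows)

    def markers(self, variable: Variable, rule: AggregationRule) -> str:
        """Significance markers for the pair comparisons of one table row."""
        out = ""
        for r in self.reliability:
            if (r.variable, r.rule) == (variable, rule) and r.label in _PAIR_MARKERS:
                if r.bias.significant:
                    out += _PAIR_MARKERS[r.label]
        return out


def default_comparisons(session_order: Sequence[str]) -> list[list[str]]:
    """The full design plus every session pair, in chronological order."""
    sessions = list(session_order)
    comps: list[list[str]] = [sessions] if len(sessions) > 2 else []
    for i in range(len(sessions)):
        for j in range(i + 1, len(sessions)):
            comps.append([sessions[i], sessions[j]])
    return comps


def load_dataset(cfg: RunConfig) -> Dataset:
    if cfg.trials_path is None and cfg.hops_path is None:
        raise ConfigError("config names neither a trials file nor a hops file")
    trials = hops = None
    if cfg.trials_path is not None:
        trials = datamodel.read_trials(cfg.trials_path, schema=cfg.schema,
                                       session_order=cfg.session_order)
    if cfg.hops_path is not None:
        hops = datamodel.read_hops(cfg.hops_path,
                                   session_order=cfg.session_order)
    if trials is not None and hops is not None:
        order = cfg.session_order or sorted(
            set(trials.session_order) | set(hops.session_order))
        return Dataset(trials.trials, hops.hops, list(order))
    return trials if trials is not None else hops


def run(cfg: RunConfig, dataset: Dataset | None = None) -> RunReport:
    """Execute the full analysis; deterministic given input and config.

    When ``out_dir`` is set, writes per-test reliability and sensitivity
    tables (rounded, with significance markers), full-precision sidecar
    CSVs and a run log.
    """
    if dataset is None:
        dataset = load_dataset(cfg)
    session_order = list(cfg.session_order or dataset.session_order)
    comparisons = [list(c) for c in (cfg.comparisons or default_comparisons(session_order))]
    for comp in comparisons:
        if len(comp) < 2 or any(s not in session_order for s in comp):
            raise ConfigError(f"invalid comparison {comp}")
    variables = list(cfg.variables or _present_variables(dataset))
    report = RunReport(session_order=session_order)

    for var in variables:
        rules = (cfg.rules or DEFAULT_RULES).get(var, DEFAULT_RULES[var])
        for rule in rules:
            validate_rule(var, rule)
            full = matrix_from_dataset(dataset, var, rule, session_order)
            report.gates[(var.value, rule.value)] = distribution_gates(
                full, alpha=cfg.alpha, levene_center=cfg.levene_center)
            for comp in comparisons:
                label = "all" if comp == session_order else "-".join(comp)
                Y = matrix_from_dataset(dataset, var, rule, comp)
                rel = analyze_reliability(Y, label=label, alpha=cfg.alpha,
                                          cv_method=cfg.cv_method)
                sens = analyze_sensitivity(Y, rel.icc, label=label,
                                           swc_multiplier=cfg.swc_multiplier,
                                           sd_pool_method=cfg.sd_pool_method)
                report.reliability.append(rel)
                report.sensitivity.append(sens)

    if cfg.out_dir is not None:
        write_outputs(report, Path(cfg.out_dir))
    return report


def _present_variables(dataset: Dataset) -> list[Variable]:
    present = [Variable(v) for v in sorted(dataset.trials["variable"].unique())]
    if not dataset.hops.empty:
        for v in (Variable.HOP_PEAK_FORCE, Variable.HOP_CONTACT_TIME):
            if v not in present:
                present.append(v)
    if not present:
        raise InsufficientDataError("dataset contains no variables")
    return present


def write_outputs(report: RunReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    tests = sorted({VARIABLE_TEST[r.variable].value for r in report.reliability})
    for test in tests:
        rel = [r for r in report.reliability
               if VARIABLE_TEST[r.variable].value == test]
        sens = [r for r in report.sensitivity
                if VARIABLE_TEST[r.variable].value == test]
        write_report_table(rel, out_dir / f"{test}_reliability.csv", "reliability")
        write_report_table(sens, out_dir / f"{test}_sensitivity.csv", "sensitivity")
    report.reliability_frame().to_csv(out_dir / "reliability_full.csv", index=False)
    report.sensitivity_frame().to_csv(out_dir / "sensitivity_full.csv", index=False)
    _write_descriptives(report, out_dir / "descriptives.csv")
    logger.info("wrote report tables to %s", out_dir)


def _write_descriptives(report: RunReport, path: Path) -> None:
    groups: dict[tuple, ReliabilityResult] = {}
    for r in report.reliability:
        key = (r.variable, r.rule)
        # prefer the widest comparison for the descriptive columns
        if key not in groups or len(r.comparison) > len(groups[key].comparison):
            groups[key] = r
    rows = []
    for r in groups.values():
        nd = UNIT_DECIMALS[r.variable]
        markers = report.markers(r.variable, r.rule)
        rec = {"variable": r.variable.value, "rule": r.rule.value,
               "n_subjects": r.n_subjects}
        for sess, m, sd in zip(r.comparison, r.session_means, r.session_sds):
            cell = f"{m:.{nd}f} (±{sd:.{nd}f})"
            if sess == r.comparison[-1] and markers:
                cell += f" {markers}"
            rec[sess] = cell
        rows.append(rec)
    pd.DataFrame(rows).to_csv(path, index=False)


def setup_logging(log_path: Path | None = None,
                  verbosity: int = logging.INFO) -> None:
    """Timestamped run log to stderr and optionally to a file."""
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if log_path is not None:
        log_path.parent.mkdir(parents=True, exist_ok=True)
        handlers.append(logging.FileHandler(log_path))
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    for h in handlers:
        h.setFormatter(fmt)
        logger.addHandler(h)
    logger.setLevel(verbosity)
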