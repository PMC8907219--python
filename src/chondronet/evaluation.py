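"""Quantitative and qualitative model evaluation.

Three error metrics over paired (predicted, measured) responses in [-1, 1]:

* ``nmad``  — mean over scored pairs of ``|x - y| / 2``        (in [0, 1])
* ``nrse``  — per-pair ``|x - y|`` divided by the largest pair error
* ``amd``   — ``|mean(ln(x + 2) - ln(y + 2))|``; the absolute value wraps
  the *mean*, so opposite-signed nodal errors can cancel.  That cancelation
  pathology is intentional and regression-tested; use
  :func:`mean_abs_log_deviation` for a per-datum-absolute variant.

Masked pairs are excluded from every metric (including the ``N`` in the
denominators): the convention exists because readouts of a perturbed protein
are not scored in its own experiment.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dynamics import (
    ConvergenceError,
    NodeParameters,
    PerturbationSpec,
    SolverConfig,
    SteadyState,
    response,
)
from .network import RegulatoryNetwork

__all__ = [
    "UndefinedMetricError",
    "nmad",
    "nrse",
    "amd",
    "mean_abs_log_deviation",
    "steady_state_ttest",
    "sign_permutation_test",
    "TTestResult",
    "Experiment",
    "ExperimentalDataset",
    "BehaviorRule",
    "qualitative_score",
    "QualitativeResult",
    "evaluate_dataset",
    "EvaluationReport",
]

MASK_SENTINEL = "NA!self"


class UndefinedMetricError(ValueError):
    """All pairs masked (or no pairs at all): the metric has no value."""


def _paired(predicted, experimental, mask):
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(experimental, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if mask is None:
        keep = np.ones(x.shape, dtype=bool)
    else:
        keep = ~np.asarray(mask, dtype=bool)
        if keep.shape != x.shape:
            raise ValueError("mask shape must match the data")
    return x, y, keep


def nmad(predicted, experimental, mask=None) -> float:
    """Normalized mean absolute deviation over unmasked pairs."""
    x, y, keep = _paired(predicted, experimental, mask)
    if not keep.any():
        raise UndefinedMetricError("nmad undefined: every pair is masked")
    return float(np.abs((x[keep] - y[keep]) / 2.0).sum() / keep.sum())


def nrse(predicted, experimental, mask=None) -> np.ndarray:
    """Per-pair normalized root squared error; masked pairs get NaN.

    When every unmasked error is zero the whole vector is 0 by the
    documented 0/0 convention.
    """
    x, y, keep = _paired(predicted, experimental, mask)
    if not keep.any():
        raise UndefinedMetricError("nrse undefined: every pair is masked")
    err = np.sqrt((x - y) ** 2)
    max_rse = err[keep].max()
    out = np.full(x.shape, np.nan)
    if max_rse == 0.0:
        out[keep] = 0.0
    else:
        out[keep] = err[keep] / max_rse
    return out


def amd(predicted, experimental, mask=None) -> float:
    """Absolute mean difference of log-shifted data (the GA fitness).

    The +2 shift maps [-1, 1] onto [1, 3] so the logarithm is defined and
    positive-bounded; the absolute value is applied to the *mean*.
    """
    x, y, keep = _paired(predicted, experimental, mask)
    if not keep.any():
        raise UndefinedMetricError("amd undefined: every pair is masked")
    diffs = np.log(x[keep] + 2.0) - np.log(y[keep] + 2.0)
    return float(abs(diffs.sum() / keep.sum()))


def mean_abs_log_deviation(predicted, experimental, mask=None) -> float:
    """Per-datum-absolute variant of :func:`amd` (no sign cancelation)."""
    x, y, keep = _paired(predicted, experimental, mask)
    if not keep.any():
        raise UndefinedMetricError("metric undefined: every pair is masked")
    diffs = np.abs(np.log(x[keep] + 2.0) - np.log(y[keep] + 2.0))
    return float(diffs.mean())


# ---------------------------------------------------------------------------
# Steady-state significance
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class TTestResult:
    p_value: float
    significant: bool
    alpha: float
    degenerate: bool = False
    note: str = ""


def _ss_values(ss) -> np.ndarray:
    if isinstance(ss, SteadyState):
        return np.asarray(ss.values, dtype=float)
    return np.asarray(ss, dtype=float)


def steady_state_ttest(ss_a, ss_b, alpha: float = 0.05) -> TTestResult:
    """Paired two-sided t-test across the per-node activations of two
    steady states.

    Zero-variance differences are degenerate: p = 1 (not significant) when
    the constant difference is zero, significant by convention otherwise.
    """
    a = _ss_values(ss_a)
    b = _ss_values(ss_b)
    if a.shape != b.shape:
        raise ValueError("steady states must share the node set")
    if a.size < 2:
        raise ValueError("need at least 2 nodes for a paired t-test")
    diff = a - b
    if np.ptp(diff) <= 1e-12:  # zero variance up to rounding
        if abs(diff.mean()) <= 1e-12:
            return TTestResult(1.0, False, alpha, degenerate=True,
                               note="identical steady states")
        return TTestResult(0.0, True, alpha, degenerate=True,
                           note="constant nonzero shift on every node")
    t_res = stats.ttest_rel(a, b)
    p = float(t_res.pvalue)
    return TTestResult(p, p < alpha, alpha)


def sign_permutation_test(ss_a, ss_b, alpha: float = 0.05,
                          n_resamples: int = 10_000, seed: int = 0) -> TTestResult:
    """Sign-permutation alternative to the paired t-test (mean statistic)."""
    a = _ss_values(ss_a)
    b = _ss_values(ss_b)
    diff = a - b
    if np.ptp(diff) == 0.0 and diff[0] == 0.0:
        return TTestResult(1.0, False, alpha, degenerate=True,
                           note="identical steady states")
    rng = np.random.default_rng(seed)
    observed = abs(diff.mean())
    signs = rng.choice([-1.0, 1.0], size=(n_resamples, diff.size))
    null = np.abs((signs * diff).mean(axis=1))
    p = float((np.sum(null >= observed - 1e-15) + 1) / (n_resamples + 1))
    return TTestResult(p, p < alpha, alpha)


# ---------------------------------------------------------------------------
# Experimental datasets
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Experiment:
    """One perturbation with measured per-node responses in [-1, 1].

    Any perturbed node that carries a measurement is masked automatically
    (the self-readout exclusion rule).
    """

    perturbation: PerturbationSpec
    measured: Mapping[str, float]
    mask: frozenset = frozenset()

    def __post_init__(self):
        for node, value in self.measured.items():
            if not (-1.0 <= value <= 1.0):
                raise ValueError(
                    f"measured[{node!r}] = {value} outside [-1, 1]"
                )
        mask = set(self.mask)
        if not mask <= set(self.measured):
            raise ValueError("mask must be a subset of the measured nodes")
        mask |= self.perturbation.nodes & set(self.measured)
        self.measured = dict(self.measured)
        self.mask = frozenset(mask)

    @property
    def scored_nodes(self) -> list:
        return [n for n in self.measured if n not in self.mask]


@dataclasses.dataclass
class ExperimentalDataset:
    experiments: list

    def __post_init__(self):
        if not all(isinstance(e, Experiment) for e in self.experiments):
            raise TypeError("experiments must be Experiment instances")

    def __len__(self):
        return len(self.experiments)

    def __iter__(self):
        return iter(self.experiments)

    @property
    def measured_nodes(self) -> set:
        out: set = set()
        for exp in self.experiments:
            out |= set(exp.measured)
        return out

    # -- CSV form: one row per experiment ------------------------------
    def to_csv(self, path) -> None:
        nodes = sorted(self.measured_nodes)
        rows = []
        for exp in self.experiments:
            row: dict = {"perturbation": exp.perturbation.to_string()}
            for node in nodes:
                if node not in exp.measured:
                    row[node] = ""
                elif node in exp.mask:
                    row[node] = MASK_SENTINEL
                else:
                    row[node] = format(exp.measured[node], ".17g")
            rows.append(row)
        frame = pd.DataFrame(rows, columns=["perturbation"] + nodes)
        frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ExperimentalDataset":
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        if "perturbation" not in frame.columns:
            raise ValueError("dataset CSV needs a 'perturbation' column")
        nodes = [c for c in frame.columns if c != "perturbation"]
        experiments = []
        for _, row in frame.iterrows():
            perturbation = PerturbationSpec.from_string(row["perturbation"])
            measured: dict = {}
            mask: set = set()
            for node in nodes:
                cell = row[node].strip()
                if not cell:
                    continue
                if cell == MASK_SENTINEL:
                    mask.add(node)
                    # masked self-readouts carry no usable magnitude; store 0
                    measured[node] = 0.0
                else:
                    measured[node] = float(cell)
            experiments.append(Experiment(perturbation, measured, frozenset(mask)))
        return cls(experiments)


def pooled_pairs(dataset: ExperimentalDataset, predictions: Sequence[Mapping[str, float]]):
    """Flatten (prediction, measurement) pairs across experiments.

    ``predictions[i]`` maps node id -> predicted response for experiment i.
    Returns ``(x, y, labels)`` over unmasked pairs only.
    """
    xs, ys, labels = [], [], []
    for i, exp in enumerate(dataset.experiments):
        pred = predictions[i]
        for node in exp.scored_nodes:
            xs.append(float(pred[node]))
            ys.append(float(exp.measured[node]))
            labels.append((i, node))
    return np.array(xs), np.array(ys), labels


# ---------------------------------------------------------------------------
# Qualitative behavior scoring
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class BehaviorRule:
    """Expected direction of a target node under a stimulus."""

    stimulus: PerturbationSpec
    target: str
    expected: str  # up | down | unchanged
    citation: str = ""

    def __post_init__(self):
        if self.expected not in ("up", "down", "unchanged"):
            raise ValueError(f"expected must be up/down/unchanged, got "
                             f"{self.expected!r}")

    def to_line(self) -> str:
        return ";".join(
            (self.stimulus.to_string().replace(";", "|"), self.target,
             self.expected, self.citation)
        )

    @classmethod
    def from_line(cls, line: str) -> "BehaviorRule":
        parts = line.split(";")
        if len(parts) < 3:
            raise ValueError(f"malformed behavior rule {line!r}")
        stimulus = PerturbationSpec.from_string(parts[0].replace("|", ";"))
        citation = parts[3] if len(parts) > 3 else ""
        return cls(stimulus, parts[1], parts[2], citation)


def read_behavior_rules(path) -> list:
    rules = []
    for raw in open(path):
        line = raw.strip()
        if not line or line.startswith("#") or line.startswith("stimulus;"):
            continue
        rules.append(BehaviorRule.from_line(line))
    return rules


def write_behavior_rules(rules: Iterable[BehaviorRule], path) -> None:
    lines = ["stimulus;target;expected;citation"]
    lines += [rule.to_line() for rule in rules]
    with open(path, "w") as handle:
        handle.write("\n".join(lines) + "\n")


@dataclasses.dataclass
class QualitativeResult:
    score: float
    outcomes: list            # dict per rule: expected/observed/matched/...
    n_evaluated: int
    n_unevaluable: int

    @property
    def percentage(self) -> float:
        return 100.0 * self.score


def classify_direction(delta: float, threshold: float) -> str:
    if delta > threshold:
        return "up"
    if delta < -threshold:
        return "down"
    return "unchanged"


def qualitative_score(
    net: RegulatoryNetwork,
    params: Optional[NodeParameters],
    rules: Sequence[BehaviorRule],
    direction_threshold: float = 0.1,
    seed: int = 0,
    solver: Optional[SolverConfig] = None,
) -> QualitativeResult:
    """Fraction of behavior rules whose simulated response direction matches.

    Rules whose simulation fails to converge are marked unevaluable and
    excluded from the denominator.
    """
    if not rules:
        raise UndefinedMetricError("qualitative score undefined for an "
                                   "empty rule list")
    for rule in rules:
        if not net.has_node(rule.target):
            raise KeyError(f"behavior rule targets unknown node "
                           f"{rule.target!r}")
    outcomes = []
    matched = 0
    unevaluable = 0
    for rule in rules:
        record = {
            "stimulus": rule.stimulus.to_string(),
            "target": rule.target,
            "expected": rule.expected,
            "citation": rule.citation,
        }
        try:
            resp = response(net, params, rule.stimulus, seed=seed, solver=solver)
        except ConvergenceError:
            unevaluable += 1
            record.update(observed=None, matched=None, evaluable=False)
            outcomes.append(record)
            continue
        delta = resp[rule.target]
        observed = classify_direction(delta, direction_threshold)
        ok = observed == rule.expected
        matched += ok
        record.update(observed=observed, delta=delta, matched=ok,
                      evaluable=True)
        outcomes.append(record)
    evaluated = len(rules) - unevaluable
    if evaluated == 0:
        raise UndefinedMetricError("no behavior rule could be evaluated")
    return QualitativeResult(
        score=matched / evaluated,
        outcomes=outcomes,
        n_evaluated=evaluated,
        n_unevaluable=unevaluable,
    )


# ---------------------------------------------------------------------------
# Dataset-level evaluation report
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class EvaluationReport:
    nmad: float
    amd: float
    nrse: dict                  # (experiment index, node) -> value
    qualitative_accuracy: Optional[float] = None
    per_rule: Optional[list] = None
    n_pairs: int = 0
    notes: dict = dataclasses.field(default_factory=dict)

    @property
    def nmad_percent(self) -> float:
        return 100.0 * self.nmad

    def to_json_lines(self) -> str:
        lines = [json.dumps({
            "record": "summary",
            "nmad": self.nmad,
            "nmad_percent": self.nmad_percent,
            "amd": self.amd,
            "qualitative_accuracy": self.qualitative_accuracy,
            "n_pairs": self.n_pairs,
            "notes": self.notes,
        })]
        for (index, node), value in self.nrse.items():
            lines.append(json.dumps({
                "record": "nrse", "experiment": index, "node": node,
                "value": value,
            }))
        for record in self.per_rule or []:
            lines.append(json.dumps({"record": "rule", **record}))
        return "\n".join(lines) + "\n"

    def summary_text(self) -> str:
        lines = [
            f"NMAD: {self.nmad:.6f} ({self.nmad_percent:.4f}%)",
            f"AMD:  {self.amd:.6f}",
            f"scored pairs: {self.n_pairs}",
        ]
        if self.qualitative_accuracy is not None:
            lines.append(
                "qualitative accuracy: "
                f"{self.qualitative_accuracy:.4f} "
                f"({100.0 * self.qualitative_accuracy:.1f}%)"
            )
        if self.nrse:
            values = np.array(list(self.nrse.values()))
            lines.append(
                f"NRSE: median {np.median(values):.4f}, "
                f"max {values.max():.4f}, "
                f"share < 0.15: {(values < 0.15).mean():.3f}"
            )
        for key, value in self.notes.items():
            lines.append(f"{key}: {value}")
        return "\n".join(lines) + "\n"


def evaluate_dataset(
    net: RegulatoryNetwork,
    params: Optional[NodeParameters],
    dataset: ExperimentalDataset,
    seed: int = 0,
    solver: Optional[SolverConfig] = None,
    rules: Optional[Sequence[BehaviorRule]] = None,
    direction_threshold: float = 0.1,
) -> EvaluationReport:
    """Simulate every experiment and score the model against the dataset."""
    missing = {
        n for exp in dataset for n in exp.measured if not net.has_node(n)
    }
    missing |= {
        n for exp in dataset for n in exp.perturbation.nodes
        if not net.has_node(n)
    }
    if missing:
        raise KeyError(
            f"dataset references nodes absent from the network: "
            f"{sorted(missing)}"
        )
    predictions = []
    for exp in dataset:
        resp = response(net, params, exp.perturbation, seed=seed, solver=solver)
        predictions.append(resp.as_dict())
    x, y, labels = pooled_pairs(dataset, predictions)
    if x.size == 0:
        raise UndefinedMetricError("no unmasked pairs to score")
    nrse_values = nrse(x, y)
    report = EvaluationReport(
        nmad=nmad(x, y),
        amd=amd(x, y),
        nrse={label: float(v) for label, v in zip(labels, nrse_values)},
        n_pairs=int(x.size),
    )
    if rules:
        qual = qualitative_score(net, params, rules,
                                 direction_threshold=direction_threshold,
                                 seed=seed, solver=solver)
        report.qualitative_accuracy = qual.score
        report.per_rule = qual.outcomes
        # sensitivity of the direction call to the threshold choice
        for alt in (0.05, 0.1, 0.2):
            alt_q = qualitative_score(net, params, rules,
                                      direction_threshold=alt,
                                      seed=seed, solver=solver)
            report.notes[f"qualitative_accuracy@threshold={alt}"] = alt_q.score
    return report
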