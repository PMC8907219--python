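"""Canned treatment experiments: OA induction and the three ACS scenarios.

OA induction clamps the six pro-inflammatory cytokines (IL1B, TNFA, IL6,
IL8, IL17, IL18) at 1 and integrates to the "OA-like" steady state.  The
blood-derivative treatment (ACS) clamps its anabolic cargo (TGFB, IGF1,
IL4, IL10) at 1 and models the IL-1 antagonist as IL1B clamped to 0.  The
three scenarios differ in what happens to the remaining five catabolic
cytokines:

* ``acs1`` — left free to be regulated by the network;
* ``acs2`` — clamped at 1 (sustained synovitis);
* ``acs3`` — clamped at 0.5 (partially mitigated synovitis).

Treatment integrations start from the OA-like steady state and are compared
against it with a paired t-test (alpha = 0.05 by default).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .dynamics import (
    NodeParameters,
    PerturbationSpec,
    SolverConfig,
    SteadyState,
    baseline,
    integrate_to_steady_state,
)
from .evaluation import TTestResult, steady_state_ttest
from .network import RegulatoryNetwork

__all__ = [
    "PROINFLAMMATORY_STIMULUS",
    "ACS_NODES",
    "ACS_ANTAGONIZED",
    "MissingNodeError",
    "ScenarioDefinition",
    "ScenarioResult",
    "builtin_scenarios",
    "oa_induction",
    "acs_scenario",
    "run_scenario",
    "run_scenario_suite",
]

#: The six cytokines clamped at 1 to induce the OA-like steady state.
PROINFLAMMATORY_STIMULUS = ("IL1B", "TNFA", "IL6", "IL8", "IL17", "IL18")
#: Anabolic cargo of the blood-derived treatment, clamped at 1.
ACS_NODES = ("TGFB", "IGF1", "IL4", "IL10")
#: The antagonized cytokine, modeled as a clamp to 0.
ACS_ANTAGONIZED = "IL1B"
#: The catabolic cytokines the three scenarios treat differently.
CATABOLIC_FREE = tuple(n for n in PROINFLAMMATORY_STIMULUS if n != ACS_ANTAGONIZED)


class MissingNodeError(KeyError):
    """The network lacks nodes a scenario requires; lists the absent ids."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(f"network lacks required nodes: {', '.join(self.missing)}")


@dataclasses.dataclass(frozen=True)
class ScenarioDefinition:
    name: str
    precondition: PerturbationSpec
    treatment: PerturbationSpec
    comparison: str = "vs_oa_ss"  # or "vs_baseline"

    def __post_init__(self):
        if self.comparison not in ("vs_oa_ss", "vs_baseline"):
            raise ValueError(f"unknown comparison {self.comparison!r}")


def builtin_scenarios() -> dict:
    oa = PerturbationSpec(clamps={n: 1.0 for n in PROINFLAMMATORY_STIMULUS})
    acs_base = {n: 1.0 for n in ACS_NODES}
    acs_base[ACS_ANTAGONIZED] = 0.0
    return {
        "acs1": ScenarioDefinition(
            "acs1", oa, PerturbationSpec(clamps=dict(acs_base))
        ),
        "acs2": ScenarioDefinition(
            "acs2", oa,
            PerturbationSpec(
                clamps={**acs_base, **{n: 1.0 for n in CATABOLIC_FREE}}
            ),
        ),
        "acs3": ScenarioDefinition(
            "acs3", oa,
            PerturbationSpec(
                clamps={**acs_base, **{n: 0.5 for n in CATABOLIC_FREE}}
            ),
        ),
    }


@dataclasses.dataclass
class ScenarioResult:
    name: str
    oa_ss: SteadyState
    treated_ss: SteadyState
    ttest: TTestResult
    deltas: dict  # node id -> treated - reference


def _require_nodes(net: RegulatoryNetwork, nodes) -> None:
    missing = [n for n in nodes if not net.has_node(n)]
    if missing:
        raise MissingNodeError(missing)


def oa_induction(
    net: RegulatoryNetwork,
    params: Optional[NodeParameters] = None,
    solver: Optional[SolverConfig] = None,
) -> SteadyState:
    """Clamp the six pro-inflammatory cytokines at 1; integrate to SS."""
    _require_nodes(net, PROINFLAMMATORY_STIMULUS)
    perturbation = PerturbationSpec(
        clamps={n: 1.0 for n in PROINFLAMMATORY_STIMULUS}
    )
    return integrate_to_steady_state(net, params, perturbation, solver=solver)


def run_scenario(
    net: RegulatoryNetwork,
    definition: ScenarioDefinition,
    params: Optional[NodeParameters] = None,
    alpha: float = 0.05,
    solver: Optional[SolverConfig] = None,
    seed: int = 0,
) -> ScenarioResult:
    """Run one scenario: precondition SS, then treatment from that state."""
    _require_nodes(
        net, set(definition.precondition.nodes) | set(definition.treatment.nodes)
    )
    pre_ss = integrate_to_steady_state(
        net, params, definition.precondition, solver=solver
    )
    # treatment starts from the preconditioned steady state
    initial = {
        n: pre_ss[n] for n in net.node_ids
        if n not in definition.treatment.clamps
    }
    treatment = PerturbationSpec(
        initial={**initial, **definition.treatment.initial},
        clamps=definition.treatment.clamps,
    )
    treated_ss = integrate_to_steady_state(net, params, treatment, solver=solver)
    if definition.comparison == "vs_baseline":
        reference = baseline(net, params, seed=seed, solver=solver)
    else:
        reference = pre_ss
    ttest = steady_state_ttest(treated_ss, reference, alpha=alpha)
    deltas = {
        n: treated_ss[n] - reference[n] for n in net.node_ids
    }
    return ScenarioResult(
        name=definition.name,
        oa_ss=pre_ss,
        treated_ss=treated_ss,
        ttest=ttest,
        deltas=deltas,
    )


def acs_scenario(
    net: RegulatoryNetwork,
    params: Optional[NodeParameters] = None,
    scenario_id: int = 1,
    alpha: float = 0.05,
    solver: Optional[SolverConfig] = None,
) -> ScenarioResult:
    """Run built-in scenario 1, 2 or 3 (see module docstring)."""
    if scenario_id not in (1, 2, 3):
        raise ValueError("scenario_id must be 1, 2 or 3")
    _require_nodes(net, ACS_NODES + (ACS_ANTAGONIZED,))
    definition = builtin_scenarios()[f"acs{scenario_id}"]
    return run_scenario(net, definition, params=params, alpha=alpha,
                        solver=solver)


# ---------------------------------------------------------------------------
# Suite runner
# ---------------------------------------------------------------------------

def _write_ss_csv(path, ss: SteadyState, header_comment: str) -> None:
    lines = [f"# {header_comment}", "node,value"]
    lines += [
        f"{n},{format(float(v), '.12g')}" for n, v in zip(ss.node_ids, ss.values)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def _write_delta_csv(path, deltas: dict, header_comment: str) -> None:
    lines = [f"# {header_comment}", "node,delta"]
    lines += [f"{n},{format(float(v), '.12g')}" for n, v in deltas.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def _bar_chart(path, result: ScenarioResult) -> None:
    from matplotlib.backends.backend_agg import FigureCanvasAgg
    from matplotlib.figure import Figure

    figure = Figure(figsize=(max(6, len(result.oa_ss.node_ids) * 0.35), 4))
    FigureCanvasAgg(figure)
    ax = figure.add_subplot(111)
    nodes = result.oa_ss.node_ids
    positions = np.arange(len(nodes))
    width = 0.4
    ax.bar(positions - width / 2, result.oa_ss.values, width,
           label="OA-like SS", color="#d95f02")
    ax.bar(positions + width / 2, result.treated_ss.values, width,
           label="treated SS", color="#1b9e77")
    ax.set_xticks(positions)
    ax.set_xticklabels(nodes, rotation=90, fontsize=7)
    ax.set_ylabel("activation")
    ax.set_ylim(0, 1.05)
    ax.set_title(
        f"{result.name}: p={result.ttest.p_value:.3g} "
        f"({'significant' if result.ttest.significant else 'n.s.'})"
    )
    ax.legend(fontsize=8)
    figure.tight_layout()
    figure.savefig(path, dpi=120, metadata={"Software": "chondronet"})


def run_scenario_suite(
    net: RegulatoryNetwork,
    out_dir,
    params: Optional[NodeParameters] = None,
    scenarios: Optional[Sequence] = None,
    alpha: float = 0.05,
    solver: Optional[SolverConfig] = None,
    make_figures: bool = True,
    solver_note: str = "",
) -> dict:
    """Run a list of scenarios, writing SS/delta CSVs, t-test records and a
    bar chart per scenario.  Per-scenario failures are recorded and the
    suite continues."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if scenarios is None:
        scenarios = list(builtin_scenarios().values())
    resolved = []
    builtins = builtin_scenarios()
    for scenario in scenarios:
        if isinstance(scenario, str):
            if scenario not in builtins:
                raise ValueError(f"unknown built-in scenario {scenario!r}")
            resolved.append(builtins[scenario])
        else:
            resolved.append(scenario)
    solver = solver or SolverConfig()
    comment = (
        f"solver={solver.method} step={solver.step} tol={solver.tol} "
        f"t_max={solver.t_max}"
    )
    if solver_note:
        comment += f" {solver_note}"
    report = {"scenarios": [], "failures": []}
    for definition in resolved:
        try:
            result = run_scenario(net, definition, params=params, alpha=alpha,
                                  solver=solver)
        except Exception as exc:  # keep going, report the failure
            report["failures"].append(
                {"scenario": definition.name, "error": str(exc)}
            )
            continue
        _write_ss_csv(out_dir / f"{definition.name}_oa_ss.csv",
                      result.oa_ss, comment)
        _write_ss_csv(out_dir / f"{definition.name}_treated_ss.csv",
                      result.treated_ss, comment)
        _write_delta_csv(out_dir / f"{definition.name}_deltas.csv",
                         result.deltas, comment)
        if make_figures:
            _bar_chart(out_dir / f"{definition.name}_bars.png", result)
        report["scenarios"].append({
            "name": definition.name,
            "p_value": result.ttest.p_value,
            "significant": result.ttest.significant,
            "degenerate": result.ttest.degenerate,
            "converged": result.treated_ss.converged,
        })
    (out_dir / "ttest_summary.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    return report
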