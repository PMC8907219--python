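"""Synthetic ground-truth networks and perturbation-response datasets.

The generator mirrors the *structure* of multiplexed cytokine-release
experiments — a set of single (80%) or paired (20%) node stimulations
clamped at 1, per-node responses normalized to [-1, 1], and self-readouts
masked — without any claim of matching real assay distributions.  Noise is
additive Gaussian, clipped to the response range.

Also packaged here: a 28-node illustrative chondrocyte network covering the
standard cytokine/enzyme/structural vocabulary.  Its edge list is
literature-motivated but *illustrative only* — it is not a published
topology and must not be mistaken for one.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import networkx as nx
import numpy as np

from .dynamics import (
    NodeParameters,
    PerturbationSpec,
    SolverConfig,
    _integrate_batch,
    baseline,
    CompiledSystem,
)
from .evaluation import Experiment, ExperimentalDataset
from .network import (
    Edge,
    Node,
    Provenance,
    RegulatoryNetwork,
    Role,
    Sign,
)

__all__ = [
    "SyntheticSpec",
    "generate_network",
    "generate_dataset",
    "fixture_chondrocyte_network",
    "FIXTURE_ACCESSION_TO_NODE",
]

_ROLE_CYCLE = (
    Role.PRO_INFLAMMATORY,
    Role.ANTI_INFLAMMATORY,
    Role.GROWTH_FACTOR,
    Role.DEGRADING_ENZYME,
    Role.STRUCTURAL_PROTEIN,
    Role.PAIN_RELATED,
    Role.APOPTOSIS_RELATED,
    Role.OTHER,
)


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    n_nodes: int = 12
    edge_density: float = 0.15
    activation_fraction: float = 0.7
    n_experiments: int = 8
    noise_sd: float = 0.0
    mask_self_readouts: bool = True
    pair_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")
        if self.n_experiments < 1:
            raise ValueError("n_experiments must be >= 1")
        if not (0.0 < self.edge_density <= 1.0):
            raise ValueError("edge_density must be in (0, 1]")
        if not (0.0 <= self.activation_fraction <= 1.0):
            raise ValueError("activation_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def generate_network(spec: SyntheticSpec) -> RegulatoryNetwork:
    """Random signed digraph, every node reachable from an input node.

    A fifth of the nodes (at least one) are designated inputs with no
    incoming edges; remaining nodes are first wired into a random
    arborescence to guarantee reachability, then extra edges are sampled up
    to the requested density.  Roles rotate through the standard vocabulary;
    deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_nodes
    n_inputs = max(1, round(0.2 * n))
    names = [f"N{i:02d}" for i in range(n)]
    net = RegulatoryNetwork(
        Node(name, role=_ROLE_CYCLE[i % len(_ROLE_CYCLE)])
        for i, name in enumerate(names)
    )
    inputs = names[:n_inputs]
    downstream = names[n_inputs:]
    possible = [
        (s, t) for s in names for t in downstream if s != t
    ]
    n_edges = max(len(downstream), round(spec.edge_density * len(possible)))
    if n_edges > len(possible):
        raise ValueError(
            "edge_density too low/high to connect the requested graph"
        )

    def sign_for():
        return (
            Sign.ACTIVATION
            if rng.random() < spec.activation_fraction
            else Sign.INHIBITION
        )

    # spanning wiring: each downstream node gets one edge from the already
    # reachable set, so everything is reachable from an input
    reachable = list(inputs)
    for target in downstream:
        source = reachable[int(rng.integers(len(reachable)))]
        net.add_edge(Edge(source, target, sign_for(),
                          provenance=Provenance.SYNTHETIC))
        reachable.append(target)
    used = {(e.source, e.target) for e in net.edges}
    remaining = [p for p in possible if p not in used]
    extra = n_edges - len(net.edges)
    if extra > 0:
        chosen = rng.choice(len(remaining), size=min(extra, len(remaining)),
                            replace=False)
        for idx in sorted(int(i) for i in chosen):
            source, target = remaining[idx]
            net.add_edge(Edge(source, target, sign_for(),
                              provenance=Provenance.SYNTHETIC))
    graph = nx.DiGraph((e.source, e.target) for e in net.edges)
    graph.add_nodes_from(names)
    covered = set(inputs)
    for node in inputs:
        covered |= nx.descendants(graph, node)
    if covered != set(names):  # pragma: no cover - construction guarantees it
        raise RuntimeError("generator failed to connect the network")
    return net


def generate_dataset(
    net: RegulatoryNetwork,
    spec: SyntheticSpec,
    params: Optional[NodeParameters] = None,
    solver: Optional[SolverConfig] = None,
    max_retries: int = 50,
) -> ExperimentalDataset:
    """Stimulation experiments with model-truth responses plus noise.

    Each experiment clamps one (or, with probability ``pair_fraction``, two)
    stimulus nodes at 1; the true response is computed with the dynamics
    module against the seeded baseline; Gaussian noise (sd ``noise_sd``) is
    added and clipped to [-1, 1]; stimulated readouts are masked when
    ``mask_self_readouts``.  Non-converged truth simulations are regenerated
    with a different stimulus (counted via the returned dataset's
    ``regenerated`` attribute).
    """
    rng = np.random.default_rng(spec.seed)
    params = params or NodeParameters()
    solver = solver or SolverConfig()
    system = CompiledSystem(net, params)
    node_ids = list(net.node_ids)
    base_ss = baseline(net, params, seed=spec.seed, solver=solver)
    if not base_ss.converged:
        raise RuntimeError("baseline simulation did not converge")

    experiments = []
    regenerated = 0
    attempts = 0
    while len(experiments) < spec.n_experiments:
        if attempts > spec.n_experiments + max_retries:
            raise RuntimeError(
                "too many non-converged experiments; relax the solver "
                "settings or change the topology"
            )
        attempts += 1
        k = 2 if rng.random() < spec.pair_fraction else 1
        stimuli = [
            node_ids[int(i)]
            for i in rng.choice(len(node_ids), size=k, replace=False)
        ]
        perturbation = PerturbationSpec(clamps={s: 1.0 for s in stimuli})
        x0, cmask, cvals = system.perturbation_arrays(perturbation)
        # boundary inputs (unclamped sources) carry their baseline value
        x0 = np.where(system.source_mask & ~cmask, base_ss.values, x0)
        result = _integrate_batch(
            system.wa, system.wb, system.h, system.gamma,
            x0[None, :], cmask[None, :], cvals[None, :],
            solver, "hold", system.node_ids,
        )
        if not result.converged[0]:
            regenerated += 1
            continue
        truth = result.x[0] - base_ss.values
        noisy = truth + rng.normal(0.0, spec.noise_sd, size=truth.shape) \
            if spec.noise_sd > 0 else truth.copy()
        noisy = np.clip(noisy, -1.0, 1.0)
        measured = {n: float(v) for n, v in zip(node_ids, noisy)}
        mask = (
            frozenset(s for s in stimuli if s in measured)
            if spec.mask_self_readouts else frozenset()
        )
        experiments.append(Experiment(perturbation, measured, mask))
    dataset = ExperimentalDataset(experiments)
    dataset.regenerated = regenerated
    return dataset


# ---------------------------------------------------------------------------
# Illustrative chondrocyte fixture
# ---------------------------------------------------------------------------

_FIXTURE_NODES = (
    # id, role, accession
    ("IL1B", Role.PRO_INFLAMMATORY, "P01584"),
    ("TNFA", Role.PRO_INFLAMMATORY, "P01375"),
    ("IL6", Role.PRO_INFLAMMATORY, "P05231"),
    ("IL8", Role.PRO_INFLAMMATORY, "P10145"),
    ("IL17", Role.PRO_INFLAMMATORY, "Q16552"),
    ("IL18", Role.PRO_INFLAMMATORY, "Q14116"),
    ("LIF", Role.PRO_INFLAMMATORY, None),
    ("IFNG", Role.PRO_INFLAMMATORY, None),
    ("TGFB", Role.GROWTH_FACTOR, "P01137"),
    ("FGF2", Role.GROWTH_FACTOR, "P09038"),
    ("BMP2", Role.GROWTH_FACTOR, "P12643"),
    ("IGF1", Role.GROWTH_FACTOR, "P05019"),
    ("IL4", Role.ANTI_INFLAMMATORY, "P05112"),
    ("IL10", Role.ANTI_INFLAMMATORY, "P22301"),
    ("IL13", Role.ANTI_INFLAMMATORY, "P35225"),
    ("MMP1", Role.DEGRADING_ENZYME, "P03956"),
    ("MMP3", Role.DEGRADING_ENZYME, "P08254"),
    ("MMP13", Role.DEGRADING_ENZYME, "P45452"),
    ("ADAMTS", Role.DEGRADING_ENZYME, "O75173"),
    ("TIMP", Role.ANTI_INFLAMMATORY, "P01033"),
    ("COL2A", Role.STRUCTURAL_PROTEIN, "P02458"),
    ("ACAN", Role.STRUCTURAL_PROTEIN, "P16112"),
    ("VEGF", Role.PAIN_RELATED, "P15692"),
    ("PGE2", Role.PAIN_RELATED, None),
    ("NO", Role.OTHER, None),
    ("ROS", Role.OTHER, None),
    ("CYCS", Role.APOPTOSIS_RELATED, "P99999"),
    ("CASP8", Role.APOPTOSIS_RELATED, "Q14790"),
)

#: The 24 enrichment accessions mapped onto fixture nodes.  Most are the
#: canonical protein for the node; P50281 (a membrane-anchored collagenase)
#: is folded into the MMP13 grouping node, since the fixture models the
#: matrix-metalloproteinase families as grouped readouts.
FIXTURE_ACCESSION_TO_NODE = {
    "P02458": "COL2A", "P10145": "IL8", "P05231": "IL6", "Q14116": "IL18",
    "P16112": "ACAN", "O75173": "ADAMTS", "P01137": "TGFB",
    "P50281": "MMP13", "P45452": "MMP13", "P03956": "MMP1",
    "P01375": "TNFA", "Q16552": "IL17", "P22301": "IL10", "P35225": "IL13",
    "P05112": "IL4", "P12643": "BMP2", "P05019": "IGF1", "P09038": "FGF2",
    "P99999": "CYCS", "Q14790": "CASP8", "P01033": "TIMP", "P15692": "VEGF",
    "P01584": "IL1B", "P08254": "MMP3",
}

# (source, sign token, target, provenance)
_FIXTURE_EDGES = (
    # pro-inflammatory drive of matrix degradation
    ("IL1B", "+", "IL1B", "literature"),    # autocrine amplification
    ("IL1B", "+", "IL6", "literature"),
    ("IL1B", "+", "IL8", "literature"),
    ("IL1B", "+", "MMP1", "literature"),
    ("IL1B", "+", "MMP3", "literature"),
    ("IL1B", "+", "MMP13", "literature"),
    ("IL1B", "+", "ADAMTS", "literature"),
    ("IL1B", "+", "NO", "literature"),
    ("IL1B", "+", "PGE2", "literature"),
    ("IL1B", "-", "COL2A", "literature"),
    ("IL1B", "-", "ACAN", "literature"),
    ("IL1B", "-", "TGFB", "enrichment"),
    ("TNFA", "+", "IL6", "literature"),
    ("TNFA", "+", "MMP1", "literature"),
    ("TNFA", "+", "MMP3", "literature"),
    ("TNFA", "+", "MMP13", "literature"),
    ("TNFA", "+", "NO", "literature"),
    ("TNFA", "-", "COL2A", "literature"),
    ("TNFA", "-", "TGFB", "enrichment"),
    ("IL6", "+", "MMP13", "literature"),
    ("IL6", "+", "VEGF", "literature"),
    ("IL8", "+", "MMP3", "literature"),
    ("IL17", "+", "IL6", "literature"),
    ("IL17", "+", "IL8", "literature"),
    ("IL17", "+", "MMP13", "literature"),
    ("IL18", "+", "IFNG", "literature"),
    ("IL18", "+", "MMP3", "literature"),
    ("LIF", "+", "IL6", "literature"),
    ("LIF", "+", "MMP3", "literature"),
    ("IFNG", "+", "NO", "literature"),
    # anabolic axis
    ("TGFB", "+", "COL2A", "literature"),
    ("TGFB", "+", "ACAN", "literature"),
    ("TGFB", "+", "TIMP", "literature"),
    ("TGFB", "-", "MMP13", "literature"),
    ("FGF2", "+", "MMP13", "literature"),
    ("FGF2", "-", "ACAN", "literature"),
    ("BMP2", "+", "COL2A", "literature"),
    ("BMP2", "+", "ACAN", "literature"),
    ("IGF1", "+", "COL2A", "literature"),
    ("IGF1", "+", "ACAN", "literature"),
    ("IGF1", "+", "TIMP", "literature"),
    # anti-inflammatory modulation
    ("IL4", "+", "IL10", "enrichment"),
    ("IL4", "+", "IL13", "enrichment"),
    ("IL4", "-", "TNFA", "literature"),
    ("IL4", "-", "IL1B", "literature"),
    ("IL10", "-", "TNFA", "literature"),
    ("IL10", "-", "IL1B", "literature"),
    ("IL13", "-", "MMP3", "literature"),
    ("IL13", "-", "IL1B", "literature"),
    ("TIMP", "-", "MMP1", "literature"),
    ("TIMP", "-", "MMP3", "literature"),
    ("TIMP", "-", "MMP13", "literature"),
    ("TIMP", "-", "ADAMTS", "literature"),
    # oxidative / nociceptive / apoptotic arm
    ("NO", "+", "IL18", "literature"),
    ("NO", "+", "CYCS", "literature"),
    ("NO", "+", "CASP8", "literature"),
    ("NO", "+", "MMP13", "literature"),
    ("NO", "-", "COL2A", "literature"),
    ("ROS", "+", "NO", "literature"),
    ("ROS", "+", "CASP8", "literature"),
    ("PGE2", "+", "VEGF", "literature"),
    ("PGE2", "+", "IL6", "literature"),
    ("CYCS", "+", "CASP8", "literature"),
    ("MMP13", "-", "COL2A", "literature"),
    ("ADAMTS", "-", "ACAN", "literature"),
)


def fixture_chondrocyte_network() -> RegulatoryNetwork:
    """The packaged 28-node illustrative chondrocyte network.

    Edge choices are motivated by well-known chondrocyte signaling examples
    (e.g. pro-inflammatory induction of metalloproteinases, growth-factor
    support of structural proteins, anti-inflammatory inhibition of the
    cytokine axis) — but the topology is ILLUSTRATIVE, assembled for testing
    and demonstration, and is not a published model.
    """
    net = RegulatoryNetwork(
        Node(node_id, role=role, accession=accession)
        for node_id, role, accession in _FIXTURE_NODES
    )
    for source, token, target, provenance in _FIXTURE_EDGES:
        net.add_edge(Edge(
            source, target, Sign.from_token(token),
            provenance=Provenance(provenance),
        ))
    return net
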