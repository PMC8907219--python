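"""Genetic-algorithm topology calibration.

A candidate genome is a binary vector over the *mutable* edges of a template
network (1 = edge kept); immutable edges are always present.  The search
only deletes edges — it never adds interactions or flips signs.  Fitness is
the pooled AMD between simulated and measured perturbation responses, with
an optional penalty on a catabolic baseline.  Simulations that fail to
converge poison the genome with ``+inf`` rather than being skipped.

The evaluator batches all (genome, experiment) integrations through the
vectorized RK4 core and memoizes fitness per genome, so repeated GA runs
and exhaustive enumerations over the same problem share work.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Sequence

import numpy as np

from . import evaluation
from .dynamics import (
    NodeParameters,
    SolverConfig,
    _integrate_batch,
    baseline_initial_condition,
)
from .evaluation import ExperimentalDataset
from .network import Provenance, RegulatoryNetwork, Role, Sign

__all__ = [
    "GAConfig",
    "FitnessEvaluator",
    "RepeatResult",
    "CalibrationResult",
    "FinalCandidate",
    "decode",
    "fitness",
    "run_ga",
    "select_final",
    "genome_jaccard",
    "mutable_edges",
]

CATABOLIC_ROLES = (Role.PRO_INFLAMMATORY, Role.DEGRADING_ENZYME)


@dataclasses.dataclass(frozen=True)
class GAConfig:
    population_size: int = 50
    generations: int = 100
    crossover_rate: float = 0.8
    mutation_rate: Optional[float] = None  # None -> 1 / genome length
    elitism: int = 2
    tournament_size: int = 3
    seed: int = 0
    repeats: int = 100
    fitness: str = "amd"  # or "amd_with_baseline_penalty"
    penalty_weight: float = 0.0
    target_fitness: Optional[float] = None  # stop a repeat early at/below
    seed_with_template: bool = False  # include the all-ones genome initially

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        for name in ("crossover_rate",):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.mutation_rate is not None and not (0.0 <= self.mutation_rate <= 1.0):
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.fitness not in ("amd", "amd_with_baseline_penalty"):
            raise ValueError(f"unknown fitness {self.fitness!r}")
        if self.penalty_weight < 0:
            raise ValueError("penalty_weight must be >= 0")
        if self.elitism < 0 or self.elitism >= self.population_size:
            raise ValueError("elitism must be in [0, population_size)")


def mutable_edges(net: RegulatoryNetwork) -> list:
    """The ordered mutable edge set the genome ranges over."""
    return [e for e in net.edges if e.mutable]


def decode(genome, template: RegulatoryNetwork) -> RegulatoryNetwork:
    """Materialize the subnetwork selected by ``genome``.

    Retained mutable edges get provenance ``optimized``; all immutable edges
    and every node are carried over unchanged.
    """
    bits = np.asarray(genome).astype(bool).ravel()
    candidates = mutable_edges(template)
    if bits.size != len(candidates):
        raise ValueError(
            f"genome length {bits.size} != mutable edge count {len(candidates)}"
        )
    kept = {id(e) for e, b in zip(candidates, bits) if b}
    result = RegulatoryNetwork(
        (dataclasses.replace(n) for n in template.nodes)
    )
    for edge in template.edges:
        if not edge.mutable:
            result.add_edge(dataclasses.replace(edge))
        elif id(edge) in kept:
            result.add_edge(
                dataclasses.replace(edge, provenance=Provenance.OPTIMIZED)
            )
    return result


def genome_jaccard(bits_a, bits_b) -> float:
    """Jaccard similarity of two kept-edge sets over the same candidate list."""
    a = np.asarray(bits_a).astype(bool)
    b = np.asarray(bits_b).astype(bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


class FitnessEvaluator:
    """Batched, memoized fitness of genomes against a dataset.

    For each genome: compute the baseline steady state (seeded random
    initial condition), simulate every experiment (clamps + overrides,
    zero default initial values), subtract the baseline, and pool the
    unmasked (prediction, measurement) pairs into one AMD value.
    """

    def __init__(
        self,
        template: RegulatoryNetwork,
        dataset: ExperimentalDataset,
        params: Optional[NodeParameters] = None,
        solver: Optional[SolverConfig] = None,
        baseline_seed: int = 0,
        fitness_kind: str = "amd",
        penalty_weight: float = 0.0,
        chunk_size: int = 256,
    ):
        if len(dataset) == 0:
            raise ValueError("dataset must be non-empty")
        self.template = template
        self.dataset = dataset
        self.params = params or NodeParameters()
        self.solver = solver or SolverConfig()
        self.fitness_kind = fitness_kind
        self.penalty_weight = penalty_weight
        self.chunk_size = chunk_size
        self.n_nonconverged = 0
        self.cache: dict = {}

        self.node_ids = template.node_ids
        self.index = {n: i for i, n in enumerate(self.node_ids)}
        n = len(self.node_ids)
        self.n = n
        # immutable skeleton; mutable edges are re-added per genome
        self.wa0 = np.zeros((n, n))
        self.wb0 = np.zeros((n, n))
        self.candidates = mutable_edges(template)
        self.edge_entries = []  # (is_activation, target index, source index, w)
        for edge in template.edges:
            row, col = self.index[edge.target], self.index[edge.source]
            if edge.mutable:
                self.edge_entries.append(
                    (edge.sign is Sign.ACTIVATION, row, col, edge.weight)
                )
            else:
                matrix = self.wa0 if edge.sign is Sign.ACTIVATION else self.wb0
                matrix[row, col] += edge.weight
        self.genome_length = len(self.edge_entries)
        self.h = self.params.h_vector(self.node_ids)
        self.gamma = self.params.gamma_vector(self.node_ids)
        self.baseline_ic = baseline_initial_condition(template, baseline_seed)
        self.catabolic_idx = np.array(
            [i for i, node in enumerate(template.nodes)
             if node.role in CATABOLIC_ROLES],
            dtype=int,
        )

        # per-experiment arrays
        self.exp_x0 = []
        self.exp_clamp_mask = []
        self.exp_clamp_values = []
        self.exp_pinned = []    # clamped or explicitly overridden nodes
        self.exp_measured = []  # (node indices, y values, keep mask)
        for exp in dataset:
            x0 = np.zeros(n)
            cmask = np.zeros(n, dtype=bool)
            cvals = np.zeros(n)
            pinned = np.zeros(n, dtype=bool)
            for node, value in exp.perturbation.initial.items():
                x0[self._require(node)] = value
                pinned[self.index[node]] = True
            for node, value in exp.perturbation.clamps.items():
                i = self._require(node)
                x0[i] = value
                cmask[i] = True
                cvals[i] = value
                pinned[i] = True
            self.exp_pinned.append(pinned)
            self.exp_x0.append(x0)
            self.exp_clamp_mask.append(cmask)
            self.exp_clamp_values.append(cvals)
            nodes = list(exp.measured)
            idx = np.array([self._require(node) for node in nodes], dtype=int)
            y = np.array([exp.measured[node] for node in nodes])
            keep = np.array([node not in exp.mask for node in nodes], dtype=bool)
            self.exp_measured.append((idx, y, keep))
        self.n_experiments = len(dataset)

    def _require(self, node: str) -> int:
        if node not in self.index:
            raise KeyError(f"dataset references unknown node {node!r}")
        return self.index[node]

    # -- evaluation ----------------------------------------------------
    def evaluate(self, genome) -> float:
        return float(self.evaluate_population(np.asarray(genome)[None, :])[0])

    def evaluate_population(self, genomes) -> np.ndarray:
        genomes = np.asarray(genomes).astype(np.uint8)
        if genomes.ndim != 2 or genomes.shape[1] != self.genome_length:
            raise ValueError(
                f"expected genomes of shape (G, {self.genome_length})"
            )
        out = np.empty(len(genomes))
        todo: list[int] = []
        seen: dict[bytes, int] = {}
        unique_rows: list[np.ndarray] = []
        for i, row in enumerate(genomes):
            key = row.tobytes()
            if key in self.cache:
                out[i] = self.cache[key]
            elif key in seen:
                todo.append(i)
            else:
                seen[key] = len(unique_rows)
                unique_rows.append(row)
                todo.append(i)
        if unique_rows:
            unique = np.stack(unique_rows)
            for start in range(0, len(unique), self.chunk_size):
                chunk = unique[start:start + self.chunk_size]
                values = self._evaluate_chunk(chunk)
                for row, value in zip(chunk, values):
                    self.cache[row.tobytes()] = float(value)
        for i in todo:
            out[i] = self.cache[genomes[i].tobytes()]
        return out

    def _build_matrices(self, chunk) -> tuple:
        g = len(chunk)
        wa = np.broadcast_to(self.wa0, (g, self.n, self.n)).copy()
        wb = np.broadcast_to(self.wb0, (g, self.n, self.n)).copy()
        for j, (is_act, row, col, weight) in enumerate(self.edge_entries):
            kept = chunk[:, j].astype(bool)
            if is_act:
                wa[kept, row, col] += weight
            else:
                wb[kept, row, col] += weight
        return wa, wb

    def _evaluate_chunk(self, chunk) -> np.ndarray:
        g = len(chunk)
        rows_per_genome = self.n_experiments + 1  # baseline first
        wa_g, wb_g = self._build_matrices(chunk)
        # per-genome source nodes: deleting edges can orphan a node, and an
        # orphan inherits the baseline boundary value in perturbed runs
        sources_g = (wa_g.sum(axis=2) + wb_g.sum(axis=2)) == 0
        wa = np.repeat(wa_g, rows_per_genome, axis=0)
        wb = np.repeat(wb_g, rows_per_genome, axis=0)
        x0 = np.empty((g * rows_per_genome, self.n))
        cmask = np.zeros((g * rows_per_genome, self.n), dtype=bool)
        cvals = np.zeros((g * rows_per_genome, self.n))
        for gi in range(g):
            base_row = gi * rows_per_genome
            x0[base_row] = self.baseline_ic
            for ei in range(self.n_experiments):
                row = base_row + 1 + ei
                inherit = sources_g[gi] & ~self.exp_pinned[ei]
                x0[row] = np.where(inherit, self.baseline_ic,
                                   self.exp_x0[ei])
                cmask[row] = self.exp_clamp_mask[ei]
                cvals[row] = self.exp_clamp_values[ei]
        result = _integrate_batch(
            wa, wb, self.h, self.gamma, x0, cmask, cvals,
            self.solver, "hold", self.node_ids,
        )
        values = np.empty(g)
        for gi in range(g):
            base_row = gi * rows_per_genome
            rows = slice(base_row, base_row + rows_per_genome)
            if not result.converged[rows].all():
                self.n_nonconverged += 1
                values[gi] = math.inf
                continue
            base_ss = result.x[base_row]
            log_diffs = []
            for ei in range(self.n_experiments):
                delta = result.x[base_row + 1 + ei] - base_ss
                idx, y, keep = self.exp_measured[ei]
                pred = delta[idx][keep]
                meas = y[keep]
                log_diffs.append(np.log(pred + 2.0) - np.log(meas + 2.0))
            pooled = np.concatenate(log_diffs)
            value = abs(float(pooled.sum()) / pooled.size)
            if self.fitness_kind == "amd_with_baseline_penalty" and \
                    self.catabolic_idx.size:
                value += self.penalty_weight * float(
                    base_ss[self.catabolic_idx].mean()
                )
            values[gi] = value
        return values


def fitness(
    genome,
    template: RegulatoryNetwork,
    params: Optional[NodeParameters],
    dataset: ExperimentalDataset,
    config: Optional[GAConfig] = None,
    solver: Optional[SolverConfig] = None,
    baseline_seed: int = 0,
) -> float:
    """One-shot genome fitness (convenience wrapper over the evaluator)."""
    config = config or GAConfig()
    evaluator = FitnessEvaluator(
        template, dataset, params=params, solver=solver,
        baseline_seed=baseline_seed, fitness_kind=config.fitness,
        penalty_weight=config.penalty_weight,
    )
    return evaluator.evaluate(genome)


# ---------------------------------------------------------------------------
# The GA proper
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RepeatResult:
    seed_entropy: int
    best_genome: np.ndarray
    best_fitness: float
    trajectory: np.ndarray  # best-so-far per generation, non-increasing

    def genome_string(self) -> str:
        return "".join("1" if b else "0" for b in self.best_genome)


@dataclasses.dataclass
class CalibrationResult:
    repeats: list
    config: GAConfig
    genome_length: int
    n_nonconverged: int

    @property
    def best(self) -> RepeatResult:
        return min(self.repeats, key=lambda r: r.best_fitness)

    def best_network(self, template: RegulatoryNetwork) -> RegulatoryNetwork:
        return decode(self.best.best_genome, template)


def _tournament(rng, fitnesses, k: int) -> int:
    contestants = rng.integers(0, len(fitnesses), size=k)
    return int(contestants[np.argmin(fitnesses[contestants])])


def run_ga(
    template: RegulatoryNetwork,
    dataset: ExperimentalDataset,
    config: Optional[GAConfig] = None,
    params: Optional[NodeParameters] = None,
    solver: Optional[SolverConfig] = None,
    evaluator: Optional[FitnessEvaluator] = None,
    baseline_seed: int = 0,
) -> CalibrationResult:
    """Generational GA: tournament selection, uniform crossover, bit-flip
    mutation, elitism.  Each repeat draws an independent seed stream from
    ``config.seed``; results are deterministic for a fixed seed."""
    config = config or GAConfig()
    if evaluator is None:
        evaluator = FitnessEvaluator(
            template, dataset, params=params, solver=solver,
            baseline_seed=baseline_seed, fitness_kind=config.fitness,
            penalty_weight=config.penalty_weight,
        )
    length = evaluator.genome_length
    if length == 0:
        raise ValueError("template network has no mutable edges to calibrate")
    mutation_rate = (
        config.mutation_rate if config.mutation_rate is not None
        else 1.0 / length
    )
    pop_size = config.population_size
    master = np.random.SeedSequence(config.seed)
    children_seeds = master.spawn(config.repeats)
    repeats = []
    for child in children_seeds:
        rng = np.random.default_rng(child)
        population = (rng.random((pop_size, length)) < 0.5).astype(np.uint8)
        if config.seed_with_template:
            population[0] = 1
        fitnesses = evaluator.evaluate_population(population)
        best_idx = int(np.argmin(fitnesses))
        best_genome = population[best_idx].copy()
        best_fitness = float(fitnesses[best_idx])
        trajectory = [best_fitness]
        for _ in range(config.generations):
            if config.target_fitness is not None and \
                    best_fitness <= config.target_fitness:
                break
            order = np.argsort(fitnesses, kind="stable")
            elites = population[order[: config.elitism]].copy()
            n_children = pop_size - config.elitism
            offspring = np.empty((n_children, length), dtype=np.uint8)
            for ci in range(0, n_children, 2):
                p1 = population[_tournament(rng, fitnesses, config.tournament_size)]
                p2 = population[_tournament(rng, fitnesses, config.tournament_size)]
                c1, c2 = p1.copy(), p2.copy()
                if rng.random() < config.crossover_rate:
                    swap = rng.random(length) < 0.5
                    c1[swap], c2[swap] = p2[swap], p1[swap]
                offspring[ci] = c1
                if ci + 1 < n_children:
                    offspring[ci + 1] = c2
            flip = rng.random(offspring.shape) < mutation_rate
            offspring ^= flip.astype(np.uint8)
            population = np.concatenate([elites, offspring])
            fitnesses = evaluator.evaluate_population(population)
            gen_best = int(np.argmin(fitnesses))
            if float(fitnesses[gen_best]) < best_fitness:
                best_fitness = float(fitnesses[gen_best])
                best_genome = population[gen_best].copy()
            trajectory.append(best_fitness)
        repeats.append(RepeatResult(
            seed_entropy=int(child.entropy) if isinstance(child.entropy, int)
            else int(np.asarray(child.entropy).ravel()[0]),
            best_genome=best_genome,
            best_fitness=best_fitness,
            trajectory=np.array(trajectory),
        ))
    return CalibrationResult(
        repeats=repeats,
        config=config,
        genome_length=length,
        n_nonconverged=evaluator.n_nonconverged,
    )


# ---------------------------------------------------------------------------
# Final-model selection
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class FinalCandidate:
    genome: np.ndarray
    network: RegulatoryNetwork
    training_amd: float
    validation_nmad: Optional[float]
    qualitative_accuracy: Optional[float]
    catabolic_baseline: bool
    rank: int = 0


def select_final(
    results: Sequence[CalibrationResult],
    template: RegulatoryNetwork,
    validation_dataset: Optional[ExperimentalDataset] = None,
    behavior_rules: Optional[Sequence] = None,
    params: Optional[NodeParameters] = None,
    solver: Optional[SolverConfig] = None,
    seed: int = 0,
    direction_threshold: float = 0.1,
) -> list:
    """Rank candidate networks from one or more calibration runs.

    The documented lexicographic rule: qualitative accuracy first (higher is
    better), then validation NMAD, then training AMD.  Candidates whose
    baseline is dominated by pro-inflammatory / degrading-enzyme activity
    are flagged (``catabolic_baseline``) but never dropped.
    """
    if not results:
        raise ValueError("need at least one calibration result")
    candidates: dict[bytes, FinalCandidate] = {}
    for result in results:
        for repeat in result.repeats:
            key = np.asarray(repeat.best_genome, dtype=np.uint8).tobytes()
            if key in candidates:
                continue
            net = decode(repeat.best_genome, template)
            validation_nmad = None
            if validation_dataset is not None:
                predictions = []
                try:
                    for exp in validation_dataset:
                        resp = evaluation.response(
                            net, params, exp.perturbation, seed=seed,
                            solver=solver,
                        )
                        predictions.append(resp.as_dict())
                    x, y, _ = evaluation.pooled_pairs(
                        validation_dataset, predictions
                    )
                    validation_nmad = evaluation.nmad(x, y)
                except evaluation.ConvergenceError:
                    validation_nmad = math.inf
            qualitative = None
            if behavior_rules:
                qualitative = evaluation.qualitative_score(
                    net, params, behavior_rules,
                    direction_threshold=direction_threshold,
                    seed=seed, solver=solver,
                ).score
            base_ss = _baseline_catabolic_mean(net, params, solver, seed)
            candidates[key] = FinalCandidate(
                genome=np.asarray(repeat.best_genome, dtype=np.uint8),
                network=net,
                training_amd=repeat.best_fitness,
                validation_nmad=validation_nmad,
                qualitative_accuracy=qualitative,
                catabolic_baseline=base_ss > 0.5,
            )
    ranked = sorted(
        candidates.values(),
        key=lambda c: (
            -(c.qualitative_accuracy if c.qualitative_accuracy is not None else 0.0),
            c.validation_nmad if c.validation_nmad is not None else 0.0,
            c.training_amd,
        ),
    )
    for i, candidate in enumerate(ranked, start=1):
        candidate.rank = i
    return ranked


def _baseline_catabolic_mean(net, params, solver, seed) -> float:
    from .dynamics import baseline as _baseline

    ss = _baseline(net, params, seed=seed, solver=solver)
    values = [
        ss[node.id] for node in net.nodes if node.role in CATABOLIC_ROLES
    ]
    if not values:
        return 0.0
    return float(np.mean(values))
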