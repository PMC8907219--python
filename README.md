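# chondronet

Semiquantitative modeling of chondrocyte biochemical regulation with signed
regulatory networks: a continuous dynamical system derived from a signed
directed graph, steady-state analysis under clamping/perturbation,
quantitative (NMAD / NRSE / AMD) and qualitative evaluation, and
genetic-algorithm topology calibration against perturbation-response data.

The package ships a synthetic-data harness (ground-truth networks and
Luminex-style stimulation datasets) so every component is testable offline,
plus a 28-node **illustrative** chondrocyte network covering the standard
cytokine / protease / structural-protein vocabulary (IL1B, TNFA, IL6, …,
COL2A, ACAN, …). The illustrative topology is assembled from
literature-motivated example interactions for demonstration and testing —
it is **not** a published model.

## Model in brief

Each node carries a normalized activation `x ∈ [0, 1]`. Regulator levels
combine into a total input `ω ∈ [0, 1]`:

* activators: `A = ((1 + Σα) / Σα) · (Σα·x_a / (1 + Σα·x_a))`
* inhibitors: `I` analogous with weights β
* `ω = A·(1 − I)` (both present), `A` (activators only), `1 − I`
  (inhibitors only)

and each regulated node follows `dx/dt = Φ(ω) − γ·x` with the normalized
sigmoid `Φ` (gain `h`, anchors `Φ(0)=0`, `Φ(0.5)=0.5`, `Φ(1)=1`). Defaults:
all weights 1, `h = 10`, `γ = 1`. Steady states are found by fixed-step RK4
(adaptive RK45 available), with clamped nodes pinned for the whole
integration. Baselines start from a seeded Mersenne-Twister random initial
condition; responses are `perturbed SS − baseline SS ∈ [−1, 1]`.

Metrics: `nmad` (mean |x−y|/2), `nrse` (per-pair |x−y| / max pair error) and
`amd` (`|mean(ln(x+2) − ln(y+2))|` — the GA fitness; note its intentional
sign-cancelation behavior, also exposed as the cancelation-free
`mean_abs_log_deviation`). Calibration deletes edges only: a binary genome
over the mutable edge set, tournament selection, uniform crossover,
bit-flip mutation, elitism, seeded repeats, and a documented lexicographic
final-model ranking (qualitative accuracy, then validation NMAD, then
training AMD).

## CLI

One entry point, `chondronet`, with five subcommands. Every run writes a
`manifest.json` (arguments, config hash, seed, version) sufficient to
reproduce its outputs byte-for-byte.

```sh
# synthetic ground truth + train/test datasets + truth.json
chondronet generate --nodes 12 --density 0.2 --experiments 8 --seed 1 --out runs/gen

# baseline + perturbed steady states + response vector (omit --network to
# use the packaged illustrative fixture)
chondronet simulate --perturb "IL1B=1" --seed 0 --out runs/sim

# NMAD/NRSE/AMD + qualitative scoring against a dataset / behavior rules
chondronet evaluate --network runs/gen/net.tsv --data runs/gen/train.csv --out runs/eval

# GA topology calibration (per-repeat genomes, trajectories, best network)
chondronet calibrate --network runs/gen/net.tsv --data runs/gen/train.csv \
    --config ga.yaml --repeats 100 --seed 0 --out runs/cal

# OA induction + the three ACS treatment scenarios with t-test gating
chondronet scenarios --scenario acs1 --scenario acs2 --scenario acs3 --out runs/scen
```

Exit codes: 0 success, 2 configuration/schema error, 3 non-convergence.

Configuration is a YAML file with optional `solver:` and `ga:` sections,
e.g.

```yaml
solver:
  method: rk4_fixed   # or adaptive
  step: 0.01
  tol: 1.0e-6
  t_max: 100.0
ga:
  population_size: 50
  generations: 100
  crossover_rate: 0.8
  elitism: 2
  repeats: 100
```

## File formats

* **sif3** network: `source sign target`, sign `+`/`-`, `#` comments
  (lossy: topology and signs only).
* **tsv_extended** network: tab-separated
  `source sign target weight provenance mutable` plus a `#nodes` section
  (`id role accession`); exact round-trip format.
* **Dataset CSV**: one row per experiment; a `perturbation` column with
  semicolon-joined `NODE=value` clamps (`init:NODE=value` for
  initial-condition overrides), then one column per measured node in
  [−1, 1]. Masked self-readouts carry the sentinel `NA!self`.
* **Behavior rules CSV**: `stimulus;target;expected;citation` with
  expected ∈ {up, down, unchanged}.

## Scenarios

OA induction clamps IL1B, TNFA, IL6, IL8, IL17, IL18 at 1. The ACS
treatment clamps TGFB, IGF1, IL4, IL10 at 1 and IL1B at 0 (antagonist);
`acs1` leaves the remaining five cytokines free, `acs2` clamps them at 1,
`acs3` at 0.5. Treatment integrations start from the OA-like steady state
and are compared against it with a paired two-sided t-test (α = 0.05).

## Network enrichment

Live database queries are out of scope. To regenerate an enrichment edge
file yourself: query STRING (the original setup used version 11.0, organism
Homo sapiens, evidence channels *text mining + experiments + databases*,
minimum interaction score 0.400 "medium confidence") with the UniProt
accessions of your nodes (for the packaged vocabulary: P02458, P10145,
P05231, Q14116, P16112, O75173, P01137, P50281, P45452, P03956, P01375,
Q16552, P22301, P35225, P05112, P12643, P05019, P09038, P99999, Q14790,
P01033, P15692, P01584, P08254), manually curate the result into a signed
edge list, and combine it with `merge_networks` (added edges are tagged
with provenance `enrichment`; opposite-sign conflicts are reported and
resolved by the chosen policy).

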