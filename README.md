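# egodyn

Agent-based simulation of how an individual's identification with two
cultures changes through random social interactions within a fixed
egocentric network, plus the composition/structure metrics for such
networks and a factorial sweep engine with verification oracles.

## Model

One *ego* holds two identification scores, each on a 1–6 scale and starting
at the midpoint 3.5. The ego is embedded in a network of 8 *alters*, each
labeled with one of two cultures; undirected ties (0–28) connect alters to
each other. At each of 50 discrete time steps the ego interacts with one
uniformly drawn alter. The interaction shifts identification by
`0.1 + degree * 0.1`, where `degree` is the alter's number of ties to
same-culture alters, under one of three mechanisms:

- **positive** — identification with the alter's culture increases;
- **negative** — identification with the *other* culture decreases;
- **mixed(α)** — both at once, the increase weighted by `α` and the
  decrease by `1 − α` (α = 1 reproduces positive, α = 0 negative).

Scores are clamped into [1, 6] after every interaction. The default
factorial design sweeps 9 culture ratios × 8 tie counts ×
(positive + negative + 11 α values) × 50 replicates = 46,800 runs.

## Layout

- `egodyn.ego_network` — network representation, uniform random generation
  with exact culture/tie counts, same-culture degree, group sizes, the
  inter-class tie weight `ω(F, C) = e(F, C) / (|F|·|C|)`, JSON/CSV I/O.
- `egodyn.identity_dynamics` — the three update rules, trajectory
  simulation, tidy CSV export.
- `egodyn.sweep_engine` — factorial grid enumeration, per-run seed
  derivation, sweep execution, per-cell mean/SD summaries.
- `egodyn.oracles` — exhaustive enumeration of all interaction sequences
  and a closed-form no-clamp expectation, used to validate the simulator.
- `egodyn.cli_io` — the `egodyn` command-line interface.

## CLI

```sh
# one trajectory: 8 same-culture alters, no ties, positive mechanism
egodyn simulate --n-culture-a 8 --ties 0 --mechanism positive --seed 1 --out traj.csv

# the full default factorial design (46,800 runs, ~10 s)
egodyn sweep --seed 1 --out-dir sweep_out

# a reduced sweep via flags or a YAML/TOML config
egodyn sweep --ratios 0,4,8 --tie-counts 0,28 --mechanisms positive --replicates 10 --out-dir out
egodyn sweep --config grid.yaml --out-dir out

# network metrics (group sizes, inter-class tie weights)
egodyn metrics --network net.json
```

Every output directory gets a JSON manifest; feeding a sweep manifest back
through `egodyn sweep --config manifest.json` reproduces the CSVs
byte-for-byte. Exit codes: 0 ok, 1 domain error, 2 usage error.

Note on the inter-class tie weight: the implemented formula
`e(F, C) / (|F|·|C|)` is bounded by 1 (it saturates exactly when the F–C
bipartite graph is complete). Empirical reports of values above 1 for this
kind of measure imply a different denominator; this package implements only
the printed formula.

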