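# pollinet

Generation and dynamics of bipartite plant–pollinator networks: a calibrated
structural generator (richness, connectance, nestedness), a consumer–resource
model of plant/pollinator/floral-reward dynamics with optional adaptive
foraging, and pollination-service metrics based on conspecific pollen
deposition rates.

## What it does

- **`pollinet.netgen`** — generates binary incidence networks at target
  species richness (e.g. 90 or 200), connectance (0.15 or 0.30) and
  nestedness label. "Nested" is operationalized as NODF z ≥ 2 against a
  connectance-preserving null; "non-nested" as |z| < 2. Structural
  descriptors: connectance, NODF, degree summaries, specialist counts.
- **`pollinet.model_core`** — parameters, state, and the model's rates:
  plant growth from quality-weighted pollination, pollinator growth from
  rewards consumption, saturating rewards dynamics, and replicator-style
  foraging-effort adaptation.
- **`pollinet.simulate`** — stiff ODE integration to quasi-steady state
  (BDF with an analytic Jacobian sparsity pattern; numba-accelerated RHS
  when available), with extinction flooring and effort renormalization.
- **`pollinet.metrics`** — per-plant and per-pollinator pollen deposition
  rates, degree–deposition rank correlations, foraging-effort profiles.
- **`pollinet.experiments`** — the 8-treatment × {fixed, adaptive} study
  with paired parameter draws, boxplot summaries and treatment rankings.
- **`pollinet.empirical_io`** — reader for web-of-life-style incidence CSVs
  and the log–log connectance–richness regression with a 95% prediction
  interval (the "empirically connected" membership test).

## CLI

```bash
pollinet generate --S 90 --C 0.15 --nested --n 10 --seed 7 --out nets/
pollinet simulate --network nets/net_S90_C0.15_nested_000.csv --af --seed 3 \
    --t-end 10000 --out result.json
pollinet experiment --treatments all --n 10 --seed 1 --out results/
pollinet summarize results/ --metric median_plant_deposition
```

## Notes

- Network files are plain CSV incidence matrices (first row = animal labels,
  first column = plant labels, cells binarized on read).
- All randomness flows through numpy `Generator`/`SeedSequence`; fixed seeds
  give bit-identical networks and parameter draws.
- `numba` is used opportunistically for the ODE right-hand side; a pure
  numpy fallback is built in and pinned to the reference implementation by
  tests.
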