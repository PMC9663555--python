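# resburn

Adjoint-based attribution of crop-residue-burning PM2.5 exposure, with the
downstream health-burden and monetization chain, exercised end to end on a
fully synthetic linear-transport world so every stage is verifiable offline.

The pipeline:

1. **synthetic_world** — generates every input: a lon/lat grid, clustered
   population, nested country/state/district regions, a per-district crop
   table, daily burning emissions concentrated in two burning seasons, a
   linear toy transport model (upwind advection + diffusion + deposition +
   diurnal mixing-depth dilution) whose exact transpose is the adjoint,
   demography, 1000 exposure-response parameter draws, and annual economic
   series. Deterministic per seed via named sub-streams.
2. **diurnal** — a triangular within-day emission profile (95% of mass in a
   configurable local-time window, mid-afternoon peak), hour-bin
   discretization by exact integration, integer-hour shifts with day-boundary
   clipping, and daily-to-hourly disaggregation.
3. **attribution** — the population-weighted exposure cost function, the
   adjoint inner-product attribution (ΔP = S·E), regional/seasonal
   aggregation, per-unit district metrics, marginal efficacy, and a
   forward-vs-adjoint consistency check (machine precision by construction;
   the contract requires ≤ 10%).
4. **health** — piecewise relative-risk evaluation, attributable-fraction
   mortality by cause and age group, Monte Carlo means and percentile CIs.
5. **valuation** — Weibull-based value-of-statistical-life benefit transfer
   (income elasticities 0.7 within-country, 1.5 cross-country) and per-draw
   monetization.
6. **interventions** — within-day timing-shift experiments, two-axis district
   categorization (C1–C4), and contribution rankings.
7. **cli_io** — YAML config validation, NetCDF/CSV writers with readers, and
   a one-command pipeline runner.

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria; the rest are unit
and property tests per module.

## CLI

```sh
resburn run --config scenario.yaml --out outputs/
resburn check-consistency --config scenario.yaml
resburn shift-experiment --config scenario.yaml --out outputs/ --shift-hours -2
resburn aggregate --config scenario.yaml --out outputs/ --by state
resburn efficacy --config scenario.yaml --region-id 0 --level state
resburn categorize --config scenario.yaml --out outputs/
resburn rank --config scenario.yaml --out outputs/
```

A minimal `scenario.yaml`:

```yaml
seed: 1
world:
  n_lon: 6
  n_lat: 6
  n_days: 60
  n_draws: 1000
year: 2019
```

`resburn run` writes the world fixtures (NetCDF fields, CSV tables), the
attribution aggregates, mortality and valuation tables, intervention tables,
and a `manifest.json` with the config hash, seed, and the forward/adjoint
discrepancy. Identical configs produce byte-identical outputs.

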