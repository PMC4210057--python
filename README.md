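# ads-star

Structured additive Poisson regression for district-by-day clinic-visit
panels with dust-storm exposure windows. The package implements the full
analysis pipeline as reusable, tested components:

- **`exposure_calendar`** — parses dust-storm event intervals, labels every
  study day as ADS / post-ADS / other (ADS > post-ADS > other precedence,
  7-day post window), and builds day-of-week dummies (Sunday reference).
- **`spatial_graph`** — district adjacency graphs and the intrinsic
  conditional-autoregressive (graph Laplacian) penalty for the spatial term.
- **`smoothers`** — B-spline bases with second-order random-walk penalties
  and sum-to-zero identifiability constraints for the calendar-time and
  temperature smooths.
- **`star_model`** — design assembly and fitting: penalized IRLS inside a
  Fellner–Schall REML loop for the smoothing variances (optionally damped by
  an IG(0.001, 0.001) prior), population offset, posterior covariance,
  effective degrees of freedom, and AIC.
- **`model_selection`** — enumerates all 31 non-empty pollutant subsets
  (CO, NOx, O3, PM10, SO2), screens for significantly positive pollutant
  coefficients, and ranks survivors by AIC.
- **`effects_reporting`** — percentage relative-rate changes (IQR-scaled for
  pollutants), spatial RR maps with 3-way posterior classification,
  smoother curves with 80/95% bands, and episode-stratified pollutant
  summaries.
- **`synthetic_data`** — generates panels with known truth (episode-linked
  pollutant regimes, seasonal temperature, CAR spatial field, Poisson counts
  with offset) so the whole pipeline is testable without confidential data.

## CLI

```bash
ads-star all --config cfg.yaml --out run/ [--seed N]
# or stage by stage:
ads-star simulate --config cfg.yaml --out run/
ads-star fit      --config cfg.yaml --out run/
ads-star select   --config cfg.yaml --out run/
ads-star report   --config cfg.yaml --out run/
```

Config is YAML with optional sections `seed`, `simulate`, `model`,
`select`, `report`; keys mirror the `SimConfig` and `ModelSpec` dataclass
fields, e.g.

```yaml
seed: 1
simulate: {n_districts: 41, start: 2002-01-01, end: 2007-12-31}
model: {pollutants: [NOx, O3], time_n_basis: 20, temp_n_basis: 10}
select: {alpha: 0.05, strategy: full}   # or: staged
```

All outputs are plain CSV/JSON keyed by district id and term name
(`effects.csv`, `spatial_map.csv`, `smoother_*.csv`, `candidates.csv`,
`episode_summary.csv`), plus per-stage run manifests with config/input
digests. Exit codes: 1 config error, 2 data validation, 3 convergence,
4 missing upstream artifact.

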