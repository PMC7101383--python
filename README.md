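# plastisize

Allometric scaling of the maximum ingestible plastic length against animal
body length, with Monte-Carlo hold-out validation and a gridded
plastic-ingestion risk index for zooplankton communities.

The package covers four analysis stages plus a CLI:

- **`plastisize.synthetic_data`** — generator for per-taxon gut-content
  records (body length, largest/smallest ingested plastic, taxonomy, habitat,
  depths, coordinates) with a known log10-log10 linear structure. Noise can
  be calibrated analytically to a target population R², so downstream
  statistics are testable without any external dataset.
- **`plastisize.allometry`** — closed-form OLS of log10 plastic length on
  log10 body length with R², F and p diagnostics, t-based confidence and
  prediction intervals (back-transformed endpoint-wise), the canonical
  published coefficients (`published_fit()`), and the body-to-plastic ratio.
- **`plastisize.validation`** — repeated random hold-out validation
  (default 10% hold-out × 1000 repetitions): pooled log10-scale RMSE,
  interval coverage, and an observed-vs-predicted regression.
- **`plastisize.riskmap`** — linearisation of integer exponential-class
  rasters via `y = 10^((E/C)·x)`, selection of the ingestible plastic size
  class from the allometric fit (smallest class whose upper bound covers the
  point prediction), grid summation, and the plastic/zooplankton ratio risk
  grid. Grids are plain delimited text (`NA` = masked).

## CLI

A single `plastisize` executable with subcommands:

```sh
# synthetic taxon table (deterministic per seed)
plastisize simulate --seed 1 --out out/sim

# fit the log10-log10 regression and serialise it
plastisize fit --records out/sim/taxa.csv --out out/fit

# predictions; --published-fit uses the canonical printed coefficients
plastisize predict --published-fit --body-mm 13.5
plastisize predict --fit out/fit/fit.txt --body-mm 13.5 --interval prediction

# Monte-Carlo hold-out validation
plastisize validate --records out/sim/taxa.csv --reps 1000 --seed 1 \
    --interval prediction --out out/val

# risk grid from class rasters (or synthetic stand-ins)
plastisize riskmap --synthetic-shape 40 60 --seed 1 --out out/risk
plastisize riskmap --plastic-grid p1.tsv --plastic-grid p2.tsv \
    --plastic-grid p3.tsv --plastic-grid p4.tsv --zoo-grid zoo.tsv --out out/risk
```

Logs go to stderr; every artifact is accompanied by a machine-readable JSON
summary. Exit codes: `0` success, `2` usage/missing input, `3` invalid data.

## Notes

- All regression arithmetic is done on the log10 scale; lengths are
  back-transformed only for reporting (mm).
- Fits imported from printed coefficients carry no residual statistics and
  refuse to fabricate intervals.
- Validation coverage can be computed against prediction intervals (nominal
  for new observations; the recommended default) or confidence intervals of
  the mean (much narrower; coverage falls far below the nominal level and
  shrinks as n grows).
- RMSE is reported on the log10 scale; a linear-scale `rmse_mm` is also
  exported and clearly labelled.
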