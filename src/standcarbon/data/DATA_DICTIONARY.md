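# Data dictionary

All tables are plain CSV. Units: D cm, heights m, BMS Mg ha^-1 (dry mass),
N stems ha^-1, carbon Mg C ha^-1, areas ha, precipitation mm yr^-1,
temperatures degC.

## stands.csv
- `stand_id` integer key
- `SI` site index (dominant height, m, at reference age)
- `AGE` stand age in years at the stand-map year (2018 by default)
- `SP` dominant species: spruce | pine | birch
- `n_cells`, `area_ha`

## cells.csv
- `cell_id`, `stand_id`
- canopy metrics per epoch, suffixed with the epoch year, e.g.
  `H_ALS_10_2001 ... H_ALS_90_2001`, `H_ALS_mean_2001`,
  `D_ALS_1_2001 ... D_ALS_10_2001`, and the same with `_2016`.
  Height percentiles are non-decreasing in the index; cumulative densities
  are proportions in [0, 1], non-increasing in the index.

## plots.csv
One row per field plot per epoch: the metric columns (no year suffix),
`T` (0 first epoch, 1 second), `year`, `plot_id`, `stratum`, and the
field-observed `D`, `Hdom`, `H`, `BMS`.

## trees.csv
`species`, `D`, `H`, and one column per biomass component
(`SW BR DB SB SU FL RF RC`, kg dry mass; empty where not measured).

## climate.csv
`year`, `precipitation`, `temperature`, `amplitude` (mean difference between
monthly max and min temperature).

## disturbance.csv
`cell_id`, `year` of the detected disturbance event (disturbed cells only).

## truth.csv (synthetic bundles only)
Per-cell generating truth: `D/Hdom/H/BMS/N` at both epochs, `C_AGB_*`,
`C_BGB_*`, `dC_AGB_true`, `dC_BGB_true`, `disturbed`, `event_year`,
plus `SP`, `SI`, `AGE_start`.

## long_term_soil_carbon.csv (package data)
Bundled long-term soil carbon reference: `SP`, `SI`, and the equilibrium
carbon stocks `A W E N H` (Mg ha^-1) used to initialise legacy soil carbon.
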