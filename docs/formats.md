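# File formats

All CSV files are comma-separated UTF-8 with a mandatory header row and "."
as the decimal separator. JSON files are UTF-8 with sorted keys.

## Peak table (CSV, long format)

One row per integrated peak.

| column | type | required | meaning |
| --- | --- | --- | --- |
| `sample_id` | str | yes | batch / injection group identifier |
| `compound_id` | str | yes | analyte identifier |
| `area` | float ≥ 0 | yes | integrated peak area, detector counts |
| `injection_volume` | float > 0 | no (default 1.0) | µL injected |
| `replicate` | int ≥ 1 | no (default 1) | replicate index |
| `instrument` | str | no | condition: instrument name |
| `column` | str | no | condition: column name |
| `temperature` | float | no | condition: column temperature, °C |
| `flow_rate` | float | no | condition: mobile-phase flow, mL/min |

The four condition columns are read only when all are present; otherwise
rows carry the nominal condition.

## Concentration matrix (CSV, wide)

First column: sample id (header `sample_id#<METHOD>`, where `<METHOD>` is
`ESM`, `QAMS` or `truth`); remaining columns: one per compound, contents in
mg per g dry powder. No missing cells; no negative values.

## Calibration curve (JSON)

Keys: `compound_id`, `slope` (counts per mg/L), `intercept` (counts),
`r_squared`, `lod`, `loq`, `mdl`, `mql` (mg/L), `linear_range` = `[low,
high]` (mg/L). A curves file maps compound id → curve object.

## RCF table (JSON)

`reference_id`, `mean_rcf` (compound id → factor; reference maps to 1.0),
`per_level_rcfs` (compound id → list), `robustness_rsd_pct` /
`robustness` (compound id → RSD% across conditions and pass flag).

## Classification model (JSON)

`group_labels` (ordered), `fisher_coefficients` (groups × variables, score
per mg/g), `fisher_constants` (per group), `variable_order` (ordered
compound ids), `canonical_eigenvalues`, `variance_shares_pct`.

## Dendrogram (JSON)

`sample_ids` (ordered), `merge_steps` = `[[a, b, height], ...]` in scipy
linkage convention (leaves 0..n−1, merged cluster i is node n+i),
`rescaled_heights` (same order, mapped linearly to 0–25). The `cluster`
subcommand adds `cut` = `{rescaled_threshold, labels}`.

## Radar coordinates (CSV)

Columns `sample_id`, `vertex`, `angle` (radians), `radius`; the final
vertex of each sample repeats the first (closed polygon).

## Confusion matrix (CSV)

Square table, rows = true groups, columns = predicted groups, integer
counts.
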