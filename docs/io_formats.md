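# File formats

All files are UTF-8, comma-delimited CSV with a header row. Malformed
input is rejected with the offending row number and column/item named.

## Long-format score file

One row per item score. Read by `cieagree.io.read_scores` and every
analysis command; written by `write_scores` and `cieagree simulate`.

| column | type | constraints |
|---|---|---|
| form_id | string | — |
| dog_id | string | several forms may share a dog |
| observer_id | string | — |
| expertise | string | `expert`, `non_expert` or `unspecified` |
| session | string | `T1` or `T2` |
| item | string | one of `attitude_activity`, `appetite`, `vomiting`, `stool_consistency`, `stool_frequency`, `weight_loss`, `albumin`, `ascites_edema`, `pruritus` |
| value | integer | 0–3 |

Rules: the six core items must be present for every (form, observer,
session); the three CCECAI extras are all present or all absent; duplicate
(form, observer, session, item) rows are rejected; index totals are always
recomputed from the items, never read.

Example:

```csv
form_id,dog_id,observer_id,expertise,session,item,value
F001,D001,E1,expert,T1,attitude_activity,1
F001,D001,E1,expert,T1,appetite,0
...
```

A wide sheet (one column per item, same id columns) can be converted with
`cieagree.io.wide_to_long`.

## Raw-observation file

One row per consultation form; read by `cieagree score` /
`cieagree.io.read_observations`.

| column | type | constraints |
|---|---|---|
| form_id | string | required |
| attitude_grade | integer | 0–3 |
| appetite_grade | integer | 0–3 |
| vomits_per_week | real | ≥ 0 |
| mean_psfs | real | 1–7 (Purina fecal score) |
| stools_per_day | real | ≥ 0 |
| blood_or_mucus | boolean | `yes`/`no`/`true`/`false`/`1`/`0` |
| weight_loss_pct | real | 0–100 |
| albumin_g_per_l | real | > 0; optional (CCECAI) |
| ascites_edema_grade | integer | 0–3; optional (CCECAI) |
| pruritus_grade | integer | 0–3; optional (CCECAI) |
| problem_flags | string | optional; semicolon-separated item names whose sign is a problem for the animal (floors those scores at 1) |

## Results

`cieagree run` writes to the output directory:

* `results.csv` — one row per (comparison, variable): n, CCC with CI,
  bias with CI, both limits of agreement with CIs, agreement `Yes`/`No`/`NA`
  and failure reason codes (`ccc_below`, `bias_exceeds`, `loa_exceeds`);
* `results.json` — the same rows plus criteria and stratified subgroup
  counts (`null` for unavailable statistics);
* `report.md` — the Markdown table (`cieagree.reliability.parse_report`
  parses it back);
* `run_log.json` — version, input, seed, criteria and effective n per
  comparison.

## Run configuration (YAML)

```yaml
input: scores.csv
outdir: out
criteria: paper            # paper | relaxed_1 | relaxed_2
loa_limit_total: 2.5       # optional overrides: ccc_min, bias_limit,
loa_limit_item: 1.5        #   loa_limit_item, loa_limit_total
stratify:
  index: CIBDAI            # CIBDAI | CCECAI
  cutoff: 5.5
decimals_ccc: 2
decimals_ba: 3
seed: 0
log_level: INFO
```
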