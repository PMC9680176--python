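# misset

Find and explain multifield missing-data patterns in tabular health
records (or any flat table) using exclusive set intersections, set
visualisation and information-gain-ratio mining.

## The problem

Missing data is the most common data-quality issue in electronic health
records, and the usual check — counting missing values per field — says
nothing about *which fields are missing together*. Multifield patterns are
what matter for cohort selection, imputation design and provider feedback:
diagnosis codes DIAG_01…DIAG_20 should be filled incrementally (a record's
missing codes should form a *suffix* — a monotone pattern), and every
operation code OPERTN_nn should have its date MYOPDATE_nn (a *block*
pattern). Violations — a *gap* in the middle of the codes, or a date
missing behind a code — are rare, structured defects that probabilistic
missingness models are poorly suited to detect.

## The method

Treat the records missing field $A$ as a set $A$. The **exclusive set
intersection** $AB$ is the group of records missing *exactly* fields
$A$ and $B$ and nothing else, so every incomplete record belongs to
exactly one intersection and the number of distinct intersections is
bounded by the number of records $n$ (and by $2^m-1$ for $m$ fields).
That bound makes complete enumeration tractable at any scale: one
streaming pass groups records by their missing-field combination.
With three fields there are exactly four possible multifield
intersections: $AB$, $AC$, $BC$, $ABC$.

Each intersection has a **degree** (number of missing fields) and a
**cardinality** (number of records). The package:

* enumerates all intersections and their cardinalities (`set_engine`),
  with field-subset projection and degree/cardinality selection;
* classifies intersections against ordered-group expectations —
  monotone vs gap, and paired-block consistency (`matched`,
  `fewer_dates`, `extra_dates`) (`patterns`);
* explains a selected group of intersections by ranking candidate fields
  with Quinlan's gain ratio
  $\mathrm{GR}(X) = \big(H(C) - \sum_v \tfrac{n_v}{n} H(C \mid X{=}v)\big) / H(X)$
  for the binary class $C$ = "record in selection", and by per-value
  entropy tables $H(n_{\mathrm{in}}, n_{\mathrm{out}})$ that pinpoint
  which values of a field are associated with the pattern (`mining`);
* builds and renders the six chart types — value bar chart, value count
  histogram, combination heatmap (fields × intersections, cardinality as
  colour), combination bar chart, combination count and length
  histograms — with deterministic orderings including two clustering
  heuristics (`charts`);
* generates synthetic EHR-like data with planted, ground-truth-recorded
  anomalies for validation (`synth`), and ties it all into a `misset`
  command-line workflow (`cli`).

## Worked example

```sh
python examples/02_classify_patterns.py
python examples/03_explain_gaps.py
```

prints, for a 10,000-record synthetic extract (seed 1):

```
585 intersections over 86 fields, 630569 missing cells

diagnosis group: 541 monotone intersections (9929 records), 44 gap
intersections (71 records)
ground truth planted gap records: 71

operation code/date pair: 559 matched, 17 with fewer dates than codes,
9 with extra dates
```

The 44 gap intersections violate the monotone expectation; the generator
planted exactly those 71 records, and the summary recovers them exactly.
Explaining the gap selection:

```
gain-ratio ranking (higher = better explanation):
  EPITYPE    gain_ratio=0.0257 info_gain=0.0235
  PROCODE    gain_ratio=0.0036 info_gain=0.0168
  ...

per-value entropy for PROCODE (values in the selection first):
  P901   n_in=  71 n_out= 1903 H=0.2235 in_fraction=0.0360
```

The episode-type field tops the ranking and every gap record belongs to
provider `P901` — the planted origin of the defect. The same analysis is
available from the shell:

```sh
misset synth --preset hes-like --n 10000 --seed 1 --out run/
misset intersections run/data.csv --policy run/policy.json --out run/itab.csv
misset explain run/data.csv --policy run/policy.json --groups run/groups.json \
       --group diag --select-gaps --field PROCODE --out run/diag_gaps
misset chart run/data.csv --policy run/policy.json --kind combo_heatmap \
       --order cluster_lex --out run/heatmap.png
```

Every command appends to `run/session.jsonl`, the provenance trail of the
analysis.

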