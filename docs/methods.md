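# Methods

## Model

A table of $n$ records and $m$ named fields is reduced to a boolean
missingness matrix under an explicit token policy. The analysis object is
the partition of incomplete records into **exclusive set intersections**:
two records fall in the same intersection iff their missing-field sets are
equal. Three invariants define correctness and are enforced throughout:

* conservation — cardinalities plus the complete-record count sum to $n$;
* cell conservation — degree-weighted cardinalities sum to the total
  number of missing cells, which also equals the sum of per-field counts;
* bounds — the number of intersections is at most $\min(n, 2^m-1)$.

Enumeration is a single pass grouping records by their mask row
(`numpy.unique` over rows); memory is proportional to the number of
distinct patterns, never to the $2^m$ possible subsets. Pattern keys are
canonicalised in dataset column order — not alphabetically — so that
ordered groups (DIAG_01…DIAG_20) read naturally; all tie-breaks
(sorting, clustering, ranking) use that canonical order, making every
output deterministic.

## Missing-token policy

Sentinel handling is declarative: a global token set, per-field
extensions, and an empty-string flag. Matching is exact string equality
after trimming, case-sensitive by default with an opt-in
case-insensitive flag (sentinels such as `R69X` vs `r69x` must be
distinguishable). No type inference happens before masking — "unknown"
sentinels are textual codes, and coercing first would corrupt them. The
default policy treats only the empty string and literal `NA` as missing;
anything else must be declared. Real extracts come with provider-specific
unknown-value lists which are not public, so the shipped defaults are
illustrative, not authoritative.

## Pattern classification

For an ordered group $g_1,\dots,g_k$, a key has a **gap** at position $i$
iff $g_i$ is missing and some $g_j$, $j>i$, is present; a key is
**monotone** iff it has no gaps, i.e. its within-group missing members
form a suffix (possibly empty or full — a record missing the whole group
is monotone, consistent with incremental filling). Classification
considers only group members, so fields outside the group never change a
verdict.

For a paired group (codes $c_i$, dates $d_i$), position $i$ mismatches
iff exactly one of $(c_i, d_i)$ is in the key. A key with only
date-missing mismatches is `fewer_dates`; only code-missing, `extra_dates`.
A key mixing both directions takes the majority label, with `fewer_dates`
winning ties — a declared convention: the two labels partition real
findings, and mixed keys are too rare to justify a third class, but the
mismatch-position list always reports both directions.

## Mining

Entropies are Shannon, base 2, with $0\log 0 = 0$. Gain ratio follows
Quinlan: information gain over split information, with fields treated as
categoricals of their raw string values (no binning — the explanatory
fields in administrative data are codes) and a field's own missing cells
forming the category `(missing)`. A single-valued field has zero split
information; its ratio is reported as 0 and flagged undefined rather than
falling back to raw gain. Candidate fields default to those not appearing
in any selected key, because a field's own missingness predicts its
pattern membership trivially. The class universe defaults to *all*
records (selection vs everyone else), matching how an analyst compares a
pattern against the whole dataset; an `incomplete_only` flag restricts to
records missing at least one value.

The per-value entropy table reports $H(n_{\text{in}}, n_{\text{out}})$
per value. Values absent from the selection ($n_{\text{in}} = 0$) have
entropy 0 but cannot explain the selection; sorting them first would bury
the informative rows, so the table lists values occurring in the
selection first (ascending entropy, then descending $n_{\text{in}}$) and
relegates absent values to the end. This is a deliberate design choice:
"minimum-entropy row" in this package always means the most cleanly
associated value *among those present in the selection*.

## Charts

Chart construction and rendering are separated: a `ChartSpec` is a
JSON-serialisable description (data, ordering, scales, bins), and
rendering is a pure function of the spec — SVG output embeds no
timestamps and uses a fixed hash salt, so identical specs produce
identical bytes. Histograms default to Sturges binning on the binned
quantity, overridable with explicit edges; bin counts always sum to the
number of binned items. The heatmap colour scale is log10 of cardinality
because cardinalities span orders of magnitude. Log-scale bar charts draw
zero-valued bars at the baseline with a `0` annotation, since a log axis
cannot represent zero.

Two deterministic row-clustering heuristics are provided: `cluster_lex`
(ascending degree, then lexicographic on the membership vector in column
order) and `cluster_similarity` (greedy nearest-neighbour chaining on
Jaccard distance between field sets, seeded at the largest-cardinality
row). Both are permutations with canonical-order tie-breaks; the
similarity chaining is validated statistically — its mean adjacent-row
Jaccard distance beats a random ordering in at least 90% of seeded
trials — not against any particular published heuristic.

## Synthetic data generator

The generator emulates the structure of an admitted-patient-care extract:
18 general fields, a 20-member diagnosis-code group, and a paired
24-member operation code/date block (86 fields). Monotone groups are
filled to a sampled depth; paired groups share one depth per record
(block pattern). Depth distributions are truncated geometrics: diagnosis
depth rarely 0 (1%) with decay 0.75 (most episodes carry a handful of
codes); operation depth 0 for 45% of records (many episodes involve no
operation) with decay 0.6. Driver fields (episode type, admission method,
30 provider codes, finished-episode flag, mortality, …) are independent
categoricals.

Anomaly rules fire per record as independent Bernoulli events,
conditioned on a conjunction of driver values. The preset plants:

* survival time missing for every surviving patient and the A&E key for
  every non-A&E admission — dominant, structurally expected patterns;
* episode order missing only for unfinished episodes at two providers
  (rate 0.8) — the rare conditional-defect archetype;
* diagnosis gaps at position 3, and operation code/date gaps at
  position 2, only in birth episodes (EPITYPE=3, 10% of records) of
  provider P901 (20% of records), rates 0.9/0.6 — at $n=10{,}000$ this
  yields on the order of 50–100 gap records, rare relative to the table
  but large enough to analyse;
* a 5% `fewer_dates` and a 1% `extra_dates` discrepancy at two other
  providers.

Non-missing cell contents are arbitrary codes; realism is confined to
the missingness structure and the driver associations, which is exactly
what the analysis consumes. Consequently, passing tests demonstrate
correct pattern enumeration, classification and driver recovery — they
do not demonstrate robustness to clinically meaningful value
distributions, correlated drivers, or longitudinal structure, none of
which the generator emulates. Every run records ground truth cell by
cell (fill depths, driver values, fired rules, exact missing sets), and
a single seeded generator stream makes output files byte-reproducible.

The planted-driver benchmark (`preset_planted_driver`) is the recovery
study: one 10-category driver, three independent noise fields, a
5-member code group always filled past the gap position, and a gap rule
conditioned on one driver value at penetrance 0.9, $n=1000$. Across 100
seeded replicates the driver field must top the gain-ratio ranking and
its value must head the entropy table in at least 95.

## Problem sizes

Default study sizes are chosen to keep every property measurable at desk
scale while remaining quick: oracle-equivalence sweeps use 200 random
masks up to 500×12 (checked exactly against record-at-a-time grouping);
structure-recovery runs use the full preset at $n=10{,}000$; the mining
recovery study uses 100 replicates at $n=1000$.

## Known limitations

* Single flat table only; no joins, no longitudinal concatenation.
* Inclusive (non-exclusive) intersection semantics are out of scope.
* No probabilistic MCAR/MAR/MNAR testing — the set approach is the
  complement of, not a substitute for, model-based missingness analysis.
* Gain ratio uses no continuous binning; numeric fields are ranked on
  their string categories.
* The pair-mismatch majority rule and the entropy-table ordering are
  package conventions, documented above.
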