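"""Build and render the six chart types for one synthetic dataset.

Writes PNG images plus their JSON chart specs to ./example_output/ — the
spec fully determines the rendering, so a saved spec reproduces its
figure byte for byte (SVG).
"""

from pathlib import Path

from misset import (
    build_chart_spec,
    build_missingness_mask,
    compute_intersections,
    compute_sets,
    generate,
    preset_hes_like,
)
from misset.charts import render

out = Path("example_output")
out.mkdir(exist_ok=True)

config = preset_hes_like(n_records=5000, seed=2)
data, _ = generate(config)
mask = build_missingness_mask(data, config.policy())
sets_ = compute_sets(mask)
table = compute_intersections(mask)

charts = {
    "value_bar": build_chart_spec("value_bar", sets_, sort="count",
                                  y_scale="log"),
    "value_count_hist": build_chart_spec("value_count_hist", sets_),
    "combo_heatmap": build_chart_spec("combo_heatmap", table,
                                      heatmap_order="cluster_lex"),
    "combo_bar": build_chart_spec("combo_bar", table, sort="cardinality"),
    "combo_count_hist": build_chart_spec("combo_count_hist", table),
    "combo_length_hist": build_chart_spec("combo_length_hist", table),
}
for name, spec in charts.items():
    path = render(spec, out / f"{name}.png")
    spec.to_json(out / f"{name}.spec.json")
    print(f"wrote {path}")

print(f"\n{table.n_intersections} intersections drawn; the length "
      "histogram shows how many fields each combination involves, the "
      "count histogram how many records each combination affects.")
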