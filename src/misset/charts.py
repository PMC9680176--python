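"""The six chart types for sets and set intersections.

Two charts describe sets (per-field missing counts): the value bar chart
and the value count histogram.  Four describe intersections: the
combination heatmap (fields × intersections, cardinality as colour), the
combination bar chart (cardinality per intersection), and the combination
count / length histograms (distributions of cardinality and degree).  The
histograms are what keep the approach readable at scale: thousands of
intersections collapse to a handful of bins.

A chart is first *built* as a JSON-serialisable :class:`ChartSpec` (data,
ordering, scales, bins) and then *rendered* to PNG or SVG; rendering is a
pure function of the spec, so saved specs reproduce their figures exactly.
Charts only consume engine outputs — they never recompute sets or
intersections.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigError, MissetError
from .set_engine import (
    FieldSetSummary,
    IntersectionTable,
    PatternKey,
    sort_intersections,
)

__all__ = [
    "CHART_KINDS",
    "HEATMAP_ORDERINGS",
    "ChartSpec",
    "HeatmapLayout",
    "build_chart_spec",
    "order_heatmap",
    "render",
]

CHART_KINDS = (
    "value_bar",
    "value_count_hist",
    "combo_heatmap",
    "combo_bar",
    "combo_count_hist",
    "combo_length_hist",
)

HEATMAP_ORDERINGS = (
    "dataset_order",
    "alphabetical",
    "degree_then_cardinality",
    "cluster_lex",
    "cluster_similarity",
)


@dataclass(frozen=True)
class ChartSpec:
    """A fully-resolved, serialisable description of one chart."""

    kind: str
    payload: dict
    x_label: str
    y_label: str
    y_scale: str = "linear"  # "linear" | "log"
    title: str = ""

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"kind": self.kind, "payload": self.payload,
                 "x_label": self.x_label, "y_label": self.y_label,
                 "y_scale": self.y_scale, "title": self.title},
                indent=2,
            ) + "\n",
            encoding="utf-8",
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ChartSpec":
        raw = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(**raw)


@dataclass(frozen=True)
class HeatmapLayout:
    """Row/column layout of a combination heatmap.

    Rows are intersections, columns fields; ``matrix[i][j]`` is 1 when row
    i's combination includes column j.  Each row is annotated with its
    cardinality; the colour scale over cardinalities is log10 because they
    can span 1 to millions.
    """

    rows: tuple[PatternKey, ...]
    cols: tuple[str, ...]
    matrix: np.ndarray  # bool, shape (len(rows), len(cols))
    cardinalities: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.rows), len(self.cols)):
            raise ConfigError("heatmap matrix shape mismatch")
        if len(self.cardinalities) != len(self.rows):
            raise ConfigError("one cardinality per heatmap row required")

    @classmethod
    def from_table(cls, table: IntersectionTable) -> "HeatmapLayout":
        rows = tuple(k for k, _ in sort_intersections(table, by="degree"))
        cols = tuple(table.field_universe)
        col_index = {c: j for j, c in enumerate(cols)}
        matrix = np.zeros((len(rows), len(cols)), dtype=bool)
        for i, key in enumerate(rows):
            for f in key.fields:
                matrix[i, col_index[f]] = True
        return cls(rows=rows, cols=cols, matrix=matrix,
                   cardinalities=tuple(table.entries[k] for k in rows))


def _sturges_edges(values: Sequence[float]) -> list[float]:
    """Integer-aligned Sturges bins over the observed range."""
    values = list(values)
    n = len(values)
    k = max(1, math.ceil(math.log2(n)) + 1) if n else 1
    lo, hi = min(values), max(values)
    if lo == hi:
        return [lo - 0.5, hi + 0.5]
    edges = np.linspace(lo, hi, k + 1)
    return [float(e) for e in edges]


def _histogram_payload(values: Sequence[float],
                       bins: Sequence[float] | None) -> dict:
    edges = list(bins) if bins is not None else _sturges_edges(values)
    counts, edges_arr = np.histogram(np.asarray(values, dtype=float), bins=edges)
    return {
        "bin_edges": [float(e) for e in edges_arr],
        "bin_counts": [int(c) for c in counts],
        "n_items": len(values),
    }


def build_chart_spec(
    kind: str,
    data: "list[FieldSetSummary] | IntersectionTable",
    sort: str | None = None,
    descending: bool = True,
    y_scale: str = "linear",
    bins: Sequence[float] | None = None,
    heatmap_order: str = "degree_then_cardinality",
) -> ChartSpec:
    """Build the spec for one chart kind from engine output.

    ``value_*`` kinds take a list of :class:`FieldSetSummary`; ``combo_*``
    kinds take an :class:`IntersectionTable`.  ``sort`` applies to bar
    charts (``"count"``/``"name"`` for value_bar, ``"degree"``/
    ``"cardinality"`` for combo_bar).
    """
    if kind not in CHART_KINDS:
        raise ConfigError(f"unknown chart kind {kind!r}")

    if kind.startswith("value_"):
        if isinstance(data, IntersectionTable) or not all(
            isinstance(s, FieldSetSummary) for s in data
        ):
            raise TypeError(f"{kind} needs a list of FieldSetSummary")
        summaries = list(data)
        if kind == "value_bar":
            if sort == "count":
                summaries.sort(key=lambda s: s.missing_count,
                               reverse=descending)
            elif sort == "name":
                summaries.sort(key=lambda s: s.field_name, reverse=descending)
            payload = {
                "fields": [s.field_name for s in summaries],
                "counts": [s.missing_count for s in summaries],
            }
            return ChartSpec(kind=kind, payload=payload, x_label="field",
                             y_label="missing values", y_scale=y_scale,
                             title="Missing values per field")
        payload = _histogram_payload([s.missing_count for s in summaries], bins)
        return ChartSpec(kind=kind, payload=payload,
                         x_label="missing values per field",
                         y_label="fields", y_scale=y_scale,
                         title="Distribution of per-field missing counts")

    if not isinstance(data, IntersectionTable):
        raise TypeError(f"{kind} needs an IntersectionTable")
    table = data
    if not table.entries:
        import warnings

        warnings.warn(f"empty intersection table for chart {kind!r}",
                      stacklevel=2)

    if kind == "combo_heatmap":
        layout = HeatmapLayout.from_table(table)
        layout = order_heatmap(layout, heatmap_order)
        payload = {
            "rows": [str(k) for k in layout.rows],
            "cols": list(layout.cols),
            "matrix": layout.matrix.astype(int).tolist(),
            "cardinalities": list(layout.cardinalities),
            "color_scale": "log10",
            "legend": "cell colour = log10(cardinality) of the row's intersection",
            "ordering": heatmap_order,
        }
        return ChartSpec(kind=kind, payload=payload, x_label="field",
                         y_label="intersection", y_scale="linear",
                         title="Combination heatmap")

    if kind == "combo_bar":
        by = sort if sort in ("degree", "cardinality") else "cardinality"
        ordered = sort_intersections(table, by=by, descending=descending)
        payload = {
            "patterns": [str(k) for k, _ in ordered],
            "cardinalities": [c for _, c in ordered],
        }
        return ChartSpec(kind=kind, payload=payload, x_label="intersection",
                         y_label="records", y_scale=y_scale,
                         title="Records per intersection")

    if kind == "combo_count_hist":
        values = [c for c in table.entries.values()]
        payload = _histogram_payload(values or [0], bins)
        payload["n_items"] = len(values)
        return ChartSpec(kind=kind, payload=payload,
                         x_label="cardinality (records per intersection)",
                         y_label="intersections", y_scale=y_scale,
                         title="Combination count histogram")

    # combo_length_hist
    values = [k.degree for k in table.entries]
    payload = _histogram_payload(values or [0], bins)
    payload["n_items"] = len(values)
    return ChartSpec(kind=kind, payload=payload,
                     x_label="degree (missing fields per intersection)",
                     y_label="intersections", y_scale=y_scale,
                     title="Combination length histogram")


# -- heatmap row ordering --------------------------------------------------


def _jaccard_distance(a: frozenset, b: frozenset) -> float:
    union = a | b
    if not union:
        return 0.0
    return 1.0 - len(a & b) / len(union)


def order_heatmap(layout: HeatmapLayout, method: str) -> HeatmapLayout:
    """Reorder heatmap rows; every method is a pure permutation.

    * ``dataset_order`` / ``alphabetical``: canonical key order or sort by
      the pattern string.
    * ``degree_then_cardinality``: ascending degree, then descending
      cardinality.
    * ``cluster_lex``: ascending degree, then lexicographic on the
      membership vector in column order.
    * ``cluster_similarity``: greedy nearest-neighbour chaining on Jaccard
      distance between the rows' field sets, seeded at the
      largest-cardinality row; ties break on canonical key order.
    """
    if method not in HEATMAP_ORDERINGS:
        raise ConfigError(f"unknown heatmap ordering {method!r}")
    n = len(layout.rows)
    idx = list(range(n))

    if method == "dataset_order":
        idx.sort(key=lambda i: layout.rows[i].indices)
    elif method == "alphabetical":
        idx.sort(key=lambda i: (str(layout.rows[i]), layout.rows[i].indices))
    elif method == "degree_then_cardinality":
        idx.sort(key=lambda i: (layout.rows[i].degree,
                                -layout.cardinalities[i],
                                layout.rows[i].indices))
    elif method == "cluster_lex":
        idx.sort(key=lambda i: (layout.rows[i].degree,
                                tuple(layout.matrix[i].astype(int))))
    else:  # cluster_similarity
        if n > 1:
            sets = [frozenset(layout.rows[i].indices) for i in range(n)]
            start = min(idx, key=lambda i: (-layout.cardinalities[i],
                                            layout.rows[i].indices))
            chain = [start]
            remaining = set(idx) - {start}
            while remaining:
                last = chain[-1]
                nxt = min(
                    remaining,
                    key=lambda i: (_jaccard_distance(sets[last], sets[i]),
                                   layout.rows[i].indices),
                )
                chain.append(nxt)
                remaining.discard(nxt)
            idx = chain

    return HeatmapLayout(
        rows=tuple(layout.rows[i] for i in idx),
        cols=layout.cols,
        matrix=layout.matrix[idx],
        cardinalities=tuple(layout.cardinalities[i] for i in idx),
    )


# -- rendering -------------------------------------------------------------


def _deterministic_savefig(fig, path: Path, fmt: str) -> None:
    import matplotlib

    with matplotlib.rc_context({"svg.hashsalt": "misset"}):
        if fmt == "svg":
            fig.savefig(path, format="svg", metadata={"Date": None})
        else:
            fig.savefig(path, format="png", dpi=120)


def render(spec: ChartSpec, path: str | Path, fmt: str | None = None) -> Path:
    """Render a spec to a PNG or SVG file.

    Pure function of the spec: the same spec always produces the same
    bytes (SVG output embeds no timestamps).  Zero-valued bars under a log
    Y scale are drawn at the axis baseline and annotated.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower() or "png"
    if fmt not in ("png", "svg"):
        raise ConfigError(f"unsupported format {fmt!r}")

    figsize = (9.0, 5.0)
    if spec.kind == "combo_heatmap":
        n_rows = len(spec.payload["rows"])
        n_cols = len(spec.payload["cols"])
        figsize = (min(24.0, max(9.0, 0.15 * n_cols + 2.0)),
                   min(40.0, max(5.0, 0.12 * n_rows + 1.5)))
    elif spec.kind in ("value_bar", "combo_bar"):
        n_bars = len(spec.payload.get("fields", spec.payload.get("patterns", [])))
        figsize = (min(24.0, max(9.0, 0.12 * n_bars + 2.0)), 5.0)
    fig, ax = plt.subplots(figsize=figsize, constrained_layout=True)
    try:
        _draw(spec, fig, ax)
        try:
            _deterministic_savefig(fig, path, fmt)
        except OSError as exc:
            raise MissetError(f"cannot write chart to {path}: {exc}") from exc
    finally:
        plt.close(fig)
    return path


def _draw_bars(ax, labels, heights, y_scale: str) -> None:
    x = np.arange(len(labels))
    heights = np.asarray(heights, dtype=float)
    if y_scale == "log":
        # log axes cannot show zero: draw those bars at the baseline
        shown = np.where(heights > 0, heights, np.nan)
        ax.bar(x, np.nan_to_num(shown, nan=0.0))
        ax.set_yscale("log")
        for xi, h in zip(x, heights):
            if h == 0:
                ax.annotate("0", (xi, ax.get_ylim()[0]), ha="center",
                            va="bottom", fontsize=7)
    else:
        ax.bar(x, heights)
    if len(labels) <= 150:  # beyond this labels are unreadable anyway
        ax.set_xticks(x)
        ax.set_xticklabels(labels, rotation=90, fontsize=6)
    else:
        ax.set_xticks([])


def _draw(spec: ChartSpec, fig, ax) -> None:
    payload = spec.payload
    if spec.kind == "value_bar":
        _draw_bars(ax, payload["fields"], payload["counts"], spec.y_scale)
    elif spec.kind == "combo_bar":
        _draw_bars(ax, payload["patterns"], payload["cardinalities"],
                   spec.y_scale)
    elif spec.kind in ("value_count_hist", "combo_count_hist",
                       "combo_length_hist"):
        edges = payload["bin_edges"]
        counts = payload["bin_counts"]
        widths = np.diff(edges)
        ax.bar(edges[:-1], counts, width=widths, align="edge",
               edgecolor="white")
        if spec.y_scale == "log":
            ax.set_yscale("log")
    elif spec.kind == "combo_heatmap":
        matrix = np.asarray(payload["matrix"], dtype=float)
        cards = np.asarray(payload["cardinalities"], dtype=float)
        if matrix.size:
            colour = matrix * np.log10(np.maximum(cards, 1.0))[:, None]
            colour[matrix == 0] = np.nan
            im = ax.imshow(colour, aspect="auto", interpolation="nearest",
                           cmap="viridis")
            cbar = fig.colorbar(im, ax=ax)
            cbar.set_label("log10(cardinality)")
        if len(payload["cols"]) <= 150:
            ax.set_xticks(np.arange(len(payload["cols"])))
            ax.set_xticklabels(payload["cols"], rotation=90, fontsize=5)
        if len(payload["rows"]) <= 150:
            ax.set_yticks(np.arange(len(payload["rows"])))
            ax.set_yticklabels(payload["rows"], fontsize=4)
        else:
            ax.set_yticks([])
    else:  # pragma: no cover - guarded by build_chart_spec
        raise ConfigError(f"unknown chart kind {spec.kind!r}")
    ax.set_xlabel(spec.x_label)
    ax.set_ylabel(spec.y_label)
    if spec.title:
        ax.set_title(spec.title)
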