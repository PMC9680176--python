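"""Explaining selected intersections with information gain ratio and entropy.

Given a selection of intersections, every record is labelled *in* or *out*
of the selection, and candidate fields are ranked by how well their values
predict that label.  The ranking statistic is Quinlan's gain ratio:
information gain of the field about the label, normalised by the field's
own entropy (split information), so many-valued fields are not favoured
simply for being many-valued.  A per-value entropy table then pinpoints
*which* values of one chosen field are associated with the selection.

All entropies are Shannon entropies in bits (base 2), with 0·log 0 = 0.
Fields are treated as categoricals of their raw string values; a field's
own missing entries form the distinct category ``"(missing)"``.
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DomainError
from .ingest import MissingnessMatrix
from .set_engine import IntersectionSelection, membership_labels

__all__ = [
    "ClassLabeling",
    "IGRResult",
    "EntropyTableRow",
    "ExplanationReport",
    "shannon_entropy",
    "gain_ratio",
    "rank_fields",
    "value_entropy_table",
    "explain_selection",
]

MISSING_CATEGORY = "(missing)"


@dataclass(frozen=True)
class ClassLabeling:
    """Binary in-selection / out-of-selection labels for a set of records."""

    labels: np.ndarray  # bool, True = in selection
    provenance: str = ""

    @property
    def n_in(self) -> int:
        return int(self.labels.sum())

    @property
    def n_out(self) -> int:
        return int(len(self.labels) - self.labels.sum())


@dataclass(frozen=True)
class IGRResult:
    """Gain-ratio score of one candidate field for one class labelling."""

    field_name: str
    entropy_before: float
    info_gain: float
    split_info: float
    gain_ratio: float
    defined: bool  # False when split_info == 0 (single-valued field)


@dataclass(frozen=True)
class EntropyTableRow:
    """Class split among the records sharing one value of a field.

    ``value_entropy`` is H(n_in, n_out) in bits: 0 iff the value is
    perfectly associated with one class, 1 at a 50/50 split.
    """

    value: str
    n_in: int
    n_out: int
    value_entropy: float
    in_fraction: float


@dataclass(frozen=True)
class ExplanationReport:
    """IGR ranking plus per-value entropy tables for one selection."""

    provenance: str
    ranking: tuple[IGRResult, ...]
    entropy_tables: dict[str, tuple[EntropyTableRow, ...]]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "provenance": self.provenance,
            "ranking": [vars(r) for r in self.ranking],
            "entropy_tables": {
                field: [vars(row) for row in rows]
                for field, rows in self.entropy_tables.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")

    def to_csv(self, ranking_path: str | Path,
               entropy_path: str | Path | None = None) -> None:
        with open(ranking_path, "w", newline="", encoding="utf-8") as fh:
            fh.write(f"# provenance={self.provenance}\n")
            writer = csv.writer(fh)
            writer.writerow(["field", "entropy_before", "info_gain",
                             "split_info", "gain_ratio", "defined"])
            for r in self.ranking:
                writer.writerow([r.field_name, r.entropy_before, r.info_gain,
                                 r.split_info, r.gain_ratio, r.defined])
        if entropy_path is not None:
            with open(entropy_path, "w", newline="", encoding="utf-8") as fh:
                fh.write(f"# provenance={self.provenance}\n")
                writer = csv.writer(fh)
                writer.writerow(["field", "value", "n_in", "n_out",
                                 "value_entropy", "in_fraction"])
                for field, rows in self.entropy_tables.items():
                    for row in rows:
                        writer.writerow([field, row.value, row.n_in, row.n_out,
                                         row.value_entropy, row.in_fraction])


def shannon_entropy(class_counts: Sequence[int] | np.ndarray) -> float:
    """H = -sum p_i log2 p_i over the count distribution, in bits."""
    counts = np.asarray(class_counts, dtype=float)
    if counts.size == 0 or counts.sum() <= 0:
        raise DomainError("entropy needs at least one positive count")
    if (counts < 0).any():
        raise DomainError("counts must be non-negative")
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum() + 0.0)  # +0.0 avoids -0.0


def _categorical_values(
    table: pd.DataFrame, mask: MissingnessMatrix, field: str
) -> np.ndarray:
    """Raw string values of a column with masked cells replaced by
    the ``(missing)`` category."""
    j = mask.field_index(field)
    values = table.iloc[:, j].astype(str).str.strip().to_numpy(dtype=object)
    values = values.copy()
    values[mask.mask[:, j]] = MISSING_CATEGORY
    return values


def gain_ratio(labeling: ClassLabeling, field_values: Sequence) -> IGRResult:
    """Quinlan gain ratio of one categorical field for a binary labelling.

    info_gain = H(labels) - sum_v (n_v/N) H(labels | value = v);
    split_info = H(value distribution); gain_ratio = gain / split_info.
    A single-valued field has split_info 0: its ratio is undefined and
    reported as 0 with ``defined=False`` and a warning.
    """
    labels = np.asarray(labeling.labels, dtype=bool)
    values = np.asarray(field_values, dtype=object)
    if len(labels) != len(values):
        raise ConfigError("labels and field values must align on records")
    if len(labels) == 0:
        raise DomainError("gain ratio needs at least one record")

    n = len(labels)
    h_before = shannon_entropy([labels.sum(), n - labels.sum()])

    value_counts: Counter = Counter(values)
    cond = 0.0
    for v, n_v in value_counts.items():
        in_v = int(labels[values == v].sum())
        cond += (n_v / n) * shannon_entropy([in_v, n_v - in_v])
    info_gain = max(0.0, h_before - cond)  # clip float round-off
    split_info = shannon_entropy(list(value_counts.values()))

    if split_info > 0.0:
        ratio = info_gain / split_info
        defined = True
    else:
        warnings.warn(
            "gain ratio undefined for single-valued field; reporting 0",
            stacklevel=2,
        )
        ratio = 0.0
        defined = False
    return IGRResult(
        field_name="",
        entropy_before=h_before,
        info_gain=info_gain,
        split_info=split_info,
        gain_ratio=ratio,
        defined=defined,
    )


def _selection_labeling(
    mask: MissingnessMatrix,
    selection: IntersectionSelection,
    incomplete_only: bool,
) -> tuple[ClassLabeling, np.ndarray]:
    """Labels + record-universe index for a selection.

    By default every record in the table's universe is considered
    (selection members versus everyone else); ``incomplete_only``
    restricts the comparison to records missing at least one field.
    """
    labels = membership_labels(selection, mask)
    if incomplete_only:
        universe = np.flatnonzero(mask.mask.any(axis=1))
    else:
        universe = np.arange(mask.n_records)
    labels = labels[universe]
    if not labels.any():
        raise DomainError("selection matches no records in the universe")
    return (
        ClassLabeling(labels=labels, provenance=selection.provenance),
        universe,
    )


def rank_fields(
    table: pd.DataFrame,
    mask: MissingnessMatrix,
    selection: IntersectionSelection,
    candidate_fields: Sequence[str] | None = None,
    incomplete_only: bool = False,
) -> list[IGRResult]:
    """Rank candidate fields by gain ratio, descending.

    Candidates default to every field NOT appearing in any selected key: a
    field's own missingness trivially predicts membership of its own
    pattern.  Ties break on dataset field order (stable sort).
    """
    if not selection.selected_keys:
        raise DomainError("cannot explain an empty selection")
    if candidate_fields is None:
        in_keys = {f for key in selection.selected_keys for f in key.fields}
        candidate_fields = [f for f in mask.field_names if f not in in_keys]
    else:
        for f in candidate_fields:
            mask.field_index(f)  # raises ConfigError for unknown names

    labeling, universe = _selection_labeling(mask, selection, incomplete_only)

    results: list[IGRResult] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for field in candidate_fields:
            values = _categorical_values(table, mask, field)[universe]
            res = gain_ratio(labeling, values)
            results.append(
                IGRResult(field_name=field, entropy_before=res.entropy_before,
                          info_gain=res.info_gain, split_info=res.split_info,
                          gain_ratio=res.gain_ratio, defined=res.defined)
            )
    results.sort(key=lambda r: -r.gain_ratio)  # stable: ties keep dataset order
    return results


def value_entropy_table(
    table: pd.DataFrame,
    mask: MissingnessMatrix,
    selection: IntersectionSelection,
    field: str,
    incomplete_only: bool = False,
) -> list[EntropyTableRow]:
    """Per-value class-split entropies for one field.

    One row per distinct value (including ``(missing)``).  Values that
    occur inside the selection come first, sorted by ascending entropy
    then descending n_in; values absent from the selection cannot explain
    it and are listed after, in the same order.
    """
    if not selection.selected_keys:
        raise DomainError("cannot explain an empty selection")
    labeling, universe = _selection_labeling(mask, selection, incomplete_only)
    values = _categorical_values(table, mask, field)[universe]
    labels = labeling.labels

    rows: list[EntropyTableRow] = []
    for v in sorted(set(values)):
        sel = values == v
        n_in = int(labels[sel].sum())
        n_out = int(sel.sum() - n_in)
        rows.append(
            EntropyTableRow(
                value=str(v),
                n_in=n_in,
                n_out=n_out,
                value_entropy=shannon_entropy([n_in, n_out]),
                in_fraction=n_in / (n_in + n_out),
            )
        )
    rows.sort(key=lambda r: (r.n_in == 0, r.value_entropy, -r.n_in))
    return rows


def explain_selection(
    table: pd.DataFrame,
    mask: MissingnessMatrix,
    selection: IntersectionSelection,
    candidate_fields: Sequence[str] | None = None,
    entropy_fields: Sequence[str] | None = None,
    incomplete_only: bool = False,
    top_n_entropy: int = 3,
) -> ExplanationReport:
    """Full explanation: IGR ranking plus entropy tables.

    ``entropy_fields`` defaults to the top-ranked fields of the IGR run.
    """
    ranking = rank_fields(table, mask, selection, candidate_fields,
                          incomplete_only)
    if entropy_fields is None:
        entropy_fields = [r.field_name for r in ranking[:top_n_entropy]]
    tables = {
        field: tuple(
            value_entropy_table(table, mask, selection, field, incomplete_only)
        )
        for field in entropy_fields
    }
    return ExplanationReport(
        provenance=selection.provenance,
        ranking=tuple(ranking),
        entropy_tables=tables,
    )
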