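"""Missingness sets and exclusive set intersections.

Set *A* is all records missing a value for field A.  The *exclusive*
intersection AB holds the records missing exactly fields A and B and
nothing else, so every incomplete record belongs to exactly one
intersection and the number of distinct intersections can never exceed the
number of records.  That bound is what makes the enumeration tractable for
arbitrarily large tables: one streaming pass groups records by their exact
missing-field combination, with memory proportional to the number of
distinct patterns, never to the 2^n possible field subsets.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from .errors import ConfigError, DomainError, SelectionError
from .ingest import MissingnessMatrix

__all__ = [
    "FieldSetSummary",
    "PatternKey",
    "IntersectionTable",
    "IntersectionSelection",
    "compute_sets",
    "compute_intersections",
    "project_fields",
    "select_intersections",
    "sort_intersections",
    "record_ids_for",
]


@dataclass(frozen=True)
class FieldSetSummary:
    """Per-field missing-value count: the cardinality of one set."""

    field_name: str
    missing_count: int
    missing_fraction: float
    degenerate: bool = False  # True when n_records == 0


@dataclass(frozen=True, order=True)
class PatternKey:
    """The exact combination of missing fields shared by a group of records.

    ``fields`` is stored in canonical (dataset column) order so keys are
    comparable and hashable; the stored ``indices`` are positions in the
    field universe the key was built against and define the canonical
    sort order for tie-breaking.
    """

    indices: tuple[int, ...] = field(compare=True)
    fields: tuple[str, ...] = field(compare=False)

    def __post_init__(self) -> None:
        if not self.fields:
            raise ConfigError("a PatternKey must name at least one field")
        if len(self.indices) != len(self.fields):
            raise ConfigError("indices and fields must be aligned")
        if list(self.indices) != sorted(set(self.indices)):
            raise ConfigError("PatternKey indices must be strictly increasing")

    @classmethod
    def from_fields(
        cls, fields: Iterable[str], universe: Sequence[str]
    ) -> "PatternKey":
        """Build a key in canonical dataset order from an unordered set."""
        index = {name: i for i, name in enumerate(universe)}
        try:
            idx = sorted(index[f] for f in set(fields))
        except KeyError as exc:
            raise ConfigError(f"unknown field {exc.args[0]!r}") from None
        return cls(indices=tuple(idx), fields=tuple(universe[i] for i in idx))

    @property
    def degree(self) -> int:
        """Number of missing fields in the combination."""
        return len(self.fields)

    def __contains__(self, field_name: str) -> bool:
        return field_name in self.fields

    def __str__(self) -> str:
        return "|".join(self.fields)


@dataclass(frozen=True)
class IntersectionTable:
    """All exclusive set intersections of a missingness matrix.

    ``entries`` maps each observed :class:`PatternKey` to its cardinality
    (number of records); fully complete records are excluded from entries
    and tracked in ``complete_record_count``.
    """

    entries: dict[PatternKey, int]
    complete_record_count: int
    field_universe: tuple[str, ...]

    @property
    def n_records(self) -> int:
        return sum(self.entries.values()) + self.complete_record_count

    @property
    def n_intersections(self) -> int:
        return len(self.entries)

    @property
    def total_missing_cells(self) -> int:
        return sum(k.degree * c for k, c in self.entries.items())

    # -- persistence ------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write entries as (pattern, degree, cardinality) rows.

        The complete-record count and field universe travel in ``#``
        comment lines so the round trip is bit-exact.
        """
        with open(path, "w", newline="", encoding="utf-8") as fh:
            fh.write(f"# complete_record_count={self.complete_record_count}\n")
            fh.write(f"# field_universe={'|'.join(self.field_universe)}\n")
            writer = csv.writer(fh)
            writer.writerow(["pattern", "degree", "cardinality"])
            for key in sorted(self.entries):
                writer.writerow([str(key), key.degree, self.entries[key]])

    @classmethod
    def from_csv(cls, path: str | Path) -> "IntersectionTable":
        complete = 0
        universe: tuple[str, ...] = ()
        entries: dict[PatternKey, int] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            meta_lines = []
            while True:
                pos = fh.tell()
                line = fh.readline()
                if line.startswith("#"):
                    meta_lines.append(line)
                else:
                    fh.seek(pos)
                    break
            for line in meta_lines:
                k, _, v = line.lstrip("# ").rstrip("\n").partition("=")
                if k == "complete_record_count":
                    complete = int(v)
                elif k == "field_universe":
                    universe = tuple(v.split("|")) if v else ()
            reader = csv.DictReader(fh)
            for row in reader:
                key = PatternKey.from_fields(row["pattern"].split("|"), universe)
                entries[key] = int(row["cardinality"])
        return cls(entries=entries, complete_record_count=complete,
                   field_universe=universe)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "complete_record_count": self.complete_record_count,
            "field_universe": list(self.field_universe),
            "entries": [
                {"pattern": list(k.fields), "cardinality": c}
                for k, c in sorted(self.entries.items())
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "IntersectionTable":
        raw = json.loads(Path(path).read_text(encoding="utf-8"))
        universe = tuple(raw["field_universe"])
        entries = {
            PatternKey.from_fields(e["pattern"], universe): int(e["cardinality"])
            for e in raw["entries"]
        }
        return cls(entries=entries,
                   complete_record_count=int(raw["complete_record_count"]),
                   field_universe=universe)


@dataclass(frozen=True)
class IntersectionSelection:
    """A chosen group of intersections plus the predicate that chose it."""

    parent: IntersectionTable
    selected_keys: frozenset[PatternKey]
    provenance: str

    def __post_init__(self) -> None:
        stray = self.selected_keys - set(self.parent.entries)
        if stray:
            raise SelectionError(
                f"selection contains keys not in parent table: "
                f"{sorted(str(k) for k in stray)}"
            )

    @property
    def n_intersections(self) -> int:
        return len(self.selected_keys)

    @property
    def n_records(self) -> int:
        return sum(self.parent.entries[k] for k in self.selected_keys)


def compute_sets(mask: MissingnessMatrix) -> list[FieldSetSummary]:
    """Per-field missing counts (column sums of the mask), in dataset order."""
    counts = mask.mask.sum(axis=0)
    n = mask.n_records
    return [
        FieldSetSummary(
            field_name=name,
            missing_count=int(c),
            missing_fraction=(int(c) / n) if n else 0.0,
            degenerate=(n == 0),
        )
        for name, c in zip(mask.field_names, counts)
    ]


def compute_intersections(mask: MissingnessMatrix) -> IntersectionTable:
    """Group records by their exact missing-field combination.

    Each record with >= 1 missing field contributes to exactly one entry;
    complete records go to ``complete_record_count``.
    """
    if mask.n_records == 0:
        return IntersectionTable(entries={}, complete_record_count=0,
                                 field_universe=mask.field_names)
    uniq, counts = np.unique(mask.mask, axis=0, return_counts=True)
    entries: dict[PatternKey, int] = {}
    complete = 0
    for row, count in zip(uniq, counts):
        idx = np.flatnonzero(row)
        if idx.size == 0:
            complete = int(count)
            continue
        key = PatternKey(
            indices=tuple(int(i) for i in idx),
            fields=tuple(mask.field_names[i] for i in idx),
        )
        entries[key] = int(count)
    return IntersectionTable(entries=entries, complete_record_count=complete,
                             field_universe=mask.field_names)


def project_fields(
    mask: MissingnessMatrix, fields: Iterable[str]
) -> IntersectionTable:
    """Intersections of the mask restricted to a subset of fields.

    Records missing none of the chosen fields count as complete even if
    they miss other fields.  The chosen fields keep dataset order.
    """
    chosen = set(fields)
    if not chosen:
        raise ConfigError("projection needs a non-empty field subset")
    unknown = chosen - set(mask.field_names)
    if unknown:
        raise ConfigError(f"unknown fields in projection: {sorted(unknown)}")
    col_idx = [i for i, name in enumerate(mask.field_names) if name in chosen]
    sub = MissingnessMatrix(
        field_names=tuple(mask.field_names[i] for i in col_idx),
        mask=mask.mask[:, col_idx],
    )
    return compute_intersections(sub)


def select_intersections(
    table: IntersectionTable,
    degree_range: tuple[int, int] | None = None,
    cardinality_range: tuple[int, int] | None = None,
    keys: Iterable[PatternKey] | None = None,
    key_predicate: Callable[[PatternKey], bool] | None = None,
    provenance: str | None = None,
) -> IntersectionSelection:
    """Select the entries satisfying the conjunction of the given predicates.

    ``key_predicate`` is the hook used by pattern-class filters (e.g. keep
    only gap keys of a group).  An explicit key not present in the table
    raises :class:`SelectionError`.
    """
    clauses: list[str] = []
    for name, rng in (("degree", degree_range), ("cardinality", cardinality_range)):
        if rng is not None:
            lo, hi = rng
            if lo > hi:
                raise ConfigError(f"malformed {name} range [{lo}, {hi}]")
            clauses.append(f"{name} in [{lo}, {hi}]")

    explicit: set[PatternKey] | None = None
    if keys is not None:
        explicit = set(keys)
        missing = explicit - set(table.entries)
        if missing:
            raise SelectionError(
                f"keys not in table: {sorted(str(k) for k in missing)}"
            )
        clauses.append(f"key in explicit list ({len(explicit)} keys)")
    if key_predicate is not None:
        clauses.append(getattr(key_predicate, "__doc__", None) or "custom predicate")

    selected = set()
    for key, card in table.entries.items():
        if degree_range is not None and not (
            degree_range[0] <= key.degree <= degree_range[1]
        ):
            continue
        if cardinality_range is not None and not (
            cardinality_range[0] <= card <= cardinality_range[1]
        ):
            continue
        if explicit is not None and key not in explicit:
            continue
        if key_predicate is not None and not key_predicate(key):
            continue
        selected.add(key)

    return IntersectionSelection(
        parent=table,
        selected_keys=frozenset(selected),
        provenance=provenance or (" AND ".join(clauses) if clauses else "all entries"),
    )


def sort_intersections(
    source: IntersectionTable | IntersectionSelection,
    by: str = "cardinality",
    descending: bool = False,
) -> list[tuple[PatternKey, int]]:
    """Order intersections by degree or cardinality.

    The sort is stable; ties break on canonical key order (lexicographic
    over dataset-order field indices).
    """
    if by not in ("degree", "cardinality"):
        raise ConfigError(f"unknown sort key {by!r}")
    if isinstance(source, IntersectionSelection):
        items = [(k, source.parent.entries[k]) for k in source.selected_keys]
    else:
        items = list(source.entries.items())
    items.sort(key=lambda kv: kv[0].indices)
    metric = (lambda kv: kv[0].degree) if by == "degree" else (lambda kv: kv[1])
    items.sort(key=metric, reverse=descending)
    return items


def record_ids_for(
    selection: IntersectionSelection, mask: MissingnessMatrix
) -> list[int]:
    """Indices of the records whose missing-field set equals a selected key.

    Needs the originating mask: the table itself does not retain record
    identity.
    """
    if tuple(mask.field_names) != tuple(selection.parent.field_universe):
        raise ConfigError(
            "mask field universe does not match the selection's parent table"
        )
    if not selection.selected_keys or mask.n_records == 0:
        return []
    uniq, inverse = np.unique(mask.mask, axis=0, return_inverse=True)
    wanted_index_sets = {key.indices for key in selection.selected_keys}
    uniq_selected = np.array(
        [tuple(int(i) for i in np.flatnonzero(row)) in wanted_index_sets
         for row in uniq],
        dtype=bool,
    )
    return [int(i) for i in np.flatnonzero(uniq_selected[inverse])]


def membership_labels(
    selection: IntersectionSelection, mask: MissingnessMatrix
) -> np.ndarray:
    """Boolean per-record vector: True = record belongs to the selection."""
    labels = np.zeros(mask.n_records, dtype=bool)
    labels[record_ids_for(selection, mask)] = True
    return labels
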