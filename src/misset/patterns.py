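"""Structural expectations for ordered field groups.

Incrementally-filled code fields (DIAG_01..DIAG_20 style) should exhibit a
*monotone* missingness pattern: a record's missing members form a suffix of
the group order.  A *gap* is a missing member followed by a present one —
the data-quality anomaly this module detects.  Paired code/date groups
(OPERTN_nn with MYOPDATE_nn) should exhibit a *block* pattern: each code
and its date are missing or present together; an asymmetric position is a
pair discrepancy, labelled ``fewer_dates`` (code present, date missing) or
``extra_dates`` (date present, code missing).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .errors import ConfigError
from .set_engine import (
    IntersectionSelection,
    IntersectionTable,
    PatternKey,
    select_intersections,
)

__all__ = [
    "OrderedFieldGroup",
    "PairedGroup",
    "PatternClassification",
    "PairConsistency",
    "GroupSummary",
    "classify_against_group",
    "summarise_group",
    "check_pair_consistency",
    "select_gap_intersections",
    "infer_group",
    "load_group_config",
]


@dataclass(frozen=True)
class OrderedFieldGroup:
    """A sequence of fields expected to be filled incrementally."""

    group_id: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ConfigError(f"group {self.group_id!r} needs >= 2 members")
        if len(set(self.members)) != len(self.members):
            raise ConfigError(f"group {self.group_id!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class PairedGroup:
    """Two equal-length ordered groups paired position-by-position."""

    left: OrderedFieldGroup   # codes
    right: OrderedFieldGroup  # dates

    def __post_init__(self) -> None:
        if len(self.left) != len(self.right):
            raise ConfigError(
                f"paired groups {self.left.group_id!r}/{self.right.group_id!r} "
                "must have equal lengths"
            )

    def __len__(self) -> int:
        return len(self.left)


@dataclass(frozen=True)
class PatternClassification:
    """Monotone/gap verdict for one key against one group.

    ``gap_positions`` lists the 1-based group positions i where member i is
    missing but some later member is present.  A key is monotone iff that
    list is empty, i.e. its within-group missing members form a (possibly
    empty or full) suffix of the group order.
    """

    key: PatternKey
    group_id: str
    pattern_class: str  # "monotone" | "gap"
    gap_positions: tuple[int, ...]


@dataclass(frozen=True)
class PairConsistency:
    """Block-pattern verdict for one key against one paired group."""

    key: PatternKey
    status: str  # "matched" | "fewer_dates" | "extra_dates"
    mismatch_positions: tuple[int, ...]


@dataclass(frozen=True)
class GroupSummary:
    """Monotone-vs-gap tallies for a whole intersection table."""

    group_id: str
    monotone_intersections: int
    monotone_records: int
    gap_intersections: int
    gap_records: int
    gap_keys: tuple[PatternKey, ...]


def classify_against_group(
    key: PatternKey, group: OrderedFieldGroup
) -> PatternClassification:
    """Classify a key as monotone or gap with respect to one group.

    Only the group's members matter; fields outside the group never change
    the verdict.  A key missing none (or all) of the members is monotone.
    """
    missing = [member in key for member in group.members]
    gaps = tuple(
        i + 1
        for i in range(len(missing))
        if missing[i] and any(not m for m in missing[i + 1:])
    )
    return PatternClassification(
        key=key,
        group_id=group.group_id,
        pattern_class="gap" if gaps else "monotone",
        gap_positions=gaps,
    )


def summarise_group(
    table: IntersectionTable, group: OrderedFieldGroup
) -> GroupSummary:
    """Partition a table's entries into monotone and gap intersections."""
    mono_i = mono_r = gap_i = gap_r = 0
    gap_keys: list[PatternKey] = []
    for key, card in table.entries.items():
        cls = classify_against_group(key, group)
        if cls.pattern_class == "gap":
            gap_i += 1
            gap_r += card
            gap_keys.append(key)
        else:
            mono_i += 1
            mono_r += card
    return GroupSummary(
        group_id=group.group_id,
        monotone_intersections=mono_i,
        monotone_records=mono_r,
        gap_intersections=gap_i,
        gap_records=gap_r,
        gap_keys=tuple(sorted(gap_keys)),
    )


def check_pair_consistency(key: PatternKey, pair: PairedGroup) -> PairConsistency:
    """Check the block expectation: each code/date pair missing together.

    Position i mismatches iff exactly one of (code_i, date_i) is in the
    key.  A key with mismatches in both directions takes the majority
    label, with ``fewer_dates`` winning ties.
    """
    fewer = 0  # code present, date missing
    extra = 0  # date present, code missing
    mismatches: list[int] = []
    for i, (code, date) in enumerate(zip(pair.left.members, pair.right.members)):
        code_missing = code in key
        date_missing = date in key
        if code_missing != date_missing:
            mismatches.append(i + 1)
            if date_missing:
                fewer += 1
            else:
                extra += 1
    if not mismatches:
        status = "matched"
    elif fewer >= extra:
        status = "fewer_dates"
    else:
        status = "extra_dates"
    return PairConsistency(
        key=key, status=status, mismatch_positions=tuple(mismatches)
    )


def select_gap_intersections(
    table: IntersectionTable, group: OrderedFieldGroup
) -> IntersectionSelection:
    """Select every intersection classified as a gap for ``group``."""

    def is_gap(key: PatternKey) -> bool:
        return classify_against_group(key, group).pattern_class == "gap"

    return select_intersections(
        table,
        key_predicate=is_gap,
        provenance=f"gap intersections of group {group.group_id!r}",
    )


def infer_group(
    field_names: Sequence[str], prefix: str, group_id: str | None = None
) -> OrderedFieldGroup:
    """Build an ordered group from numbered names like ``DIAG_01..DIAG_20``.

    Members are fields matching ``PREFIX_<number>``; positions must be
    consecutive from 1 after sorting numerically.
    """
    pattern = re.compile(re.escape(prefix) + r"_(\d+)$")
    found: list[tuple[int, str]] = []
    for name in field_names:
        m = pattern.match(name)
        if m:
            found.append((int(m.group(1)), name))
    found.sort()
    if not found:
        raise ConfigError(f"no fields match prefix {prefix!r}")
    positions = [p for p, _ in found]
    if positions != list(range(1, len(found) + 1)):
        raise ConfigError(
            f"group {prefix!r} positions are not consecutive from 1: {positions}"
        )
    return OrderedFieldGroup(
        group_id=group_id or prefix.lower(),
        members=tuple(name for _, name in found),
    )


def load_group_config(
    path: str | Path, field_universe: Sequence[str] | None = None
) -> tuple[dict[str, OrderedFieldGroup], list[PairedGroup]]:
    """Load group/pair definitions from JSON.

    Format: ``{"groups": [{"id": ..., "fields": [...]}],
    "pairs": [{"left": <group id>, "right": <group id>}]}``.
    """
    raw = json.loads(Path(path).read_text(encoding="utf-8"))
    groups: dict[str, OrderedFieldGroup] = {}
    for g in raw.get("groups", []):
        group = OrderedFieldGroup(group_id=g["id"], members=tuple(g["fields"]))
        if field_universe is not None:
            unknown = set(group.members) - set(field_universe)
            if unknown:
                raise ConfigError(
                    f"group {group.group_id!r} names unknown fields "
                    f"{sorted(unknown)}"
                )
        groups[group.group_id] = group
    pairs: list[PairedGroup] = []
    for p in raw.get("pairs", []):
        try:
            pairs.append(PairedGroup(left=groups[p["left"]], right=groups[p["right"]]))
        except KeyError as exc:
            raise ConfigError(f"pair references unknown group {exc.args[0]!r}") from None
    return groups, pairs
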