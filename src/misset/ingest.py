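"""Reading delimited tables and deriving missingness under a token policy.

A record×field table of raw text cells is turned into a boolean
*missingness matrix*: cell (i, j) is True when record i is missing a value
for field j.  Which raw strings count as "missing" is governed entirely by
an explicit :class:`MissingTokenPolicy` — sentinel codes used by data
providers ("unknown" values such as ``"99"`` for an unknown sex code) are
declared per field, never guessed.  No type inference happens before
masking: sentinels are textual codes and are matched as trimmed strings.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ParseError

__all__ = [
    "ColumnSpec",
    "MissingTokenPolicy",
    "MissingnessMatrix",
    "read_table",
    "build_missingness_mask",
]


@dataclass(frozen=True)
class ColumnSpec:
    """One column of the source table.

    ``role`` is ``"general"`` for standalone fields or ``"group-member"``
    for fields that belong to an ordered group (e.g. ``DIAG_03`` at
    position 3 of the diagnosis group).
    """

    name: str
    role: str = "general"
    group_id: str | None = None
    position_in_group: int | None = None

    def __post_init__(self) -> None:
        if self.role not in ("general", "group-member"):
            raise ConfigError(f"unknown column role {self.role!r}")
        if self.role == "group-member":
            if self.group_id is None or self.position_in_group is None:
                raise ConfigError(
                    f"group-member column {self.name!r} needs group_id and "
                    "position_in_group"
                )
            if self.position_in_group < 1:
                raise ConfigError("position_in_group must be >= 1")


@dataclass(frozen=True)
class MissingTokenPolicy:
    """Which raw strings are treated as missing.

    Per-field token sets *extend* the global set; they never replace it.
    Matching is exact string equality after trimming leading/trailing
    whitespace, case-sensitive unless ``case_insensitive`` is set.
    """

    global_tokens: frozenset[str] = frozenset({"NA"})
    per_field_tokens: Mapping[str, frozenset[str]] = field(default_factory=dict)
    empty_string_is_missing: bool = True
    case_insensitive: bool = False

    @classmethod
    def default(cls) -> "MissingTokenPolicy":
        """Empty string and literal ``"NA"`` are missing; nothing else."""
        return cls()

    @classmethod
    def from_json(cls, path: str | Path) -> "MissingTokenPolicy":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        return cls(
            global_tokens=frozenset(raw.get("global_tokens", ["NA"])),
            per_field_tokens={
                name: frozenset(tokens)
                for name, tokens in raw.get("per_field_tokens", {}).items()
            },
            empty_string_is_missing=bool(raw.get("empty_string_is_missing", True)),
            case_insensitive=bool(raw.get("case_insensitive", False)),
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "global_tokens": sorted(self.global_tokens),
            "per_field_tokens": {
                name: sorted(tokens)
                for name, tokens in sorted(self.per_field_tokens.items())
            },
            "empty_string_is_missing": self.empty_string_is_missing,
            "case_insensitive": self.case_insensitive,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")

    def tokens_for(self, field_name: str) -> frozenset[str]:
        extra = self.per_field_tokens.get(field_name, frozenset())
        tokens = self.global_tokens | frozenset(extra)
        if self.case_insensitive:
            tokens = frozenset(t.casefold() for t in tokens)
        return tokens


@dataclass(frozen=True)
class MissingnessMatrix:
    """Boolean record×field indicator grid (True = missing).

    Field order is preserved from the source file ("dataset order"); every
    downstream canonical ordering of pattern keys is defined against it.
    """

    field_names: tuple[str, ...]
    mask: np.ndarray  # shape (n_records, n_fields), dtype bool

    def __post_init__(self) -> None:
        if self.mask.ndim != 2 or self.mask.shape[1] != len(self.field_names):
            raise ConfigError(
                f"mask shape {self.mask.shape} does not match "
                f"{len(self.field_names)} field names"
            )

    @property
    def n_records(self) -> int:
        return int(self.mask.shape[0])

    @property
    def n_fields(self) -> int:
        return int(self.mask.shape[1])

    def field_index(self, name: str) -> int:
        try:
            return self.field_names.index(name)
        except ValueError:
            raise ConfigError(f"unknown field {name!r}") from None


def read_table(
    path: str | Path,
    delimiter: str = ",",
    has_header: bool = True,
) -> tuple[pd.DataFrame, list[ColumnSpec]]:
    """Read a delimited text file into a DataFrame of raw text cells.

    All cells are retained as text — no type coercion happens before
    token matching.  Column order is file order.

    Raises
    ------
    ParseError
        For an empty file or ragged rows (the message names the offending
        1-based row number).
    ConfigError
        For duplicate header names.
    OSError
        If the file cannot be read.
    """
    path = Path(path)
    rows: list[list[str]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        rows = list(reader)
    if not rows:
        raise ParseError(f"{path}: file is empty")

    if has_header:
        header = [h.strip() for h in rows[0]]
        data_rows = rows[1:]
        if len(set(header)) != len(header):
            dupes = sorted({h for h in header if header.count(h) > 1})
            raise ConfigError(f"{path}: duplicate header names {dupes}")
    else:
        header = [f"col_{i + 1}" for i in range(len(rows[0]))]
        data_rows = rows

    width = len(header)
    # blank separator lines parse as zero-cell rows; skip them
    kept: list[list[str]] = []
    for i, row in enumerate(data_rows):
        if not row:
            continue
        kept.append(row)
        if len(row) != width:
            row_number = i + (2 if has_header else 1)
            raise ParseError(
                f"{path}: row {row_number} has {len(row)} cells, expected {width}"
            )

    table = pd.DataFrame(kept, columns=header, dtype=object)
    specs = [ColumnSpec(name=name) for name in header]
    return table, specs


def build_missingness_mask(
    table: pd.DataFrame,
    policy: MissingTokenPolicy | None = None,
) -> MissingnessMatrix:
    """Flag cells as missing under the token policy.

    A cell is missing iff it is empty/whitespace-only (when the policy says
    so) or its trimmed value is in the union of global and per-field token
    sets.  The mask is a pure function of table + policy.
    """
    if policy is None:
        policy = MissingTokenPolicy.default()

    for name in policy.per_field_tokens:
        if name not in table.columns:
            raise ConfigError(f"policy names unknown field {name!r}")

    n_records = len(table)
    field_names = tuple(str(c) for c in table.columns)
    mask = np.zeros((n_records, len(field_names)), dtype=bool)

    for j, name in enumerate(field_names):
        col = table.iloc[:, j].astype(str).str.strip()
        if policy.case_insensitive:
            col = col.str.casefold()
        tokens = policy.tokens_for(name)
        missing = col.isin(tokens).to_numpy()
        if policy.empty_string_is_missing:
            missing |= (col == "").to_numpy()
        mask[:, j] = missing

    return MissingnessMatrix(field_names=field_names, mask=mask)


def mask_from_file(
    path: str | Path,
    policy: MissingTokenPolicy | None = None,
    delimiter: str = ",",
) -> tuple[pd.DataFrame, MissingnessMatrix]:
    """Convenience: read a table and build its missingness matrix."""
    table, _ = read_table(path, delimiter=delimiter)
    return table, build_missingness_mask(table, policy)
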