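"""Shared fixtures and brute-force oracle helpers.

The oracles deliberately avoid the library's own code paths: they tally
cell by cell over plain Python sets so every engine result can be checked
against an independent computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from misset import MissingnessMatrix, PatternKey


def mask_of(rows: list[set[str]], fields: list[str]) -> MissingnessMatrix:
    """Build a matrix from per-record missing-field sets."""
    mask = np.zeros((len(rows), len(fields)), dtype=bool)
    for i, missing in enumerate(rows):
        for f in missing:
            mask[i, fields.index(f)] = True
    return MissingnessMatrix(field_names=tuple(fields), mask=mask)


def brute_force_intersections(
    mask: MissingnessMatrix,
) -> tuple[dict[frozenset, int], int]:
    """Group records by frozen missing-field set, one at a time."""
    groups: dict[frozenset, int] = {}
    complete = 0
    for row in mask.mask:
        missing = frozenset(
            mask.field_names[j] for j in range(mask.n_fields) if row[j]
        )
        if not missing:
            complete += 1
        else:
            groups[missing] = groups.get(missing, 0) + 1
    return groups, complete


def table_as_sets(table) -> dict[frozenset, int]:
    return {frozenset(k.fields): c for k, c in table.entries.items()}


def key_of(fields, universe) -> PatternKey:
    return PatternKey.from_fields(fields, universe)


@pytest.fixture
def rng():
    return np.random.default_rng(20160331)


@pytest.fixture
def random_mask(rng):
    def make(n_records=50, n_fields=8, p=0.3, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        fields = [f"F{j:02d}" for j in range(n_fields)]
        return MissingnessMatrix(
            field_names=tuple(fields),
            mask=r.random((n_records, n_fields)) < p,
        )

    return make
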