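"""Synthetic EHR-like tables with known missingness structure.

The generator emulates the structure of English admitted-patient-care
extracts: a block of general fields (identifiers, episode metadata,
admission method, provider code), an incrementally-filled diagnosis-code
group whose missingness should be monotone, and a paired operation
code/date block where each code and its date should be missing together.
On top of that clean structure, anomaly rules plant the archetypal
data-quality defects: *gaps* (an interior code blanked while later codes
remain) concentrated in specific values of categorical driver fields,
*pair mismatches* (dates dropped or added relative to codes), and general
fields blanked under driver conditions.

Every generated table ships with a :class:`GroundTruth` record of exactly
which cells were blanked and why, so every downstream module can be tested
against a known answer, and with the missing-token policy needed to read
the file back, so the full raw-text pipeline is exercised.

Cell contents are arbitrary category codes: realism is confined to the
missingness structure and driver associations, which is what the analysis
operates on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .ingest import MissingTokenPolicy
from .patterns import OrderedFieldGroup, PairedGroup

__all__ = [
    "DriverField",
    "MonotoneGroupSpec",
    "PairedGroupSpec",
    "AnomalyRule",
    "SynthConfig",
    "GroundTruth",
    "generate",
    "preset_hes_like",
    "zero_anomaly",
]

_PROB_TOL = 1e-9


def _check_probs(probs: Sequence[float], what: str) -> None:
    p = np.asarray(probs, dtype=float)
    if (p < 0).any() or abs(p.sum() - 1.0) > _PROB_TOL:
        raise ConfigError(f"{what}: probabilities must be >= 0 and sum to 1")


@dataclass(frozen=True)
class DriverField:
    """A categorical field whose values may drive anomalies."""

    name: str
    categories: tuple[str, ...]
    probabilities: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.categories) != len(self.probabilities):
            raise ConfigError(f"driver {self.name!r}: categories/probs mismatch")
        _check_probs(self.probabilities, f"driver {self.name!r}")


@dataclass(frozen=True)
class MonotoneGroupSpec:
    """An incrementally-filled group: members 1..depth present, rest missing.

    ``depth_distribution`` has ``n_members + 1`` entries, for fill depths
    0..n_members.
    """

    group_id: str
    prefix: str
    n_members: int
    depth_distribution: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.n_members < 2:
            raise ConfigError(f"group {self.group_id!r}: need >= 2 members")
        if len(self.depth_distribution) != self.n_members + 1:
            raise ConfigError(
                f"group {self.group_id!r}: depth distribution needs "
                f"{self.n_members + 1} entries"
            )
        _check_probs(self.depth_distribution, f"group {self.group_id!r}")

    @property
    def members(self) -> tuple[str, ...]:
        return tuple(f"{self.prefix}_{i:02d}" for i in range(1, self.n_members + 1))


@dataclass(frozen=True)
class PairedGroupSpec:
    """Two groups filled jointly to a shared depth (block pattern)."""

    pair_id: str
    left_prefix: str   # codes
    right_prefix: str  # dates
    n_members: int
    depth_distribution: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.depth_distribution) != self.n_members + 1:
            raise ConfigError(
                f"pair {self.pair_id!r}: depth distribution needs "
                f"{self.n_members + 1} entries"
            )
        _check_probs(self.depth_distribution, f"pair {self.pair_id!r}")

    @property
    def left_id(self) -> str:
        return f"{self.pair_id}_codes"

    @property
    def right_id(self) -> str:
        return f"{self.pair_id}_dates"

    @property
    def left_members(self) -> tuple[str, ...]:
        return tuple(f"{self.left_prefix}_{i:02d}"
                     for i in range(1, self.n_members + 1))

    @property
    def right_members(self) -> tuple[str, ...]:
        return tuple(f"{self.right_prefix}_{i:02d}"
                     for i in range(1, self.n_members + 1))


@dataclass(frozen=True)
class AnomalyRule:
    """One planted defect, fired per record with probability ``rate`` when
    the record satisfies the driver condition.

    ``condition`` is a conjunction of (driver field, allowed values)
    clauses.  Kinds:

    * ``gap`` — blank group ``group_id`` at ``position`` (1-based) when the
      fill depth reaches past it (``position`` may be ``None``: a random
      interior position is drawn per firing record);
    * ``pair_mismatch`` — on pair ``pair_id``, drop the last date
      (``direction="fewer_dates"``) or add a date beyond the code depth
      (``direction="extra_dates"``);
    * ``field_missing`` — blank the general field ``target_field``.
    """

    kind: str  # "gap" | "pair_mismatch" | "field_missing"
    rate: float
    condition: tuple[tuple[str, tuple[str, ...]], ...] = ()
    group_id: str | None = None
    position: int | None = None
    pair_id: str | None = None
    direction: str = "fewer_dates"
    target_field: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("gap", "pair_mismatch", "field_missing"):
            raise ConfigError(f"unknown anomaly kind {self.kind!r}")
        if not 0.0 <= self.rate <= 1.0:
            raise ConfigError("anomaly rate must be in [0, 1]")
        if self.kind == "gap" and self.group_id is None:
            raise ConfigError("gap rule needs a group_id")
        if self.kind == "pair_mismatch":
            if self.pair_id is None:
                raise ConfigError("pair_mismatch rule needs a pair_id")
            if self.direction not in ("fewer_dates", "extra_dates"):
                raise ConfigError(f"unknown direction {self.direction!r}")
        if self.kind == "field_missing" and self.target_field is None:
            raise ConfigError("field_missing rule needs a target_field")


@dataclass(frozen=True)
class SynthConfig:
    """Full description of one synthetic dataset."""

    n_records: int
    general_fields: tuple[str, ...]
    driver_fields: tuple[DriverField, ...]
    groups: tuple[MonotoneGroupSpec, ...] = ()
    pairs: tuple[PairedGroupSpec, ...] = ()
    anomaly_rules: tuple[AnomalyRule, ...] = ()
    seed: int = 0
    missing_tokens: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise ConfigError("n_records must be positive")
        driver_names = {d.name for d in self.driver_fields}
        if not driver_names <= set(self.general_fields):
            raise ConfigError("every driver field must appear in general_fields")

    @property
    def field_names(self) -> tuple[str, ...]:
        names = list(self.general_fields)
        for g in self.groups:
            names.extend(g.members)
        for p in self.pairs:
            names.extend(p.left_members)
            names.extend(p.right_members)
        if len(set(names)) != len(names):
            raise ConfigError("duplicate field names in configuration")
        return tuple(names)

    def policy(self) -> MissingTokenPolicy:
        """The token policy needed to read the emitted file back."""
        return MissingTokenPolicy(
            global_tokens=frozenset({"NA"}),
            per_field_tokens={
                name: frozenset({token})
                for name, token in self.missing_tokens.items()
                if token != ""
            },
            empty_string_is_missing=True,
        )

    def ordered_groups(self) -> dict[str, OrderedFieldGroup]:
        """Every monotone expectation, including both sides of each pair."""
        groups = {
            g.group_id: OrderedFieldGroup(g.group_id, g.members)
            for g in self.groups
        }
        for p in self.pairs:
            groups[p.left_id] = OrderedFieldGroup(p.left_id, p.left_members)
            groups[p.right_id] = OrderedFieldGroup(p.right_id, p.right_members)
        return groups

    def paired_groups(self) -> dict[str, PairedGroup]:
        groups = self.ordered_groups()
        return {
            p.pair_id: PairedGroup(left=groups[p.left_id],
                                   right=groups[p.right_id])
            for p in self.pairs
        }

    def groups_json(self, path: str | Path) -> None:
        groups = self.ordered_groups()
        payload = {
            "groups": [
                {"id": gid, "fields": list(g.members)}
                for gid, g in groups.items()
            ],
            "pairs": [
                {"left": p.left_id, "right": p.right_id} for p in self.pairs
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n",
                              encoding="utf-8")


@dataclass(frozen=True)
class GroundTruth:
    """Cell-exact record of what the generator did.

    ``missing_field_indices`` indexes into ``field_names`` and reproduces,
    per record, the exact set of missing fields in the emitted file.
    """

    field_names: tuple[str, ...]
    depths: dict[str, list[int]]          # group/pair-side id -> per-record depth
    driver_values: dict[str, list[str]]
    anomalies: list[list[dict]]           # per record: fired-rule descriptors
    missing_field_indices: list[list[int]]
    rule_fired_counts: list[int]          # per rule: number of firing records

    def missing_sets(self) -> list[set[str]]:
        return [
            {self.field_names[i] for i in idx}
            for idx in self.missing_field_indices
        ]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "field_names": list(self.field_names),
            "depths": self.depths,
            "driver_values": self.driver_values,
            "anomalies": self.anomalies,
            "missing_field_indices": self.missing_field_indices,
            "rule_fired_counts": self.rule_fired_counts,
        }
        Path(path).write_text(json.dumps(payload) + "\n", encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        raw = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            field_names=tuple(raw["field_names"]),
            depths={k: list(v) for k, v in raw["depths"].items()},
            driver_values={k: list(v) for k, v in raw["driver_values"].items()},
            anomalies=raw["anomalies"],
            missing_field_indices=raw["missing_field_indices"],
            rule_fired_counts=list(raw["rule_fired_counts"]),
        )


def generate(
    config: SynthConfig, out_dir: str | Path | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate one table (as raw text cells) plus its ground truth.

    Deterministic given the config (a single generator stream seeded from
    ``config.seed``).  When ``out_dir`` is given, writes ``data.csv``,
    ``groundtruth.json``, ``policy.json`` and ``groups.json`` there;
    missing cells are written as the per-field sentinel token (default:
    empty string) so the raw-text ingest path is exercised end to end.
    """
    n = config.n_records
    field_names = config.field_names
    rng = np.random.default_rng(config.seed)

    values: dict[str, np.ndarray] = {}
    missing: dict[str, np.ndarray] = {}

    driver_values: dict[str, np.ndarray] = {}
    for d in config.driver_fields:
        driver_values[d.name] = rng.choice(
            np.array(d.categories, dtype=object), size=n,
            p=np.asarray(d.probabilities, dtype=float),
        )

    for name in config.general_fields:
        if name in driver_values:
            values[name] = driver_values[name].copy()
        else:
            values[name] = np.array(
                [f"{name[:2]}{i:07d}" for i in range(n)], dtype=object
            )
        missing[name] = np.zeros(n, dtype=bool)

    # monotone groups: present up to the sampled depth, missing after
    depths: dict[str, np.ndarray] = {}
    group_members: dict[str, tuple[str, ...]] = {}
    for g in config.groups:
        depth = rng.choice(g.n_members + 1, size=n,
                           p=np.asarray(g.depth_distribution, dtype=float))
        depths[g.group_id] = depth
        group_members[g.group_id] = g.members
        codes = rng.integers(100, 999, size=(n, g.n_members))
        for pos, member in enumerate(g.members, start=1):
            values[member] = np.array(
                [f"C{c}" for c in codes[:, pos - 1]], dtype=object
            )
            missing[member] = depth < pos

    # paired groups: both sides share one depth (block pattern)
    for p in config.pairs:
        depth = rng.choice(p.n_members + 1, size=n,
                           p=np.asarray(p.depth_distribution, dtype=float))
        depths[p.left_id] = depth
        depths[p.right_id] = depth
        group_members[p.left_id] = p.left_members
        group_members[p.right_id] = p.right_members
        codes = rng.integers(100, 999, size=(n, p.n_members))
        days = rng.integers(1, 366, size=(n, p.n_members))
        for pos in range(1, p.n_members + 1):
            left, right = p.left_members[pos - 1], p.right_members[pos - 1]
            values[left] = np.array(
                [f"O{c}" for c in codes[:, pos - 1]], dtype=object
            )
            values[right] = np.array(
                [f"2016-{d:03d}" for d in days[:, pos - 1]], dtype=object
            )
            missing[left] = depth < pos
            missing[right] = (depth < pos).copy()

    anomalies: list[list[dict]] = [[] for _ in range(n)]
    rule_fired_counts: list[int] = []

    for rule_idx, rule in enumerate(config.anomaly_rules):
        cond = np.ones(n, dtype=bool)
        for fname, allowed in rule.condition:
            if fname not in values:
                raise ConfigError(f"anomaly condition names unknown field {fname!r}")
            cond &= np.isin(values[fname], np.array(allowed, dtype=object))

        fired_records: list[int] = []
        if rule.kind == "field_missing":
            if rule.target_field not in missing:
                raise ConfigError(
                    f"field_missing rule targets unknown field "
                    f"{rule.target_field!r}"
                )
            fire = cond & (rng.random(n) < rule.rate)
            missing[rule.target_field] |= fire
            fired_records = [int(i) for i in np.flatnonzero(fire)]
            for i in fired_records:
                anomalies[i].append(
                    {"rule": rule_idx, "kind": "field_missing",
                     "field": rule.target_field}
                )
        elif rule.kind == "gap":
            if rule.group_id not in depths:
                raise ConfigError(f"gap rule names unknown group {rule.group_id!r}")
            depth = depths[rule.group_id]
            members = group_members[rule.group_id]
            if rule.position is not None:
                # need a later present member: depth must reach past position
                eligible = cond & (depth >= rule.position + 1)
                fire = eligible & (rng.random(n) < rule.rate)
                pos_of = {int(i): rule.position for i in np.flatnonzero(fire)}
            else:
                eligible = cond & (depth >= 2)
                fire = eligible & (rng.random(n) < rule.rate)
                pos_of = {
                    int(i): int(rng.integers(1, depth[i]))
                    for i in np.flatnonzero(fire)
                }
            for i, pos in pos_of.items():
                missing[members[pos - 1]][i] = True
                anomalies[i].append(
                    {"rule": rule_idx, "kind": "gap",
                     "group": rule.group_id, "position": pos}
                )
            fired_records = sorted(pos_of)
        else:  # pair_mismatch
            pair = next(
                (p for p in config.pairs if p.pair_id == rule.pair_id), None
            )
            if pair is None:
                raise ConfigError(
                    f"pair_mismatch rule names unknown pair {rule.pair_id!r}"
                )
            depth = depths[pair.left_id]
            if rule.direction == "fewer_dates":
                eligible = cond & (depth >= 1)
            else:
                eligible = cond & (depth < pair.n_members)
            fire = eligible & (rng.random(n) < rule.rate)
            for i in np.flatnonzero(fire):
                i = int(i)
                if rule.direction == "fewer_dates":
                    pos = int(depth[i])  # drop the last date
                    missing[pair.right_members[pos - 1]][i] = True
                else:
                    pos = int(depth[i]) + 1  # extra date beyond code depth
                    missing[pair.right_members[pos - 1]][i] = False
                anomalies[i].append(
                    {"rule": rule_idx, "kind": "pair_mismatch",
                     "pair": rule.pair_id, "direction": rule.direction,
                     "position": pos}
                )
                fired_records.append(i)
        rule_fired_counts.append(len(fired_records))

    mask_matrix = np.column_stack([missing[name] for name in field_names])
    missing_field_indices = [
        [int(j) for j in np.flatnonzero(row)] for row in mask_matrix
    ]

    truth = GroundTruth(
        field_names=field_names,
        depths={gid: [int(d) for d in arr] for gid, arr in depths.items()},
        driver_values={
            name: [str(v) for v in arr] for name, arr in driver_values.items()
        },
        anomalies=anomalies,
        missing_field_indices=missing_field_indices,
        rule_fired_counts=rule_fired_counts,
    )

    cells = {}
    for name in field_names:
        token = config.missing_tokens.get(name, "")
        col = values[name].copy()
        col[missing[name]] = token
        cells[name] = col
    table = pd.DataFrame(cells, columns=list(field_names), dtype=object)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "data.csv", index=False)
        truth.to_json(out_dir / "groundtruth.json")
        config.policy().to_json(out_dir / "policy.json")
        config.groups_json(out_dir / "groups.json")

    return table, truth


def zero_anomaly(config: SynthConfig) -> SynthConfig:
    """A copy of the config with every anomaly rate set to 0."""
    return replace(
        config,
        anomaly_rules=tuple(replace(r, rate=0.0) for r in config.anomaly_rules),
    )


def _geometric_depth(n_members: int, p_zero: float, decay: float) -> tuple[float, ...]:
    """Depth distribution: mass p_zero at 0, then a truncated geometric."""
    tail = np.array([decay ** k for k in range(n_members)], dtype=float)
    tail = (1.0 - p_zero) * tail / tail.sum()
    probs = np.concatenate([[p_zero], tail])
    return tuple(float(x) for x in probs / probs.sum())


def preset_planted_driver(
    n_records: int = 1000, penetrance: float = 0.9, seed: int = 0
) -> SynthConfig:
    """A small recovery benchmark: one driver, three noise fields.

    A 5-member code group is always filled to depth 4 or 5, and records
    with ``PROV == "P03"`` get a gap at position 3 with probability
    ``penetrance``.  The three noise fields are independent of the gaps,
    so a correct explanation run must rank PROV first and single out
    value ``P03``.
    """
    prov = DriverField(
        "PROV", tuple(f"P{i:02d}" for i in range(1, 11)), (0.1,) * 10
    )
    noise = (
        DriverField("N1", ("a", "b", "c"), (0.5, 0.3, 0.2)),
        DriverField("N2", ("u", "v", "w", "x", "y"), (0.2,) * 5),
        DriverField("N3", ("0", "1"), (0.5, 0.5)),
    )
    group = MonotoneGroupSpec(
        group_id="code", prefix="CODE", n_members=5,
        depth_distribution=(0.0, 0.0, 0.0, 0.0, 0.5, 0.5),
    )
    rule = AnomalyRule(
        kind="gap", rate=penetrance, condition=(("PROV", ("P03",)),),
        group_id="code", position=3,
    )
    return SynthConfig(
        n_records=n_records,
        general_fields=("RECID", "PROV", "N1", "N2", "N3"),
        driver_fields=(prov,) + noise,
        groups=(group,),
        anomaly_rules=(rule,),
        seed=seed,
    )


def preset_hes_like(n_records: int = 10_000, seed: int = 0) -> SynthConfig:
    """An 86-field configuration shaped like an admitted-patient-care extract.

    18 general fields (identifiers, episode metadata, admission method,
    provider code), a 20-member diagnosis-code group, and a paired
    24-member operation code/date block.  Three categorical drivers
    (episode type, admission method, provider code) concentrate the
    planted anomalies:

    * survival time is blanked for every surviving patient, and the A&E
      linkage key for every admission that did not come through A&E — the
      two dominant, structurally expected patterns;
    * the episode-order field is blanked for unfinished episodes at two
      specific providers — a rare conditional defect;
    * diagnosis-code gaps at position 3 (and operation code/date gaps) are
      planted exclusively in birth episodes recorded by one provider;
    * a small fraction of one provider's operations lack the matching
      date, and another provider occasionally records an extra date.
    """
    epitype = DriverField(
        "EPITYPE", ("1", "2", "3", "5", "6"), (0.83, 0.03, 0.10, 0.03, 0.01)
    )
    admimeth = DriverField(
        "ADMIMETH", ("11", "12", "21", "31", "81"), (0.42, 0.05, 0.35, 0.10, 0.08)
    )
    n_prov = 30
    prov_codes = tuple(f"P9{i:02d}" for i in range(1, n_prov + 1))
    prov_probs = (0.2,) + tuple(0.8 / (n_prov - 1) for _ in range(n_prov - 1))
    procode = DriverField("PROCODE", prov_codes, prov_probs)
    fae = DriverField("FAE", ("1", "0"), (0.8, 0.2))
    mortality = DriverField("Mortality", ("0", "1"), (0.96, 0.04))
    sex = DriverField("SEX", ("1", "2"), (0.49, 0.51))
    epistat = DriverField("EPISTAT", ("3", "1"), (0.97, 0.03))
    epiorder = DriverField("EPIORDER", ("1", "2", "3"), (0.7, 0.2, 0.1))

    general = (
        "ENCRYPTED_HESID", "EPIKEY", "AEKEY", "EPIORDER", "EPISTAT",
        "EPITYPE", "FAE", "FCE", "MYADMIDATE", "MYEPISTART", "MYEPIEND",
        "MYDOB", "ADMIAGE", "SEX", "Mortality", "SURVIVALTIME",
        "ADMIMETH", "PROCODE",
    )
    fce = DriverField("FCE", ("1", "0"), (0.9, 0.1))

    diag = MonotoneGroupSpec(
        group_id="diag", prefix="DIAG", n_members=20,
        depth_distribution=_geometric_depth(20, p_zero=0.01, decay=0.75),
    )
    opertn = PairedGroupSpec(
        pair_id="opertn", left_prefix="OPERTN", right_prefix="MYOPDATE",
        n_members=24,
        depth_distribution=_geometric_depth(24, p_zero=0.45, decay=0.6),
    )

    gap_condition = (
        ("EPITYPE", ("3",)),
        ("PROCODE", ("P901",)),
    )
    rules = (
        AnomalyRule(kind="field_missing", rate=1.0,
                    condition=(("Mortality", ("0",)),),
                    target_field="SURVIVALTIME"),
        AnomalyRule(kind="field_missing", rate=1.0,
                    condition=(("ADMIMETH", ("11", "12", "31", "81")),),
                    target_field="AEKEY"),
        AnomalyRule(kind="field_missing", rate=0.8,
                    condition=(("FAE", ("0",)),
                               ("PROCODE", ("P904", "P905"))),
                    target_field="EPIORDER"),
        AnomalyRule(kind="gap", rate=0.9, condition=gap_condition,
                    group_id="diag", position=3),
        AnomalyRule(kind="gap", rate=0.6, condition=gap_condition,
                    group_id="opertn_codes", position=2),
        AnomalyRule(kind="gap", rate=0.6, condition=gap_condition,
                    group_id="opertn_dates", position=2),
        AnomalyRule(kind="pair_mismatch", rate=0.05, direction="fewer_dates",
                    condition=(("PROCODE", ("P902",)),), pair_id="opertn"),
        AnomalyRule(kind="pair_mismatch", rate=0.01, direction="extra_dates",
                    condition=(("PROCODE", ("P903",)),), pair_id="opertn"),
    )

    return SynthConfig(
        n_records=n_records,
        general_fields=general,
        driver_fields=(epitype, admimeth, procode, fae, fce, mortality, sex,
                       epistat, epiorder),
        groups=(diag,),
        pairs=(opertn,),
        anomaly_rules=rules,
        seed=seed,
        missing_tokens={"AEKEY": "-1", "SEX": "9"},
    )
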