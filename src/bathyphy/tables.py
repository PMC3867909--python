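"""Reference tables and discrete character data.

A reference table lists named species or ESUs (evolutionary significant
units) with their genus, habitat classes, recorded depth range and per-locus
sequence identifiers — the tabular backbone of a barcode reference set.
Character data map taxa onto a small ordered state space (e.g. habitat coded
0–3, depth coded 0/1).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import BathyphyError, CodingError

#: Canonical habitat classes, in the coding order 0..3 used downstream.
HABITAT_CLASSES = ("nonchemosynthetic", "vent", "seep", "organic_fall")

#: Free-text habitat vocabulary -> canonical class.
_HABITAT_SYNONYMS = {
    "nonchemosynthetic": "nonchemosynthetic",
    "intertidal": "nonchemosynthetic",
    "subtidal": "nonchemosynthetic",
    "intertidal subtidal": "nonchemosynthetic",
    "shallow": "nonchemosynthetic",
    "vent": "vent",
    "hydrothermal vent": "vent",
    "v": "vent",
    "seep": "seep",
    "cold seep": "seep",
    "s": "seep",
    "organic_fall": "organic_fall",
    "organic fall": "organic_fall",
    "organic remain": "organic_fall",
    "wood": "organic_fall",
    "bone": "organic_fall",
    "whale fall": "organic_fall",
    "w": "organic_fall",
    "b": "organic_fall",
}


def parse_habitats(text: str) -> tuple[str, ...]:
    """Parse a free-text habitat field ("Vent, wood, bone") into canonical classes."""
    classes: list[str] = []
    for token in re.split(r"[,;/]| and ", text.strip().lower()):
        token = token.strip()
        if not token:
            continue
        cls = _HABITAT_SYNONYMS.get(token)
        if cls is None:
            raise CodingError(f"unknown habitat label {token!r}")
        if cls not in classes:
            classes.append(cls)
    if not classes:
        raise CodingError(f"no habitat class in {text!r}")
    return tuple(classes)


@dataclass(frozen=True)
class ReferenceRecord:
    """One species/ESU row of the reference set."""

    taxon: str
    genus: str
    habitats: tuple[str, ...]
    depth_min: float | None
    depth_max: float | None
    sequence_ids: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.habitats:
            raise CodingError(f"{self.taxon}: empty habitat class")
        for h in self.habitats:
            if h not in HABITAT_CLASSES:
                raise CodingError(f"{self.taxon}: unknown habitat class {h!r}")
        if (
            self.depth_min is not None
            and self.depth_max is not None
            and self.depth_min > self.depth_max
        ):
            raise BathyphyError(f"{self.taxon}: depth_min > depth_max")


@dataclass(frozen=True)
class ReferenceTable:
    """The barcode reference data set: unique taxa with genus and ecology."""

    records: tuple[ReferenceRecord, ...]

    def __post_init__(self) -> None:
        labels = [r.taxon for r in self.records]
        if len(set(labels)) != len(labels):
            raise BathyphyError("duplicate taxon labels in reference table")

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(r.taxon for r in self.records)

    def by_taxon(self, taxon: str) -> ReferenceRecord:
        for r in self.records:
            if r.taxon == taxon:
                return r
        raise KeyError(taxon)

    def genus_of(self, taxon: str) -> str:
        return self.by_taxon(taxon).genus

    @property
    def genera(self) -> tuple[str, ...]:
        seen: list[str] = []
        for r in self.records:
            if r.genus not in seen:
                seen.append(r.genus)
        return tuple(seen)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReferenceTable":
        """Read a tab-separated table with header
        ``taxon genus habitat depth_min depth_max [locus columns...]``."""
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        required = {"taxon", "genus", "habitat"}
        missing = required - set(df.columns)
        if missing:
            raise BathyphyError(f"reference table missing columns {sorted(missing)}")
        locus_cols = [
            c for c in df.columns
            if c not in {"taxon", "genus", "habitat", "depth_min", "depth_max"}
        ]
        records = []
        for _, row in df.iterrows():
            seq_ids = {
                c: row[c] for c in locus_cols if isinstance(row[c], str) and row[c]
            }
            records.append(
                ReferenceRecord(
                    taxon=row["taxon"],
                    genus=row["genus"],
                    habitats=parse_habitats(row["habitat"]),
                    depth_min=_opt_float(row.get("depth_min")),
                    depth_max=_opt_float(row.get("depth_max")),
                    sequence_ids=seq_ids,
                )
            )
        return cls(tuple(records))

    def to_tsv(self, path: str | Path) -> None:
        loci = sorted({k for r in self.records for k in r.sequence_ids})
        rows = []
        for r in self.records:
            row = {
                "taxon": r.taxon,
                "genus": r.genus,
                "habitat": ",".join(r.habitats),
                "depth_min": r.depth_min,
                "depth_max": r.depth_max,
            }
            row.update({l: r.sequence_ids.get(l, "") for l in loci})
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, str):
        value = value.strip()
        if not value:
            return None
    return float(value)


@dataclass(frozen=True)
class CharacterData:
    """Taxon -> state index over an ordered state space of k >= 2 labels."""

    state_space: tuple[str, ...]
    assignments: dict[str, int]

    def __post_init__(self) -> None:
        if len(self.state_space) < 2:
            raise CodingError("state space needs at least two states")
        for taxon, state in self.assignments.items():
            if not 0 <= state < self.k:
                raise CodingError(f"{taxon}: state index {state} outside [0,{self.k})")

    @property
    def k(self) -> int:
        return len(self.state_space)

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(self.assignments)

    def state_of(self, taxon: str) -> int | None:
        return self.assignments.get(taxon)

    @classmethod
    def from_tsv(cls, path: str | Path, state_space: tuple[str, ...] | None = None):
        """Read ``taxon<TAB>state`` rows; states may be indices or labels."""
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        if not {"taxon", "state"} <= set(df.columns):
            raise CodingError("character table needs 'taxon' and 'state' columns")
        values = list(df["state"])
        if state_space is None:
            if all(v.isdigit() for v in values):
                k = max(int(v) for v in values) + 1
                state_space = tuple(str(i) for i in range(max(k, 2)))
            else:
                state_space = tuple(sorted(set(values)))
        assignments = {}
        for taxon, v in zip(df["taxon"], values):
            if v.isdigit() and state_space[0].isdigit():
                assignments[taxon] = int(v)
            else:
                assignments[taxon] = state_space.index(v)
        return cls(tuple(state_space), assignments)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"taxon": list(self.assignments), "state": list(self.assignments.values())}
        ).to_csv(path, sep="\t", index=False)
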