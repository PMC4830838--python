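"""Bioactivity table parsing and qualification filtering.

A bioactivity table has one row per measurement. A (molecule, target) pair
becomes a *known target* association when at least one of its measurements
passes every categorical filter and has a potency at or below the activity
threshold. Targets supported by fewer than ``min_ligands`` distinct
qualifying ligands are removed from the map entirely.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import ConfigurationError

logger = logging.getLogger(__name__)

#: Default column mapping: logical field -> column name in the input table.
DEFAULT_DIALECT: dict[str, str] = {
    "molecule_id": "molecule_chembl_id",
    "target_id": "target_chembl_id",
    "target_type": "target_type",
    "activity_type": "standard_type",
    "relation": "standard_relation",
    "value": "standard_value",
    "units": "standard_units",
    "assay_type": "assay_type",
    "confidence": "confidence_score",
}


@dataclass(frozen=True)
class ActivityRecord:
    """One raw bioactivity measurement with all qualification fields."""

    molecule_id: str
    target_id: str
    target_type: str
    activity_type: str
    relation: str
    value: float
    units: str
    assay_type: str
    confidence: int

    def __post_init__(self) -> None:
        if not self.molecule_id or not self.target_id:
            raise ValueError("molecule_id and target_id must be non-empty")


@dataclass(frozen=True)
class FilterCriteria:
    """Qualification criteria for turning measurements into known targets.

    ``threshold_nM`` is the potency cutoff (values strictly above it never
    qualify; values exactly equal do). ``min_ligands`` is the minimum number
    of distinct qualifying ligands a target needs to stay in the universe
    (the ligand-centric setting is 1).
    """

    threshold_nM: float = 10_000.0
    allowed_activity_types: frozenset[str] = frozenset({"EC50", "Ki", "Kd", "IC50"})
    required_relation: str = "="
    required_units: str = "nM"
    required_assay_type: str = "B"
    required_confidence: int = 9
    required_target_type: str = "SINGLE PROTEIN"
    min_ligands: int = 1

    def __post_init__(self) -> None:
        if self.threshold_nM <= 0:
            raise ConfigurationError("threshold_nM must be positive")
        if self.min_ligands < 1:
            raise ConfigurationError("min_ligands must be >= 1")
        object.__setattr__(
            self, "allowed_activity_types", frozenset(self.allowed_activity_types)
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["allowed_activity_types"] = sorted(self.allowed_activity_types)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "FilterCriteria":
        d = dict(d)
        if "allowed_activity_types" in d:
            d["allowed_activity_types"] = frozenset(d["allowed_activity_types"])
        return cls(**d)


@dataclass(frozen=True)
class LoadReport:
    """Outcome of parsing a bioactivity table."""

    records: tuple[ActivityRecord, ...]
    n_rows: int
    n_dropped: int

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def load_activity_table(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> LoadReport:
    """Parse a CSV/TSV bioactivity table into :class:`ActivityRecord` rows.

    Rows whose numeric fields (value, confidence) cannot be parsed, or whose
    ids are empty, are dropped and counted in the report — never silently.

    Raises
    ------
    ConfigurationError
        If a mapped column is missing from the table, naming the column.
    """
    colmap = dict(DEFAULT_DIALECT)
    if dialect:
        colmap.update(dialect)
    df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                     keep_default_na=False)
    for logical, column in colmap.items():
        if column not in df.columns:
            raise ConfigurationError(
                f"required column {column!r} (for field {logical!r}) "
                f"not found in {path}"
            )

    records: list[ActivityRecord] = []
    n_dropped = 0
    for row in df.itertuples(index=False):
        raw = {logical: getattr(row, colmap[logical]) for logical in colmap}
        try:
            value = float(raw["value"])
            confidence = int(float(raw["confidence"]))
            rec = ActivityRecord(
                molecule_id=str(raw["molecule_id"]).strip(),
                target_id=str(raw["target_id"]).strip(),
                target_type=str(raw["target_type"]).strip(),
                activity_type=str(raw["activity_type"]).strip(),
                relation=str(raw["relation"]).strip(),
                value=value,
                units=str(raw["units"]).strip(),
                assay_type=str(raw["assay_type"]).strip(),
                confidence=confidence,
            )
        except (TypeError, ValueError):
            n_dropped += 1
            continue
        records.append(rec)
    if n_dropped:
        logger.info("load_activity_table: dropped %d unparseable rows of %d",
                    n_dropped, len(df))
    return LoadReport(records=tuple(records), n_rows=len(df), n_dropped=n_dropped)


def record_qualifies(record: ActivityRecord, criteria: FilterCriteria) -> bool:
    """True if this single measurement passes every filter and the threshold."""
    return (
        record.activity_type in criteria.allowed_activity_types
        and record.relation == criteria.required_relation
        and record.units == criteria.required_units
        and record.assay_type == criteria.required_assay_type
        and record.confidence == criteria.required_confidence
        and record.target_type == criteria.required_target_type
        and record.value <= criteria.threshold_nM
    )


class KnownTargetMap:
    """Molecule -> qualifying-target sets under fixed criteria.

    Maintains a consistent reverse index (target -> ligand set). Every
    molecule present maps to a non-empty set; NKT(molecule) is the size of
    its set.
    """

    def __init__(
        self,
        pairs: Iterable[tuple[str, str]],
        criteria: FilterCriteria,
    ) -> None:
        forward: dict[str, set[str]] = {}
        reverse: dict[str, set[str]] = {}
        for mol, tgt in pairs:
            forward.setdefault(mol, set()).add(tgt)
            reverse.setdefault(tgt, set()).add(mol)
        self._forward = {m: frozenset(ts) for m, ts in forward.items() if ts}
        self._reverse = {t: frozenset(ms) for t, ms in reverse.items() if ms}
        self.criteria = criteria

    @property
    def molecules(self) -> frozenset[str]:
        return frozenset(self._forward)

    @property
    def targets(self) -> frozenset[str]:
        return frozenset(self._reverse)

    def known_targets(self, molecule_id: str) -> frozenset[str]:
        """The molecule's qualifying target set; empty set if absent."""
        return self._forward.get(molecule_id, frozenset())

    def nkt(self, molecule_id: str) -> int:
        return len(self.known_targets(molecule_id))

    def ligands_of(self, target_id: str) -> frozenset[str]:
        return self._reverse.get(target_id, frozenset())

    def pairs(self) -> set[tuple[str, str]]:
        return {(m, t) for m, ts in self._forward.items() for t in ts}

    def target_universe(self, min_ligands: int) -> frozenset[str]:
        """Targets with at least ``min_ligands`` distinct retained ligands."""
        if min_ligands < 1:
            raise ConfigurationError("min_ligands must be >= 1")
        return frozenset(
            t for t, ligs in self._reverse.items() if len(ligs) >= min_ligands
        )

    def __len__(self) -> int:
        return len(self._forward)

    def __contains__(self, molecule_id: str) -> bool:
        return molecule_id in self._forward

    # -- serialization -----------------------------------------------------

    def save(self, pairs_path: str | Path, criteria_path: str | Path) -> None:
        """Write the pair list (molecule_id, target_id) as TSV and the
        criteria as JSON."""
        rows = sorted(self.pairs())
        with open(pairs_path, "w") as fh:
            fh.write("molecule_id\ttarget_id\n")
            for mol, tgt in rows:
                fh.write(f"{mol}\t{tgt}\n")
        with open(criteria_path, "w") as fh:
            json.dump(self.criteria.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def load(cls, pairs_path: str | Path, criteria_path: str | Path) -> "KnownTargetMap":
        with open(criteria_path) as fh:
            criteria = FilterCriteria.from_dict(json.load(fh))
        df = pd.read_csv(pairs_path, sep="\t", dtype=str)
        pairs = list(zip(df["molecule_id"], df["target_id"]))
        return cls(pairs, criteria)


def apply_selection_filters(
    records: Iterable[ActivityRecord], criteria: FilterCriteria
) -> KnownTargetMap:
    """Build the known-target map from raw measurements.

    A (molecule, target) pair is retained iff ANY single measurement for the
    pair qualifies under every filter and the threshold. Targets with fewer
    than ``criteria.min_ligands`` distinct retained ligands are then removed
    entirely, and molecules left with empty sets are dropped.
    """
    qualifying: set[tuple[str, str]] = set()
    for rec in records:
        if record_qualifies(rec, criteria):
            qualifying.add((rec.molecule_id, rec.target_id))

    ligand_count: dict[str, set[str]] = {}
    for mol, tgt in qualifying:
        ligand_count.setdefault(tgt, set()).add(mol)
    kept_targets = {
        t for t, ligs in ligand_count.items() if len(ligs) >= criteria.min_ligands
    }
    retained = [(m, t) for (m, t) in qualifying if t in kept_targets]
    return KnownTargetMap(retained, criteria)


def known_targets(known_map: KnownTargetMap, molecule_id: str) -> frozenset[str]:
    """Module-level convenience wrapper around :meth:`KnownTargetMap.known_targets`."""
    return known_map.known_targets(molecule_id)


def target_universe(known_map: KnownTargetMap, min_ligands: int) -> frozenset[str]:
    """Module-level convenience wrapper around :meth:`KnownTargetMap.target_universe`."""
    return known_map.target_universe(min_ligands)
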