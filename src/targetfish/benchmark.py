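"""Benchmark partitions, confusion-matrix scoring and aggregate statistics.

Each query's prediction is scored as a binary classification over the fixed
target universe (all targets qualifying under the map's criteria). Per-query
accuracy/precision/recall/MCC are aggregated as plain means over evaluable
queries; excluded queries are reported, never imputed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .activity import FilterCriteria, KnownTargetMap
from .errors import ContractError
from .predict import ExcludedQuery, QueryPrediction, predict_targets
from .similarity import Fingerprint

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BenchmarkPartition:
    """A disjoint (queries, database) split of the known-target map."""

    label: str
    criteria: FilterCriteria
    query_ids: tuple[str, ...]
    database_ids: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        if set(self.query_ids) & set(self.database_ids):
            raise ContractError("query and database sets must be disjoint")


def make_partitions(
    known_map: KnownTargetMap,
    designated_queries: Sequence[str],
    seed: int,
    labels: tuple[str, str] = ("designated", "random-control"),
) -> tuple[BenchmarkPartition, BenchmarkPartition]:
    """Build the designated-query partition and its random control.

    The control is drawn uniformly without replacement from map molecules
    excluding the designated queries, same size as the designated set. The
    database is all remaining molecules and is identical for both
    partitions. Fully reproducible from ``seed``.
    """
    designated = list(dict.fromkeys(designated_queries))
    molecules = set(known_map.molecules)
    missing = [q for q in designated if q not in molecules]
    if missing:
        raise ContractError(f"designated queries not in map: {missing[:5]}")
    if len(molecules) < 2 * len(designated):
        raise ContractError(
            f"map has {len(molecules)} molecules; cannot draw a control of "
            f"size {len(designated)} plus a non-trivial database"
        )
    pool = sorted(molecules - set(designated))
    rng = np.random.default_rng(seed)
    control = sorted(rng.choice(pool, size=len(designated), replace=False).tolist())
    database = sorted(molecules - set(designated) - set(control))
    part_a = BenchmarkPartition(
        label=labels[0],
        criteria=known_map.criteria,
        query_ids=tuple(designated),
        database_ids=tuple(database),
        seed=seed,
    )
    part_b = BenchmarkPartition(
        label=labels[1],
        criteria=known_map.criteria,
        query_ids=tuple(control),
        database_ids=tuple(database),
        seed=seed,
    )
    return part_a, part_b


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/FN/TN against a fixed target universe for one query."""

    tp: int
    fp: int
    fn: int
    tn: int
    universe_size: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.fp + self.fn + self.tn != self.universe_size:
            raise ValueError("TP+FP+FN+TN must equal universe_size")


def confusion_matrix(
    predicted: Iterable[str], known: Iterable[str], universe: Iterable[str]
) -> ConfusionCounts:
    """Classify every universe target as TP/FP/FN/TN for one query.

    Raises :class:`ContractError` if predicted or known targets fall outside
    the universe (that indicates inconsistent filter criteria upstream).
    """
    predicted = set(predicted)
    known = set(known)
    universe = set(universe)
    if not known <= universe:
        raise ContractError("known targets must be a subset of the universe")
    if not predicted <= universe:
        raise ContractError("predicted targets must be a subset of the universe")
    tp = len(predicted & known)
    fp = len(predicted - known)
    fn = len(known - predicted)
    tn = len(universe) - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn, universe_size=len(universe))


@dataclass(frozen=True)
class QueryMetrics:
    """Accuracy, precision, recall, MCC with degenerate-denominator flags."""

    accuracy: float
    precision: float
    recall: float
    mcc: float
    flags: frozenset[str] = frozenset()


def compute_metrics(c: ConfusionCounts) -> QueryMetrics:
    """Four per-query measures from the confusion counts.

    accuracy = (TP+TN)/universe; precision = TP/(TP+FP); recall = TP/(TP+FN);
    MCC = (TP*TN - FP*FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)). Undefined
    denominators yield 0 with an explicit flag so edge cases cannot poison
    averages silently.
    """
    if c.universe_size < 1:
        raise ContractError("universe_size must be >= 1")
    flags: set[str] = set()
    accuracy = (c.tp + c.tn) / c.universe_size
    if c.tp + c.fp == 0:
        precision = 0.0
        flags.add("precision_undefined")
    else:
        precision = c.tp / (c.tp + c.fp)
    if c.tp + c.fn == 0:
        recall = 0.0
        flags.add("recall_undefined")
    else:
        recall = c.tp / (c.tp + c.fn)
    denom = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    if denom == 0:
        mcc = 0.0
        flags.add("mcc_degenerate")
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    return QueryMetrics(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        mcc=mcc,
        flags=frozenset(flags),
    )


@dataclass(frozen=True)
class SummaryStats:
    """Boxplot-style summary: mean, median, quartiles, range, Tukey outliers."""

    mean: float
    median: float
    q1: float
    q3: float
    min: float
    max: float
    outlier_ids: tuple[str, ...] = ()


def summarize(
    values: Sequence[float], ids: Optional[Sequence[str]] = None
) -> SummaryStats:
    """Summary statistics with linear-interpolation quartiles and 1.5*IQR
    Tukey-fence outliers."""
    if len(values) == 0:
        raise ContractError("summarize requires a non-empty list")
    arr = np.asarray(values, dtype=float)
    if ids is not None and len(ids) != len(values):
        raise ContractError("ids must parallel values")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers: tuple[str, ...] = ()
    if ids is not None:
        outliers = tuple(
            ids[i] for i in range(len(arr)) if arr[i] < lo or arr[i] > hi
        )
    return SummaryStats(
        mean=float(arr.mean()),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        min=float(arr.min()),
        max=float(arr.max()),
        outlier_ids=outliers,
    )


@dataclass(frozen=True)
class CoverageRow:
    """Target counts and neglect for a (min-ligands, threshold) method class."""

    label: str
    min_ligands: int
    threshold_nM: float
    n_targets_method: int
    n_targets_ligand_centric: int

    @property
    def n_neglected(self) -> int:
        return neglected_targets(self.n_targets_ligand_centric, self.n_targets_method)


def neglected_targets(n_ligand_centric: int, n_method: int) -> int:
    """Targets a min-ligand-constrained method cannot evaluate but a
    ligand-centric one can."""
    if n_method < 0 or n_ligand_centric < n_method:
        raise ContractError(
            "require n_ligand_centric >= n_method >= 0; "
            f"got ({n_ligand_centric}, {n_method})"
        )
    return n_ligand_centric - n_method


def coverage_row(
    known_map: KnownTargetMap, min_ligands: int, label: str = ""
) -> CoverageRow:
    """Coverage of a method class needing ``min_ligands`` ligands per target,
    versus the ligand-centric universe (min 1), at the map's threshold."""
    n_method = len(known_map.target_universe(min_ligands))
    n_lig = len(known_map.target_universe(1))
    return CoverageRow(
        label=label or f"min_ligands={min_ligands}",
        min_ligands=min_ligands,
        threshold_nM=known_map.criteria.threshold_nM,
        n_targets_method=n_method,
        n_targets_ligand_centric=n_lig,
    )


@dataclass(frozen=True)
class OverlapReport:
    """Named target lists per confusion cell for one query (Venn-style)."""

    query_id: str
    nkt: int
    npt: int
    tp_targets: tuple[str, ...]
    fp_targets: tuple[str, ...]
    fn_targets: tuple[str, ...]
    support: dict[str, tuple[str, ...]] = field(default_factory=dict)


def overlap_report(prediction: QueryPrediction, known: Iterable[str]) -> OverlapReport:
    """Case-study record: which predicted targets are confirmed, which known
    targets are missed, and which hits support each predicted target."""
    known = set(known)
    predicted = set(prediction.predicted_targets)
    tp = tuple(sorted(predicted & known))
    fp = tuple(sorted(predicted - known))
    fn = tuple(sorted(known - predicted))
    support = {
        t: tuple(h.molecule_id for h in prediction.support.get(t, ()))
        for t in sorted(predicted)
    }
    return OverlapReport(
        query_id=prediction.query_id,
        nkt=len(known),
        npt=len(predicted),
        tp_targets=tp,
        fp_targets=fp,
        fn_targets=fn,
        support=support,
    )


PER_QUERY_COLUMNS = [
    "query_id", "k", "NKT", "NPT", "TP", "FP", "FN", "TN",
    "accuracy", "precision", "recall", "mcc", "flags",
]


@dataclass(frozen=True)
class BenchmarkResult:
    """Per-query metrics table plus the aggregate row for one (partition, k)."""

    partition_label: str
    k: int
    per_query: pd.DataFrame
    aggregate: dict
    exclusions: tuple[ExcludedQuery, ...]


def run_benchmark(
    partition: BenchmarkPartition,
    known_map: KnownTargetMap,
    fingerprints: Mapping[str, Optional[Fingerprint]],
    k: int,
) -> BenchmarkResult:
    """Score every evaluable query in the partition at a given k.

    The TN universe is the target universe at the partition's criteria.
    Database molecules without an available fingerprint are dropped from the
    searchable database (they cannot be ranked); queries without one are
    excluded and reported.
    """
    universe = known_map.target_universe(partition.criteria.min_ligands)
    db = {
        mid: fingerprints[mid]
        for mid in partition.database_ids
        if fingerprints.get(mid) is not None
    }
    rows = []
    exclusions: list[ExcludedQuery] = []
    for query_id in partition.query_ids:
        fp = fingerprints.get(query_id)
        pred = predict_targets(query_id, fp, db, known_map, k)
        if pred is None:
            exclusions.append(
                ExcludedQuery(query_id=query_id, reason="fingerprint unavailable")
            )
            continue
        known = known_map.known_targets(query_id)
        counts = confusion_matrix(pred.predicted_targets, known, universe)
        metrics = compute_metrics(counts)
        rows.append({
            "query_id": query_id,
            "k": k,
            "NKT": len(known),
            "NPT": pred.npt,
            "TP": counts.tp,
            "FP": counts.fp,
            "FN": counts.fn,
            "TN": counts.tn,
            "accuracy": metrics.accuracy,
            "precision": metrics.precision,
            "recall": metrics.recall,
            "mcc": metrics.mcc,
            "flags": ";".join(sorted(metrics.flags)),
        })
    per_query = pd.DataFrame(rows, columns=PER_QUERY_COLUMNS)
    if len(per_query):
        aggregate = {
            "partition": partition.label,
            "k": k,
            "n_queries": len(per_query),
            "n_excluded": len(exclusions),
            "avNPT": float(per_query["NPT"].mean()),
            "avAccuracy": float(per_query["accuracy"].mean()),
            "avPrecision": float(per_query["precision"].mean()),
            "avRecall": float(per_query["recall"].mean()),
            "avMCC": float(per_query["mcc"].mean()),
        }
    else:
        aggregate = {
            "partition": partition.label,
            "k": k,
            "n_queries": 0,
            "n_excluded": len(exclusions),
        }
    if exclusions:
        logger.info(
            "benchmark %s k=%d: %d queries excluded",
            partition.label, k, len(exclusions),
        )
    return BenchmarkResult(
        partition_label=partition.label,
        k=k,
        per_query=per_query,
        aggregate=aggregate,
        exclusions=tuple(exclusions),
    )
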