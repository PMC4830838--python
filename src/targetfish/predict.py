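"""Target prediction by top-k neighbor target transfer.

The predicted target set of a query is the deduplicated union of the known
targets of its k most similar database molecules. Predictions are unordered
sets; per-target hit support is retained for reporting only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional

from .activity import KnownTargetMap
from .errors import ContractError
from .similarity import Fingerprint, RankedHit, rank_database, top_k

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QueryPrediction:
    """Top-k hits and the deduplicated predicted-target set for one query.

    NPT (number of predicted targets) is ``len(predicted_targets)``.
    ``support`` maps each predicted target to the hits contributing it.
    """

    query_id: str
    k: int
    hits: tuple[RankedHit, ...]
    predicted_targets: frozenset[str]
    support: dict[str, tuple[RankedHit, ...]] = field(default_factory=dict)

    @property
    def npt(self) -> int:
        return len(self.predicted_targets)

    def to_json_dict(self) -> dict:
        return {
            "query_id": self.query_id,
            "k": self.k,
            "hits": [
                {"molecule_id": h.molecule_id, "score": h.score, "rank": h.rank}
                for h in self.hits
            ],
            "predicted_targets": {
                t: [h.molecule_id for h in self.support.get(t, ())]
                for t in sorted(self.predicted_targets)
            },
        }


@dataclass(frozen=True)
class ExcludedQuery:
    """A query that could not be evaluated, with the reason why."""

    query_id: str
    reason: str


def predict_targets(
    query_id: str,
    query_fp: Optional[Fingerprint],
    db: Mapping[str, Fingerprint],
    known_map: KnownTargetMap,
    k: int,
) -> Optional[QueryPrediction]:
    """Predict targets for one query; ``None`` if its fingerprint is unavailable.

    Preconditions: the query must not be a database molecule (partitions are
    disjoint) and k >= 1.
    """
    if k < 1:
        raise ContractError("k must be >= 1")
    if query_id in db:
        raise ContractError(
            f"query {query_id!r} present in database: partitions must be disjoint"
        )
    if query_fp is None:
        logger.info("query %s excluded: fingerprint unavailable", query_id)
        return None
    hits = tuple(top_k(rank_database(query_fp, db), k))
    support: dict[str, list[RankedHit]] = {}
    for hit in hits:
        for target in known_map.known_targets(hit.molecule_id):
            support.setdefault(target, []).append(hit)
    predicted = frozenset(support)
    return QueryPrediction(
        query_id=query_id,
        k=k,
        hits=hits,
        predicted_targets=predicted,
        support={t: tuple(hs) for t, hs in support.items()},
    )


def batch_predict(
    queries: Mapping[str, Optional[Fingerprint]],
    db: Mapping[str, Fingerprint],
    known_map: KnownTargetMap,
    k: int,
) -> tuple[list[QueryPrediction], list[ExcludedQuery]]:
    """Predict for each evaluable query; report unevaluable ones separately."""
    predictions: list[QueryPrediction] = []
    exclusions: list[ExcludedQuery] = []
    for query_id in queries:
        pred = predict_targets(query_id, queries[query_id], db, known_map, k)
        if pred is None:
            exclusions.append(
                ExcludedQuery(query_id=query_id, reason="fingerprint unavailable")
            )
        else:
            predictions.append(pred)
    return predictions, exclusions


def write_predictions_jsonl(path, predictions: list[QueryPrediction]) -> None:
    """One JSON object per line per query."""
    with open(path, "w") as fh:
        for pred in predictions:
            fh.write(json.dumps(pred.to_json_dict(), sort_keys=True) + "\n")
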