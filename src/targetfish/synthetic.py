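"""Synthetic chemogenomics databases with known ground truth.

Molecules come in chemical series: each series has a prototype fingerprint
and its members are noisy copies that share the series target set. A
heavy-tailed promiscuity mechanism adds extra cross-series targets to some
molecules, emulating promiscuous outliers. An observation mask retains each
true (molecule, target) pair with a role-dependent probability, modelling
the deeper experimental testing of drug-like query molecules versus
ordinary database molecules.

Synthetic molecules carry fingerprints directly (no structures), so the
generator has no chemistry-toolkit dependency; downstream stages consume
them through the same interfaces as real data.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .activity import ActivityRecord, DEFAULT_DIALECT
from .errors import ConfigurationError
from .similarity import FP_LENGTH, Fingerprint

logger = logging.getLogger(__name__)

# substream indices off the master seed, one per generation stage, so that
# changing one stage's draw count does not perturb the others
_STREAM_FINGERPRINTS = 0
_STREAM_TARGETS = 1
_STREAM_ACTIVITIES = 2
_STREAM_MASK = 3
_STREAM_DISQUALIFIED = 4


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs for the generator; every random choice derives from ``seed``.

    ``promiscuity_mean`` is the expected number of extra cross-series
    targets per molecule; ``promiscuity_tail`` is the log-normal sigma of
    the per-molecule rate, so larger values give heavier tails (rare,
    extremely promiscuous outliers) at the same mean.
    """

    n_series: int = 10
    molecules_per_series: int = 6
    fingerprint_length: int = FP_LENGTH
    prototype_on_rate: float = 0.3
    bitflip_noise: float = 0.0
    targets_per_series: int = 3
    promiscuity_mean: float = 0.0
    promiscuity_tail: float = 1.0
    activity_range: tuple[float, float] = (1.0, 100_000.0)
    observation_rate_db: float = 1.0
    observation_rate_query: float = 1.0
    queries_per_series: int = 1
    disqualified_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_series < 1:
            raise ConfigurationError("n_series must be >= 1")
        if self.molecules_per_series < 2:
            raise ConfigurationError(
                "molecules_per_series must be >= 2 so queries have series mates"
            )
        if self.fingerprint_length != FP_LENGTH:
            raise ConfigurationError(f"fingerprint_length must be {FP_LENGTH}")
        for name in ("prototype_on_rate", "bitflip_noise",
                     "observation_rate_db", "observation_rate_query",
                     "disqualified_fraction"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {p}")
        lo, hi = self.activity_range
        if not (0 < lo <= hi):
            raise ConfigurationError("activity_range must be positive with lo <= hi")
        if self.targets_per_series < 1:
            raise ConfigurationError("targets_per_series must be >= 1")
        if not 0 <= self.queries_per_series < self.molecules_per_series:
            raise ConfigurationError(
                "queries_per_series must leave at least one database molecule per series"
            )
        if self.promiscuity_mean < 0 or self.promiscuity_tail <= 0:
            raise ConfigurationError("promiscuity parameters must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Complete pre-mask truth plus the observed activity table."""

    truth_map: dict[str, frozenset[str]]
    series_of: dict[str, int]
    query_ids: tuple[str, ...]
    full_records: tuple[ActivityRecord, ...]
    records: tuple[ActivityRecord, ...]
    fingerprints: dict[str, Fingerprint]
    config: SyntheticConfig


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(5)[stream])


def _molecule_id(series: int, member: int) -> str:
    return f"S{series:03d}M{member:02d}"


def _series_target_ids(series: int, n: int) -> list[str]:
    return [f"T{series:03d}x{j:02d}" for j in range(n)]


def generate_database(config: SyntheticConfig) -> GroundTruth:
    """Generate molecules, fingerprints, the truth map and the observed table.

    Each series draws a prototype fingerprint with independent
    Bernoulli(prototype_on_rate) bits; members copy it with per-bit flip
    probability ``bitflip_noise``. Series members share the series target
    set; extra cross-series targets follow a Poisson-lognormal count per
    molecule. Activity values are log-uniform in ``activity_range``.
    """
    cfg = config
    mol_ids: list[str] = []
    series_of: dict[str, int] = {}
    for s in range(cfg.n_series):
        for m in range(cfg.molecules_per_series):
            mid = _molecule_id(s, m)
            mol_ids.append(mid)
            series_of[mid] = s

    # fingerprints: prototypes then member noise, all from one substream
    rng_fp = _rng(cfg.seed, _STREAM_FINGERPRINTS)
    fingerprints: dict[str, Fingerprint] = {}
    for s in range(cfg.n_series):
        proto = (rng_fp.random(FP_LENGTH) < cfg.prototype_on_rate).astype(np.uint8)
        for m in range(cfg.molecules_per_series):
            flips = (rng_fp.random(FP_LENGTH) < cfg.bitflip_noise).astype(np.uint8)
            fingerprints[_molecule_id(s, m)] = Fingerprint(proto ^ flips)

    # targets: shared series set plus heavy-tailed cross-series extras
    rng_t = _rng(cfg.seed, _STREAM_TARGETS)
    series_targets = {
        s: _series_target_ids(s, cfg.targets_per_series) for s in range(cfg.n_series)
    }
    truth: dict[str, set[str]] = {}
    for mid in mol_ids:
        truth[mid] = set(series_targets[series_of[mid]])
    if cfg.promiscuity_mean > 0:
        all_targets = sorted({t for ts in series_targets.values() for t in ts})
        sigma = cfg.promiscuity_tail
        mu = np.log(cfg.promiscuity_mean) - sigma**2 / 2.0
        for mid in mol_ids:
            lam = float(rng_t.lognormal(mean=mu, sigma=sigma))
            n_extra = int(rng_t.poisson(lam))
            pool = [t for t in all_targets if t not in truth[mid]]
            n_extra = min(n_extra, len(pool))
            if n_extra:
                extras = rng_t.choice(pool, size=n_extra, replace=False)
                truth[mid].update(extras.tolist())

    truth_map = {m: frozenset(ts) for m, ts in truth.items()}
    query_ids = tuple(
        _molecule_id(s, m)
        for s in range(cfg.n_series)
        for m in range(cfg.queries_per_series)
    )

    # one activity row per true pair, qualifying metadata, log-uniform value
    rng_a = _rng(cfg.seed, _STREAM_ACTIVITIES)
    lo, hi = cfg.activity_range
    full_records: list[ActivityRecord] = []
    for mid in mol_ids:
        for tgt in sorted(truth_map[mid]):
            value = float(np.exp(rng_a.uniform(np.log(lo), np.log(hi))))
            full_records.append(ActivityRecord(
                molecule_id=mid,
                target_id=tgt,
                target_type="SINGLE PROTEIN",
                activity_type="IC50",
                relation="=",
                value=value,
                units="nM",
                assay_type="B",
                confidence=9,
            ))
    full_records_t = tuple(full_records)

    gt = GroundTruth(
        truth_map=truth_map,
        series_of=series_of,
        query_ids=query_ids,
        full_records=full_records_t,
        records=(),
        fingerprints=fingerprints,
        config=cfg,
    )
    observed = bias_mask(
        gt, query_ids, cfg.observation_rate_query, cfg.observation_rate_db, cfg.seed
    )
    observed = _add_disqualified_rows(observed, cfg)
    return GroundTruth(
        truth_map=truth_map,
        series_of=series_of,
        query_ids=query_ids,
        full_records=full_records_t,
        records=observed,
        fingerprints=fingerprints,
        config=cfg,
    )


def bias_mask(
    truth: GroundTruth,
    query_ids: Sequence[str],
    rate_query: float,
    rate_db: float,
    seed: int,
) -> tuple[ActivityRecord, ...]:
    """Retain each true pair independently with a role-dependent probability.

    One uniform draw per pair in a fixed order, compared against the role's
    rate: with the same seed, the retained set at a lower rate is a subset
    of the set at a higher rate (nesting), and results are reproducible.
    """
    for r in (rate_query, rate_db):
        if not 0.0 <= r <= 1.0:
            raise ConfigurationError(f"observation rates must be in [0, 1], got {r}")
    queries = set(query_ids)
    rng = _rng(seed, _STREAM_MASK)
    uniforms = rng.random(len(truth.full_records))
    kept = []
    for u, rec in zip(uniforms, truth.full_records):
        rate = rate_query if rec.molecule_id in queries else rate_db
        if u < rate:
            kept.append(rec)
    return tuple(kept)


def _spoil(rec: ActivityRecord, mode: int) -> ActivityRecord:
    """Copy a qualifying record with exactly one field made disqualifying."""
    kwargs = dict(
        molecule_id=rec.molecule_id, target_id=rec.target_id,
        target_type=rec.target_type, activity_type=rec.activity_type,
        relation=rec.relation, value=rec.value, units=rec.units,
        assay_type=rec.assay_type, confidence=rec.confidence,
    )
    mode = mode % 5
    if mode == 0:
        kwargs["relation"] = ">"
    elif mode == 1:
        kwargs["confidence"] = 8
    elif mode == 2:
        kwargs["units"] = "ug.mL-1"
    elif mode == 3:
        kwargs["activity_type"] = "Inhibition"
    else:
        kwargs["assay_type"] = "F"
    return ActivityRecord(**kwargs)


def _add_disqualified_rows(
    records: tuple[ActivityRecord, ...], cfg: SyntheticConfig
) -> tuple[ActivityRecord, ...]:
    if cfg.disqualified_fraction == 0.0 or not records:
        return records
    rng = _rng(cfg.seed, _STREAM_DISQUALIFIED)
    n_extra = int(round(cfg.disqualified_fraction * len(records)))
    idx = rng.integers(0, len(records), size=n_extra)
    modes = rng.integers(0, 5, size=n_extra)
    extras = tuple(_spoil(records[i], int(m)) for i, m in zip(idx, modes))
    return records + extras


def write_activity_csv(path: str | Path, records: Sequence[ActivityRecord]) -> None:
    """Emit the same CSV dialect :func:`targetfish.activity.load_activity_table` reads."""
    field_order = list(DEFAULT_DIALECT)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([DEFAULT_DIALECT[f] for f in field_order])
        for rec in records:
            writer.writerow([getattr(rec, f) for f in field_order])


def write_truth_map(path: str | Path, truth_map: Mapping[str, frozenset[str]]) -> None:
    """Two-column TSV of the pre-mask truth pairs, for test assertions."""
    with open(path, "w") as fh:
        fh.write("molecule_id\ttarget_id\n")
        for mid in sorted(truth_map):
            for tgt in sorted(truth_map[mid]):
                fh.write(f"{mid}\t{tgt}\n")
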