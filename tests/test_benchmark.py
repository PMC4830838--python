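import math

import numpy as np
import pytest

from targetfish.activity import FilterCriteria, KnownTargetMap
from targetfish.benchmark import (
    BenchmarkPartition,
    confusion_matrix,
    compute_metrics,
    coverage_row,
    make_partitions,
    neglected_targets,
    overlap_report,
    run_benchmark,
    summarize,
)
from targetfish.errors import ContractError
from targetfish.predict import predict_targets
from targetfish.synthetic import SyntheticConfig, generate_database

from conftest import make_fp


@pytest.fixture
def criteria():
    return FilterCriteria(threshold_nM=10_000.0, min_ligands=1)


class TestMakePartitions:
    @pytest.fixture
    def map_ten(self, criteria):
        pairs = [(f"M{i}", f"T{i % 4}") for i in range(10)]
        return KnownTargetMap(pairs, criteria)

    def test_sizes_and_disjointness(self, map_ten):
        designated = ["M0", "M1", "M2"]
        part_q, part_r = make_partitions(map_ten, designated, seed=99)
        assert len(part_q.query_ids) == 3
        assert len(part_r.query_ids) == 3
        assert len(part_q.database_ids) == 4
        assert part_q.database_ids == part_r.database_ids
        q, r, d = (set(part_q.query_ids), set(part_r.query_ids),
                   set(part_q.database_ids))
        assert not (q & r) and not (q & d) and not (r & d)

    def test_same_seed_identical_control(self, map_ten):
        _, r1 = make_partitions(map_ten, ["M0", "M1", "M2"], seed=4)
        _, r2 = make_partitions(map_ten, ["M0", "M1", "M2"], seed=4)
        assert r1.query_ids == r2.query_ids

    def test_sizing_error(self, map_ten):
        with pytest.raises(ContractError):
            make_partitions(map_ten, [f"M{i}" for i in range(6)], seed=0)

    def test_unknown_designated_query(self, map_ten):
        with pytest.raises(ContractError):
            make_partitions(map_ten, ["nope"], seed=0)

    def test_partition_disjointness_enforced(self, criteria):
        with pytest.raises(ContractError):
            BenchmarkPartition(
                label="x", criteria=criteria,
                query_ids=("A",), database_ids=("A", "B"), seed=0)


class TestConfusionMatrix:
    def test_worked_example_67_known_9_predicted(self):
        universe = {f"T{i}" for i in range(3035)}
        known = {f"T{i}" for i in range(67)}
        predicted = {f"T{i}" for i in range(59, 68)}  # 8 in known, 1 outside
        c = confusion_matrix(predicted, known, universe)
        assert (c.tp, c.fp, c.fn, c.tn) == (8, 1, 59, 2967)

    def test_perfect_prediction(self):
        universe = {"T1", "T2", "T3"}
        c = confusion_matrix({"T1"}, {"T1"}, universe)
        assert c.fp == 0 and c.fn == 0

    def test_small_hand_example(self):
        c = confusion_matrix({"T2", "T3"}, {"T1", "T2"},
                             {"T1", "T2", "T3", "T4", "T5"})
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 2)

    def test_predicted_outside_universe_rejected(self):
        with pytest.raises(ContractError):
            confusion_matrix({"TX"}, {"T1"}, {"T1", "T2"})

    def test_known_outside_universe_rejected(self):
        with pytest.raises(ContractError):
            confusion_matrix({"T1"}, {"TX"}, {"T1", "T2"})

    def test_conservation_random(self):
        rng = np.random.default_rng(41)
        universe = [f"T{i}" for i in range(50)]
        for _ in range(50):
            known = set(rng.choice(universe, rng.integers(0, 20), replace=False))
            predicted = set(rng.choice(universe, rng.integers(0, 20), replace=False))
            c = confusion_matrix(predicted, known, universe)
            assert c.tp + c.fp + c.fn + c.tn == 50
            assert c.tp + c.fn == len(known)
            assert c.tp + c.fp == len(predicted)


class TestComputeMetrics:
    def test_worked_example_precision_and_recall(self):
        universe = {f"T{i}" for i in range(3035)}
        known = {f"T{i}" for i in range(67)}
        predicted = {f"T{i}" for i in range(59, 68)}
        m = compute_metrics(confusion_matrix(predicted, known, universe))
        assert round(m.precision, 2) == 0.89
        assert round(m.recall, 2) == 0.12

    def test_perfect_prediction_all_ones(self):
        c = confusion_matrix({"T1"}, {"T1"}, {"T1", "T2"})
        m = compute_metrics(c)
        assert m.accuracy == m.precision == m.recall == m.mcc == 1.0
        assert not m.flags

    def test_mcc_hand_example(self):
        # TP=1 FP=1 FN=1 TN=2 -> (2-1)/sqrt(2*2*3*3) = 1/6
        c = confusion_matrix({"T2", "T3"}, {"T1", "T2"},
                             {"T1", "T2", "T3", "T4", "T5"})
        m = compute_metrics(c)
        assert m.mcc == pytest.approx(1 / 6)

    def test_degenerate_precision_flagged(self):
        c = confusion_matrix(set(), {"T1"}, {"T1", "T2"})
        m = compute_metrics(c)
        assert m.precision == 0.0
        assert "precision_undefined" in m.flags
        assert "mcc_degenerate" in m.flags

    def test_oracle_equivalence_small_universe(self):
        # enumerate every outcome target-by-target and apply the formulas
        # directly, independent of ConfusionCounts bookkeeping
        rng = np.random.default_rng(43)
        universe = [f"T{i}" for i in range(12)]
        for _ in range(100):
            known = set(rng.choice(universe, rng.integers(0, 13), replace=False))
            predicted = set(rng.choice(universe, rng.integers(0, 13), replace=False))
            tp = fp = fn = tn = 0
            for t in universe:
                if t in predicted and t in known:
                    tp += 1
                elif t in predicted:
                    fp += 1
                elif t in known:
                    fn += 1
                else:
                    tn += 1
            m = compute_metrics(confusion_matrix(predicted, known, universe))
            assert m.accuracy == pytest.approx((tp + tn) / 12)
            if tp + fp:
                assert m.precision == pytest.approx(tp / (tp + fp))
            if tp + fn:
                assert m.recall == pytest.approx(tp / (tp + fn))
            denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
            if denom:
                assert m.mcc == pytest.approx(
                    (tp * tn - fp * fn) / math.sqrt(denom))


class TestSummarize:
    def test_single_value(self):
        s = summarize([7.0], ids=["a"])
        assert s.mean == s.median == s.q1 == s.q3 == s.min == s.max == 7.0
        assert s.outlier_ids == ()

    def test_hand_example_with_outlier(self):
        s = summarize([1, 2, 3, 4, 100], ids=list("abcde"))
        assert s.median == 3
        assert s.mean == 22
        assert s.q1 == 2 and s.q3 == 4  # linear interpolation
        assert s.outlier_ids == ("e",)  # fences [2-3, 4+3] = [-1, 7]

    def test_median_stable_under_median_append(self):
        rng = np.random.default_rng(47)
        values = rng.random(21).tolist()
        med = summarize(values).median
        assert summarize(values + [med]).median == pytest.approx(med)

    def test_empty_rejected(self):
        with pytest.raises(ContractError):
            summarize([])

    def test_order_invariants(self):
        rng = np.random.default_rng(53)
        for _ in range(20):
            s = summarize(rng.normal(size=30).tolist())
            assert s.min <= s.q1 <= s.median <= s.q3 <= s.max


class TestNeglectedTargets:
    def test_ligand_centric_vs_40_ligand_class(self):
        assert neglected_targets(3035, 917) == 2118

    def test_five_ligand_class(self):
        assert neglected_targets(2580, 1788) == 792

    def test_equal_counts(self):
        assert neglected_targets(1234, 1234) == 0

    def test_negative_difference_rejected(self):
        with pytest.raises(ContractError):
            neglected_targets(10, 11)

    def test_coverage_row_from_map(self, criteria):
        pairs = ([(f"A{i}", "T_big") for i in range(5)]
                 + [("B0", "T_small"), ("B1", "T_mid"), ("B2", "T_mid")])
        kmap = KnownTargetMap(pairs, criteria)
        row = coverage_row(kmap, min_ligands=2)
        assert row.n_targets_ligand_centric == 3
        assert row.n_targets_method == 2
        assert row.n_neglected == 1


class TestOverlapReport:
    def _prediction(self, predicted, criteria, query="Q"):
        # route through the real predictor with one hit carrying all targets
        db = {"H1": make_fp([0, 1, 2])}
        kmap = KnownTargetMap([("H1", t) for t in predicted], criteria)
        return predict_targets(query, make_fp([0, 1]), db, kmap, k=1)

    def test_high_precision_case(self, criteria):
        known = {f"T{i}" for i in range(67)}
        predicted = {f"T{i}" for i in range(59, 68)}
        rep = overlap_report(self._prediction(predicted, criteria), known)
        assert rep.nkt == 67 and rep.npt == 9
        assert len(rep.tp_targets) == 8
        assert len(rep.fp_targets) == 1
        assert len(rep.fn_targets) == 59

    def test_low_precision_case(self, criteria):
        known = {"K1", "K2", "K3"}
        predicted = {"K1"} | {f"X{i}" for i in range(20)}
        rep = overlap_report(self._prediction(predicted, criteria), known)
        assert rep.nkt == 3 and rep.npt == 21
        assert len(rep.tp_targets) == 1 and len(rep.fp_targets) == 20

    def test_empty_prediction(self):
        from targetfish.predict import QueryPrediction

        pred = QueryPrediction(query_id="Q", k=1, hits=(),
                               predicted_targets=frozenset(), support={})
        rep = overlap_report(pred, {"TA", "TB"})
        assert set(rep.fn_targets) == {"TA", "TB"}
        assert rep.tp_targets == () and rep.fp_targets == ()


class TestRunBenchmark:
    def test_noiseless_regime_all_ones(self, criteria):
        gt = generate_database(SyntheticConfig(
            n_series=8, molecules_per_series=6, bitflip_noise=0.0,
            activity_range=(1.0, 5000.0), seed=21))
        kmap = KnownTargetMap(
            [(m, t) for m, ts in gt.truth_map.items() for t in ts], criteria)
        database = tuple(sorted(set(gt.fingerprints) - set(gt.query_ids)))
        part = BenchmarkPartition(
            label="noiseless", criteria=criteria,
            query_ids=gt.query_ids, database_ids=database, seed=0)
        result = run_benchmark(part, kmap, gt.fingerprints, k=3)
        assert result.aggregate["avPrecision"] == 1.0
        assert result.aggregate["avRecall"] == 1.0
        assert result.aggregate["avMCC"] == 1.0

    def test_handcrafted_full_trace(self, criteria):
        # one query, three database molecules; every cell hand-computed
        fps = {
            "Q": make_fp([0, 1, 2, 3]),
            "M1": make_fp([0, 1, 2, 100, 101, 102]),  # dice 0.6
            "M2": make_fp([0, 1, 2, 3]),              # dice 1.0
            "M3": make_fp([10, 11]),                  # dice 0.0
        }
        kmap = KnownTargetMap(
            [("M1", "T1"), ("M1", "T2"), ("M2", "T2"), ("M2", "T3"),
             ("M3", "T4"), ("Q", "T2"), ("Q", "T3"), ("Q", "T5")],
            criteria)
        part = BenchmarkPartition(
            label="hand", criteria=criteria,
            query_ids=("Q",), database_ids=("M1", "M2", "M3"), seed=0)
        result = run_benchmark(part, kmap, fps, k=2)
        row = result.per_query.iloc[0]
        # top-2 hits = M2 (1.0), M1 (0.6); predicted = {T1,T2,T3}
        # known = {T2,T3,T5}; universe = {T1..T5}
        assert row["NKT"] == 3 and row["NPT"] == 3
        assert (row["TP"], row["FP"], row["FN"], row["TN"]) == (2, 1, 1, 1)
        assert row["accuracy"] == pytest.approx(0.6)
        assert row["precision"] == pytest.approx(2 / 3)
        assert row["recall"] == pytest.approx(2 / 3)
        assert row["mcc"] == pytest.approx(1 / 6)

    def test_recall_monotone_in_k(self, criteria):
        gt = generate_database(SyntheticConfig(
            n_series=10, molecules_per_series=6, bitflip_noise=0.05,
            promiscuity_mean=1.0, activity_range=(1.0, 5000.0), seed=77))
        kmap = KnownTargetMap(
            [(m, t) for m, ts in gt.truth_map.items() for t in ts], criteria)
        database = tuple(sorted(set(gt.fingerprints) - set(gt.query_ids)))
        part = BenchmarkPartition(
            label="mono", criteria=criteria,
            query_ids=gt.query_ids, database_ids=database, seed=0)
        recalls = []
        npts = []
        for k in (1, 5, 10, 15):
            res = run_benchmark(part, kmap, gt.fingerprints, k)
            recalls.append(res.aggregate["avRecall"])
            npts.append(res.aggregate["avNPT"])
        assert recalls == sorted(recalls)
        assert npts == sorted(npts)

    def test_unavailable_query_excluded(self, criteria):
        fps = {"Q1": make_fp([0, 1]), "M1": make_fp([0, 1, 2])}
        kmap = KnownTargetMap([("M1", "T1"), ("Q1", "T1"), ("Q2", "T1")], criteria)
        part = BenchmarkPartition(
            label="x", criteria=criteria,
            query_ids=("Q1", "Q2"), database_ids=("M1",), seed=0)
        result = run_benchmark(part, kmap, fps, k=1)
        assert result.aggregate["n_queries"] == 1
        assert result.aggregate["n_excluded"] == 1
        assert result.exclusions[0].query_id == "Q2"
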