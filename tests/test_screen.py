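"""Combination screening: enumeration, carriers, precision, enrichment."""

import math

import numpy as np
import pandas as pd
import pytest

import slem
from slem.exceptions import InvalidArgumentError, ScreeningError
from slem.screen import GenotypeCombination, records_to_frame


def combo(*pairs):
    return GenotypeCombination(tuple(pairs))


def make_data(geno_rows, labels, snps=("A", "B", "C", "D", "E")):
    idx = pd.Index([f"S{i}" for i in range(len(geno_rows))], name="sample")
    return slem.EndToEndDataset(
        genotypes=pd.DataFrame(geno_rows, index=idx, columns=list(snps)[: len(geno_rows[0])]),
        labels=pd.Series(labels, index=idx),
    )


class TestEnumeration:
    def test_single_snp_three_states(self):
        combos = slem.enumerate_combinations(["A"], 1, 1)
        assert [str(c) for c in combos] == ["A0", "A1", "A2"]

    def test_five_snps_all_orders(self):
        combos = slem.enumerate_combinations(list("ABCDE"), 1, 5)
        expected = sum(math.comb(5, k) * 3**k for k in range(1, 6))
        assert expected == 4**5 - 1 == 1023
        assert len(combos) == 1023
        assert len({str(c) for c in combos}) == 1023  # no duplicates

    def test_order_bounds_validated(self):
        with pytest.raises(InvalidArgumentError):
            slem.enumerate_combinations([], 1, 1)
        with pytest.raises(InvalidArgumentError):
            slem.enumerate_combinations(["A"], 2, 1)
        with pytest.raises(InvalidArgumentError):
            slem.enumerate_combinations(["A"], 1, 2)

    def test_notation_round_trip(self):
        c = combo(("A", 0), ("B", 1), ("C", 2))
        assert str(c) == "A0B1C2"
        assert c.order == 3


class TestCarriers:
    def test_hand_built_matrix(self):
        data = make_data(
            [[2, 1, 0, 0], [2, 0, 1, 0], [1, 1, 1, 1], [2, 2, 2, 0], [0, 0, 0, 0]],
            [1, 0, 1, 1, 0],
            snps=("A", "B", "C", "D"),
        )
        got = slem.carriers(data.genotypes, combo(("A", 2), ("D", 0)))
        assert got == ["S0", "S1", "S3"]

    def test_no_samples(self):
        geno = pd.DataFrame(columns=["A", "B"], dtype=float)
        assert slem.carriers(geno, combo(("A", 1))) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_row_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        geno = pd.DataFrame(
            rng.integers(0, 3, size=(50, 4)), columns=list("ABCD"),
            index=[f"S{i}" for i in range(50)],
        )
        c = combo(("B", 1), ("D", 2))
        oracle = [
            i for i, row in geno.iterrows() if row["B"] == 1 and row["D"] == 2
        ]
        assert slem.carriers(geno, c) == oracle

    def test_missing_genotype_excludes_sample(self):
        geno = pd.DataFrame(
            [[2.0, 0.0], [np.nan, 0.0], [2.0, 0.0]], columns=["A", "B"],
            index=["S0", "S1", "S2"],
        )
        assert slem.carriers(geno, combo(("A", 2), ("B", 0))) == ["S0", "S2"]

    def test_anti_monotone_in_constraints(self):
        rng = np.random.default_rng(7)
        geno = pd.DataFrame(
            rng.integers(0, 3, size=(200, 5)), columns=list("ABCDE"),
            index=[f"S{i}" for i in range(200)],
        )
        base = combo(("A", 1))
        extended = combo(("A", 1), ("B", 0))
        more = combo(("A", 1), ("B", 0), ("C", 2))
        counts = [len(slem.carriers(geno, c)) for c in (base, extended, more)]
        assert counts[0] >= counts[1] >= counts[2]


class TestPrecision:
    @pytest.mark.parametrize(
        "tp,pos,expected",
        [(10, 13, 0.769), (6, 6, 1.0), (0, 5, 0.0)],
    )
    def test_printed_ratios(self, tp, pos, expected):
        assert slem.precision(tp, pos) == pytest.approx(expected, abs=5e-4)

    def test_zero_positives_is_nan_not_crash(self):
        assert math.isnan(slem.precision(0, 0))

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(InvalidArgumentError):
            slem.precision(5, 3)

    def test_union_precision_between_parts(self):
        # precision of a disjoint union is the weighted mean of the parts
        for tp1, n1, tp2, n2 in [(3, 5, 7, 10), (0, 4, 4, 4), (2, 9, 1, 2)]:
            p1, p2 = slem.precision(tp1, n1), slem.precision(tp2, n2)
            pu = slem.precision(tp1 + tp2, n1 + n2)
            assert min(p1, p2) - 1e-12 <= pu <= max(p1, p2) + 1e-12


def hypergeom_enumeration_oracle(N, K, n, k):
    """Exhaustive tail sum over the support using binomial coefficients."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, j) * math.comb(N - K, n - j) for j in range(k, min(K, n) + 1)
    ) / total


class TestHypergeom:
    def test_zero_successes_is_one(self):
        assert slem.hypergeom_upper(20, 8, 5, 0) == pytest.approx(1.0)

    def test_small_exact_value(self):
        # C(5,4)*C(5,0)/C(10,4) = 5/210
        assert slem.hypergeom_upper(10, 5, 4, 4) == pytest.approx(5 / 210, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(4, 13))
        K = int(rng.integers(1, N + 1))
        n = int(rng.integers(1, N + 1))
        k = int(rng.integers(0, min(K, n) + 1))
        assert slem.hypergeom_upper(N, K, n, k) == pytest.approx(
            hypergeom_enumeration_oracle(N, K, n, k), abs=1e-12
        )

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(InvalidArgumentError):
            slem.hypergeom_upper(10, 12, 4, 2)
        with pytest.raises(InvalidArgumentError):
            slem.hypergeom_upper(10, 5, 4, 5)


class TestScreen:
    def test_planted_penetrant_combination_passes(self):
        rng = np.random.default_rng(0)
        geno = rng.integers(0, 3, size=(500, 3))
        labels = rng.integers(0, 2, size=500)
        is_carrier = (geno[:, 0] == 2) & (geno[:, 1] == 0)
        labels[is_carrier] = 1  # fully penetrant
        data = make_data(geno.tolist(), labels.tolist(), snps=("A", "B", "C"))
        records = slem.screen(data, ["A", "B", "C"])
        rec = next(r for r in records if str(r.combination) == "A2B0")
        assert rec.passed and rec.precision == 1.0

    def test_strict_inequality_at_thresholds(self):
        # precision exactly 0.6 fails; just above passes (p forced tiny)
        geno = [[1]] * 10
        labels = [1] * 6 + [0] * 4
        data = make_data(geno, labels, snps=("A",))
        records = slem.screen(data, ["A"], precision_threshold=0.6, p_threshold=0.999)
        rec = next(r for r in records if str(r.combination) == "A1")
        assert rec.precision == pytest.approx(0.6)
        assert not rec.passed

    def test_no_carrier_combination_flagged(self):
        data = make_data([[0], [0], [1]], [1, 0, 1], snps=("A",))
        records = slem.screen(data, ["A"])
        rec = next(r for r in records if str(r.combination) == "A2")
        assert rec.no_carriers and not rec.passed

    def test_zero_patients_rejected(self):
        data = make_data([[0], [1]], [0, 0], snps=("A",))
        with pytest.raises(ScreeningError):
            slem.screen(data, ["A"])

    def test_null_pass_rate_controlled(self):
        # Label permutation: a fixed combination passes at most ~alpha often.
        rng = np.random.default_rng(1)
        geno = rng.integers(0, 3, size=(400, 2))
        labels = rng.integers(0, 2, size=400)
        data = make_data(geno.tolist(), labels.tolist(), snps=("A", "B"))
        passes = 0
        reps = 100
        for _ in range(reps):
            perm = slem.EndToEndDataset(
                genotypes=data.genotypes,
                labels=pd.Series(
                    rng.permutation(data.labels.to_numpy()), index=data.genotypes.index
                ),
            )
            recs = slem.screen(perm, ["A", "B"], min_order=2, max_order=2)
            rec = next(r for r in recs if str(r.combination) == "A1B1")
            passes += rec.passed
        se = np.sqrt(0.05 * 0.95 / reps)
        assert passes / reps <= 0.05 + 3 * se

    def test_single_snp_control_group(self):
        rng = np.random.default_rng(2)
        geno = rng.integers(0, 3, size=(100, 3))
        labels = rng.integers(0, 2, size=100)
        data = make_data(geno.tolist(), labels.tolist(), snps=("A", "B", "C"))
        records = slem.screen_single_snps(data, ["A", "B", "C"])
        assert len(records) == 9
        assert all(r.combination.order == 1 for r in records)


class TestEvaluateHoldout:
    def test_identical_holdout_reproduces_precisions(self):
        rng = np.random.default_rng(3)
        geno = rng.integers(0, 3, size=(300, 2))
        labels = rng.integers(0, 2, size=300)
        is_carrier = geno[:, 0] == 2
        labels[is_carrier] = 1
        data = make_data(geno.tolist(), labels.tolist(), snps=("A", "B"))
        records = slem.screen(data, ["A", "B"])
        table = slem.evaluate_holdout(records, data)
        assert len(table) == sum(r.passed for r in records)
        np.testing.assert_allclose(table["holdout_precision"], table["train_precision"])

    def test_tiny_holdout_single_carrier(self):
        train = make_data([[2], [2], [0], [0]], [1, 1, 0, 1], snps=("A",))
        records = slem.screen(train, ["A"], p_threshold=0.9)
        holdout = make_data([[2], [0]], [1, 0], snps=("A",))
        table = slem.evaluate_holdout(records, holdout)
        row = table[table["combination"] == "A2"].iloc[0]
        assert row["holdout_precision"] == pytest.approx(1.0)

    def test_no_holdout_carriers_flagged(self):
        train = make_data([[2], [2], [0], [0]], [1, 1, 0, 1], snps=("A",))
        records = slem.screen(train, ["A"], p_threshold=0.9)
        holdout = make_data([[0], [1], [0]], [1, 0, 1], snps=("A",))
        table = slem.evaluate_holdout(records, holdout)
        row = table[table["combination"] == "A2"].iloc[0]
        assert row["no_carriers"]
        assert math.isnan(row["holdout_precision"])

    def test_de_enriched_label(self):
        train = make_data([[2], [2], [2], [0]], [1, 1, 1, 0], snps=("A",))
        records = slem.screen(train, ["A"], p_threshold=0.9)
        # holdout where carriers are mostly controls, base rate high
        holdout = make_data([[2], [2], [2], [0], [0]], [0, 0, 1, 1, 1], snps=("A",))
        table = slem.evaluate_holdout(records, holdout)
        row = table[table["combination"] == "A2"].iloc[0]
        assert row["de_enriched"]

    def test_frame_export_columns(self):
        data = make_data([[1], [0], [1], [2]], [1, 0, 1, 0], snps=("A",))
        frame = records_to_frame(slem.screen(data, ["A"]))
        assert list(frame.columns) == [
            "combination", "order", "positives", "true_positives", "precision", "p", "passed",
        ]
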