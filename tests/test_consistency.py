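"""BMU assignment, pair distances and the quartile outlier rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import somcoex as sx
from somcoex import consistency as cons
from somcoex.som import HexGrid, SomModel, TrainingConfig

GRID = HexGrid(20, 20)


def _table(name, assignments):
    return cons.BmuTable(name, dict(assignments))


# independent quantile oracle: sort + linear interpolation between order stats
def _quantile_oracle(vals, q):
    s = sorted(vals)
    pos = q * (len(s) - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    return s[lo] + (pos - lo) * (s[hi] - s[lo])


def _tukey_oracle(vals, multiplier=1.5):
    q1 = _quantile_oracle(vals, 0.25)
    q3 = _quantile_oracle(vals, 0.75)
    iqr = q3 - q1
    lo, hi = q1 - multiplier * iqr, q3 + multiplier * iqr
    return (lo, hi), [v < lo or v > hi for v in vals]


class TestAssignBmus:
    def _model(self):
        rng = np.random.default_rng(0)
        W = rng.uniform(0, 1, (400, 5))
        return SomModel(grid=GRID, weights=W, config=TrainingConfig())

    def test_profile_equal_to_weight_maps_there(self):
        model = self._model()
        ds = sx.ExpressionDataset(
            "d", ["g1"], np.arange(5.0),
            model.weights[41][None, :], np.zeros((1, 5), bool), scale="fraction01",
        )
        assert cons.assign_bmus(model, ds).assignments["g1"] == 42

    def test_identical_profiles_co_cluster(self):
        model = self._model()
        x = np.array([0.2, 0.4, 0.6, 0.8, 1.0])
        ds = sx.ExpressionDataset(
            "d", ["g1", "g2"], np.arange(5.0),
            np.vstack([x, x]), np.zeros((2, 5), bool), scale="fraction01",
        )
        t = cons.assign_bmus(model, ds)
        assert t.assignments["g1"] == t.assignments["g2"]
        assert len(t.clusters[t.assignments["g1"]]) == 2

    def test_most_units_empty_with_fewer_genes_than_units(self, synthetic_run):
        # 120 genes on 400 units leaves at least 280 units empty
        for table in synthetic_run["tables"]:
            occupied = len(table.clusters)
            assert occupied <= 120
            assert 400 - occupied >= 280

    def test_dimension_mismatch(self):
        model = self._model()
        ds = sx.ExpressionDataset(
            "d", ["g1"], np.arange(4.0),
            np.zeros((1, 4)), np.zeros((1, 4), bool), scale="fraction01",
        )
        with pytest.raises(ValueError):
            cons.assign_bmus(model, ds)


class TestCommonGenes:
    def test_identical_tables(self):
        t = _table("a", {"g1": 1, "g2": 2})
        assert cons.common_genes([t, _table("b", {"g1": 5, "g2": 9})]) == ["g1", "g2"]

    def test_disjoint_tables(self):
        assert cons.common_genes(
            [_table("a", {"g1": 1}), _table("b", {"g2": 1})]
        ) == []

    def test_known_overlap(self):
        rng = np.random.default_rng(1)
        shared = [f"s{i}" for i in range(100)]
        sizes = [275, 236, 278, 238, 253]
        tables = []
        for k, size in enumerate(sizes):
            extra = [f"x{k}_{i}" for i in range(size - 100)]
            genes = shared + extra
            tables.append(_table(f"db{k}", {g: int(rng.integers(1, 401)) for g in genes}))
        assert cons.common_genes(tables) == sorted(shared)


class TestPairDistances:
    def test_pair_count_is_n_choose_2(self):
        genes = {f"g{i}": i + 1 for i in range(10)}
        tables = [_table("a", genes), _table("b", genes)]
        records = cons.pair_distance_table(tables, GRID)
        assert len(records) == 45

    def test_co_located_pair_distance_zero(self):
        tables = [
            _table("a", {"g1": 7, "g2": 7}),
            _table("b", {"g1": 7, "g2": 300}),
        ]
        rec = cons.pair_distance_table(tables, GRID)[0]
        assert rec.distances[0] == 0.0
        assert rec.distances[1] > 0

    def test_adjacent_row_units_distance_one(self):
        tables = [_table("a", {"g1": 2, "g2": 22})]
        rec = cons.pair_distance_table(tables, GRID, genes=["g1", "g2"])[0]
        assert rec.distances[0] == 1.0

    def test_missing_gene_is_contract_violation(self):
        tables = [_table("a", {"g1": 1, "g2": 2}), _table("b", {"g1": 1})]
        with pytest.raises(ValueError, match="absent"):
            cons.pair_distance_table(tables, GRID, genes=["g1", "g2"])


class TestFlagOutliers:
    def test_zero_spread_no_flags(self):
        fences, flags = cons.flag_outliers(np.array([3, 3, 3, 3, 3.0]))
        assert not flags.any()

    def test_degenerate_iqr_flags_the_deviant(self):
        fences, flags = cons.flag_outliers(np.array([1, 1, 1, 1, 10.0]))
        assert fences == (1.0, 1.0)
        assert list(flags) == [False, False, False, False, True]

    def test_moderate_spread_no_flags(self):
        fences, flags = cons.flag_outliers(np.array([1, 2, 3, 4, 5.0]))
        assert fences == (-1.0, 7.0)
        assert not flags.any()

    def test_fewer_than_four_refused(self):
        with pytest.raises(ValueError):
            cons.flag_outliers(np.array([1.0, 2.0, 3.0]))

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        vals = np.round(rng.uniform(0, 25, 5), 3)
        fences, flags = cons.flag_outliers(vals)
        oracle_fences, oracle_flags = _tukey_oracle(list(vals))
        assert fences[0] == pytest.approx(oracle_fences[0])
        assert fences[1] == pytest.approx(oracle_fences[1])
        assert list(flags) == oracle_flags


class TestOutlierReport:
    def test_identical_databases_no_outliers(self):
        genes = {f"g{i}": 3 * i + 1 for i in range(8)}
        tables = [_table(f"db{k}", genes) for k in range(5)]
        report = cons.outlier_report(tables, GRID)
        assert report.total_pairs == 28
        assert all(v == 0 for v in report.per_database_outlier_counts.values())

    def test_constructed_discordant_distance_flagged_once(self):
        # g2 moves from unit 2 to unit 21 in db4: both are lattice neighbors
        # of g1's unit 1, so only the (g2, g3) distance becomes discordant
        base = {"g1": 1, "g2": 2, "g3": 12}
        tables = [_table(f"db{k}", base) for k in range(4)]
        tables.append(_table("db4", {"g1": 1, "g2": 21, "g3": 12}))
        report = cons.outlier_report(tables, GRID)
        assert report.total_pairs == 3
        counts = report.per_database_outlier_counts
        assert counts["db4"] == 1
        assert sum(counts.values()) == 1
        flagged = next(r for r in report.records if r.outlier_flags.any())
        assert {flagged.gene_a, flagged.gene_b} == {"g2", "g3"}

    def test_counts_conserve_flags(self, synthetic_run):
        report = cons.outlier_report(synthetic_run["tables"], GRID)
        manual = dict.fromkeys(report.database_names, 0)
        for rec in report.records:
            for name, f in zip(report.database_names, rec.outlier_flags):
                manual[name] += bool(f)
        assert manual == report.per_database_outlier_counts
        assert report.total_pairs == len(report.records)

    def test_fewer_than_four_databases_refused(self):
        genes = {"g1": 1, "g2": 2}
        with pytest.raises(ValueError):
            cons.outlier_report([_table("a", genes), _table("b", genes)], GRID)

    def test_shuffled_database_has_strictly_most_outliers(self):
        rng = np.random.default_rng(42)
        genes = [f"g{i}" for i in range(40)]
        base = {g: int(rng.integers(1, 401)) for g in genes}
        tables = [_table(f"db{k}", base) for k in range(4)]
        shuffled = dict(zip(genes, rng.permutation(list(base.values()))))
        tables.append(_table("odd", shuffled))
        counts = cons.outlier_report(tables, GRID).per_database_outlier_counts
        assert counts["odd"] > max(v for k, v in counts.items() if k != "odd")


class TestPairLists:
    def _tables(self):
        a = {"g1": 1, "g2": 1, "g3": 400}
        b = {"g1": 5, "g2": 5, "g3": 396}
        return [_table("a", a), _table("b", b)]

    def test_zero_threshold_only_co_located(self):
        pairs = cons.consistent_pairs(self._tables(), GRID, 0.0)
        assert pairs == [("g1", "g2")]

    def test_diameter_threshold_returns_all(self):
        pairs = cons.consistent_pairs(self._tables(), GRID, GRID.diameter())
        assert len(pairs) == 3

    def test_opposite_above_diameter_empty(self):
        assert cons.opposite_pairs(self._tables(), GRID, GRID.diameter() + 1) == []

    def test_opposite_zero_threshold_returns_all(self):
        assert len(cons.opposite_pairs(self._tables(), GRID, 0.0)) == 3

    def test_threshold_monotonicity(self, synthetic_run):
        tables = synthetic_run["tables"]
        close_small = set(cons.consistent_pairs(tables, GRID, 2.0))
        close_big = set(cons.consistent_pairs(tables, GRID, 5.0))
        assert close_small <= close_big
        far_strict = set(cons.opposite_pairs(tables, GRID, 15.0))
        far_loose = set(cons.opposite_pairs(tables, GRID, 10.0))
        assert far_strict <= far_loose

    def test_planted_anti_phase_pair_found_far(self, synthetic_run):
        tables = synthetic_run["tables"]
        far = set(cons.opposite_pairs(tables, GRID, GRID.diameter() / 2))
        truth = synthetic_run["truth"]
        for pair in truth.anti_phase_pairs:
            assert pair in far


def test_report_tsv_round_trip_counts(tmp_path, synthetic_run):
    report = cons.outlier_report(synthetic_run["tables"], GRID)
    out = cons.write_outlier_report(report, tmp_path / "r.tsv")
    lines = out.read_text().splitlines()
    assert len(lines) == report.total_pairs + 1
    flag_cols = [l.split("\t")[-5:] for l in lines[1:]]
    total_flags = sum(int(v) for row in flag_cols for v in row)
    assert total_flags == sum(report.per_database_outlier_counts.values())
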