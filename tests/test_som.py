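"""Hex geometry, training arithmetic and map-organization behavior."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

import somcoex as sx
from somcoex.som import (
    HexGrid,
    SomModel,
    TrainingConfig,
    epochs_for,
    find_bmu,
    load_model,
    neighborhood_value,
    pca_initialize,
    quantization_error,
    save_model,
    unit_distance,
    update_weight,
)

GRID = HexGrid(20, 20)


class TestHexGeometry:
    def test_labels_20_apart_are_lattice_adjacent(self):
        # units 2 and 22 sit in adjacent rows one half-column apart
        assert unit_distance(GRID, 2, 22) == 1.0

    def test_identity(self):
        assert unit_distance(GRID, 137, 137) == 0.0

    def test_same_row_two_columns(self):
        assert unit_distance(GRID, 1, 3) == 2.0

    def test_interior_unit_has_six_neighbors_at_one(self):
        lab = GRID.rc_to_label(10, 10)
        d = GRID.pairwise_distances()[lab - 1]
        assert (d == 1.0).sum() == 6

    def test_coordinate_convention(self):
        xy = GRID.coords()
        r, c = 7, 3
        lab = GRID.rc_to_label(r, c)
        assert lab == r * 20 + c + 1
        assert xy[lab - 1, 0] == c + 0.5 * (r % 2)
        assert xy[lab - 1, 1] == pytest.approx(r * math.sqrt(3) / 2)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(1, 400), st.integers(1, 400), st.integers(1, 400))
    def test_metric_properties(self, a, b, c):
        dab = unit_distance(GRID, a, b)
        assert dab == unit_distance(GRID, b, a)
        assert (dab == 0) == (a == b)
        assert dab <= unit_distance(GRID, a, c) + unit_distance(GRID, c, b) + 1e-12

    def test_label_out_of_range(self):
        with pytest.raises(ValueError):
            unit_distance(GRID, 0, 5)
        with pytest.raises(ValueError):
            unit_distance(GRID, 1, 401)


class TestEpochRule:
    @pytest.mark.parametrize(
        "grid,n,m,expected",
        [
            (HexGrid(20, 20), 275, 10, 15),   # ceil(4000/275)
            (HexGrid(20, 20), 400, 10, 10),   # exact division
            (HexGrid(10, 10), 10_000, 10, 1), # clamped to one epoch
        ],
    )
    def test_rule(self, grid, n, m, expected):
        assert epochs_for(grid, n, m) == expected

    def test_invalid_gene_count(self):
        with pytest.raises(ValueError):
            epochs_for(GRID, 0)


class TestNeighborhood:
    def test_bmu_gets_exactly_one(self):
        assert neighborhood_value(0.0, 3.0) == 1.0
        assert neighborhood_value(0.0, 0.01) == 1.0

    def test_closed_form_at_sigma(self):
        assert neighborhood_value(3.0, 3.0) == pytest.approx(math.exp(-0.5))

    def test_effectively_zero_far_away(self):
        assert neighborhood_value(10.0, 1.0) < 1e-21

    def test_strictly_decreasing(self):
        vals = [neighborhood_value(d, 2.0) for d in np.linspace(0, 8, 30)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            neighborhood_value(1.0, 0.0)


class TestUpdateWeight:
    def test_full_step_reaches_input(self):
        w, x = np.array([0.2, 0.8]), np.array([1.0, 0.0])
        assert np.allclose(update_weight(w, x, 1.0, 1.0), x)

    def test_zero_rate_freezes(self):
        w, x = np.array([0.2, 0.8]), np.array([1.0, 0.0])
        assert np.array_equal(update_weight(w, x, 0.0, 1.0), w)

    def test_quarter_step_arithmetic(self):
        out = update_weight(np.array([0.0]), np.array([1.0]), 0.5, 0.5)
        assert out[0] == pytest.approx(0.25)


class TestFindBmu:
    def _model(self, weights):
        n = len(weights)
        rows = max(1, int(np.ceil(n / 2)))
        grid = HexGrid(rows, 2)
        W = np.zeros((grid.n_units, len(weights[0])))
        W[: len(weights)] = weights
        W[len(weights):] = 1e6  # park unused units far away
        return SomModel(grid=grid, weights=W, config=TrainingConfig(n_rows=rows, n_cols=2))

    def test_exact_match_wins(self):
        m = self._model([[0.0, 0.0], [1.0, 1.0], [0.3, 0.7]])
        assert find_bmu(np.array([0.3, 0.7]), m) == 3

    def test_two_unit_toy(self):
        m = self._model([[0.0, 0.0], [1.0, 1.0]])
        assert find_bmu(np.array([0.9, 0.8]), m) == 2

    def test_tie_breaks_to_lowest_label(self):
        m = self._model([[0.0, 0.0], [2.0, 0.0], [0.0, 0.0], [2.0, 0.0]])
        assert find_bmu(np.array([1.0, 0.0]), m) == 1

    def test_dimension_mismatch(self):
        m = self._model([[0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(ValueError):
            find_bmu(np.array([1.0, 2.0, 3.0]), m)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_argmin(self, seed):
        rng = np.random.default_rng(seed)
        grid = HexGrid(5, 5)
        W = rng.uniform(0, 1, (25, 6))
        model = SomModel(grid=grid, weights=W, config=TrainingConfig(n_rows=5, n_cols=5))
        x = rng.uniform(0, 1, 6)
        # independent oracle: explicit loop over units
        best, best_d = None, np.inf
        for j in range(25):
            d = float(np.sqrt(((x - W[j]) ** 2).sum()))
            if d < best_d:
                best, best_d = j + 1, d
        assert find_bmu(x, model) == best


class TestPcaInitialize:
    def test_planar_data_stays_on_plane(self):
        rng = np.random.default_rng(0)
        basis = rng.normal(size=(2, 10))
        coeff = rng.normal(size=(40, 2))
        data = 0.3 + coeff @ basis  # exact 2-D affine plane
        W = pca_initialize(HexGrid(6, 6), data)
        # residual after projecting back onto the plane
        centered = W - data.mean(axis=0)
        q, _ = np.linalg.qr(basis.T)
        resid = centered - centered @ q @ q.T
        assert np.abs(resid).max() < 1e-9

    def test_identical_rows_give_constant_weights(self):
        data = np.tile(np.array([0.1, 0.5, 0.9]), (8, 1))
        W = pca_initialize(HexGrid(4, 4), data)
        assert np.allclose(W, data[0], atol=1e-12)

    def test_sign_flip_leaves_quantization_error_unchanged(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(30, 8))
        grid = HexGrid(6, 6)
        W = pca_initialize(grid, data)
        flipped = pca_initialize(grid, -data)  # flips principal directions
        assert quantization_error(data, W) == pytest.approx(
            quantization_error(-data, flipped)
        )


class TestTraining:
    def test_degenerate_identical_profiles_converge(self):
        profile = np.linspace(0, 1, 7)
        data = np.tile(profile, (12, 1))
        ds = sx.ExpressionDataset(
            "const", [f"g{i}" for i in range(12)], np.arange(7.0),
            data, np.zeros_like(data, dtype=bool), scale="fraction01",
        )
        model = sx.train(ds, TrainingConfig(n_rows=4, n_cols=4, rng_seed=0))
        d = np.sqrt(((model.weights - profile) ** 2).sum(axis=1)).min()
        assert d < 1e-6

    def test_bit_determinism(self):
        rng = np.random.default_rng(4)
        data = rng.uniform(0, 1, (40, 9))
        cfg = TrainingConfig(n_rows=8, n_cols=8, rng_seed=11)
        m1 = sx.train(data, cfg)
        m2 = sx.train(data, cfg)
        assert np.array_equal(m1.weights, m2.weights)

    def test_quantization_error_not_increasing(self):
        rng = np.random.default_rng(5)
        data = rng.uniform(0, 1, (60, 12))
        model = sx.train(data, TrainingConfig(rng_seed=2))
        assert model.qe_history[-1] <= model.qe_history[0]

    def test_two_well_separated_clusters_map_apart(self):
        """Anti-phase sinusoid clusters occupy disjoint map regions."""
        rng = np.random.default_rng(6)
        t = np.linspace(0, 4 * np.pi, 15)
        a = np.array([np.sin(t) + rng.normal(0, 0.02, 15) for _ in range(20)])
        b = np.array([np.sin(t + np.pi) + rng.normal(0, 0.02, 15) for _ in range(20)])
        data = (np.vstack([a, b]) + 1.2) / 2.4
        # map sized to the data so cluster regions stay compact
        model = sx.train(data, TrainingConfig(n_rows=10, n_cols=10, rng_seed=3))
        bmus = np.array([find_bmu(x, model) for x in data])
        D = model.grid.pairwise_distances()
        within, between = [], []
        for i in range(40):
            for j in range(i + 1, 40):
                d = D[bmus[i] - 1, bmus[j] - 1]
                (within if (i < 20) == (j < 20) else between).append(d)
        assert set(bmus[:20]).isdisjoint(bmus[20:])
        assert np.mean(between) / max(np.mean(within), 1e-9) > 3

    def test_phase_gradient_maps_monotonically(self):
        """A 1-D phase gradient lands on the map in phase order."""
        t = np.linspace(0, 4 * np.pi, 20)
        phases = np.linspace(0, np.pi, 50)
        data = (np.array([np.sin(t + p) for p in phases]) + 1) / 2
        model = sx.train(data, TrainingConfig(rng_seed=7))
        coords = model.grid.coords()
        pos = np.array([coords[find_bmu(x, model) - 1] for x in data])
        # project positions on their leading axis of variation
        centered = pos - pos.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        proj = centered @ vt[0]
        rho = abs(spearmanr(phases, proj).statistic)
        assert rho > 0.8

    def test_anti_phase_profiles_far_apart(self, synthetic_run):
        grid = synthetic_run["models"][0].grid
        D = grid.pairwise_distances()
        avg = D[np.triu_indices_from(D, 1)].mean()
        for a, b in synthetic_run["truth"].anti_phase_pairs:
            for table in synthetic_run["tables"]:
                d = D[table.assignments[a] - 1, table.assignments[b] - 1]
                assert d > avg

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            sx.train(np.zeros((0, 5)), TrainingConfig())

    def test_model_round_trip(self, tmp_path):
        rng = np.random.default_rng(8)
        data = rng.uniform(0, 1, (30, 6))
        model = sx.train(data, TrainingConfig(n_rows=6, n_cols=6, rng_seed=1))
        save_model(model, tmp_path / "m.json", tmp_path / "m.tsv")
        back = load_model(tmp_path / "m.json", tmp_path / "m.tsv")
        assert np.array_equal(back.weights, model.weights)
        assert back.grid == model.grid
        assert back.config == model.config
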