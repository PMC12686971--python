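import numpy as np
import pytest

from invpopgen.core import PairwiseMatrix, pairwise_from_condensed
from invpopgen.resistance import (
    ConductanceRaster,
    aicc,
    buffer_and_rasterize,
    compare_models,
    effective_resistance,
    fit_categorical_surface,
    ibd_candidate,
    null_candidate,
    read_ascii_grid,
    write_ascii_grid,
)


class TestRaster:
    def test_validation(self):
        with pytest.raises(ValueError, match="positive"):
            ConductanceRaster(np.array([[1.0, -2.0]]))
        with pytest.raises(ValueError, match="2-D"):
            ConductanceRaster(np.ones(4))

    def test_masked_cells_exempt_from_validation(self):
        r = ConductanceRaster(
            np.array([[1.0, -9999.0]]), mask=np.array([[False, True]])
        )
        assert r.mask.sum() == 1

    def test_cell_of_origin_and_orientation(self):
        r = ConductanceRaster(np.ones((3, 2)), cell_size=10.0, origin=(100.0, 200.0))
        assert r.cell_of(105.0, 205.0) == (2, 0)  # bottom-left cell is last row
        assert r.cell_of(115.0, 225.0) == (0, 1)  # top-right
        with pytest.raises(ValueError, match="outside"):
            r.cell_of(99.0, 205.0)

    def test_ascii_roundtrip(self, tmp_path):
        grid = np.array([[1.0, 2.5], [0.5, 4.0]])
        mask = np.array([[False, True], [False, False]])
        r = ConductanceRaster(grid, cell_size=25.0, origin=(10.0, 20.0), mask=mask)
        path = tmp_path / "g.asc"
        write_ascii_grid(r, path)
        back = read_ascii_grid(path)
        np.testing.assert_array_equal(back.mask, mask)
        np.testing.assert_allclose(back.grid[~mask], grid[~mask])
        assert back.cell_size == 25.0
        assert back.origin == (10.0, 20.0)


def test_buffer_rasterize_geometric_oracle():
    # 3x3 grid of 30 m cells over (0,0)-(90,90); cell centres at 15/45/75.
    # A vertical line at x=45 with a 20 m buffer covers only the middle column.
    lines = [[(45.0, 0.0), (45.0, 90.0)]]
    out = buffer_and_rasterize(lines, (0, 0, 90, 90), buffer_m=20.0, cell_m=30.0)
    expected = np.array([[False, True, False]] * 3)
    np.testing.assert_array_equal(out, expected)
    # 40 m buffer reaches every centre (30 m away)
    out2 = buffer_and_rasterize(lines, (0, 0, 90, 90), buffer_m=40.0, cell_m=30.0)
    assert out2.all()
    # no polylines -> empty mask
    assert not buffer_and_rasterize([], (0, 0, 90, 90)).any()


class TestEffectiveResistance:
    def test_series_strip(self):
        # 1x4 strip of unit conductance: three unit resistors in series
        r = ConductanceRaster(np.ones((1, 4)))
        m = effective_resistance(r, [(0, 0), (0, 3)])
        assert m.get("p0", "p1") == pytest.approx(3.0)

    def test_series_with_middle_conductance(self):
        # 1x3 strip, middle cell conductance c: edges (1+c)/2 each in series
        c = 4.0
        r = ConductanceRaster(np.array([[1.0, c, 1.0]]))
        m = effective_resistance(r, [(0, 0), (0, 2)])
        assert m.get("p0", "p1") == pytest.approx(2 * 2 / (1 + c))

    def test_parallel_square(self):
        # 2x2 unit grid: two 2-ohm paths in parallel across the diagonal
        r = ConductanceRaster(np.ones((2, 2)))
        m = effective_resistance(r, [(0, 0), (1, 1)])
        assert m.get("p0", "p1") == pytest.approx(1.0)

    def test_laplacian_pinv_oracle(self):
        rng = np.random.default_rng(8)
        grid = np.exp(rng.normal(0, 0.5, size=(7, 9)))
        raster = ConductanceRaster(grid)
        pts = [(0, 0), (3, 4), (6, 8), (2, 7)]
        m = effective_resistance(raster, pts)

        # dense oracle: build the Laplacian by explicit loops, use pinv
        nrows, ncols = grid.shape
        n = nrows * ncols
        L = np.zeros((n, n))
        for i in range(nrows):
            for j in range(ncols):
                for di, dj in ((0, 1), (1, 0)):
                    i2, j2 = i + di, j + dj
                    if i2 < nrows and j2 < ncols:
                        c = (grid[i, j] + grid[i2, j2]) / 2
                        a, b = i * ncols + j, i2 * ncols + j2
                        L[a, a] += c
                        L[b, b] += c
                        L[a, b] -= c
                        L[b, a] -= c
        G = np.linalg.pinv(L, hermitian=True)
        for x in range(len(pts)):
            for y in range(x + 1, len(pts)):
                a = pts[x][0] * ncols + pts[x][1]
                b = pts[y][0] * ncols + pts[y][1]
                oracle = G[a, a] + G[b, b] - 2 * G[a, b]
                assert m.values[x, y] == pytest.approx(oracle, rel=1e-8)

    def test_disconnected_pairs_inf(self):
        grid = np.ones((3, 3))
        mask = np.zeros((3, 3), dtype=bool)
        mask[:, 1] = True  # wall splits left and right columns
        r = ConductanceRaster(grid, mask=mask)
        m = effective_resistance(r, [(0, 0), (0, 2), (2, 0)])
        assert np.isinf(m.get("p0", "p1"))
        assert np.isfinite(m.get("p0", "p2"))

    def test_masked_point_rejected(self):
        r = ConductanceRaster(np.ones((2, 2)), mask=np.array([[True, False], [False, False]]))
        with pytest.raises(ValueError, match="masked cell"):
            effective_resistance(r, [(0, 0), (1, 1)])

    def test_rayleigh_monotonicity(self):
        rng = np.random.default_rng(9)
        grid = np.exp(rng.normal(0, 0.3, size=(5, 5)))
        pts = [(0, 0), (4, 4), (0, 4)]
        base = effective_resistance(ConductanceRaster(grid), pts)
        bumped = grid.copy()
        bumped[2, 2] *= 5.0  # raising a conductance can only help current
        after = effective_resistance(ConductanceRaster(bumped), pts)
        assert (after.values <= base.values + 1e-12).all()

    def test_scaling_property(self):
        rng = np.random.default_rng(10)
        grid = np.exp(rng.normal(0, 0.3, size=(4, 6)))
        pts = [(0, 0), (3, 5)]
        base = effective_resistance(ConductanceRaster(grid), pts)
        scaled = effective_resistance(ConductanceRaster(3.0 * grid), pts)
        assert scaled.get("p0", "p1") == pytest.approx(base.get("p0", "p1") / 3.0)


class TestModelComparison:
    def test_aicc_closed_form(self):
        assert aicc(20, 3, 5.0) == pytest.approx(
            20 * np.log(5.0 / 20) + 6 + 24 / 16
        )
        assert aicc(4, 3, 5.0) == np.inf  # n - k - 1 <= 0

    def test_ibd_beats_null_on_linear_data(self):
        labels = [f"p{k}" for k in range(8)]
        n = len(labels)
        vals = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                vals[i, j] = abs(i - j) * 7.0
        dist = PairwiseMatrix(labels, vals)
        rng = np.random.default_rng(2)
        lin = 0.05 + 0.08 * np.log(dist.condensed()) + rng.normal(0, 0.003, n * (n - 1) // 2)
        fst = pairwise_from_condensed(labels, lin / (1 + lin))
        table = compare_models(
            [ibd_candidate(fst, dist), null_candidate(fst)]
        )
        assert table.loc[0, "model"] == "IBD"
        assert table.loc[0, "dAICc"] == 0.0
        assert not table.loc[1, "well_supported"]

    def test_compare_models_empty(self):
        with pytest.raises(ValueError, match="no candidate"):
            compare_models([])

    def test_zero_budget_flagged(self):
        classes = np.zeros((5, 5), dtype=int)
        classes[:, 2] = 1
        pts = [(2, 0), (2, 4), (0, 0), (4, 4)]
        labels = ["a", "b", "c", "d"]
        fst = pairwise_from_condensed(labels, np.full(6, 0.2))
        model = fit_categorical_surface(
            fst, classes, pts, labels, optimizer_budget=0
        )
        assert model.flagged
        assert "unoptimised" in model.note or "initial" in model.note
        np.testing.assert_allclose(model.params["resistances"][0], 1.0)
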