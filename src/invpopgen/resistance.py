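"""Circuit-theory landscape resistance.

The landscape is a grid of per-cell conductances; gene flow is modelled
as current through a 4-neighbour resistor network, so the difficulty of
movement between two waterbodies is the effective electrical resistance
between their cells.  Candidate resistance surfaces (categorical class
resistances or a monotone transform of a continuous layer) are fitted by
minimising the AICc of an ordinary least-squares regression of
linearised F_ST on effective resistance, and compared against
isolation-by-distance and intercept-only null models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import minimize
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import splu

from .core import PairwiseMatrix


@dataclass
class ConductanceRaster:
    """Rectangular grid of per-cell conductances.

    ``grid`` holds positive finite conductances; ``mask`` marks nodata
    cells (True = excluded).  ``origin`` is the projected (x, y) of the
    lower-left corner and ``cell_size`` the cell edge in metres.
    """

    grid: np.ndarray
    cell_size: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ValueError("raster grid must be 2-D")
        if self.mask is None:
            self.mask = np.zeros(self.grid.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise ValueError("mask shape mismatch")
        vals = self.grid[~self.mask]
        if vals.size and (~np.isfinite(vals) | (vals <= 0)).any():
            raise ValueError("conductances must be positive and finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell containing projected point (x, y); row 0 is
        the top row (ESRI grid convention)."""
        col = int((x - self.origin[0]) // self.cell_size)
        row_from_bottom = int((y - self.origin[1]) // self.cell_size)
        row = self.grid.shape[0] - 1 - row_from_bottom
        if not (0 <= row < self.grid.shape[0] and 0 <= col < self.grid.shape[1]):
            raise ValueError(f"point ({x}, {y}) outside raster extent")
        return row, col


def write_ascii_grid(raster: ConductanceRaster, path: str, nodata: float = -9999.0) -> None:
    """Write an ESRI ASCII grid (row 0 = northernmost row)."""
    nrows, ncols = raster.shape
    out = np.where(raster.mask, nodata, raster.grid)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {raster.origin[0]:g}\n")
        fh.write(f"yllcorner {raster.origin[1]:g}\n")
        fh.write(f"cellsize {raster.cell_size:g}\n")
        fh.write(f"NODATA_value {nodata:g}\n")
        for row in out:
            fh.write(" ".join(f"{v:g}" for v in row) + "\n")


def read_ascii_grid(path: str) -> ConductanceRaster:
    """Read an ESRI ASCII grid into a :class:`ConductanceRaster`."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    grid = np.asarray(rows)
    nodata = header.get("nodata_value", -9999.0)
    mask = grid == nodata
    grid = np.where(mask, 1.0, grid)
    return ConductanceRaster(
        grid,
        cell_size=header.get("cellsize", 30.0),
        origin=(header.get("xllcorner", 0.0), header.get("yllcorner", 0.0)),
        mask=mask,
    )


# ---------------------------------------------------------------------------
# rasterisation of line features


def buffer_and_rasterize(
    lines: Sequence[Sequence[tuple[float, float]]],
    extent: tuple[float, float, float, float],
    buffer_m: float = 60.0,
    cell_m: float = 30.0,
) -> np.ndarray:
    """Boolean mask of cells whose centre lies within ``buffer_m`` of any
    polyline.  ``extent`` is (xmin, ymin, xmax, ymax) in projected metres;
    returned array is row 0 = northernmost row.
    """
    import shapely

    xmin, ymin, xmax, ymax = extent
    ncols = max(int(np.ceil((xmax - xmin) / cell_m)), 1)
    nrows = max(int(np.ceil((ymax - ymin) / cell_m)), 1)
    out = np.zeros((nrows, ncols), dtype=bool)
    polylines = [ls for ls in lines if len(ls) >= 2]
    if not polylines:
        return out
    geom = shapely.MultiLineString([list(map(tuple, ls)) for ls in polylines])
    xs = xmin + (np.arange(ncols) + 0.5) * cell_m
    ys_top_down = ymax - (np.arange(nrows) + 0.5) * cell_m
    gx, gy = np.meshgrid(xs, ys_top_down)
    pts = shapely.points(gx.ravel(), gy.ravel())
    dist = shapely.distance(pts, geom)
    return (dist <= buffer_m).reshape(nrows, ncols)


# ---------------------------------------------------------------------------
# effective resistance


def _grid_laplacian(raster: ConductanceRaster) -> tuple[sparse.csc_matrix, np.ndarray]:
    """Laplacian over unmasked cells; returns (L, node_index_grid)."""
    nrows, ncols = raster.shape
    ok = ~raster.mask
    node = -np.ones((nrows, ncols), dtype=int)
    node[ok] = np.arange(ok.sum())
    n = ok.sum()
    rows_i, cols_j, conds = [], [], []
    for dr, dc in ((0, 1), (1, 0)):
        a_ok = ok[: nrows - dr, : ncols - dc] & ok[dr:, dc:]
        ca = raster.grid[: nrows - dr, : ncols - dc][a_ok]
        cb = raster.grid[dr:, dc:][a_ok]
        na = node[: nrows - dr, : ncols - dc][a_ok]
        nb = node[dr:, dc:][a_ok]
        c = (ca + cb) / 2.0
        rows_i.append(na)
        cols_j.append(nb)
        conds.append(c)
    i = np.concatenate(rows_i) if rows_i else np.array([], dtype=int)
    j = np.concatenate(cols_j) if cols_j else np.array([], dtype=int)
    c = np.concatenate(conds) if conds else np.array([])
    adj = sparse.coo_matrix((c, (i, j)), shape=(n, n))
    adj = adj + adj.T
    deg = np.asarray(adj.sum(axis=1)).ravel()
    lap = sparse.diags(deg) - adj
    return lap.tocsc(), node


def effective_resistance(
    raster: ConductanceRaster,
    points: Sequence[tuple[int, int]],
    labels: Sequence[str] | None = None,
) -> PairwiseMatrix:
    """Pairwise effective resistance between raster cells.

    ``points`` are (row, col) cells; each must be unmasked.  A pair in
    disconnected components gets the sentinel ``inf``.  Resistances are
    computed from sparse LU solves of the grounded Laplacian.
    """
    if labels is None:
        labels = [f"p{k}" for k in range(len(points))]
    lap, node = _grid_laplacian(raster)
    pt_nodes = []
    for (r, c) in points:
        if raster.mask[r, c]:
            raise ValueError(f"point at masked cell ({r}, {c})")
        pt_nodes.append(node[r, c])
    n_comp, comp = connected_components(lap != 0, directed=False)
    k = len(points)
    vals = np.zeros((k, k))
    for cid in range(n_comp):
        members = [a for a in range(k) if comp[pt_nodes[a]] == cid]
        if len(members) < 2:
            continue
        inside = np.flatnonzero(comp == cid)
        sub = lap[np.ix_(inside, inside)]
        local = {g: i for i, g in enumerate(inside)}
        ground = 0
        keep = np.arange(sub.shape[0]) != ground
        red = sub[np.ix_(keep, keep)].tocsc()
        lu = splu(red)
        cols = {}
        for a in members:
            li = local[pt_nodes[a]]
            if li == ground:
                cols[a] = np.zeros(sub.shape[0])
            else:
                e = np.zeros(red.shape[0])
                e[li - 1] = 1.0
                v = lu.solve(e)
                full = np.zeros(sub.shape[0])
                full[1:] = v
                cols[a] = full
        for ai in range(len(members)):
            for bi in range(ai + 1, len(members)):
                a, b = members[ai], members[bi]
                la, lb = local[pt_nodes[a]], local[pt_nodes[b]]
                r = cols[a][la] + cols[b][lb] - cols[a][lb] - cols[b][la]
                vals[a, b] = vals[b, a] = r
    for a in range(k):
        for b in range(a + 1, k):
            if comp[pt_nodes[a]] != comp[pt_nodes[b]]:
                vals[a, b] = vals[b, a] = np.inf
    return PairwiseMatrix(list(labels), vals)


# ---------------------------------------------------------------------------
# model fitting and AICc comparison


def aicc(n: int, k: int, rss: float) -> float:
    """AICc of a Gaussian OLS fit: n ln(RSS/n) + 2k + 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        return np.inf
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _ols_rss(y: np.ndarray, X: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid)


@dataclass
class SurfaceModel:
    """A fitted landscape-resistance hypothesis."""

    name: str
    params: dict
    aicc: float
    k: int
    rss: float
    n_pairs: int
    flagged: bool = False
    note: str = ""


def _categorical_conductance(
    classes: np.ndarray, resistances: np.ndarray
) -> np.ndarray:
    res = resistances[classes]
    return 1.0 / res


def fit_categorical_surface(
    fst: PairwiseMatrix,
    classes: np.ndarray,
    points: Sequence[tuple[int, int]],
    labels: Sequence[str],
    n_classes: int | None = None,
    optimizer_budget: int = 200,
    n_starts: int = 3,
    seed: int | None = None,
    cell_size: float = 30.0,
    name: str = "categorical",
) -> SurfaceModel:
    """Optimise per-class resistances of a categorical surface.

    The first class is the reference with resistance fixed at 1; the
    remaining classes get free log-scale resistances >= 1 optimised by
    multistart Nelder-Mead against the AICc of linearised-F_ST ~
    effective-resistance OLS.  ``optimizer_budget`` caps function
    evaluations per start; a zero budget returns the initial (uniform)
    parameters flagged as unoptimised.
    """
    rng = np.random.default_rng(seed)
    classes = np.asarray(classes, dtype=int)
    if n_classes is None:
        n_classes = int(classes.max()) + 1
    fst_sub = fst.reordered(list(labels))
    y = _linearized(fst_sub.condensed())
    n_free = n_classes - 1
    k = n_free + 3  # surface params + slope + intercept + sigma

    def objective(log_res: np.ndarray) -> float:
        res = np.ones(n_classes)
        res[1:] = 1.0 + np.exp(log_res)  # resistances >= 1
        raster = ConductanceRaster(
            _categorical_conductance(classes, res), cell_size=cell_size
        )
        r = effective_resistance(raster, points, labels=list(labels)).condensed()
        if not np.isfinite(r).all():
            return np.inf
        X = np.column_stack([np.ones_like(r), r])
        return aicc(len(y), k, _ols_rss(y, X))

    x0 = np.zeros(n_free)
    if optimizer_budget == 0:
        res = np.ones(n_classes)
        res[1:] = 2.0
        return SurfaceModel(
            name, {"resistances": res}, objective(x0), k, np.nan, len(y),
            flagged=True, note="optimizer budget 0: initial parameters returned",
        )
    best_x, best_f = None, np.inf
    starts = [x0] + [rng.normal(0, 2, size=n_free) for _ in range(n_starts - 1)]
    for s in starts:
        out = minimize(
            objective, s, method="Nelder-Mead",
            options={"maxfev": optimizer_budget, "xatol": 1e-2, "fatol": 1e-3},
        )
        if out.fun < best_f:
            best_f, best_x = out.fun, out.x
    res = np.ones(n_classes)
    res[1:] = 1.0 + np.exp(best_x)
    return SurfaceModel(name, {"resistances": res}, float(best_f), k, np.nan, len(y))


def _linearized(f: np.ndarray) -> np.ndarray:
    f = np.clip(f, None, 1 - 1e-9)
    return f / (1.0 - f)


def ibd_candidate(
    fst: PairwiseMatrix, dist_km: PairwiseMatrix, name: str = "IBD"
) -> SurfaceModel:
    """Isolation-by-distance candidate: linearised F_ST ~ ln(distance)."""
    d = fst.reordered(fst.labels)  # ensure consistent ordering
    dist = dist_km.reordered(fst.labels)
    y = _linearized(d.condensed())
    x = np.log(dist.condensed())
    X = np.column_stack([np.ones_like(x), x])
    k = 3
    rss = _ols_rss(y, X)
    return SurfaceModel(name, {}, aicc(len(y), k, rss), k, rss, len(y))


def null_candidate(fst: PairwiseMatrix, name: str = "null") -> SurfaceModel:
    """Intercept-only candidate."""
    y = _linearized(fst.condensed())
    X = np.ones((len(y), 1))
    k = 2
    rss = _ols_rss(y, X)
    return SurfaceModel(name, {}, aicc(len(y), k, rss), k, rss, len(y))


def compare_models(candidates: Sequence[SurfaceModel]) -> pd.DataFrame:
    """Rank candidates by AICc; ΔAICc <= 2 flags comparable support."""
    if not candidates:
        raise ValueError("no candidate models")
    rows = [
        {"model": c.name, "AICc": c.aicc, "k": c.k, "n_pairs": c.n_pairs}
        for c in candidates
    ]
    out = pd.DataFrame(rows).sort_values("AICc", kind="stable").reset_index(drop=True)
    out["dAICc"] = out["AICc"] - out["AICc"].iloc[0]
    out["well_supported"] = out["dAICc"] <= 2.0
    return out
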