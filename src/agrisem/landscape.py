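"""Neutral raster landscapes and the landscape metrics measured on them.

The raster pathway emulates a 30-m land-cover grid over the 1 km² square
around a survey site: a patch-growing process seeds cover patches and grows
them to target class proportions, hedgerows are drawn as one-cell-wide
strips, and three metrics are read back off the grid — class proportions,
mean agricultural field size in hectares (4-connected components, fields
under 1 ha discarded), and total forest edge length in metres (forest /
non-forest cell faces, map border excluded).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "CLASS_CODES",
    "AGRICULTURAL_CLASSES",
    "RasterLandscape",
    "generate_raster",
    "landscape_metrics",
]

CLASS_CODES = {
    "other": 0,
    "cropland": 1,
    "forage_grassland": 2,
    "forest": 3,
    "shrubland": 4,
    "hedgerow": 5,
}

#: Classes counted as agricultural fields for the mean-field-size metric.
AGRICULTURAL_CLASSES = ("cropland", "forage_grassland")

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


@dataclass(frozen=True)
class RasterLandscape:
    """A square categorical land-cover grid.

    Default geometry is a 1 km² landscape at 30 m resolution (33×33 cells).
    """

    grid: np.ndarray
    resolution: float = 30.0
    classes: dict = field(default_factory=lambda: dict(CLASS_CODES))

    def __post_init__(self) -> None:
        g = np.asarray(self.grid)
        if g.ndim != 2 or g.shape[0] != g.shape[1]:
            raise ValueError("grid must be a square 2-d array")
        object.__setattr__(self, "grid", g.astype(np.int64))

    @property
    def n_cells(self) -> int:
        return int(self.grid.size)

    @property
    def cell_area_m2(self) -> float:
        return self.resolution**2

    def mask(self, *class_names: str) -> np.ndarray:
        codes = [self.classes[c] for c in class_names]
        return np.isin(self.grid, codes)

    def save_text(self, path: str | Path) -> None:
        np.savetxt(path, self.grid, fmt="%d")

    @classmethod
    def load_text(cls, path: str | Path, resolution: float = 30.0) -> "RasterLandscape":
        return cls(np.loadtxt(path, dtype=np.int64), resolution=resolution)


def _grow_class(
    grid: np.ndarray,
    code: int,
    n_target: int,
    rng: np.random.Generator,
    mean_patch_cells: int = 90,
) -> None:
    """Grow ``n_target`` cells of one class onto unassigned (0) cells by
    seeding patches and expanding random 4-neighbour frontiers."""
    size = grid.shape[0]
    placed = 0
    while placed < n_target:
        free = np.flatnonzero(grid == 0)
        if free.size == 0:
            break
        seed = free[rng.integers(free.size)]
        frontier = [divmod(int(seed), size)]
        quota = min(n_target - placed, max(1, int(rng.poisson(mean_patch_cells))))
        grown = 0
        while frontier and grown < quota:
            idx = int(rng.integers(len(frontier)))
            r, c = frontier.pop(idx)
            if grid[r, c] != 0:
                continue
            grid[r, c] = code
            placed += 1
            grown += 1
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < size and 0 <= cc < size and grid[rr, cc] == 0:
                    frontier.append((rr, cc))


def _draw_hedgerows(grid: np.ndarray, n_target: int, rng: np.random.Generator) -> None:
    """Place one-cell-wide straight strips, preferring cells that border
    agricultural fields (hedgerows sit between fields)."""
    size = grid.shape[0]
    ag = np.isin(grid, [CLASS_CODES[c] for c in AGRICULTURAL_CLASSES])
    near_ag = ndimage.binary_dilation(ag, structure=_FOUR_CONN)
    placed = 0
    attempts = 0
    while placed < n_target and attempts < 200:
        attempts += 1
        r, c = rng.integers(size), rng.integers(size)
        dr, dc = (0, 1) if rng.random() < 0.5 else (1, 0)
        length = int(rng.integers(4, 13))
        for step in range(length):
            rr, cc = r + dr * step, c + dc * step
            if not (0 <= rr < size and 0 <= cc < size) or placed >= n_target:
                break
            convertible = grid[rr, cc] in (CLASS_CODES["other"],) or (
                ag[rr, cc] and near_ag[rr, cc]
            )
            if convertible and grid[rr, cc] != CLASS_CODES["hedgerow"]:
                grid[rr, cc] = CLASS_CODES["hedgerow"]
                placed += 1


def generate_raster(
    proportions: dict[str, float],
    size: int = 33,
    resolution: float = 30.0,
    seed: int = 0,
    mean_patch_cells: int = 90,
) -> RasterLandscape:
    """Grow a neutral landscape with the given target class proportions.

    ``proportions`` maps class names (any of cropland, forage_grassland,
    forest, shrubland, hedgerow) to target area fractions; the remainder is
    ``other``.  Patch growing fills exact cell quotas, so realised
    proportions differ from targets only by rounding to whole cells.
    Reproducible per seed.
    """
    unknown = set(proportions) - set(CLASS_CODES)
    if unknown:
        raise ValueError(f"unknown classes: {sorted(unknown)}")
    total = sum(proportions.values())
    if total > 1.0 + 1e-9:
        raise ValueError(f"target proportions sum to {total:.3f} > 1")
    if any(p < 0 for p in proportions.values()):
        raise ValueError("negative target proportion")
    rng = np.random.default_rng(seed)
    grid = np.zeros((size, size), dtype=np.int64)
    n_cells = size * size
    # grow large-structure classes first, hedgerow strips last
    for name in ("forest", "cropland", "forage_grassland", "shrubland"):
        target = proportions.get(name, 0.0)
        if target > 0:
            _grow_class(grid, CLASS_CODES[name], round(target * n_cells), rng, mean_patch_cells)
    hedge = proportions.get("hedgerow", 0.0)
    if hedge > 0:
        _draw_hedgerows(grid, round(hedge * n_cells), rng)
    return RasterLandscape(grid=grid, resolution=resolution)


def landscape_metrics(raster: RasterLandscape) -> dict[str, float]:
    """Measure the covariate record of one raster landscape.

    Returns per-class proportions (``proportion_<class>``), mean
    agricultural field size in hectares after removing fields smaller than
    1 ha (``mean_field_size_ha``; 0 when no field survives), and total
    forest edge length in metres (``forest_edge_m``).
    """
    grid = raster.grid
    n = raster.n_cells
    out: dict[str, float] = {}
    for name, code in raster.classes.items():
        out[f"proportion_{name}"] = float(np.sum(grid == code)) / n

    # mean field size: 4-connected agricultural components of >= 1 ha
    ag_mask = raster.mask(*AGRICULTURAL_CLASSES)
    labels, n_comp = ndimage.label(ag_mask, structure=_FOUR_CONN)
    cell_ha = raster.cell_area_m2 / 10_000.0
    if n_comp:
        sizes = np.bincount(labels.ravel())[1:]  # cells per component
        areas_ha = sizes * cell_ha
        fields = areas_ha[areas_ha >= 1.0]
        out["mean_field_size_ha"] = float(fields.mean()) if fields.size else 0.0
        out["n_fields"] = int(fields.size)
    else:
        out["mean_field_size_ha"] = 0.0
        out["n_fields"] = 0

    # forest edge: interior forest/non-forest faces only
    forest = raster.mask("forest")
    horiz = forest[:, :-1] != forest[:, 1:]
    vert = forest[:-1, :] != forest[1:, :]
    out["forest_edge_m"] = float((horiz.sum() + vert.sum()) * raster.resolution)
    return out
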