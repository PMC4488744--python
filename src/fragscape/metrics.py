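"""Class-level landscape pattern indices and the landscape contagion index.

Implemented indices (FRAGSTATS conventions):

* PD — patch density, patches per 100 ha (optionally per km^2);
* NLSI — normalized landscape shape index in [0, 1]: total class edge
  rescaled between the minimum for a maximally compact arrangement and the
  maximum for a fully dispersed one;
* COHESION — patch cohesion index in [0, 100], a perimeter-area measure of
  physical connectedness;
* MESH — effective mesh size in hectares, sum of squared patch areas over
  landscape area (the expected patch size seen by a random cell);
* CONTAG — contagion in (0, 100], an adjacency/aggregation index over all
  classes of a categorical map.

Perimeters count cell edges adjoining other classes or the map border
(border edges count, so a patch's perimeter is translation invariant).
Patch adjacency defaults to the 8-neighbor rule to match the structural
segmentation; contagion uses 4-neighbor rook adjacency with double counting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .landscape import BinaryLandscape

_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class PatchSet:
    """Labeled foreground patches with per-patch area and perimeter.

    Areas are in cells and perimeters in cell edges; conversion to physical
    units happens at the reporting boundary.
    """

    areas: np.ndarray  # cells per patch
    perimeters: np.ndarray  # cell edges per patch
    n_rows: int
    n_cols: int
    cell_size: float

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=np.int64)
        self.perimeters = np.asarray(self.perimeters, dtype=np.int64)

    @property
    def n(self) -> int:
        return self.areas.size

    @property
    def total_cells(self) -> int:
        """Z, the landscape cell count (class and non-class cells)."""
        return self.n_rows * self.n_cols

    @property
    def class_cells(self) -> int:
        return int(self.areas.sum())

    @property
    def cell_area_ha(self) -> float:
        return self.cell_size**2 / 10_000.0

    @property
    def landscape_area_ha(self) -> float:
        return self.total_cells * self.cell_area_ha


def delineate_patches(landscape: BinaryLandscape, connectivity: int = 8) -> PatchSet:
    """Label foreground patches and tally exact areas and perimeters."""
    struct = _STRUCT8 if connectivity == 8 else _STRUCT4
    lab, n = ndimage.label(landscape.grid, structure=struct)
    if n == 0:
        areas = np.zeros(0)
        perims = np.zeros(0)
    else:
        areas = np.bincount(lab.ravel())[1:]
        # per-cell count of 4-neighbors outside the patch (background or
        # border); distinct patches are never 4-adjacent, so "outside the
        # patch" equals "background or border"
        padded = np.pad(landscape.grid, 1, constant_values=False)
        exposure = np.zeros(landscape.grid.shape, dtype=np.int64)
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            exposure += ~padded[1 + dr : padded.shape[0] - 1 + dr, 1 + dc : padded.shape[1] - 1 + dc]
        perims = ndimage.sum_labels(exposure, labels=lab, index=np.arange(1, n + 1))
    return PatchSet(
        areas=areas,
        perimeters=perims,
        n_rows=landscape.n_rows,
        n_cols=landscape.n_cols,
        cell_size=landscape.cell_size,
    )


def patch_density(ps: PatchSet, per: str = "100ha") -> float:
    """Patches per 100 ha (default) or per km^2."""
    area_ha = ps.landscape_area_ha
    if area_ha <= 0:
        raise ValueError("landscape area must be positive")
    if per == "100ha":
        return ps.n / area_ha * 100.0
    if per == "km2":
        return ps.n / (area_ha / 100.0)
    raise ValueError("per must be '100ha' or 'km2'")


def min_class_edge(a: int) -> int:
    """Minimum total edge for ``a`` cells arranged maximally compactly.

    Integer-square construction: with n = floor(sqrt(a)), the minimum is 4n
    for a perfect square, 4n + 2 while a row of the (n+1)-rectangle is
    partially filled, else 4n + 4.  Equals 2 * ceil(2 * sqrt(a)).
    """
    if a <= 0:
        return 0
    n = int(np.floor(np.sqrt(a)))
    if a == n * n:
        return 4 * n
    if a <= n * (n + 1):
        return 4 * n + 2
    return 4 * n + 4


def max_class_edge(a: int, n_rows: int, n_cols: int) -> int:
    """Maximum total edge for ``a`` cells on an n_rows x n_cols grid with
    border edges counting toward the total.

    While the class can be fully dispersed (no two cells 4-adjacent, possible
    up to half the grid) every cell exposes 4 edges.  Beyond that the
    complement is dispersed instead: each background cell can free at most
    its 4 incident adjacencies from the full grid's internal adjacency count.
    """
    Z = n_rows * n_cols
    if a <= 0:
        return 0
    if 2 * a <= Z + (Z % 2):
        return 4 * a
    internal = n_rows * (n_cols - 1) + n_cols * (n_rows - 1)
    return 4 * a - 2 * max(0, internal - 4 * (Z - a))


def normalized_lsi(ps: PatchSet) -> float:
    """NLSI = (e - e_min) / (e_max - e_min), clamped to [0, 1].

    0 for a single maximally compact block, 1 for a fully dispersed
    (checkerboard-like) arrangement; defined as 0 when the class fills the
    landscape (e_max = e_min).
    """
    a = ps.class_cells
    if a == 0:
        raise ValueError("NLSI is undefined for an empty class")
    e = int(ps.perimeters.sum())
    e_min = min_class_edge(a)
    e_max = max_class_edge(a, ps.n_rows, ps.n_cols)
    if e_max == e_min:
        return 0.0
    return float(np.clip((e - e_min) / (e_max - e_min), 0.0, 1.0))


def cohesion(ps: PatchSet) -> float:
    """Patch cohesion index, percent.

    COHESION = [1 - sum(p_j) / sum(p_j * sqrt(a_j))] / [1 - 1/sqrt(Z)] * 100
    with p_j, a_j in cell units and Z the landscape cell count.  0 when every
    patch is a single cell, 100 when one patch fills the landscape.
    """
    if ps.total_cells <= 1:
        raise ValueError("COHESION needs a landscape with more than one cell")
    if ps.n == 0:
        raise ValueError("COHESION is undefined for an empty class")
    p = ps.perimeters.astype(float)
    a = ps.areas.astype(float)
    denom = float((p * np.sqrt(a)).sum())
    ratio = float(p.sum()) / denom
    correction = 1.0 - 1.0 / np.sqrt(ps.total_cells)
    return (1.0 - ratio) / correction * 100.0


def effective_mesh(ps: PatchSet) -> float:
    """Effective mesh size in hectares: sum of squared patch areas (ha^2)
    over the total landscape area (ha)."""
    if ps.landscape_area_ha <= 0:
        raise ValueError("landscape area must be positive")
    a_ha = ps.areas * ps.cell_area_ha
    return float((a_ha**2).sum() / ps.landscape_area_ha)


def contagion(grid: np.ndarray) -> float:
    """Contagion of a categorical grid, percent.

    CONTAG = [1 + sum_ik q_ik ln q_ik / (2 ln m)] * 100 with
    q_ik = P_i * g_ik / sum_k g_ik, where P_i is the proportional abundance
    of class i and g_ik counts rook adjacencies between classes i and k by
    the double-count method.  Requires at least two classes present.
    """
    grid = np.asarray(grid)
    classes, inverse = np.unique(grid, return_inverse=True)
    m = classes.size
    if m < 2:
        raise ValueError("contagion requires at least 2 classes present")
    coded = inverse.reshape(grid.shape)
    g = np.zeros((m, m), dtype=np.int64)
    pairs_h = coded[:, :-1].ravel() * m + coded[:, 1:].ravel()
    pairs_v = coded[:-1, :].ravel() * m + coded[1:, :].ravel()
    counts = np.bincount(np.concatenate([pairs_h, pairs_v]), minlength=m * m).reshape(m, m)
    g = counts + counts.T  # double count: each shared edge in both directions
    P = np.bincount(coded.ravel(), minlength=m) / coded.size
    row_sums = g.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        q = P[:, None] * g / row_sums
    q = np.where(row_sums > 0, q, 0.0)
    terms = np.zeros_like(q)
    positive = q > 0
    terms[positive] = q[positive] * np.log(q[positive])
    return float((1.0 + terms.sum() / (2.0 * np.log(m))) * 100.0)


def compute_indices(landscape: BinaryLandscape, connectivity: int = 8) -> dict[str, float]:
    """PD, NLSI, COHESION, MESH for the foreground class plus CONTAG of the
    binary map, as one report dictionary."""
    ps = delineate_patches(landscape, connectivity=connectivity)
    report = {
        "PD_per_100ha": patch_density(ps) if ps.n else 0.0,
        "NLSI": normalized_lsi(ps) if ps.n else float("nan"),
        "COHESION_pct": cohesion(ps) if ps.n else float("nan"),
        "MESH_ha": effective_mesh(ps),
    }
    try:
        report["CONTAG_pct"] = contagion(landscape.grid.astype(np.int8))
    except ValueError:
        report["CONTAG_pct"] = float("nan")
    return report
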