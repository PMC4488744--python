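"""Morphological spatial pattern analysis: pixel-level segmentation of a
binary landscape into seven mutually exclusive structural classes.

The classifier partitions every foreground cell into exactly one of

``core``
    farther than the edge width *D* (Euclidean, cell units) from background;
``islet``
    member of a foreground connected component containing no core;
``bridge``
    on a shortest geodesic path, through non-core foreground, joining two
    distinct core components (a corridor between cores);
``loop``
    on a re-entrant corridor that rejoins the same core component — made
    precise below;
``perforation``
    within *D* of core with its nearest background cell inside a hole
    (background enclosed by foreground): the inner boundary;
``edge``
    within *D* of core facing open background: the outer boundary;
``branch``
    any remaining foreground.

Decision order is core > islet > bridge > loop > perforation > edge >
branch; connectors are resolved before the boundary band so that corridors
shorter than 2*D* are still detected (``boundary_over_connector=True`` flips
this, absorbing short corridors into the boundary classes).

Loop rule
---------
A corridor that leaves a core component and re-enters the same component
necessarily encloses background that the core alone does not enclose (an
"extra hole").  A non-core foreground cell is classified loop iff deleting
that single cell reduces the count of extra holes.  This captures unit-width
re-entrant corridors exactly; see the methods note for what wider re-entrant
structures do.

Foreground connectivity R is 4 or 8; the background always uses the dual
rule (R=8 foreground with 4-connected background by default) to avoid
topological paradoxes in hole detection.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.csgraph import dijkstra

from .landscape import ALL_LABELS, MSPA_CLASSES, BinaryLandscape

_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_STRUCT8 = np.ones((3, 3), dtype=bool)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return _STRUCT4
    if connectivity == 8:
        return _STRUCT8
    raise ValueError("connectivity must be 4 or 8")


@dataclass(frozen=True)
class MSPAParams:
    """Segmentation parameters.

    ``edge_width`` is the buffer distance D in cell units (D = sqrt(a^2 + b^2)
    for axis offsets a, b); the study default D=4 corresponds to 120 m at
    30 m cells.  ``connectivity`` is the foreground rule R; the background
    connectivity is its dual.
    """

    edge_width: float = 4.0
    connectivity: int = 8

    def __post_init__(self) -> None:
        if not self.edge_width > 0:
            raise ValueError("edge_width must be > 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    @property
    def background_connectivity(self) -> int:
        return 4 if self.connectivity == 8 else 8


@dataclass
class MSPAClassMap:
    """Result of :func:`segment`: per-cell labels plus per-class tallies.

    ``labels`` holds small integer codes indexing
    :data:`~fragscape.landscape.ALL_LABELS` (0 = background).
    """

    labels: np.ndarray
    params: MSPAParams
    cell_size: float = 30.0

    @property
    def foreground_cells(self) -> int:
        return int((self.labels > 0).sum())

    def class_counts(self) -> dict[str, int]:
        counts = np.bincount(self.labels.ravel(), minlength=len(ALL_LABELS))
        return {label: int(counts[i]) for i, label in enumerate(ALL_LABELS)}

    def class_areas_ha(self) -> dict[str, float]:
        cell_ha = self.cell_size**2 / 10_000.0
        return {label: n * cell_ha for label, n in self.class_counts().items()}

    def label_mask(self, label: str) -> np.ndarray:
        return self.labels == ALL_LABELS.index(label)


def distance_to_background(landscape: BinaryLandscape) -> np.ndarray:
    """Per-cell Euclidean distance (cell units, center-to-center) to the
    nearest background cell; 0 on background, +inf when no background exists.
    """
    fg = landscape.grid
    if not (~fg).any():
        return np.where(fg, np.inf, 0.0)
    return ndimage.distance_transform_edt(fg)


def extract_core(landscape: BinaryLandscape, params: MSPAParams) -> np.ndarray:
    """Boolean core mask: foreground strictly farther than D from background."""
    return distance_to_background(landscape) > params.edge_width


def label_components(mask: np.ndarray, connectivity: int = 8) -> tuple[np.ndarray, int]:
    """Connected components of a boolean mask, labeled 1..k in the raster-scan
    order of each component's first cell (deterministic)."""
    labeled, n = ndimage.label(np.asarray(mask, dtype=bool), structure=_structure(connectivity))
    if n == 0:
        return labeled, 0
    # scipy already labels in raster-scan order of first occurrence, but that
    # is an implementation detail; relabel explicitly to guarantee it.
    flat = labeled.ravel()
    first = np.full(n + 1, flat.size, dtype=np.int64)
    nz = np.flatnonzero(flat)
    np.minimum.at(first, flat[nz], nz)
    order = np.argsort(first[1:], kind="stable")
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[1 + order] = np.arange(1, n + 1)
    return remap[labeled], n


def find_holes(landscape: BinaryLandscape, params: MSPAParams) -> tuple[np.ndarray, int]:
    """Label background components fully enclosed by foreground (holes).

    A hole is a background connected component, under the dual of the
    foreground connectivity, that does not touch the map border.
    """
    bg = ~landscape.grid
    labeled, n = label_components(bg, params.background_connectivity)
    if n == 0:
        return labeled, 0
    border = np.zeros_like(bg)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    border_ids = np.unique(labeled[border & bg])
    keep = np.setdiff1d(np.arange(1, n + 1), border_ids)
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[keep] = np.arange(1, keep.size + 1)
    return remap[labeled], keep.size


def _adjacent_mask(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Cells adjacent (given connectivity) to ``mask``, excluding the mask."""
    dilated = ndimage.binary_dilation(mask, structure=_structure(connectivity))
    return dilated & ~mask


def _noncore_graph(noncore: np.ndarray, connectivity: int):
    """CSR adjacency over non-core foreground cells plus a flat index map."""
    idx = -np.ones(noncore.shape, dtype=np.int64)
    cells = np.flatnonzero(noncore)
    idx.ravel()[cells] = np.arange(cells.size)
    shifts = [(0, 1), (1, 0)]
    if connectivity == 8:
        shifts += [(1, 1), (1, -1)]
    rows, cols = [], []
    R, C = noncore.shape
    for dr, dc in shifts:
        r0a, r1a = max(0, -dr), R - max(0, dr)
        c0a, c1a = max(0, -dc), C - max(0, dc)
        r0b, r1b = max(0, dr), R - max(0, -dr)
        c0b, c1b = max(0, dc), C - max(0, -dc)
        a = idx[r0a:r1a, c0a:c1a]
        b = idx[r0b:r1b, c0b:c1b]
        ok = (a >= 0) & (b >= 0)
        rows.append(a[ok])
        cols.append(b[ok])
    if rows:
        r = np.concatenate(rows)
        c = np.concatenate(cols)
    else:  # pragma: no cover - empty landscape
        r = c = np.array([], dtype=np.int64)
    n = cells.size
    graph = sparse.csr_matrix(
        (np.ones(r.size + c.size, dtype=np.int8), (np.concatenate([r, c]), np.concatenate([c, r]))),
        shape=(n, n),
    )
    return graph, idx


def _bridge_cells(
    fg: np.ndarray,
    core: np.ndarray,
    core_labels: np.ndarray,
    n_core: int,
    comp_labels: np.ndarray,
    connectivity: int,
) -> np.ndarray:
    """Cells on some shortest non-core-foreground geodesic joining two
    distinct core components (within the same foreground component)."""
    bridge = np.zeros_like(fg)
    if n_core < 2:
        return bridge
    noncore = fg & ~core
    if not noncore.any():
        return bridge
    graph, idx = _noncore_graph(noncore, connectivity)
    nc_cells = np.flatnonzero(noncore)
    # geodesic distance from each core component's contact set; d=1 on contacts
    dists = []
    for k in range(1, n_core + 1):
        contacts = _adjacent_mask(core_labels == k, connectivity) & noncore
        contact_idx = idx.ravel()[np.flatnonzero(contacts)]
        if contact_idx.size == 0:
            dists.append(np.full(nc_cells.size, np.inf))
            continue
        d = dijkstra(graph, directed=False, indices=contact_idx, min_only=True, unweighted=True)
        dists.append(d + 1.0)
    # core components grouped by their foreground component
    core_comp_of = np.zeros(n_core + 1, dtype=np.int64)
    for k in range(1, n_core + 1):
        core_comp_of[k] = comp_labels[core_labels == k][0]
    for a, b in itertools.combinations(range(1, n_core + 1), 2):
        if core_comp_of[a] != core_comp_of[b]:
            continue
        s = dists[a - 1] + dists[b - 1] - 1.0
        finite = np.isfinite(s)
        if not finite.any():
            continue
        L = s[finite].min()
        on_path = np.zeros(nc_cells.size, dtype=bool)
        on_path[finite] = s[finite] == L
        bridge.ravel()[nc_cells[on_path]] = True
    return bridge


def _count_extra_holes(
    fg: np.ndarray, inherited_region: np.ndarray, bg_connectivity: int
) -> int:
    """Number of foreground holes not already enclosed by the core mask.

    ``inherited_region`` marks the cells of non-border components of the core
    complement; a hole contained entirely inside it is enclosed by core alone.
    """
    bg = ~fg
    labeled, n = label_components(bg, bg_connectivity)
    if n == 0:
        return 0
    border = np.zeros_like(bg)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    border_ids = set(np.unique(labeled[border & bg]))
    extra = 0
    inside = ndimage.minimum(
        inherited_region.astype(np.int8), labels=labeled, index=np.arange(1, n + 1)
    )
    for k in range(1, n + 1):
        if k in border_ids:
            continue
        if not inside[k - 1]:
            extra += 1
    return extra


def _loop_cells(fg: np.ndarray, core: np.ndarray, params: MSPAParams) -> np.ndarray:
    loop = np.zeros_like(fg)
    if not core.any():
        return loop
    bgc = params.background_connectivity
    # cells of non-border components of the complement of core: holes lying
    # entirely inside are enclosed by core alone ("inherited")
    nc_lab, n_nc = label_components(~core, bgc)
    inherited_region = np.zeros_like(fg)
    if n_nc:
        border = np.zeros_like(fg)
        border[0, :] = border[-1, :] = True
        border[:, 0] = border[:, -1] = True
        border_ids = np.unique(nc_lab[border & ~core])
        non_border = np.setdiff1d(np.arange(1, n_nc + 1), border_ids)
        inherited_region = np.isin(nc_lab, non_border)
    base = _count_extra_holes(fg, inherited_region, bgc)
    if base == 0:
        return loop
    # only cells background-adjacent to an extra hole can reduce the count
    bg = ~fg
    hole_lab, n_holes = label_components(bg, bgc)
    border = np.zeros_like(bg)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    border_ids = set(np.unique(hole_lab[border & bg]))
    inside = ndimage.minimum(
        inherited_region.astype(np.int8), labels=hole_lab, index=np.arange(1, n_holes + 1)
    ) if n_holes else []
    extra_mask = np.zeros_like(bg)
    for k in range(1, n_holes + 1):
        if k in border_ids or inside[k - 1]:
            continue
        extra_mask |= hole_lab == k
    candidates = _adjacent_mask(extra_mask, bgc) & fg & ~core
    for cell in np.flatnonzero(candidates):
        trial = fg.copy()
        trial.ravel()[cell] = False
        if _count_extra_holes(trial, inherited_region, bgc) < base:
            loop.ravel()[cell] = True
    return loop


def segment(
    landscape: BinaryLandscape,
    params: MSPAParams | None = None,
    boundary_over_connector: bool = False,
) -> MSPAClassMap:
    """Classify every foreground cell into one of the seven structural classes.

    The seven classes partition the foreground exactly; background cells keep
    label 0.  See the module docstring for the decision order.
    """
    params = params or MSPAParams()
    fg = landscape.grid
    D = params.edge_width
    R = params.connectivity
    labels = np.zeros(fg.shape, dtype=np.uint8)
    if not fg.any():
        return MSPAClassMap(labels, params, landscape.cell_size)

    dist_bg = distance_to_background(landscape)
    core = fg & (dist_bg > D)

    comp_labels, _ = label_components(fg, R)
    core_comp_ids = np.unique(comp_labels[core]) if core.any() else np.array([], dtype=int)
    in_core_comp = np.isin(comp_labels, core_comp_ids)
    islet = fg & ~in_core_comp

    core_labels, n_core = label_components(core, R)
    bridge = _bridge_cells(fg, core, core_labels, n_core, comp_labels, R)
    loop = _loop_cells(fg, core, params)

    # boundary band: within D (Euclidean) of a core cell
    if core.any():
        dist_core = ndimage.distance_transform_edt(~core)
        near_core = fg & (dist_core <= D)
    else:
        near_core = np.zeros_like(fg)
    bg = ~fg
    hole_lab, n_holes = find_holes(landscape, params)
    hole_bg = hole_lab > 0
    open_bg = bg & ~hole_bg
    d_hole = (
        ndimage.distance_transform_edt(~hole_bg) if hole_bg.any() else np.full(fg.shape, np.inf)
    )
    d_open = (
        ndimage.distance_transform_edt(~open_bg) if open_bg.any() else np.full(fg.shape, np.inf)
    )
    # nearest background decides inner vs outer boundary; ties go to edge
    perforation_zone = near_core & (d_hole < d_open)
    edge_zone = near_core & ~(d_hole < d_open)

    order = [
        ("core", core),
        ("islet", islet),
        ("bridge", bridge),
        ("loop", loop),
        ("perforation", perforation_zone),
        ("edge", edge_zone),
    ]
    if boundary_over_connector:
        order = [order[0], order[1], order[4], order[5], order[2], order[3]]
    assigned = np.zeros_like(fg)
    for name, mask in order:
        take = fg & mask & ~assigned
        labels[take] = ALL_LABELS.index(name)
        assigned |= take
    labels[fg & ~assigned] = ALL_LABELS.index("branch")
    return MSPAClassMap(labels, params, landscape.cell_size)


def class_proportions(class_map: MSPAClassMap, per: str = "foreground") -> dict[str, float]:
    """Per-class fractions, over the 7 foreground classes (``per="foreground"``,
    summing to 1 over foreground) or over all 8 labels (``per="landscape"``)."""
    counts = class_map.class_counts()
    if per == "foreground":
        total = sum(counts[c] for c in MSPA_CLASSES)
        if total == 0:
            raise ValueError("no foreground cells; per='foreground' is undefined")
        return {c: counts[c] / total for c in MSPA_CLASSES}
    if per == "landscape":
        total = class_map.labels.size
        return {c: counts[c] / total for c in ALL_LABELS}
    raise ValueError("per must be 'foreground' or 'landscape'")
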