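"""Synthetic binary landscapes.

Two kinds of inputs stand in for classified satellite maps:

* :func:`generate_mrc` — a modified-random-clusters neutral landscape model
  with controllable foreground proportion F and aggregation (contagion).
  Plain Bernoulli percolation cannot reach the strongly aggregated regime
  real farmland maps show (contagion around 47-50 at F near 0.5-0.65, close
  to the two-class maximum of ~50), so marked cells are first clustered at
  probability ``cluster_p``, whole clusters are assigned to the foreground
  until the target proportion is reached, and the remaining cells are filled
  by neighborhood majority.
* :func:`generate_fixture` — deterministic geometric shapes (squares,
  donuts, dumbbells, ...) whose structural classes are analytically known;
  each fixture is returned together with a ground-truth label grid computed
  by a literal, loop-free-of-shortcuts classifier kept in this module.

:func:`apply_scenario` degrades a base landscape through loss-only edits
(edge erosion, hole punching, patch removal, corridor carving), emulating a
multi-date fragmentation sequence.  All randomness flows through one seeded
generator; identical parameters give bit-identical landscapes.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .landscape import ALL_LABELS, BinaryLandscape

#: Cluster-growth probability giving the most aggregated single-scale maps
#: (just below the 4-neighbor site-percolation threshold).
DEFAULT_CLUSTER_P = 0.55

#: Generator setting calibrated once so that contagion lands in the observed
#: 47-50 band at F near 0.5-0.65 (see docs/methods.md): clusters are grown on
#: a grid 8x coarser and block-upsampled, then smoothed by one majority pass.
CALIBRATED_AGGREGATION = {"cluster_p": 0.5, "scale": 8, "smooth": 1}


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the modified-random-clusters generator.

    ``scale`` grows clusters on an n/scale coarser grid and block-upsamples,
    producing features ``scale`` cells wide; ``smooth`` rounds cluster
    outlines with that many 3x3 majority-filter passes.  Both raise
    aggregation (contagion) beyond what ``cluster_p`` alone can reach.
    """

    n_rows: int
    n_cols: int
    target_f: float
    cluster_p: float = DEFAULT_CLUSTER_P
    seed: int = 0
    connectivity: int = 4
    scale: int = 1
    smooth: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be positive")
        if not 0.0 < self.target_f < 1.0:
            raise ValueError("target_f must be strictly between 0 and 1")
        if not 0.0 <= self.cluster_p < 1.0:
            raise ValueError("cluster_p must be in [0, 1)")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.scale < 1 or self.n_rows // self.scale < 1 or self.n_cols // self.scale < 1:
            raise ValueError("scale must be >= 1 and smaller than the grid")
        if self.smooth < 0:
            raise ValueError("smooth must be >= 0")


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    return np.ones((3, 3), dtype=bool)


def generate_mrc(params: GeneratorParams, cell_size: float = 30.0) -> BinaryLandscape:
    """Generate a clustered binary landscape with realized foreground
    proportion within ±0.02 of ``target_f`` (grids of a few thousand cells
    and up; a final boundary-flip adjustment pins it to ±0.005 + one cell).
    """
    Z = params.n_rows * params.n_cols
    k_target = params.target_f * Z
    if round(k_target) < 1 or round(k_target) > Z - 1:
        min_cells = int(np.ceil(1.0 / min(params.target_f, 1.0 - params.target_f)))
        raise ValueError(
            f"target_f={params.target_f} is unreachable on a {params.n_rows}x"
            f"{params.n_cols} grid; at least {min_cells} cells are required"
        )
    rng = np.random.default_rng(params.seed)
    shape = (params.n_rows // params.scale, params.n_cols // params.scale)
    k_coarse = params.target_f * shape[0] * shape[1]

    marked = rng.random(shape) < params.cluster_p
    lab, n_clusters = ndimage.label(marked, structure=_structure(params.connectivity))

    state = np.full(shape, -1, dtype=np.int8)  # -1 unassigned, 0 bg, 1 fg
    fg_count = 0
    if n_clusters:
        sizes = np.bincount(lab.ravel())
        order = rng.permutation(n_clusters) + 1
        cluster_fg = np.zeros(n_clusters + 1, dtype=bool)
        for cid in order:
            size = int(sizes[cid])
            if fg_count >= k_coarse:
                break
            # take the cluster only if it moves the count closer to target
            if abs(fg_count + size - k_coarse) <= abs(fg_count - k_coarse):
                cluster_fg[cid] = True
                fg_count += size
        state[marked] = cluster_fg[lab[marked]].astype(np.int8)

    unassigned = state == -1
    if unassigned.any():
        kernel = np.ones((3, 3))
        kernel[1, 1] = 0
        fg_n = ndimage.convolve((state == 1).astype(float), kernel, mode="constant")
        bg_n = ndimage.convolve((state == 0).astype(float), kernel, mode="constant")
        take_fg = unassigned & (fg_n > bg_n)
        take_bg = unassigned & (bg_n > fg_n)
        state[take_fg] = 1
        state[take_bg] = 0
        tied = state == -1
        state[tied] = (rng.random(shape) < params.target_f)[tied].astype(np.int8)

    fg = state == 1
    if params.scale > 1:
        fg = np.kron(fg, np.ones((params.scale, params.scale), dtype=bool))
        # pad out non-divisible extents by reflecting the last rows/columns
        pad_r = params.n_rows - fg.shape[0]
        pad_c = params.n_cols - fg.shape[1]
        if pad_r or pad_c:
            fg = np.pad(fg, ((0, pad_r), (0, pad_c)), mode="reflect")
    if params.smooth:
        kernel = np.ones((3, 3))
        for _ in range(params.smooth):
            fg = ndimage.convolve(fg.astype(float), kernel, mode="constant") >= 5
    fg = _adjust_proportion(fg, k_target, rng)
    return BinaryLandscape(fg, cell_size=cell_size)


def _adjust_proportion(fg: np.ndarray, k_target: float, rng: np.random.Generator) -> np.ndarray:
    """Flip random class-boundary cells until the count is within tolerance.

    Boundary flips preserve the clustered structure far better than flipping
    interior cells at random.
    """
    Z = fg.size
    tol = max(1, int(0.005 * Z))
    struct = _structure(4)
    for _ in range(64):
        diff = int(fg.sum()) - int(round(k_target))
        if abs(diff) <= tol:
            break
        if diff > 0:
            candidates = np.flatnonzero(fg & _boundary(fg, struct))
            if candidates.size == 0:
                candidates = np.flatnonzero(fg)
            drop = rng.choice(candidates, size=min(diff, candidates.size), replace=False)
            fg.ravel()[drop] = False
        else:
            candidates = np.flatnonzero(~fg & _boundary(~fg, struct))
            if candidates.size == 0:
                candidates = np.flatnonzero(~fg)
            add = rng.choice(candidates, size=min(-diff, candidates.size), replace=False)
            fg.ravel()[add] = True
    return fg


def _boundary(mask: np.ndarray, struct: np.ndarray) -> np.ndarray:
    """Cells of ``mask`` 4-adjacent to its complement (or the map border)."""
    eroded = ndimage.binary_erosion(mask, structure=struct, border_value=0)
    return mask & ~eroded


# ---------------------------------------------------------------------------
# geometric fixtures


def generate_fixture(
    name: str,
    size: int | None = None,
    edge_width: float = 4.0,
    connectivity: int = 8,
    cell_size: float = 30.0,
    **geometry,
) -> tuple[BinaryLandscape, np.ndarray]:
    """Build a named geometric fixture and its ground-truth label grid.

    Returns ``(landscape, expected)`` where ``expected`` holds integer codes
    indexing :data:`~fragscape.landscape.ALL_LABELS`, computed by the
    literal-definition classifier in this module.
    """
    builders = {
        "solid_square": _fixture_solid_square,
        "donut": _fixture_donut,
        "dumbbell": _fixture_dumbbell,
        "ring": _fixture_ring,
        "scatter": _fixture_scatter,
        "two_cores_with_branch": _fixture_two_cores_with_branch,
    }
    if name not in builders:
        raise ValueError(f"unknown fixture {name!r}; choose from {sorted(builders)}")
    grid = builders[name](size, edge_width, **geometry)
    expected_names = literal_classify(grid, edge_width=edge_width, connectivity=connectivity)
    lut = {label: i for i, label in enumerate(ALL_LABELS)}
    expected = np.vectorize(lut.__getitem__, otypes=[np.uint8])(expected_names)
    return BinaryLandscape(grid, cell_size=cell_size), expected


def _margin(edge_width: float) -> int:
    return int(np.ceil(edge_width)) + 2


def _fixture_solid_square(size, edge_width, **_):
    size = 11 if size is None else size
    minimum = 2 * int(np.floor(edge_width)) + 1
    if size < minimum:
        raise ValueError(f"solid_square needs size >= {minimum} for a core at D={edge_width}")
    m = _margin(edge_width)
    grid = np.zeros((size + 2 * m, size + 2 * m), dtype=bool)
    grid[m : m + size, m : m + size] = True
    return grid


def _fixture_donut(size, edge_width, hole: int | None = None, **_):
    size = 25 if size is None else size
    hole = max(3, size // 5) if hole is None else hole
    thickness = (size - hole) // 2
    minimum_t = 2 * int(np.floor(edge_width)) + 1
    if thickness < minimum_t:
        raise ValueError(
            f"donut ring thickness {thickness} too thin; needs >= {minimum_t} at D={edge_width}"
        )
    m = _margin(edge_width)
    grid = np.zeros((size + 2 * m, size + 2 * m), dtype=bool)
    grid[m : m + size, m : m + size] = True
    h0 = m + (size - hole) // 2
    grid[h0 : h0 + hole, h0 : h0 + hole] = False
    return grid


def _fixture_dumbbell(size, edge_width, corridor: int | None = None, **_):
    size = 13 if size is None else size
    minimum = 2 * int(np.floor(edge_width)) + 1
    if size < minimum:
        raise ValueError(f"dumbbell needs square size >= {minimum} at D={edge_width}")
    corridor = int(2 * edge_width) + 3 if corridor is None else corridor
    m = _margin(edge_width)
    rows = size + 2 * m
    cols = 2 * size + corridor + 2 * m
    grid = np.zeros((rows, cols), dtype=bool)
    grid[m : m + size, m : m + size] = True
    grid[m : m + size, m + size + corridor : m + 2 * size + corridor] = True
    mid = m + size // 2
    grid[mid, m + size : m + size + corridor] = True
    return grid


def _fixture_ring(size, edge_width, span: int | None = None, height: int | None = None, **_):
    # a solid square with a one-cell-wide handle arching over its top edge:
    # the handle re-joins the same core and encloses background (a loop)
    size = 13 if size is None else size
    minimum = 2 * int(np.floor(edge_width)) + 1
    if size < minimum:
        raise ValueError(f"ring needs square size >= {minimum} at D={edge_width}")
    span = max(4, size // 2) if span is None else span
    height = 3 if height is None else height
    m = _margin(edge_width) + height + 1
    grid = np.zeros((size + 2 * m, size + 2 * m), dtype=bool)
    top = m
    grid[top : top + size, m : m + size] = True
    c0 = m + (size - span) // 2
    c1 = c0 + span - 1
    for h in range(1, height + 1):
        grid[top - h, c0] = True
        grid[top - h, c1] = True
    grid[top - height, c0 : c1 + 1] = True
    return grid


def _fixture_scatter(size, edge_width, spacing: int = 3, **_):
    size = 5 if size is None else size  # size x size isolated single cells
    if size < 1:
        raise ValueError("scatter needs size >= 1")
    m = _margin(edge_width)
    extent = (size - 1) * spacing + 1 + 2 * m
    grid = np.zeros((extent, extent), dtype=bool)
    for i in range(size):
        for j in range(size):
            grid[m + i * spacing, m + j * spacing] = True
    return grid


def _fixture_two_cores_with_branch(size, edge_width, stub: int = 3, **_):
    grid = _fixture_dumbbell(size, edge_width)
    size = 13 if size is None else size
    m = _margin(edge_width)
    mid_col = m + size // 2
    for h in range(1, stub + 1):  # stub attached to the left square's top
        grid[m - h, mid_col] = True
    return grid


# ---------------------------------------------------------------------------
# literal classifier (ground truth for fixtures)

_N4 = ((-1, 0), (1, 0), (0, -1), (0, 1))
_N8 = _N4 + ((-1, -1), (-1, 1), (1, -1), (1, 1))


def literal_classify(fg: np.ndarray, edge_width: float = 4.0, connectivity: int = 8) -> np.ndarray:
    """Classify by enumerating the class definitions directly.

    Quadratic-time reference used only for fixture ground truth; the
    production path is :func:`fragscape.mspa.segment`.
    """
    fg = np.asarray(fg, dtype=bool)
    R, C = fg.shape
    D2 = float(edge_width) ** 2
    neigh = _N8 if connectivity == 8 else _N4
    bgc_neigh = _N4 if connectivity == 8 else _N8
    out = np.full((R, C), "background", dtype=object)
    if not fg.any():
        return out

    d2_bg = _min_sq_dist(fg, ~fg)
    core = fg & (d2_bg > D2)
    comp = _flood(fg, neigh)
    core_ids = np.unique(comp[core])
    islet = fg & ~np.isin(comp, core_ids)
    core_lab = _flood(core, neigh)
    n_core = core_lab.max()
    noncore = fg & ~core

    bridge = np.zeros_like(fg)
    if n_core >= 2:
        dists = [_geodesic(core_lab == k, noncore, neigh) for k in range(1, n_core + 1)]
        rep = [tuple(np.argwhere(core_lab == k)[0]) for k in range(1, n_core + 1)]
        for a in range(n_core):
            for b in range(a + 1, n_core):
                if comp[rep[a]] != comp[rep[b]]:
                    continue
                s = dists[a] + dists[b] - 1.0
                finite = np.isfinite(s)
                if finite.any():
                    bridge |= finite & (s == s[finite].min())

    loop = _loop_by_deletion(fg, core, bgc_neigh)

    hole_mask = _hole_mask(~fg, bgc_neigh)
    open_bg = ~fg & ~hole_mask
    d2_core = _min_sq_dist(fg, core)
    d2_hole = _min_sq_dist(fg, hole_mask)
    d2_open = _min_sq_dist(fg, open_bg)

    for r, c in np.argwhere(fg):
        if core[r, c]:
            out[r, c] = "core"
        elif islet[r, c]:
            out[r, c] = "islet"
        elif bridge[r, c]:
            out[r, c] = "bridge"
        elif loop[r, c]:
            out[r, c] = "loop"
        elif core.any() and d2_core[r, c] <= D2:
            out[r, c] = "perforation" if d2_hole[r, c] < d2_open[r, c] else "edge"
        else:
            out[r, c] = "branch"
    return out


def _min_sq_dist(domain: np.ndarray, targets: np.ndarray) -> np.ndarray:
    out = np.full(domain.shape, np.inf)
    pts = np.argwhere(targets)
    if pts.size == 0:
        return out
    for r, c in np.argwhere(domain):
        out[r, c] = ((pts[:, 0] - r) ** 2 + (pts[:, 1] - c) ** 2).min()
    return out


def _flood(mask: np.ndarray, neigh) -> np.ndarray:
    R, C = mask.shape
    lab = np.zeros((R, C), dtype=int)
    k = 0
    for r in range(R):
        for c in range(C):
            if mask[r, c] and not lab[r, c]:
                k += 1
                stack = [(r, c)]
                lab[r, c] = k
                while stack:
                    rr, cc = stack.pop()
                    for dr, dc in neigh:
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < R and 0 <= nc < C and mask[nr, nc] and not lab[nr, nc]:
                            lab[nr, nc] = k
                            stack.append((nr, nc))
    return lab


def _geodesic(core_mask: np.ndarray, domain: np.ndarray, neigh) -> np.ndarray:
    R, C = core_mask.shape
    dist = np.full((R, C), np.inf)
    q: deque = deque()
    for r, c in np.argwhere(domain):
        if any(
            0 <= r + dr < R and 0 <= c + dc < C and core_mask[r + dr, c + dc]
            for dr, dc in neigh
        ):
            dist[r, c] = 1.0
            q.append((r, c))
    while q:
        r, c = q.popleft()
        for dr, dc in neigh:
            nr, nc = r + dr, c + dc
            if 0 <= nr < R and 0 <= nc < C and domain[nr, nc] and np.isinf(dist[nr, nc]):
                dist[nr, nc] = dist[r, c] + 1.0
                q.append((nr, nc))
    return dist


def _hole_mask(bg: np.ndarray, neigh) -> np.ndarray:
    lab = _flood(bg, neigh)
    border = set(lab[0, :]) | set(lab[-1, :]) | set(lab[:, 0]) | set(lab[:, -1])
    holes = [k for k in range(1, lab.max() + 1) if k not in border]
    return np.isin(lab, holes) if holes else np.zeros_like(bg)


def _loop_by_deletion(fg: np.ndarray, core: np.ndarray, bgc_neigh) -> np.ndarray:
    loop = np.zeros_like(fg)
    if not core.any():
        return loop
    nc_lab = _flood(~core, bgc_neigh)
    border = set(nc_lab[0, :]) | set(nc_lab[-1, :]) | set(nc_lab[:, 0]) | set(nc_lab[:, -1])
    inherited = np.isin(
        nc_lab, [k for k in range(1, nc_lab.max() + 1) if k not in border]
    )

    def extra_count(mask):
        lab = _flood(~mask, bgc_neigh)
        bset = set(lab[0, :]) | set(lab[-1, :]) | set(lab[:, 0]) | set(lab[:, -1])
        n = 0
        for k in range(1, lab.max() + 1):
            if k not in bset and not inherited[lab == k].all():
                n += 1
        return n

    base = extra_count(fg)
    if base == 0:
        return loop
    lab = _flood(~fg, bgc_neigh)
    bset = set(lab[0, :]) | set(lab[-1, :]) | set(lab[:, 0]) | set(lab[:, -1])
    extra_mask = np.zeros_like(fg)
    for k in range(1, lab.max() + 1):
        if k not in bset and not inherited[lab == k].all():
            extra_mask |= lab == k
    R, C = fg.shape
    for r, c in np.argwhere(fg & ~core):
        if not any(
            0 <= r + dr < R and 0 <= c + dc < C and extra_mask[r + dr, c + dc]
            for dr, dc in bgc_neigh
        ):
            continue
        trial = fg.copy()
        trial[r, c] = False
        if extra_count(trial) < base:
            loop[r, c] = True
    return loop


# ---------------------------------------------------------------------------
# change scenarios


@dataclass(frozen=True)
class EditStep:
    """One loss edit: kind in {erode_from_edge, punch_holes,
    remove_random_patches, carve_corridors} with a rate in [0, 1]."""

    kind: str
    rate: float
    max_patch_cells: int | None = None  # remove_random_patches size cap

    def __post_init__(self) -> None:
        kinds = {"erode_from_edge", "punch_holes", "remove_random_patches", "carve_corridors"}
        if self.kind not in kinds:
            raise ValueError(f"unknown edit kind {self.kind!r}; choose from {sorted(kinds)}")
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError(f"rate must be in [0, 1], got {self.rate}")


@dataclass
class ChangeScenario:
    """A base landscape plus an ordered list of loss edits."""

    base: BinaryLandscape
    steps: list[EditStep] = field(default_factory=list)
    seed: int = 0


def apply_scenario(scenario: ChangeScenario) -> list[BinaryLandscape]:
    """Apply the edits in order; returns ``[base, after step 1, ...]``.

    All edits only remove foreground, so total foreground is monotone
    non-increasing along the sequence.
    """
    rng = np.random.default_rng(scenario.seed)
    out = [scenario.base.copy()]
    current = scenario.base.grid.copy()
    for step in scenario.steps:
        current = _apply_edit(current, step, rng)
        out.append(BinaryLandscape(current.copy(), scenario.base.cell_size))
    return out


def _apply_edit(fg: np.ndarray, step: EditStep, rng: np.random.Generator) -> np.ndarray:
    fg = fg.copy()
    if step.rate == 0.0 or not fg.any():
        return fg
    if step.kind == "erode_from_edge":
        boundary = _boundary(fg, _structure(4))
        remove = boundary & (rng.random(fg.shape) < step.rate)
        fg[remove] = False
    elif step.kind == "punch_holes":
        n_fg = int(fg.sum())
        n_holes = max(1, int(round(step.rate * n_fg / 50.0)))
        cells = np.flatnonzero(fg)
        centers = rng.choice(cells, size=min(n_holes, cells.size), replace=False)
        rr, cc = np.unravel_index(centers, fg.shape)
        yy, xx = np.mgrid[0 : fg.shape[0], 0 : fg.shape[1]]
        for r, c in zip(rr, cc):
            radius = rng.integers(1, 4)
            fg[(yy - r) ** 2 + (xx - c) ** 2 <= radius**2] = False
    elif step.kind == "remove_random_patches":
        lab, n = ndimage.label(fg, structure=_structure(8))
        if n:
            sizes = np.bincount(lab.ravel())
            cap = step.max_patch_cells or max(1, int(0.01 * fg.size))
            removable = np.flatnonzero((sizes <= cap) & (np.arange(sizes.size) > 0))
            chosen = removable[rng.random(removable.size) < step.rate]
            fg[np.isin(lab, chosen)] = False
    elif step.kind == "carve_corridors":
        n_lines = max(1, int(round(step.rate * np.sqrt(fg.size) / 4.0)))
        for _ in range(n_lines):
            if rng.random() < 0.5:
                r = int(rng.integers(0, fg.shape[0]))
                c0 = int(rng.integers(0, fg.shape[1]))
                length = int(rng.integers(fg.shape[1] // 4, fg.shape[1]))
                fg[r, c0 : c0 + length] = False
            else:
                c = int(rng.integers(0, fg.shape[1]))
                r0 = int(rng.integers(0, fg.shape[0]))
                length = int(rng.integers(fg.shape[0] // 4, fg.shape[0]))
                fg[r0 : r0 + length, c] = False
    return fg


def degrade_to_target(
    landscape: BinaryLandscape,
    target_f: float,
    rng: np.random.Generator,
    patch_rate: float = 0.05,
) -> BinaryLandscape:
    """Degrade a landscape with hole punching, small-patch removal and edge
    erosion until the foreground proportion reaches ``target_f`` (within half
    a percentage point plus one cell).  Deterministic given the generator
    state.

    Each pass budgets its removals against the remaining deficit so the
    target is approached without large overshoot; a final boundary-flip
    adjustment pins the proportion.
    """
    fg = landscape.grid.copy()
    Z = fg.size
    k_target = target_f * Z
    if landscape.foreground_fraction <= target_f:
        return landscape.copy()
    for _ in range(256):
        deficit = int(fg.sum()) - k_target
        if deficit <= 0.01 * Z:
            break
        # punch holes worth at most a third of the deficit (mean hole ~13 cells)
        budget = min(deficit / 3.0, 0.003 * Z)
        n_holes = max(1, int(budget / 13.0))
        cells = np.flatnonzero(fg)
        centers = rng.choice(cells, size=min(n_holes, cells.size), replace=False)
        rr, cc = np.unravel_index(centers, fg.shape)
        yy, xx = np.mgrid[0 : fg.shape[0], 0 : fg.shape[1]]
        for r, c in zip(rr, cc):
            radius = rng.integers(1, 4)
            fg[(yy - r) ** 2 + (xx - c) ** 2 <= radius**2] = False
        fg = _apply_edit(fg, EditStep("remove_random_patches", patch_rate, max_patch_cells=64), rng)
        deficit = int(fg.sum()) - k_target
        boundary_cells = int(_boundary(fg, _structure(4)).sum())
        if deficit > 0 and boundary_cells:
            erosion_rate = min(0.3, max(0.01, 0.5 * deficit / boundary_cells))
            fg = _apply_edit(fg, EditStep("erode_from_edge", erosion_rate), rng)
    fg = _adjust_proportion(fg, k_target, rng)
    return BinaryLandscape(fg, landscape.cell_size)
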