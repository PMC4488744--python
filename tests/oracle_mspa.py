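"""Independent brute-force structural classifier used as a test oracle.

This enumerates the class definitions literally, with its own flood fill,
pairwise distances and breadth-first searches — it shares no code with
``fragscape.mspa`` and is deliberately slow and simple.

Decision order (mutually exclusive): core > islet > bridge > loop >
perforation > edge > branch.

* core: foreground with squared Euclidean distance to every background cell
  > D^2 (exhaustive pairwise minimum).
* islet: foreground component (connectivity R, flood fill) without core.
* bridge: cell on a shortest path through non-core foreground joining two
  distinct core components (BFS from each component's contact cells;
  a cell is on a shortest A-B path iff dA + dB - 1 equals the minimum).
* loop: non-core foreground cell whose deletion reduces the number of
  "extra holes" — foreground-enclosed background components that are not
  already enclosed by the core mask alone.  Only cells background-adjacent
  to an extra hole are tested: deleting a foreground cell turns it into
  background and can only merge the complement components it is
  background-adjacent to, so the extra-hole count can only drop through
  such a cell (it cannot rise: removing foreground never encloses new
  background).
* perforation / edge: remaining cells within D of core; perforation iff the
  strictly nearest background cell lies in a hole (ties resolve to edge).
* branch: whatever is left.

The background uses the dual connectivity of R throughout.
"""

from collections import deque

import numpy as np

LABELS = ("background", "core", "islet", "bridge", "loop", "perforation", "edge", "branch")

_N4 = ((-1, 0), (1, 0), (0, -1), (0, 1))
_N8 = _N4 + ((-1, -1), (-1, 1), (1, -1), (1, 1))


def _neigh(connectivity):
    return _N8 if connectivity == 8 else _N4


def flood_fill_label(mask, connectivity):
    """Label components 1..k in raster-scan order with an explicit stack."""
    R, C = mask.shape
    labels = np.zeros((R, C), dtype=int)
    k = 0
    for r in range(R):
        for c in range(C):
            if mask[r, c] and labels[r, c] == 0:
                k += 1
                stack = [(r, c)]
                labels[r, c] = k
                while stack:
                    rr, cc = stack.pop()
                    for dr, dc in _neigh(connectivity):
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < R and 0 <= nc < C and mask[nr, nc] and labels[nr, nc] == 0:
                            labels[nr, nc] = k
                            stack.append((nr, nc))
    return labels, k


def _sq_dist_to_set(cells_rc, target_mask):
    """Exhaustive min squared distance from each (r, c) to any True cell."""
    targets = np.argwhere(target_mask)
    if targets.size == 0:
        return np.full(len(cells_rc), np.inf)
    cells = np.asarray(cells_rc)
    d2 = (
        (cells[:, None, 0] - targets[None, :, 0]) ** 2
        + (cells[:, None, 1] - targets[None, :, 1]) ** 2
    )
    return d2.min(axis=1)


def _holes(bg_mask, bg_connectivity):
    """(labels, ids of components not touching the border)."""
    lab, n = flood_fill_label(bg_mask, bg_connectivity)
    border_ids = set(lab[0, :]) | set(lab[-1, :]) | set(lab[:, 0]) | set(lab[:, -1])
    return lab, [k for k in range(1, n + 1) if k not in border_ids]


def _count_extra_holes(fg, inherited_region, bg_connectivity):
    lab, hole_ids = _holes(~fg, bg_connectivity)
    extra = 0
    for k in hole_ids:
        if not inherited_region[lab == k].all():
            extra += 1
    return extra


def classify(fg, edge_width=4.0, connectivity=8):
    """Return a grid of label names for a boolean foreground mask."""
    fg = np.asarray(fg, dtype=bool)
    R, C = fg.shape
    D2 = float(edge_width) ** 2
    bgc = 4 if connectivity == 8 else 8
    out = np.full((R, C), "background", dtype=object)
    if not fg.any():
        return out

    fg_cells = [tuple(rc) for rc in np.argwhere(fg)]
    d2_bg = dict(zip(fg_cells, _sq_dist_to_set(fg_cells, ~fg)))
    core = np.zeros_like(fg)
    for (r, c), d2 in d2_bg.items():
        core[r, c] = d2 > D2

    comp, _ = flood_fill_label(fg, connectivity)
    core_comps = set(comp[core])
    islet = fg & ~np.isin(comp, list(core_comps) or [0])

    core_lab, n_core = flood_fill_label(core, connectivity)
    noncore = fg & ~core

    bridge = np.zeros_like(fg)
    if n_core >= 2:
        dists = []
        for k in range(1, n_core + 1):
            d = _bfs_from_contacts(core_lab == k, noncore, connectivity)
            dists.append(d)
        for a in range(n_core):
            for b in range(a + 1, n_core):
                ka, kb = np.argwhere(core_lab == a + 1)[0], np.argwhere(core_lab == b + 1)[0]
                if comp[tuple(ka)] != comp[tuple(kb)]:
                    continue
                s = dists[a] + dists[b] - 1.0
                finite = np.isfinite(s)
                if finite.any():
                    L = s[finite].min()
                    bridge |= np.isfinite(s) & (s == L)

    loop = np.zeros_like(fg)
    nc_lab, n_nc = flood_fill_label(~core, bgc)
    border_nc = set(nc_lab[0, :]) | set(nc_lab[-1, :]) | set(nc_lab[:, 0]) | set(nc_lab[:, -1])
    inherited_region = np.isin(
        nc_lab, [k for k in range(1, n_nc + 1) if k not in border_nc]
    )
    base_extra = _count_extra_holes(fg, inherited_region, bgc)
    if base_extra:
        hole_lab, hole_ids = _holes(~fg, bgc)
        extra_mask = np.zeros_like(fg)
        for k in hole_ids:
            if not inherited_region[hole_lab == k].all():
                extra_mask |= hole_lab == k
        for r, c in fg_cells:
            if core[r, c]:
                continue
            adjacent = any(
                0 <= r + dr < R and 0 <= c + dc < C and extra_mask[r + dr, c + dc]
                for dr, dc in _neigh(bgc)
            )
            if not adjacent:
                continue
            trial = fg.copy()
            trial[r, c] = False
            if _count_extra_holes(trial, inherited_region, bgc) < base_extra:
                loop[r, c] = True

    # boundary: within D of core, split by the strictly nearest background
    hole_lab, hole_ids = _holes(~fg, bgc)
    hole_bg = np.isin(hole_lab, hole_ids) if hole_ids else np.zeros_like(fg)
    open_bg = ~fg & ~hole_bg
    d2_core = dict(zip(fg_cells, _sq_dist_to_set(fg_cells, core)))
    d2_hole = dict(zip(fg_cells, _sq_dist_to_set(fg_cells, hole_bg)))
    d2_open = dict(zip(fg_cells, _sq_dist_to_set(fg_cells, open_bg)))

    for r, c in fg_cells:
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


def _bfs_from_contacts(core_mask, noncore, connectivity):
    """Geodesic distance through non-core foreground from a core component;
    cells adjacent to the component have distance 1."""
    R, C = core_mask.shape
    dist = np.full((R, C), np.inf)
    queue = deque()
    for r, c in np.argwhere(noncore):
        for dr, dc in _neigh(connectivity):
            nr, nc = r + dr, c + dc
            if 0 <= nr < R and 0 <= nc < C and core_mask[nr, nc]:
                dist[r, c] = 1.0
                queue.append((r, c))
                break
    while queue:
        r, c = queue.popleft()
        for dr, dc in _neigh(connectivity):
            nr, nc = r + dr, c + dc
            if 0 <= nr < R and 0 <= nc < C and noncore[nr, nc] and np.isinf(dist[nr, nc]):
                dist[nr, nc] = dist[r, c] + 1.0
                queue.append((nr, nc))
    return dist
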