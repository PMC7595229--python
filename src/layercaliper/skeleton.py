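"""Centerline extraction: thinning, branch pruning, longest path, trimming.

The measurement core needs an *ordered*, single-pixel-wide, branch-free
path along the layer's long axis.  Morphological thinning of a real mask
produces short spurs and occasional junction clusters; these are pruned and
the longest geodesic (BFS) path between endpoint pixels is retained.  The
path ends are then trimmed so no calliper is anchored near the skeleton
tips, where thinning artifacts and image edges would bias the measurement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from skimage.morphology import medial_axis, skeletonize as _sk_thin

from .io import BinaryMask

logger = logging.getLogger(__name__)

_NEIGHBORS = [(dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1) if (dx, dy) != (0, 0)]


@dataclass
class Skeleton:
    """Ordered single-pixel-wide centerline path.

    ``path`` is an (N, 2) integer array of (x, y) = (column, row)
    coordinates; consecutive entries are 8-neighbours and no pixel repeats.
    """

    path: np.ndarray
    source_mask_shape: tuple[int, int]  # (rows, cols)

    def __post_init__(self) -> None:
        self.path = np.asarray(self.path, int)
        if self.path.ndim != 2 or self.path.shape[1] != 2 or len(self.path) < 2:
            raise ValueError("skeleton path must be an (N>=2, 2) array of (x, y)")

    def __len__(self) -> int:
        return len(self.path)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.path, columns=["x", "y"])


def skeletonize(mask: BinaryMask | np.ndarray, method: str = "zhang") -> np.ndarray:
    """Thin a mask to a 1-pixel-wide 8-connected boolean skeleton image.

    ``method`` is ``'zhang'`` (topology-preserving thinning, default) or
    ``'medial'`` (distance-transform medial axis).
    """
    data = mask.data if isinstance(mask, BinaryMask) else np.asarray(mask, bool)
    if not data.any():
        raise ValueError("cannot skeletonize an empty mask")
    if method == "zhang":
        return _sk_thin(data)
    if method == "medial":
        return medial_axis(data)
    raise ValueError(f"unknown thinning method {method!r}")


def _pixel_graph(skel_img: np.ndarray) -> nx.Graph:
    ys, xs = np.nonzero(skel_img)
    pixels = set(zip(xs.tolist(), ys.tolist()))
    g = nx.Graph()
    g.add_nodes_from(pixels)
    for (x, y) in pixels:
        for dx, dy in _NEIGHBORS:
            q = (x + dx, y + dy)
            if q in pixels:
                g.add_edge((x, y), q)
    return g


def _prune_short_branches(g: nx.Graph, min_branch_len: int) -> None:
    """Iteratively remove endpoint-to-junction branches shorter than the cutoff."""
    while True:
        removed = False
        for end in [n for n in g.nodes if g.degree(n) == 1]:
            if end not in g:
                continue
            walk = [end]
            prev, cur = None, end
            while g.degree(cur) <= 2:
                nxt = [q for q in g.neighbors(cur) if q != prev]
                if not nxt:
                    break
                prev, cur = cur, min(nxt)
                if g.degree(cur) >= 3:
                    break
                walk.append(cur)
            if g.degree(cur) >= 3 and len(walk) < min_branch_len:
                g.remove_nodes_from(walk)
                removed = True
        if not removed:
            return


def longest_path(skel_img: np.ndarray, min_branch_len: int = 10) -> Skeleton:
    """Prune short branches, then return the longest geodesic path.

    The path runs between the pair of endpoint (degree-1) pixels with the
    greatest BFS distance.  A cyclic skeleton with no endpoints is broken
    at a deterministic point (the lexicographically smallest pixel) with a
    warning.  The returned path starts at the endpoint with the smaller x
    (ties: smaller y).
    """
    g = _pixel_graph(skel_img)
    if g.number_of_nodes() == 0:
        raise ValueError("empty skeleton")
    # keep the largest connected component (masks are single-component by
    # contract, but thinning of degenerate inputs can shed isolated pixels)
    comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    g = g.subgraph(comps[0]).copy()
    if min_branch_len > 0:
        _prune_short_branches(g, min_branch_len)
    ends = sorted(n for n in g.nodes if g.degree(n) == 1)
    if not ends:
        pivot = min(g.nodes)
        nbrs = sorted(g.neighbors(pivot))
        if nbrs:
            logger.warning("cyclic skeleton: breaking cycle at %s", pivot)
            g.remove_edge(pivot, nbrs[0])
        ends = sorted(n for n in g.nodes if g.degree(n) == 1)
        if not ends:
            ends = [pivot]
    best = (-1, None, None)
    for e in ends:
        dist = nx.single_source_shortest_path_length(g, e)
        far, d = max(dist.items(), key=lambda kv: (kv[1], kv[0]))
        if d > best[0]:
            best = (d, e, far)
    _, a, b = best
    if b is None or a == b:
        raise ValueError("skeleton reduced to a single pixel; mask too small")
    path = nx.shortest_path(g, a, b)
    if path[0] > path[-1]:
        path = path[::-1]
    return Skeleton(np.array(path, int), skel_img.shape)


def trim_tails(skel: Skeleton, mask: BinaryMask | np.ndarray,
               tol: float = 2.0, max_frac: float = 0.3) -> Skeleton:
    """Trim skeleton ends that lie off the layer's medial plateau.

    Thinning a thick band does not stop at the centerline ends: it leaves
    diagonal tails running toward the mask corners.  A calliper anchored on
    such a tail measures along a spurious orientation.  On the centerline
    proper, the distance-transform value equals the local half-thickness;
    on a tail it falls away toward the corner.  Each end is therefore
    trimmed up to the first pixel whose distance-transform value comes
    within ``tol`` px of that end's local plateau (the maximum over the
    first/last ``max_frac`` of the path — a local reference, so a layer
    whose thickness genuinely varies along its length is not eaten into).
    """
    data = mask.data if isinstance(mask, BinaryMask) else np.asarray(mask, bool)
    from scipy import ndimage
    dt = ndimage.distance_transform_edt(data)
    path = skel.path
    vals = dt[path[:, 1], path[:, 0]]
    n = len(path)
    m = max(2, int(n * max_frac))
    lo_ref = vals[:m].max()
    hi_ref = vals[-m:].max()
    lo_ok = np.nonzero(vals[:m] >= lo_ref - tol)[0]
    hi_ok = np.nonzero(vals[-m:] >= hi_ref - tol)[0]
    i0 = int(lo_ok[0]) if len(lo_ok) else 0
    i1 = n - m + int(hi_ok[-1]) if len(hi_ok) else n - 1
    if i1 - i0 + 1 < 2:
        return skel
    return Skeleton(path[i0:i1 + 1], skel.source_mask_shape)


def trim_ends(skel: Skeleton, trim: int) -> Skeleton:
    """Drop the first and last ``trim`` path pixels.

    Keeps callipers away from skeleton tips and image borders; fails
    explicitly when the trim would consume the whole path.
    """
    if trim < 0:
        raise ValueError("trim must be non-negative")
    if trim == 0:
        return skel
    if 2 * trim >= len(skel):
        raise ValueError(f"trim {trim} too large for path of {len(skel)} pixels")
    return Skeleton(skel.path[trim:len(skel) - trim], skel.source_mask_shape)
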