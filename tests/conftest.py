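import numpy as np
import pytest

from layercaliper import BinaryMask, CaliperParams, run_calibration


@pytest.fixture(scope="session")
def calibration_report():
    """Full calibration protocol, run once for the whole session."""
    return run_calibration(CaliperParams())


@pytest.fixture
def band_mask():
    """Small horizontal band: 200 wide, 21 px thick, centered on 100 rows."""
    def make(thickness=21, h=100, w=200):
        m = np.zeros((h, w), bool)
        start = (h - thickness) // 2
        m[start:start + thickness, :] = True
        return BinaryMask(m)
    return make


def subpixel_march_oracle(mask, centroid, alpha_deg, step=0.1, max_dist=2000.0):
    """Independent dense ray-march: 0.1-px steps along ±normal.

    Walks the continuous ray on both sides, rounds each sample to a pixel,
    and stops at the first sample whose pixel is outside the mask; the
    thickness is the rounded endpoint distance under the same first-outside
    minus-one convention as the implementation.
    """
    import math
    data = mask.data
    h, w = data.shape
    x0, y0 = centroid
    a = math.radians(alpha_deg)
    ux, uy = math.sin(a), -math.cos(a)

    def hround(v):
        return int(math.floor(v + 0.5))

    def walk(sign):
        t = step
        while t < max_dist:
            x = hround(x0 + sign * ux * t)
            y = hround(y0 + sign * uy * t)
            if not (0 <= x < w and 0 <= y < h) or not data[y, x]:
                return (x, y)
            t += step
        raise AssertionError("oracle ray never left the mask")

    xi, yi = walk(+1)
    xf, yf = walk(-1)
    d = math.hypot(xf - xi, yf - yi)
    return max(1, hround(d) - 1)


def column_run_lengths(mask):
    """Brute-force per-column foreground run lengths of a band mask."""
    data = mask.data if hasattr(mask, "data") else mask
    out = []
    for col in data.T:
        idx = np.nonzero(col)[0]
        out.append(0 if len(idx) == 0 else int(idx[-1] - idx[0] + 1))
    return np.array(out)


def bfs_diameter(pixels):
    """Brute-force all-pairs BFS diameter of an 8-connected pixel set.

    Returns (diameter_in_edges, endpoints). Independent of networkx.
    """
    from collections import deque
    pix = set(pixels)
    best = (-1, None, None)
    for src in pix:
        dist = {src: 0}
        q = deque([src])
        while q:
            x, y = q.popleft()
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    if dx == dy == 0:
                        continue
                    nb = (x + dx, y + dy)
                    if nb in pix and nb not in dist:
                        dist[nb] = dist[(x, y)] + 1
                        q.append(nb)
        far, d = max(dist.items(), key=lambda kv: kv[1])
        if d > best[0]:
            best = (d, src, far)
    return best[0], (best[1], best[2])


def random_curved_band(rng, w=300, h=200):
    """Seeded random layer-like mask: smooth centerline, varying thickness."""
    x = np.arange(w)
    center = h / 2 + sum(
        rng.uniform(5, 15) * np.sin(2 * np.pi * rng.uniform(0.5, 1.5) * x / w
                                    + rng.uniform(0, 2 * np.pi))
        for _ in range(3))
    half = rng.uniform(8, 20) + rng.uniform(2, 6) * np.sin(
        2 * np.pi * rng.uniform(0.5, 1.0) * x / w + rng.uniform(0, 2 * np.pi))
    yy, xx = np.mgrid[0:h, 0:w]
    return BinaryMask(np.abs(yy - center[xx]) < half[xx])


def random_blob_mask(rng, size=120, sigma=6.0):
    """Seeded smooth random blob mask (largest connected component)."""
    from scipy import ndimage
    noise = rng.standard_normal((size, size))
    smooth = ndimage.gaussian_filter(noise, sigma)
    fg = smooth > np.quantile(smooth, 0.75)
    labels, n = ndimage.label(fg, structure=np.ones((3, 3), int))
    if n == 0:
        raise AssertionError("degenerate blob")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    return BinaryMask(labels == (int(np.argmax(sizes)) + 1))
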