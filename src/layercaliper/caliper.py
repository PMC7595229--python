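"""Perpendicular-calliper thickness measurement.

The trimmed centerline is fragmented into *n* contiguous segments; each
segment contributes one calliper anchored at its centroid.  The local
skeleton orientation θ (degrees versus the horizontal zero-plane, measured
in the y-up sense) is estimated by a total-least-squares line fit over the
skeleton pixels inside a square window, and the calliper marches along the
supplementary angle α = 180° − θ.

Marching construction (one side at a time, both step counters starting at 1
pixel from the anchor):

    x_i = round(sin(α·π/180) · k + x0)        (initial, "positive" side)
    y_i = round(y0 − cos(α·π/180) · k)
    x_f = round(x0 − sin(α·π/180) · k)        (final, "negative" side)
    y_f = round(cos(α·π/180) · k + y0)

While the candidate pixel lies inside the mask the side's step counter k
increases by 1; the first *outside* pixel becomes that side's endpoint.
The thickness is the rounded Euclidean distance between the two endpoints
minus 1: each endpoint sits one pixel beyond the layer boundary, so the
raw endpoint distance overshoots the true span by exactly one pixel on an
axis-aligned band.  This boundary convention is frozen by the calibration
phantoms: a band of thickness T reads exactly T for every T in 10…500 px
and for every even-edge rotation of the 200-px band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import BinaryMask
from .skeleton import (Skeleton, longest_path, skeletonize, trim_ends,
                       trim_tails)


class MeasurementError(RuntimeError):
    """Raised when a mask yields no valid callipers."""


def _hround(x: float) -> int:
    """Half-up rounding (0.5 rounds away from zero for positives)."""
    return int(math.floor(x + 0.5))


@dataclass
class Caliper:
    """One thickness measurement.

    ``centroid`` anchors the calliper on the skeleton; ``theta`` is the
    local skeleton orientation and ``alpha`` its supplementary angle along
    which the two half-rays march.  Endpoints are the first pixels outside
    the mask on each side; ``steps_initial``/``steps_final`` are the final
    per-side step counters.  ``length_px`` is the calibrated rounded
    Euclidean endpoint distance.  Callipers that escape the canvas or
    exceed the marching cap are flagged invalid and excluded from
    statistics (never truncated, which would bias minima).
    """

    centroid: tuple[int, int]
    theta: float
    alpha: float
    initial_endpoint: tuple[int, int]
    final_endpoint: tuple[int, int]
    steps_initial: int
    steps_final: int
    length_px: int
    valid: bool = True
    invalid_reason: str = ""


@dataclass
class CaliperParams:
    """Measurement parameters.

    n_calipers : number of callipers spread along the trimmed centerline.
    angle_window : side (px) of the square window for the orientation fit.
    trim_px : pixels trimmed from each skeleton end before fragmenting.
    min_branch_len : skeleton branches shorter than this are pruned.
    max_march : per-side marching cap in pixels (default: image diagonal).
    auto_trim : distance-transform tail trimming of the skeleton ends.
    scale_um_per_px : physical scale applied to reported µm lengths.
    thinning : 'zhang' thinning (default) or 'medial' axis.
    """

    n_calipers: int = 50
    angle_window: int = 15
    trim_px: int = 20
    min_branch_len: int = 10
    max_march: int | None = None
    scale_um_per_px: float = 1.0
    thinning: str = "zhang"
    auto_trim: bool = True

    def __post_init__(self) -> None:
        if self.n_calipers < 1:
            raise ValueError("n_calipers must be >= 1")
        if self.angle_window < 3:
            raise ValueError("angle_window must be >= 3")


@dataclass
class ThicknessProfile:
    """Ordered calliper series for one layer."""

    calipers: list[Caliper]
    scale_um_per_px: float = 1.0
    name: str = ""

    @property
    def lengths_px(self) -> np.ndarray:
        return np.array([c.length_px for c in self.calipers if c.valid], float)

    @property
    def lengths_um(self) -> np.ndarray:
        return self.lengths_px * self.scale_um_per_px

    @property
    def n_valid(self) -> int:
        return sum(c.valid for c in self.calipers)


def fragment_skeleton(skel: Skeleton, n: int) -> list[np.ndarray]:
    """Split the path into n contiguous near-equal (±1 px) segments."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > len(skel):
        raise ValueError(f"cannot place {n} callipers on a {len(skel)}-pixel path")
    return [seg for seg in np.array_split(skel.path, n)]


def segment_centroid(segment: np.ndarray) -> tuple[int, int]:
    """Arithmetic-mean centroid snapped to the nearest segment pixel.

    Ties break toward the earlier path index so that curved (e.g. C-shaped)
    segments still anchor on the skeleton deterministically.
    """
    seg = np.asarray(segment)
    if len(seg) == 0:
        raise ValueError("empty segment")
    mean = seg.mean(axis=0)
    d2 = ((seg - mean) ** 2).sum(axis=1)
    x, y = seg[int(np.argmin(d2))]
    return int(x), int(y)


def local_angle(skel: Skeleton, centroid: tuple[int, int], window: int = 15) -> float:
    """Local orientation θ ∈ [0°, 180°) of the centerline at ``centroid``.

    Total-least-squares (principal-direction) fit over the skeleton path
    pixels inside the window×window box centered on the centroid.  θ is
    measured against the horizontal in the y-up sense, so a horizontal
    centerline gives θ = 0 and its callipers march vertically.  If fewer
    than two pixels fall inside the window it is doubled once, then the
    fit fails explicitly.
    """
    if window < 3:
        raise ValueError("window must be >= 3")
    pts = skel.path.astype(float)
    cx, cy = centroid
    for w in (window, 2 * window):
        half = w // 2
        sel = (np.abs(pts[:, 0] - cx) <= half) & (np.abs(pts[:, 1] - cy) <= half)
        if sel.sum() >= 2:
            sub = pts[sel] - pts[sel].mean(axis=0)
            # principal direction of the windowed pixels
            _, _, vt = np.linalg.svd(sub, full_matrices=False)
            vx, vy = vt[0]
            return float(np.degrees(np.arctan2(-vy, vx)) % 180.0)
    raise ValueError(f"fewer than 2 skeleton pixels within window {window} of {centroid}")


def march_caliper(mask: BinaryMask, centroid: tuple[int, int], alpha: float,
                  max_march: int | None = None) -> Caliper:
    """March both half-rays from the anchor and return the calliper.

    Candidates outside the canvas terminate the side but flag the calliper
    invalid (open boundary); exceeding ``max_march`` likewise.
    """
    data = mask.data
    h, w = data.shape
    x0, y0 = int(centroid[0]), int(centroid[1])
    if not (0 <= x0 < w and 0 <= y0 < h) or not data[y0, x0]:
        raise ValueError(f"centroid {centroid} is not inside the mask")
    if max_march is None:
        max_march = int(math.hypot(w, h)) + 1
    a = math.radians(alpha)
    sa, ca = math.sin(a), math.cos(a)

    def _march(sign: int) -> tuple[tuple[int, int], int, str]:
        k = 1
        while k <= max_march:
            x = _hround(x0 + sign * sa * k)
            y = _hround(y0 - sign * ca * k)
            if not (0 <= x < w and 0 <= y < h):
                return (x, y), k, "escaped canvas"
            if not data[y, x]:
                return (x, y), k, ""
            k += 1
        return (x, y), k - 1, "exceeded max_march"

    (xi, yi), ki, why_i = _march(+1)
    (xf, yf), kf, why_f = _march(-1)
    dist = math.hypot(xf - xi, yf - yi)
    length = max(1, _hround(dist) - 1)
    why = why_i or why_f
    return Caliper(
        centroid=(x0, y0), theta=(180.0 - alpha) % 180.0, alpha=alpha,
        initial_endpoint=(xi, yi), final_endpoint=(xf, yf),
        steps_initial=ki, steps_final=kf, length_px=length,
        valid=not why, invalid_reason=why)


def measure(mask: BinaryMask, params: CaliperParams | None = None) -> ThicknessProfile:
    """Full pipeline: thin → prune → trim → fragment → angle → march.

    Deterministic: identical mask and parameters give identical profiles.
    """
    if params is None:
        params = CaliperParams()
    skel_img = skeletonize(mask, params.thinning)
    skel = longest_path(skel_img, params.min_branch_len)
    if params.auto_trim:
        skel = trim_tails(skel, mask)
    skel = trim_ends(skel, params.trim_px)
    segments = fragment_skeleton(skel, params.n_calipers)
    calipers = []
    for seg in segments:
        c = segment_centroid(seg)
        theta = local_angle(skel, c, params.angle_window)
        alpha = 180.0 - theta
        calipers.append(march_caliper(mask, c, alpha, params.max_march))
    profile = ThicknessProfile(calipers, params.scale_um_per_px,
                               name=getattr(mask, "name", ""))
    if profile.n_valid < 1:
        raise MeasurementError(
            f"no valid callipers on {mask.name or 'mask'}: "
            f"{[c.invalid_reason for c in calipers][:5]}")
    return profile
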