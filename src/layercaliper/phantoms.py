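"""Calibration phantom generation.

Three procedurally defined phantom datasets with exact ground truth:

1. *Increasing thickness* — horizontal full-width bands of 10–500 px
   thickness in 10-px steps on a 1344×1024 canvas (50 images).
2. *Rotated band* — a 1344×200 px band rotated about the canvas center at
   10° intervals over [0°, 180°], plus 45° and 135° (21 images).
3. *Step band* — one band whose thickness switches abruptly between
   segments (default 200/150/250 px), emulating layer thinning/thickening.

Rotated bands are rasterized geometrically: a pixel is foreground iff its
center lies inside the exact rotated rectangle.  No image interpolation is
involved, so rasterization is deterministic and the 0°/45°/90°/135°/180°
rotations have perfectly regular ("even") edges while the remaining
rotations show the stair-step ("jagged") aliasing that the calibration
criteria budget at ±2 px.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import BinaryMask, write_mask

#: rotations with regular rasterized edges; everything else is jagged
EVEN_EDGE_ROTATIONS = frozenset({0.0, 45.0, 90.0, 135.0, 180.0})

DEFAULT_CANVAS = (1344, 1024)  # (width, height)
DEFAULT_ROTATIONS = tuple(sorted(set(range(0, 181, 10)) | {45, 135}))


def edge_class(rotation_deg: float) -> str:
    """'even' for 0/45/90/135/180°, else 'jagged'."""
    return "even" if float(rotation_deg) % 180.0 in {r % 180.0 for r in EVEN_EDGE_ROTATIONS} \
        else "jagged"


@dataclass
class PhantomTruth:
    """Ground truth attached to a generated phantom.

    ``known_thickness`` is a scalar for constant bands or a per-column
    array (length = canvas width) for step bands.
    """

    known_thickness: float | np.ndarray
    rotation: float = 0.0

    @property
    def edge_class(self) -> str:
        return edge_class(self.rotation)

    @property
    def is_profile(self) -> bool:
        return isinstance(self.known_thickness, np.ndarray)


def _horizontal_band(canvas_w: int, canvas_h: int, thickness: int) -> np.ndarray:
    if not 1 <= thickness <= canvas_h:
        raise ValueError(f"thickness {thickness} outside [1, {canvas_h}]")
    m = np.zeros((canvas_h, canvas_w), bool)
    start = (canvas_h - thickness) // 2
    m[start:start + thickness, :] = True
    return m


def gen_increasing_thickness(canvas_w: int = 1344, canvas_h: int = 1024,
                             t_min: int = 10, t_max: int = 500,
                             step: int = 10) -> list[tuple[BinaryMask, PhantomTruth]]:
    """Horizontal, vertically centered, full-width bands of increasing thickness.

    The defaults produce the 50-image calibration set (10, 20, …, 500 px).
    Each mask's foreground count is exactly ``canvas_w * thickness``.
    """
    if t_min > t_max:
        raise ValueError("t_min must not exceed t_max")
    if step <= 0:
        raise ValueError("step must be positive")
    if t_max > canvas_h:
        raise ValueError(f"t_max {t_max} exceeds canvas height {canvas_h}: band would clip")
    out = []
    for t in range(t_min, t_max + 1, step):
        mask = BinaryMask(_horizontal_band(canvas_w, canvas_h, t),
                          name=f"band_t{t:04d}")
        out.append((mask, PhantomTruth(float(t), 0.0)))
    return out


def _rasterize_rotated_rect(canvas_w: int, canvas_h: int, length: float,
                            thickness: float, rotation_deg: float) -> np.ndarray:
    """Pixel-center-in-rectangle rasterization, pivot at canvas center.

    The canvas is enlarged symmetrically (kept even-sized so the pivot is
    preserved) whenever the rotated band would clip.
    """
    th = np.deg2rad(rotation_deg)
    c, s = np.cos(th), np.sin(th)
    half_w = length / 2 * abs(c) + thickness / 2 * abs(s)
    half_h = length / 2 * abs(s) + thickness / 2 * abs(c)
    need_w = int(2 * np.ceil(half_w))
    need_h = int(2 * np.ceil(half_h))
    w = canvas_w if need_w <= canvas_w else need_w + 4
    h = canvas_h if need_h <= canvas_h else need_h + 4
    w += w % 2
    h += h % 2
    cx, cy = w / 2.0, h / 2.0
    jj, ii = np.mgrid[0:h, 0:w]
    dx = ii + 0.5 - cx
    dy = jj + 0.5 - cy
    u = c * dx - s * dy  # band-frame long axis
    v = s * dx + c * dy  # band-frame short axis
    return (np.abs(u) < length / 2) & (np.abs(v) < thickness / 2)


def gen_rotated_band(canvas_w: int = 1344, canvas_h: int = 1024,
                     band_len: int = 1344, thickness: int = 200,
                     rotations: Sequence[float] | None = None,
                     ) -> list[tuple[BinaryMask, PhantomTruth]]:
    """A fixed band rotated counter-clockwise about the canvas center.

    Defaults reproduce the 21-image rotation calibration set: 10° intervals
    over [0°, 180°] plus the 45° and 135° diagonals.
    """
    if rotations is None:
        rotations = DEFAULT_ROTATIONS
    diag = float(np.hypot(band_len, thickness))
    out = []
    for r in rotations:
        r = float(r)
        if not 0.0 <= r <= 180.0:
            raise ValueError(f"rotation {r} outside [0, 180]")
        if diag > np.hypot(canvas_w, canvas_h) * 4:
            raise ValueError("band diagonal vastly exceeds canvas; refusing to pad")
        m = _rasterize_rotated_rect(canvas_w, canvas_h, band_len, thickness, r)
        mask = BinaryMask(m, name=f"rot_{r:05.1f}deg")
        out.append((mask, PhantomTruth(float(thickness), r)))
    return out


def gen_step_band(canvas_w: int = 1344, canvas_h: int = 1024,
                  segments: Sequence[tuple[int, int]] = ((448, 200), (448, 150), (448, 250)),
                  ) -> tuple[BinaryMask, PhantomTruth]:
    """Horizontal band with abrupt per-segment thickness changes.

    ``segments`` is an ordered list of ``(length, thickness)`` pairs laid
    out left to right, each segment vertically centered.  The truth carries
    the per-column thickness profile (0 where no band is present).
    """
    total = sum(l for l, _ in segments)
    if total > canvas_w:
        raise ValueError(f"segment lengths sum to {total} > canvas width {canvas_w}")
    m = np.zeros((canvas_h, canvas_w), bool)
    profile = np.zeros(canvas_w, float)
    x = 0
    for length, t in segments:
        if not 1 <= t <= canvas_h:
            raise ValueError(f"segment thickness {t} outside [1, {canvas_h}]")
        start = (canvas_h - t) // 2
        m[start:start + t, x:x + length] = True
        profile[x:x + length] = t
        x += length
    mask = BinaryMask(m, name="step_band")
    return mask, PhantomTruth(profile, 0.0)


def step_transitions(truth: PhantomTruth) -> np.ndarray:
    """Column indices where the per-column truth changes value."""
    p = np.asarray(truth.known_thickness, float)
    return np.nonzero(np.diff(p) != 0)[0] + 1


def write_phantom(mask: BinaryMask, path: str | Path,
                  dialect: str = "inside_is_zero") -> Path:
    """Write a phantom as an 8-bit TIFF/PNG in the chosen dialect."""
    return write_mask(mask, path, dialect)


def write_truth_sidecar(pairs: Sequence[tuple[BinaryMask, PhantomTruth]],
                        path: str | Path) -> Path:
    """CSV sidecar (image, rotation, thickness, edge_class) for a dataset.

    Step-band profiles are stored as a JSON list in the thickness column.
    """
    rows = []
    for mask, truth in pairs:
        t = truth.known_thickness
        rows.append({
            "image": mask.name,
            "rotation_deg": truth.rotation,
            "thickness_px": json.dumps(np.asarray(t).tolist()) if truth.is_profile else t,
            "edge_class": truth.edge_class,
        })
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
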