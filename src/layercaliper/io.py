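"""Mask file I/O and batch processing.

Masks travel through the library as :class:`BinaryMask` (boolean foreground)
regardless of the on-disk dialect.  Two 8-bit dialects are supported:

``inside_is_zero``
    Foreground (the layer) is pixel value 0, background 255.  This mirrors
    the marching convention of the measurement core, which treats a zero
    pixel value as "inside the layer".
``inside_is_max``
    Foreground is the maximum value (255), background 0 — the common
    white-on-black mask convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
import imageio.v3 as iio

logger = logging.getLogger(__name__)

DIALECTS = ("inside_is_zero", "inside_is_max")


@dataclass
class BinaryMask:
    """A 2-D boolean raster of a segmented layer.

    Parameters
    ----------
    data : ndarray of bool, shape (rows, cols)
        ``True`` marks pixels inside the layer.
    scale_um_per_px : float
        Physical scale. The default of 1.0 reports pixel units unchanged.
    name : str
        Optional identifier carried into result tables.
    """

    data: np.ndarray
    scale_um_per_px: float = 1.0
    name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {self.data.shape}")
        if self.data.dtype != bool:
            self.data = self.data.astype(bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def area(self) -> int:
        return int(self.data.sum())


def mask_to_uint8(mask: BinaryMask | np.ndarray, dialect: str = "inside_is_zero") -> np.ndarray:
    data = mask.data if isinstance(mask, BinaryMask) else np.asarray(mask, bool)
    if dialect == "inside_is_zero":
        return np.where(data, 0, 255).astype(np.uint8)
    if dialect == "inside_is_max":
        return np.where(data, 255, 0).astype(np.uint8)
    raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def write_mask(mask: BinaryMask | np.ndarray, path: str | Path,
               dialect: str = "inside_is_zero") -> Path:
    """Write a boolean mask as an 8-bit single-channel TIFF or PNG."""
    path = Path(path)
    img = mask_to_uint8(mask, dialect)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, img)
    else:
        iio.imwrite(path, img)
    return path


def read_mask(path: str | Path, dialect: str = "inside_is_zero",
              scale_um_per_px: float = 1.0) -> BinaryMask:
    """Read an 8-bit or boolean single-channel image as a boolean mask.

    Raises
    ------
    ValueError
        If the image has more than one channel, or if its pixel histogram
        is not binary (more than two distinct values): such an image must
        either be thresholded first or run through the stand-in segmenter.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        img = tifffile.imread(path)
    else:
        img = iio.imread(path)
    img = np.asarray(img)
    if img.ndim == 3 and img.shape[2] in (3, 4) and np.all(img[..., :1] == img[..., :3]):
        img = img[..., 0]  # gray saved as RGB(A)
    if img.ndim != 2:
        raise ValueError(
            f"{path}: expected a single-channel image, got shape {img.shape}; "
            "convert to grayscale or supply a pre-made binary mask")
    if img.dtype == bool:
        fg = img if dialect == "inside_is_max" else ~img
        return BinaryMask(fg, scale_um_per_px, name=path.name)
    values = np.unique(img)
    if len(values) > 2:
        counts = {int(v): int((img == v).sum()) for v in values[:8]}
        raise ValueError(
            f"{path}: pixel histogram is not binary ({len(values)} distinct "
            f"values, e.g. {counts}); either threshold/segment the image "
            "first (see segment_layer) or supply a binary mask")
    if dialect == "inside_is_zero":
        fg = img == values.min()
    elif dialect == "inside_is_max":
        fg = img == values.max()
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if len(values) == 1:
        # a constant image is ambiguous; treat min==max as all-foreground
        # only for the value matching the dialect's foreground end
        v = int(values[0])
        fg = np.full(img.shape, (v == 0) == (dialect == "inside_is_zero"), bool)
    return BinaryMask(fg, scale_um_per_px, name=path.name)


@dataclass
class RunConfig:
    """Batch-run configuration (config file keys; CLI flags override)."""

    inputs: list[Path] = field(default_factory=list)
    output_dir: Path = Path("layercaliper_out")
    dialect: str = "inside_is_zero"
    n_calipers: int = 50
    angle_window: int = 15
    trim_px: int = 20
    min_branch_len: int = 10
    scale_um_per_px: float = 1.0
    max_march: int | None = None
    overlay: bool = False
    segment: bool = False
    log_level: str = "INFO"


def write_caliper_csv(profile, path: str | Path) -> Path:
    """Per-calliper table: anchor, angles, endpoints, length, validity."""
    rows = []
    for i, c in enumerate(profile.calipers):
        rows.append({
            "index": i,
            "x0": c.centroid[0], "y0": c.centroid[1],
            "theta_deg": c.theta, "alpha_deg": c.alpha,
            "x_i": c.initial_endpoint[0], "y_i": c.initial_endpoint[1],
            "x_f": c.final_endpoint[0], "y_f": c.final_endpoint[1],
            "length_px": c.length_px,
            "length_um": c.length_px * profile.scale_um_per_px,
            "valid": c.valid,
        })
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_overlay(mask: BinaryMask, profile, path: str | Path) -> Path:
    """QC overlay: callipers drawn over the mask."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 8 * mask.shape[0] / mask.shape[1]))
    ax.imshow(mask.data, cmap="gray", interpolation="nearest")
    for c in profile.calipers:
        color = "tab:red" if c.valid else "tab:orange"
        ax.plot([c.initial_endpoint[0], c.final_endpoint[0]],
                [c.initial_endpoint[1], c.final_endpoint[1]],
                color=color, lw=0.8)
        ax.plot(c.centroid[0], c.centroid[1], ".", color="tab:blue", ms=2)
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return Path(path)


def batch_measure(config: RunConfig):
    """Measure every input mask; continue past per-image failures.

    Returns ``(summary_frame, failures)`` where *failures* maps filename to
    the error message.  Outputs (per-image calliper CSV, a combined summary
    CSV, optional overlays) are written under ``config.output_dir`` in
    deterministic filename order.
    """
    from .caliper import CaliperParams, measure
    from .stats import index_of_dispersion, summarize

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = CaliperParams(
        n_calipers=config.n_calipers, angle_window=config.angle_window,
        trim_px=config.trim_px, min_branch_len=config.min_branch_len,
        scale_um_per_px=config.scale_um_per_px, max_march=config.max_march)
    rows, failures = [], {}
    for path in sorted(Path(p) for p in config.inputs):
        try:
            mask = read_mask(path, config.dialect, config.scale_um_per_px)
            profile = measure(mask, params)
            write_caliper_csv(profile, outdir / f"{path.stem}_calipers.csv")
            if config.overlay:
                write_overlay(mask, profile, outdir / f"{path.stem}_overlay.png")
            s = summarize(profile)
            rows.append({
                "image": path.name, "n": s.n,
                "mean_px": s.mean_px, "mean_um": s.mean_um,
                "sd_px": s.sd_px, "min_px": s.min_px, "max_px": s.max_px,
                "index_of_dispersion": index_of_dispersion(profile.lengths_px),
            })
        except Exception as exc:  # keep going; report at the end
            logger.error("failed on %s: %s", path.name, exc)
            failures[path.name] = str(exc)
    frame = pd.DataFrame(rows)
    frame.to_csv(outdir / "summary.csv", index=False)
    return frame, failures
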