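"""Profile summaries, pairwise coefficient of variation, index of dispersion."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .caliper import ThicknessProfile


@dataclass
class ProfileSummary:
    """Mean / SD / min / max of valid calliper lengths, in px and µm."""

    n: int
    mean_px: float
    sd_px: float
    min_px: float
    max_px: float
    scale_um_per_px: float = 1.0

    @property
    def mean_um(self) -> float:
        return self.mean_px * self.scale_um_per_px

    @property
    def sd_um(self) -> float:
        return self.sd_px * self.scale_um_per_px

    @property
    def min_um(self) -> float:
        return self.min_px * self.scale_um_per_px

    @property
    def max_um(self) -> float:
        return self.max_px * self.scale_um_per_px


@dataclass
class DispersionReport:
    index_of_dispersion: float
    cov_vs_truth: float
    cov_pct: float


def summarize(profile: ThicknessProfile) -> ProfileSummary:
    lengths = profile.lengths_px
    if len(lengths) == 0:
        raise ValueError("profile has no valid callipers")
    return ProfileSummary(
        n=len(lengths),
        mean_px=float(lengths.mean()),
        sd_px=float(lengths.std(ddof=1)) if len(lengths) > 1 else 0.0,
        min_px=float(lengths.min()),
        max_px=float(lengths.max()),
        scale_um_per_px=profile.scale_um_per_px,
    )


def cov_pairwise(a: float, b: float) -> float:
    """Pairwise coefficient of variation (A − B) / ((A + B)/2).

    Antisymmetric in its arguments; multiply by 100 for percent.
    """
    if a + b == 0:
        raise ValueError("cov_pairwise undefined for a + b = 0")
    return (a - b) / ((a + b) / 2.0)


def index_of_dispersion(lengths) -> float:
    """Variance-to-mean ratio of calliper lengths (population variance).

    Zero iff all lengths are equal — the calibration signature of a
    perfectly uniform rectangular layer.
    """
    x = np.asarray(lengths, float)
    if len(x) == 0:
        raise ValueError("empty length series")
    mean = x.mean()
    if mean <= 0:
        raise ValueError("index of dispersion requires a positive mean")
    return float(x.var(ddof=0) / mean)


def dispersion_report(profile: ThicknessProfile, known_thickness: float) -> DispersionReport:
    """Dispersion and truth-agreement summary for one measured layer."""
    lengths = profile.lengths_px
    cov = cov_pairwise(float(lengths.mean()), float(known_thickness))
    return DispersionReport(
        index_of_dispersion=index_of_dispersion(lengths),
        cov_vs_truth=cov,
        cov_pct=100.0 * cov,
    )
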