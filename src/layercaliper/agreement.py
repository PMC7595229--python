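"""Bland–Altman agreement analysis between two paired measurement series.

Bias is the mean paired difference a − b; the 95% limits of agreement are
bias ± 1.96 · SD(differences) with the sample SD.  The identity
``loa_interval = 2 · 1.96 · sd_diff = 3.92 · se · √n`` holds for every
result.  The paired significance test is a matched-pairs t-test by
default, with the Wilcoxon signed-rank test available for non-normal
differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats as sps


@dataclass
class AgreementResult:
    bias: float
    se: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    loa_interval: float
    p_value: float
    n: int
    test: str = "t"

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("bias", "se", "sd_diff", "loa_lower", "loa_upper",
                 "loa_interval", "p_value", "n", "test")}


def bland_altman(a, b, test: str = "t") -> AgreementResult:
    """Agreement between two equal-length paired series (a vs b)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    se = sd / np.sqrt(n)
    if test == "t":
        p = float(sps.ttest_rel(a, b).pvalue) if sd > 0 else (1.0 if bias == 0 else 0.0)
    elif test == "wilcoxon":
        p = 1.0 if np.all(d == 0) else float(sps.wilcoxon(a, b).pvalue)
    else:
        raise ValueError(f"unknown test {test!r}; use 't' or 'wilcoxon'")
    return AgreementResult(
        bias=bias, se=float(se), sd_diff=sd,
        loa_lower=bias - 1.96 * sd, loa_upper=bias + 1.96 * sd,
        loa_interval=2 * 1.96 * sd, p_value=p, n=n, test=test)


def bland_altman_plot(result: AgreementResult, a, b, path: str | Path,
                      title: str = "") -> Path:
    """Difference-vs-mean scatter with bias and limit-of-agreement lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    mean = (a + b) / 2.0
    diff = a - b
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(mean, diff, s=14, alpha=0.7, edgecolor="none")
    ax.axhline(result.bias, color="tab:blue", lw=1.2,
               label=f"bias = {result.bias:.2f}")
    for y, lbl in ((result.loa_lower, "lower LoA"), (result.loa_upper, "upper LoA")):
        ax.axhline(y, color="tab:red", ls="--", lw=1.0,
                   label=f"{lbl} = {y:.2f}")
    ax.set_xlabel("mean of paired measurements")
    ax.set_ylabel("difference (a − b)")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
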