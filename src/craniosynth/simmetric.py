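"""Structural similarity (SSIM) and similarity-to-closest-clinical-sample.

``ssim`` is the standard windowed structural similarity index (luminance,
contrast and structure terms with stabilizing constants (k1*L)^2 and
(k2*L)^2 over a sliding Gaussian or uniform window). ``ssim_cc`` scores a
synthetic image by its maximum SSIM over all clinical images of the same
class: 1 if it matches any of them, near 0 if it resembles none.

The in-package SSIM uses a 7-pixel window by default (an 11-pixel window is
borderline on 28 x 28 images) with Gaussian weights (sigma 1.5).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, uniform_filter

from .distmap import DistanceMap


@dataclass
class SSIMConfig:
    window: int = 7
    k1: float = 0.01
    k2: float = 0.03
    data_range: float = 1.0
    window_kind: str = "gaussian"  # or "uniform"
    gaussian_sigma: float = 1.5

    def __post_init__(self):
        if self.window % 2 == 0 or self.window < 3:
            raise ValueError("window must be an odd integer >= 3")
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("k1 and k2 must be positive")
        if self.window_kind not in ("gaussian", "uniform"):
            raise ValueError("window_kind must be 'gaussian' or 'uniform'")


def _as_pixels(x) -> np.ndarray:
    return x.pixels if isinstance(x, DistanceMap) else np.asarray(x, dtype=float)


def ssim(a, b, cfg: SSIMConfig | None = None) -> float:
    """Mean local SSIM between two equally sized images, in [-1, 1]."""
    cfg = cfg or SSIMConfig()
    x, y = _as_pixels(a), _as_pixels(b)
    if x.shape != y.shape:
        raise ValueError(f"image sizes differ: {x.shape} vs {y.shape}")
    if cfg.window > min(x.shape):
        raise ValueError("window exceeds image side")

    if cfg.window_kind == "gaussian":
        # truncate the kernel to the window radius, as is conventional
        radius = (cfg.window - 1) // 2
        truncate = radius / cfg.gaussian_sigma

        def filt(img):
            return gaussian_filter(img, cfg.gaussian_sigma, mode="reflect", truncate=truncate)

    else:

        def filt(img):
            return uniform_filter(img, cfg.window, mode="reflect")

    c1 = (cfg.k1 * cfg.data_range) ** 2
    c2 = (cfg.k2 * cfg.data_range) ** 2
    mx, my = filt(x), filt(y)
    mxx, myy, mxy = filt(x * x), filt(y * y), filt(x * y)
    vx = mxx - mx * mx
    vy = myy - my * my
    cov = mxy - mx * my
    num = (2 * mx * my + c1) * (2 * cov + c2)
    den = (mx * mx + my * my + c1) * (vx + vy + c2)
    smap = num / den
    # average over windows fully inside the image (crop the filter margin)
    r = (cfg.window - 1) // 2
    interior = smap[r:-r, r:-r] if r > 0 else smap
    return float(interior.mean())


def ssim_cc(synthetic, clinical_same_class: list, cfg: SSIMConfig | None = None) -> float:
    """Maximum SSIM of one synthetic image over same-class clinical images."""
    if len(clinical_same_class) == 0:
        raise ValueError("clinical list must be nonempty")
    if isinstance(synthetic, DistanceMap):
        for m in clinical_same_class:
            if isinstance(m, DistanceMap) and m.label != synthetic.label:
                raise ValueError(
                    f"class mismatch: synthetic {synthetic.label!r} vs clinical {m.label!r}"
                )
    return max(ssim(synthetic, m, cfg) for m in clinical_same_class)


def ssim_cc_report(
    synthetic_sets: dict[str, list[DistanceMap]],
    clinical: list[DistanceMap],
    cfg: SSIMConfig | None = None,
) -> pd.DataFrame:
    """Boxplot-ready SSIM_cc summary per (source, class).

    ``synthetic_sets`` maps a source name (e.g. ssm/pca/gan) to its labeled
    images. Returns one row per (source, class) with median, quartiles,
    whiskers (1.5 IQR convention) and outlier count.
    """
    by_class: dict[str, list[DistanceMap]] = {}
    for m in clinical:
        by_class.setdefault(m.label, []).append(m)
    rows = []
    for source, images in synthetic_sets.items():
        labels = {im.label for im in images}
        for label in sorted(labels):
            vals = np.array(
                [ssim_cc(im, by_class[label], cfg) for im in images if im.label == label]
            )
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            iqr = q3 - q1
            lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
            inside = vals[(vals >= lo) & (vals <= hi)]
            rows.append(
                {
                    "source": source,
                    "class": label,
                    "n": len(vals),
                    "median": med,
                    "q1": q1,
                    "q3": q3,
                    "whisker_low": inside.min() if len(inside) else np.nan,
                    "whisker_high": inside.max() if len(inside) else np.nan,
                    "n_outliers": int(((vals < lo) | (vals > hi)).sum()),
                }
            )
    return pd.DataFrame(rows)


def plot_ssim_cc(report: pd.DataFrame, path: str | Path) -> None:
    """Boxplot figure of the SSIM_cc report (one panel per source)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sources = report["source"].unique()
    fig, axes = plt.subplots(1, len(sources), figsize=(4 * len(sources), 3.2), squeeze=False)
    for ax, source in zip(axes[0], sources):
        sub = report[report["source"] == source]
        boxes = [
            {
                "label": r["class"],
                "med": r["median"],
                "q1": r["q1"],
                "q3": r["q3"],
                "whislo": r["whisker_low"],
                "whishi": r["whisker_high"],
                "fliers": [],
            }
            for _, r in sub.iterrows()
        ]
        ax.bxp(boxes, showfliers=False, medianprops={"color": "red"})
        ax.set_title(source)
        ax.set_ylabel("SSIM$_{cc}$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
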