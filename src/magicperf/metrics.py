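"""Image-quality metrics, brain bounding box, and severity stratification.

SSIM and UQI are evaluated on local sliding windows (11x11 Gaussian,
sigma 1.5 for SSIM; 8x8 uniform for UQI) and averaged, optionally within a
mask; whole-image ("global") single-window evaluation is also exposed.
UQI is exactly SSIM with both stabilizing constants set to zero when
computed on the same windows.

Severity stratification uses the volume-wise mismatch ratio: the number of
infarct-core pixels divided by the number of penumbra pixels, classified as
no infarction (ratio 0), mild-to-moderate (0 < ratio <= 0.5), or severe
(ratio > 0.5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

logger = logging.getLogger(__name__)

SEVERITY_LABELS = ("none", "mild_moderate", "severe")


@dataclass(frozen=True)
class SSIMConstants:
    """Stabilizers and window of the structural-similarity statistic.

    Defaults follow the original reference implementation: c1 = (0.01 L)^2,
    c2 = (0.03 L)^2 with dynamic range L = 1 for [0, 1] maps, and an 11x11
    Gaussian window with sigma 1.5.
    """

    L: float = 1.0
    c1: float | None = None
    c2: float | None = None
    window: int = 11
    sigma: float = 1.5
    window_type: str = "gaussian"      # gaussian | uniform

    def resolved(self) -> tuple[float, float]:
        c1 = (0.01 * self.L) ** 2 if self.c1 is None else self.c1
        c2 = (0.03 * self.L) ** 2 if self.c2 is None else self.c2
        return c1, c2

    def kernel(self) -> np.ndarray:
        k = self.window
        if self.window_type == "uniform":
            w = np.ones((k, k))
        else:
            ax = np.arange(k) - (k - 1) / 2.0
            g = np.exp(-(ax ** 2) / (2.0 * self.sigma ** 2))
            w = np.outer(g, g)
        return w / w.sum()


def _window_moments(x, y, kernel):
    """Weighted window means/variances/covariance on valid positions."""
    mx = fftconvolve(x, kernel, mode="valid")
    my = fftconvolve(y, kernel, mode="valid")
    mxx = fftconvolve(x * x, kernel, mode="valid")
    myy = fftconvolve(y * y, kernel, mode="valid")
    mxy = fftconvolve(x * y, kernel, mode="valid")
    return mx, my, mxx - mx * mx, myy - my * my, mxy - mx * my


def _valid_center_mask(mask, k):
    off = (k - 1) // 2
    ho = mask.shape[0] - k + 1
    wo = mask.shape[1] - k + 1
    return mask[off:off + ho, off:off + wo]


def ssim(x, y, consts: SSIMConstants | None = None, mask=None,
         mode: str = "local") -> float:
    """Structural similarity of two equally shaped 2-D images.

    ``mode='local'``: the statistic is computed per valid sliding window
    and averaged (over windows whose center lies in ``mask``, if given).
    ``mode='global'``: one statistic from whole-image (or masked) moments.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    consts = consts or SSIMConstants()
    c1, c2 = consts.resolved()
    if mode == "global":
        sel = np.ones(x.shape, bool) if mask is None else np.asarray(mask, bool)
        xs, ys = x[sel], y[sel]
        mx, my = xs.mean(), ys.mean()
        vx, vy = xs.var(), ys.var()
        cov = ((xs - mx) * (ys - my)).mean()
        return float((2 * mx * my + c1) * (2 * cov + c2)
                     / ((mx * mx + my * my + c1) * (vx + vy + c2)))
    if mode != "local":
        raise ValueError(f"unknown mode {mode!r}")
    kern = consts.kernel()
    mx, my, vx, vy, cov = _window_moments(x, y, kern)
    num = (2 * mx * my + c1) * (2 * cov + c2)
    den = (mx * mx + my * my + c1) * (vx + vy + c2)
    smap = num / den
    if mask is not None:
        sel = _valid_center_mask(np.asarray(mask, bool), consts.window)
        if not sel.any():
            raise ValueError("mask selects no valid windows")
        return float(smap[sel].mean())
    return float(smap.mean())


def uqi(x, y, window: int = 8, mask=None) -> float:
    """Universal quality index on sliding uniform windows.

    Equals SSIM with c1 = c2 = 0 on the same windows.  Windows whose
    denominator is exactly zero are skipped (their count is logged).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    kern = np.ones((window, window)) / window ** 2
    mx, my, vx, vy, cov = _window_moments(x, y, kern)
    num = 4 * cov * mx * my
    den = (vx + vy) * (mx * mx + my * my)
    if mask is not None:
        sel = _valid_center_mask(np.asarray(mask, bool), window)
        num, den = num[sel], den[sel]
    ok = den != 0
    skipped = int((~ok).sum())
    if skipped:
        logger.info("uqi: skipped %d zero-denominator windows", skipped)
    if not ok.any():
        raise ValueError("all windows have zero denominator")
    return float((num[ok] / den[ok]).mean())


def brain_bbox(mask) -> tuple:
    """Tightest axis-aligned box containing the mask.

    Returns half-open intervals ``(r0, r1, c0, c1)``.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask has no bounding box")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1


def mmr_ratio(core_mask, penumbra_mask) -> float:
    """Volume mismatch ratio: total core pixels / total penumbra pixels.

    Zero when both are empty; +inf when core exists without penumbra
    (classified severe downstream).
    """
    core = np.asarray(core_mask, bool)
    pen = np.asarray(penumbra_mask, bool)
    if core.shape != pen.shape:
        raise ValueError(f"mask grids differ: {core.shape} vs {pen.shape}")
    n_core = int(core.sum())
    n_pen = int(pen.sum())
    if n_pen == 0:
        return 0.0 if n_core == 0 else float("inf")
    return n_core / n_pen


@dataclass(frozen=True)
class SeverityClass:
    label: str
    ratio: float


def classify_severity(ratio: float) -> SeverityClass:
    """Three-way infarction severity from the mismatch ratio.

    0 -> none; (0, 0.5] -> mild_moderate; > 0.5 -> severe (the 0.5
    boundary is inclusive on the mild-to-moderate side).
    """
    if not np.isinf(ratio) and ratio < 0:
        raise ValueError(f"ratio must be >= 0, got {ratio}")
    if ratio == 0:
        label = "none"
    elif ratio <= 0.5:
        label = "mild_moderate"
    else:
        label = "severe"
    return SeverityClass(label=label, ratio=float(ratio))


def evaluate_cohort(gen, cases, consts: SSIMConstants | None = None,
                    uqi_window: int = 8, synthesize=None) -> pd.DataFrame:
    """Per-map, per-stratum SSIM/UQI table over phantom cases.

    For each case, paired samples are built with the standard
    preprocessing, maps are synthesized, mapped back to the [0, 1]
    physiological-range scale, and compared with the real normalized maps
    inside the brain bounding box.  Strata: all cases, mismatch ratio
    zero vs positive, and the three severity classes.
    """
    from .losses import unit_to_model
    from .network import generate_maps
    from .preprocess import pair_slices

    if synthesize is None:
        synthesize = lambda x: generate_maps(gen, x)  # noqa: E731
    per_case = []
    for case in cases:
        samples = pair_slices(case.ncct, case.maps, case.ctp_z_mm)
        if not samples:
            continue
        ratio = mmr_ratio(case.core_mask, case.penumbra_mask)
        sev = classify_severity(ratio).label
        bbox_mask = case.brain_mask.any(axis=0)
        r0, r1, c0, c1 = brain_bbox(bbox_mask)
        scores = {m: {"ssim": [], "uqi": []} for m in case.maps}
        for sample in samples:
            x = unit_to_model(sample.x[None].astype(np.float32))
            fake = synthesize(x)
            for m, real in sample.maps.items():
                syn = np.clip((fake[m][0, 0] + 1.0) / 2.0, 0.0, 1.0)
                real_c = real[r0:r1, c0:c1]
                syn_c = syn[r0:r1, c0:c1]
                scores[m]["ssim"].append(ssim(syn_c, real_c, consts))
                scores[m]["uqi"].append(uqi(syn_c, real_c, uqi_window))
        per_case.append({"ratio": ratio, "severity": sev,
                         "scores": {m: {k: float(np.mean(v))
                                        for k, v in d.items()}
                                    for m, d in scores.items()}})

    strata = {
        "all": lambda c: True,
        "ratio=0": lambda c: c["ratio"] == 0,
        "ratio>0": lambda c: c["ratio"] > 0,
        "none": lambda c: c["severity"] == "none",
        "mild_moderate": lambda c: c["severity"] == "mild_moderate",
        "severe": lambda c: c["severity"] == "severe",
    }
    map_types = list(cases[0].maps) if cases else []
    rows = []
    for name, pred in strata.items():
        sub = [c for c in per_case if pred(c)]
        for m in map_types:
            if sub:
                sv = [c["scores"][m]["ssim"] for c in sub]
                uv = [c["scores"][m]["uqi"] for c in sub]
                rows.append({"map_type": m, "stratum": name, "n": len(sub),
                             "ssim_mean": np.mean(sv), "ssim_sd": np.std(sv),
                             "uqi_mean": np.mean(uv), "uqi_sd": np.std(uv)})
            else:
                rows.append({"map_type": m, "stratum": name, "n": 0,
                             "ssim_mean": np.nan, "ssim_sd": np.nan,
                             "uqi_mean": np.nan, "uqi_sd": np.nan})
    return pd.DataFrame(rows)
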