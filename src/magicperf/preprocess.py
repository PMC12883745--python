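"""Raw volumes -> paired, normalized, augmented 2-D training samples.

Pipeline: HU windowing (center 40, width 80), skull stripping, pairing of
each coarse perfusion slice with three NCCT slices at -4/0/+4 mm stacked
as a pseudo-RGB image, physiological-range normalization of the maps, and
static augmentation (one joint random reflection/rotation/translation draw
applied identically to all seven channels).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology
from skimage.transform import resize as sk_resize

logger = logging.getLogger(__name__)

NCCT_OFFSET_MM = 4.0
MAX_CTP_SLICES = 10

ROTATION_RANGE_DEG = (-10.0, 10.0)
TRANSLATION_RANGE_PX = (-30, 30)
FLIP_PROBABILITY = 0.5


class PairingError(ValueError):
    pass


@dataclass(frozen=True)
class MapRange:
    """Physiological display range of one perfusion-map type."""

    map_type: str
    lo: float
    hi: float

    def __post_init__(self):
        if self.hi <= self.lo:
            raise ValueError(f"invalid range [{self.lo}, {self.hi}]")


#: defaults: CBF ml/100g/min, CBV ml/100g, MTT s, TTP s
MAP_RANGES = {
    "CBF": MapRange("CBF", 0.0, 60.0),
    "CBV": MapRange("CBV", 0.0, 4.0),
    "MTT": MapRange("MTT", 0.0, 12.0),
    "TTP": MapRange("TTP", 0.0, 25.0),
}


@dataclass
class PairedSample:
    """One training unit: pseudo-RGB NCCT + four normalized map slices."""

    x: np.ndarray                     # (3, S, S) in [0, 1]
    maps: dict                        # map type -> (S, S) in [0, 1]
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# intensity transforms
# ---------------------------------------------------------------------------

def window_hu(slice_hu, center: float = 40.0, width: float = 80.0) -> np.ndarray:
    """Linear display windowing of HU values onto [0, 1], clipped outside."""
    if width <= 0:
        raise ValueError(f"window width must be positive, got {width}")
    v = np.asarray(slice_hu, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite HU values")
    return np.clip((v - (center - width / 2.0)) / width, 0.0, 1.0)


def normalize_map(slice_phys, map_range: MapRange) -> np.ndarray:
    """(v - lo) / (hi - lo), clipped to [0, 1]."""
    v = np.asarray(slice_phys, dtype=float)
    return np.clip((v - map_range.lo) / (map_range.hi - map_range.lo), 0.0, 1.0)


def denormalize_map(slice_norm, map_range: MapRange) -> np.ndarray:
    """Inverse of :func:`normalize_map` on in-range values."""
    v = np.asarray(slice_norm, dtype=float)
    return v * (map_range.hi - map_range.lo) + map_range.lo


def skull_strip(slice_hu, closing_radius: int = 2):
    """Brain mask and masked windowed slice from a raw HU slice.

    Soft tissue is thresholded at HU in (0, 80), closed morphologically,
    hole-filled, and reduced to the largest connected component.  An empty
    mask (e.g. an all-air slice) is returned as-is with a logged warning;
    callers exclude such samples.
    """
    hu = np.asarray(slice_hu, dtype=float)
    soft = (hu > 0.0) & (hu < 80.0)
    soft = ndi.binary_closing(soft, structure=morphology.disk(closing_radius))
    soft = ndi.binary_fill_holes(soft)
    labels = measure.label(soft)
    if labels.max() == 0:
        logger.warning("skull_strip: empty brain mask; sample flagged")
        mask = np.zeros_like(soft, dtype=bool)
    else:
        largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
        mask = labels == largest
    return mask, window_hu(hu) * mask


def resize_image(img, size: int, order: int = 1) -> np.ndarray:
    """Resize to (size, size); bilinear for intensities, order=0 for masks."""
    return sk_resize(np.asarray(img, float), (size, size), order=order,
                     preserve_range=True, anti_aliasing=order > 0)


# ---------------------------------------------------------------------------
# slice pairing
# ---------------------------------------------------------------------------

def pair_slices(ncct, maps, ctp_z_mm, case_id: str = "",
                image_size: int | None = None, strip: bool = True,
                map_ranges: dict | None = None) -> list[PairedSample]:
    """Pair up to ten central CTP slices with +-4 mm NCCT neighbors.

    ``ncct`` is the 1 mm HU volume (z, H, W); ``maps`` are the CTP-grid
    physical-unit volumes; ``ctp_z_mm`` locates each CTP slice on the NCCT
    axial axis (mm == slice index).  Channels are ordered (below, center,
    above).  Slices whose neighbors fall outside the volume, or whose brain
    mask is empty, are skipped with a log entry.
    """
    ncct = np.asarray(ncct)
    ctp_z_mm = np.asarray(ctp_z_mm, dtype=float)
    ranges = map_ranges or MAP_RANGES
    n_ctp = len(ctp_z_mm)
    if any(np.asarray(v).shape[0] != n_ctp for v in maps.values()):
        raise PairingError(
            f"CTP volumes and ctp_z_mm disagree on slice count ({n_ctp})")
    offsets = ctp_z_mm - np.round(ctp_z_mm)
    if np.any(np.abs(offsets) > 1e-6):
        raise PairingError(
            f"CTP slice positions not aligned to the 1 mm NCCT grid: "
            f"offsets {offsets.tolist()}")

    # central-by-index selection of at most ten slices
    if n_ctp > MAX_CTP_SLICES:
        start = (n_ctp - MAX_CTP_SLICES) // 2
        selected = range(start, start + MAX_CTP_SLICES)
    else:
        selected = range(n_ctp)

    samples = []
    for k in selected:
        z = int(round(ctp_z_mm[k]))
        lo, hi = z - int(NCCT_OFFSET_MM), z + int(NCCT_OFFSET_MM)
        if lo < 0 or hi >= ncct.shape[0]:
            logger.info("pair_slices: CTP slice at z=%d mm lacks a +-4 mm "
                        "neighbor; skipped", z)
            continue
        if strip:
            mask, center = skull_strip(ncct[z])
            if not mask.any():
                logger.warning("pair_slices: empty brain mask at z=%d mm; "
                               "sample excluded", z)
                continue
            channels = [window_hu(ncct[lo]) * mask, center,
                        window_hu(ncct[hi]) * mask]
        else:
            channels = [window_hu(ncct[lo]), window_hu(ncct[z]),
                        window_hu(ncct[hi])]
        x = np.stack(channels).astype(np.float32)
        norm_maps = {m: normalize_map(np.asarray(vol)[k], ranges[m]).astype(np.float32)
                     for m, vol in maps.items()}
        if image_size is not None and x.shape[-1] != image_size:
            x = np.stack([resize_image(c, image_size) for c in x]).astype(np.float32)
            norm_maps = {m: resize_image(v, image_size).astype(np.float32)
                         for m, v in norm_maps.items()}
        samples.append(PairedSample(
            x=x, maps=norm_maps,
            meta={"case_id": case_id, "z_mm": float(z), "ctp_index": int(k),
                  "augmented": False}))
    return samples


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def _shift_int(img: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Integer translation with zero fill; +dr moves content down rows,
    +dc moves it rightward along columns."""
    out = np.zeros_like(img)
    h, w = img.shape
    r_src = slice(max(0, -dr), min(h, h - dr))
    c_src = slice(max(0, -dc), min(w, w - dc))
    r_dst = slice(max(0, dr), min(h, h + dr))
    c_dst = slice(max(0, dc), min(w, w + dc))
    out[r_dst, c_dst] = img[r_src, c_src]
    return out


def _apply_transform(img, flip: bool, angle_deg: float, shift) -> np.ndarray:
    out = np.asarray(img, float)
    if flip:
        out = out[:, ::-1]
    if angle_deg != 0.0:
        out = ndi.rotate(out, angle_deg, reshape=False, order=1, cval=0.0)
    out = _shift_int(out, int(shift[0]), int(shift[1]))
    return out


def draw_augmentation(rng: np.random.Generator) -> dict:
    return {
        "flip": bool(rng.random() < FLIP_PROBABILITY),
        "angle_deg": float(rng.uniform(*ROTATION_RANGE_DEG)),
        "shift": (int(rng.integers(TRANSLATION_RANGE_PX[0],
                                   TRANSLATION_RANGE_PX[1] + 1)),
                  int(rng.integers(TRANSLATION_RANGE_PX[0],
                                   TRANSLATION_RANGE_PX[1] + 1))),
    }


def augment(sample: PairedSample, seed=None, params: dict | None = None) -> PairedSample:
    """One joint transform draw applied identically to all seven channels.

    Reflection with p = 0.5, rotation uniform in [-10, 10] degrees,
    integer translations uniform in [-30, 30] px per axis; exposed pixels
    are zero-filled.  Deterministic for a fixed seed.
    """
    if params is None:
        rng = np.random.default_rng(seed)
        params = draw_augmentation(rng)
    x = np.stack([
        _apply_transform(c, params["flip"], params["angle_deg"], params["shift"])
        for c in sample.x]).astype(np.float32)
    maps = {m: _apply_transform(v, params["flip"], params["angle_deg"],
                                params["shift"]).astype(np.float32)
            for m, v in sample.maps.items()}
    meta = dict(sample.meta)
    meta.update(augmented=True, augmentation=params)
    return PairedSample(x=np.clip(x, 0.0, 1.0),
                        maps={m: np.clip(v, 0.0, 1.0) for m, v in maps.items()},
                        meta=meta)


def expand_dataset(samples, multiplier: int = 1, seed: int = 0) -> list[PairedSample]:
    """Static augmentation: append ``multiplier`` transformed copies of
    every sample (the original is kept)."""
    rng = np.random.default_rng(seed)
    out = list(samples)
    for _ in range(multiplier):
        for s in samples:
            out.append(augment(s, params=draw_augmentation(rng)))
    return out
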