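"""Composite physiology-informed GAN objective.

Components
----------
adversarial_loss
    Patch-wise binary cross-entropy over the PatchGAN probability grids,
    averaged over patches, batch and the N map types.  The generator side
    uses the non-saturating ``-log D(G(x))`` form by default.
l1_fidelity
    Mean absolute error between synthesized and real maps.
multimodal_loss
    Central Volume Principle coupling: ``| CBF_hat * MTT_hat - CBV |`` on
    normalized maps, tying the CBF and MTT branches together.
extrema_loss
    Weighted squared error emphasizing pixels far from the real map's
    midrange: weights ``W = (minmax(real) - 0.5)^2``, error
    ``H = (minmax(fake) - minmax(real))^2``, loss ``mean(W * H)``.

All component losses are non-negative and vanish exactly when their
defining equality holds.  Inputs may be numpy arrays or autograd Tensors;
Tensor inputs propagate gradients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .autograd import Tensor

logger = logging.getLogger(__name__)

EPS_PROB = 1e-7     # probability clipping for log terms
MODEL_LO, MODEL_HI = -1.0, 1.0


@dataclass(frozen=True)
class LossWeights:
    """Weights of the composite objective: total = GAN + l1*lambda1 +
    extrema*lambda2 + multimodal*lambda3.  The L1 weight follows the
    pix2pix convention; none of these is a published value."""

    lambda1: float = 100.0   # L1 fidelity
    lambda2: float = 100.0   # extrema
    lambda3: float = 10.0    # multimodal (Central Volume Principle)

    def __post_init__(self):
        for name in ("lambda1", "lambda2", "lambda3"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class LossReport:
    """Per-batch scalar components; total is the exact weighted sum."""

    gan_g: float
    gan_d: float
    l1: float
    extrema: float
    multimodal: float
    total: float

    def as_dict(self) -> dict:
        return dict(gan_g=self.gan_g, gan_d=self.gan_d, l1=self.l1,
                    extrema=self.extrema, multimodal=self.multimodal,
                    total=self.total)


def _as_list(x):
    return list(x.values()) if isinstance(x, dict) else list(np.atleast_1d(x)) \
        if not isinstance(x, (list, tuple)) else list(x)


def _mean_over(terms):
    total = None
    for t in terms:
        total = t if total is None else total + t
    return total * (1.0 / len(terms))


def adversarial_loss(d_real, d_fake, side: str):
    """Binary cross-entropy adversarial term on patch probability grids.

    ``d_real``/``d_fake`` are single grids or lists/dicts over map types;
    the result is averaged over the map types (1/N sum).  ``side``
    selects whose loss: 'discriminator' scores real as real and fake as
    fake; 'generator' (non-saturating) rewards fooling the discriminator.
    For the generator side ``d_real`` may be ``None``.
    """
    if side not in ("generator", "discriminator"):
        raise ValueError(f"side must be generator|discriminator, got {side!r}")
    fakes = _as_list(d_fake)
    terms = []
    if side == "discriminator":
        reals = _as_list(d_real)
        if len(reals) != len(fakes):
            raise ValueError("d_real and d_fake must cover the same map types")
        for pr, pf in zip(reals, fakes):
            pr = Tensor.as_tensor(pr).clip(EPS_PROB, 1.0 - EPS_PROB)
            pf = Tensor.as_tensor(pf).clip(EPS_PROB, 1.0 - EPS_PROB)
            terms.append(-(pr.log().mean() + (1.0 - pf).log().mean()))
    else:
        for pf in fakes:
            pf = Tensor.as_tensor(pf).clip(EPS_PROB, 1.0 - EPS_PROB)
            terms.append(-pf.log().mean())
    return _mean_over(terms)


def l1_fidelity(fake_maps, real_maps):
    """Mean |fake - real| over pixels, batch and map types."""
    fakes, reals = _as_list(fake_maps), _as_list(real_maps)
    if len(fakes) != len(reals):
        raise ValueError("fake and real map sets differ in length")
    terms = []
    for f, r in zip(fakes, reals):
        f, r = Tensor.as_tensor(f), Tensor.as_tensor(r)
        if f.data.shape != r.data.shape:
            raise ValueError(f"shape mismatch {f.data.shape} vs {r.data.shape}")
        terms.append((f - r).abs().mean())
    return _mean_over(terms)


def multimodal_loss(fake_cbf, fake_mtt, real_cbv, scale: str = "printed"):
    """Central-Volume-Principle coupling loss.

    Inputs are expected on the common normalized [0, 1] scale (callers
    holding model-range [-1, 1] tensors map them with
    :func:`model_to_unit` first).  With ``scale='printed'`` the plain
    product of normalized CBF and MTT is compared with normalized CBV,
    exactly as published.  ``scale='physical'`` rescales the product so
    the comparison is unit-consistent with the physiological ranges
    (CBF [0,60] ml/100g/min, MTT [0,12] s, CBV [0,4] ml/100g):
    cbv_n = 3 * cbf_n * mtt_n.
    """
    if scale not in ("printed", "physical"):
        raise ValueError(f"unknown mml scale {scale!r}")
    f_cbf = Tensor.as_tensor(fake_cbf)
    f_mtt = Tensor.as_tensor(fake_mtt)
    r_cbv = Tensor.as_tensor(real_cbv)
    if f_cbf.data.shape != f_mtt.data.shape or f_cbf.data.shape != r_cbv.data.shape:
        raise ValueError("CBF/MTT/CBV shapes differ")
    prod = f_cbf * f_mtt
    if scale == "physical":
        prod = prod * 3.0     # 60 * 12 / 60s-per-min / 4 = 3 on unit scales
    return (prod - r_cbv).abs().mean()


def model_to_unit(t):
    """Affine map from the model range [-1, 1] onto [0, 1]."""
    return (Tensor.as_tensor(t) - MODEL_LO) * (1.0 / (MODEL_HI - MODEL_LO))


def unit_to_model(a: np.ndarray) -> np.ndarray:
    """Affine map from [0, 1] onto the model (Tanh) range [-1, 1]."""
    return np.asarray(a) * (MODEL_HI - MODEL_LO) + MODEL_LO


def _minmax_normalize(t: Tensor):
    """Per-(sample, channel) min-max normalization to [0, 1]; a constant
    image (max == min) normalizes to all-zeros (guarded division)."""
    lo = t.amin_spatial()
    hi = t.amax_spatial()
    span = hi.data - lo.data
    if np.any(span == 0):
        # constant map: defined as all-zeros, no gradient contribution
        logger.warning("constant map in min-max normalization; "
                       "normalized image defined as all-zeros")
        safe = np.where(span == 0, 1.0, span)
        scaled = (t - lo) * Tensor(1.0 / safe)
        return scaled * Tensor((span != 0).astype(t.data.dtype))
    return (t - lo) / (hi - lo)


def extrema_weight(real_map) -> np.ndarray:
    """W = (minmax(real) - 0.5)^2; 0.25 at the extremes, 0 at midrange."""
    r = np.asarray(real_map.data if isinstance(real_map, Tensor) else real_map,
                   dtype=float)
    lo = r.min(axis=(-2, -1), keepdims=True)
    hi = r.max(axis=(-2, -1), keepdims=True)
    span = hi - lo
    norm = np.where(span == 0, 0.0, (r - lo) / np.where(span == 0, 1.0, span))
    return (norm - 0.5) ** 2


def extrema_loss(fake_map, real_map, return_parts: bool = False):
    """Weighted squared error between min-max-normalized maps.

    Accepts single maps or lists/dicts over map types (averaged 1/N).
    The weight matrix derives from the real map only and carries no
    gradient; the fake map is normalized by its own extrema.
    """
    fakes, reals = _as_list(fake_map), _as_list(real_map)
    if len(fakes) != len(reals):
        raise ValueError("fake and real map sets differ in length")
    terms, parts = [], []
    for f, r in zip(fakes, reals):
        f = Tensor.as_tensor(f)
        r_arr = np.asarray(r.data if isinstance(r, Tensor) else r, dtype=float)
        if f.data.shape != r_arr.shape:
            raise ValueError(f"shape mismatch {f.data.shape} vs {r_arr.shape}")
        w = extrema_weight(r_arr)
        lo = r_arr.min(axis=(-2, -1), keepdims=True)
        hi = r_arr.max(axis=(-2, -1), keepdims=True)
        span = hi - lo
        if np.any(span == 0):
            logger.warning("constant real map in extrema loss; its "
                           "normalization is defined as all-zeros")
        r_norm = np.where(span == 0, 0.0,
                          (r_arr - lo) / np.where(span == 0, 1.0, span))
        f_norm = _minmax_normalize(f)
        h = (f_norm - Tensor(r_norm)).square()
        terms.append((h * Tensor(w)).mean())
        if return_parts:
            parts.append((w, h.data))
    loss = _mean_over(terms)
    return (loss, parts) if return_parts else loss


def total_objective(gan_g, l1, extrema, multimodal, weights: LossWeights):
    """Exact weighted sum of the generator-side components."""
    return gan_g + weights.lambda1 * l1 + weights.lambda2 * extrema \
        + weights.lambda3 * multimodal
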