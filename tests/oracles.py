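"""Independent brute-force reference implementations used as test oracles.

Everything here is written as directly as possible from the defining
formulas (explicit loops, no shared code with the package) so that
agreement between the package and these functions is meaningful.
"""

import numpy as np


# ---------------------------------------------------------------------------
# convolution arithmetic
# ---------------------------------------------------------------------------

def conv2d_loops(x, w, b, stride, pad):
    """Direct quadruple-loop 2-D cross-correlation."""
    n, ci, h, wd = x.shape
    co, _, k, _ = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - k) // stride + 1
    wo = (wd + 2 * pad - k) // stride + 1
    y = np.zeros((n, co, ho, wo))
    for ni in range(n):
        for oi in range(co):
            for r in range(ho):
                for c in range(wo):
                    patch = xp[ni, :, r * stride:r * stride + k,
                               c * stride:c * stride + k]
                    y[ni, oi, r, c] = (patch * w[oi]).sum()
            if b is not None:
                y[ni, oi] += b[oi]
    return y


def conv_transpose2d_loops(x, w, b, stride, pad):
    """Direct scatter implementation of transposed convolution."""
    n, ci, h, wd = x.shape
    _, co, k, _ = w.shape
    ho = stride * (h - 1) + k - 2 * pad
    wo = stride * (wd - 1) + k - 2 * pad
    y = np.zeros((n, co, ho + 2 * pad, wo + 2 * pad))
    for ni in range(n):
        for ii in range(ci):
            for r in range(h):
                for c in range(wd):
                    y[ni, :, r * stride:r * stride + k,
                      c * stride:c * stride + k] += x[ni, ii, r, c] * w[ii]
    y = y[:, :, pad:pad + ho, pad:pad + wo]
    if b is not None:
        y += b[None, :, None, None]
    return y


def conv_param_count(c_in, c_out, k, bias=True):
    return k * k * c_in * c_out + (c_out if bias else 0)


def generator_param_count(input_channels, enc_shared, enc_branch, dec, k,
                          n_maps, pilo_k=1):
    """Layer-by-layer arithmetic for the shared-encoder multitask U-Net."""
    total = 0
    prev = input_channels
    for c in enc_shared:
        total += conv_param_count(prev, c, k)
        prev = c
    per_branch = 0
    prev_b = enc_shared[-1]
    for c in enc_branch:
        per_branch += conv_param_count(prev_b, c, k)
        prev_b = c
    enc_all = list(enc_shared) + list(enc_branch)
    depth = len(enc_all)
    dec_in = [enc_all[-1]]
    for i in range(2, depth + 1):
        dec_in.append(dec[i - 2] + enc_all[depth - i])
    for ci, co in zip(dec_in, dec):
        per_branch += conv_param_count(ci, co, k)
    per_branch += conv_param_count(1 + input_channels, 1, pilo_k)
    return total + n_maps * per_branch


def patchgan_param_count(in_channels, channels, k):
    total = 0
    prev = in_channels
    for c in channels:
        total += conv_param_count(prev, c, k)
        prev = c
    return total


# ---------------------------------------------------------------------------
# losses (per-element evaluation)
# ---------------------------------------------------------------------------

def bce_discriminator(d_real_list, d_fake_list, eps=1e-7):
    terms = []
    for pr, pf in zip(d_real_list, d_fake_list):
        pr = np.clip(pr, eps, 1 - eps)
        pf = np.clip(pf, eps, 1 - eps)
        terms.append(-(np.log(pr).mean() + np.log(1 - pf).mean()))
    return float(np.mean(terms))


def bce_generator(d_fake_list, eps=1e-7):
    return float(np.mean([-np.log(np.clip(pf, eps, 1 - eps)).mean()
                          for pf in d_fake_list]))


def l1_mean(fakes, reals):
    return float(np.mean([np.abs(f - r).mean() for f, r in zip(fakes, reals)]))


def multimodal(f_cbf, f_mtt, r_cbv):
    return float(np.abs(f_cbf * f_mtt - r_cbv).mean())


def minmax01(img):
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def extrema(fakes, reals):
    """Eqs for the weighted extrema loss, one (N,1,H,W)-style pair list."""
    terms = []
    for f, r in zip(fakes, reals):
        per_image = []
        for fi, ri in zip(f.reshape(-1, *f.shape[-2:]),
                          r.reshape(-1, *r.shape[-2:])):
            w = (minmax01(ri) - 0.5) ** 2
            h = (minmax01(fi) - minmax01(ri)) ** 2
            per_image.append((w * h).mean())
        terms.append(np.mean(per_image))
    return float(np.mean(terms))


# ---------------------------------------------------------------------------
# windowed image-quality metrics
# ---------------------------------------------------------------------------

def ssim_windows(x, y, k=11, sigma=1.5, c1=0.01 ** 2, c2=0.03 ** 2,
                 uniform=False):
    """Direct per-window evaluation over all valid window positions."""
    ax = np.arange(k) - (k - 1) / 2.0
    if uniform:
        w = np.ones((k, k))
    else:
        g = np.exp(-(ax ** 2) / (2 * sigma ** 2))
        w = np.outer(g, g)
    w = w / w.sum()
    h, wd = x.shape
    vals = []
    for r in range(h - k + 1):
        for c in range(wd - k + 1):
            xa = x[r:r + k, c:c + k]
            ya = y[r:r + k, c:c + k]
            mx = (w * xa).sum()
            my = (w * ya).sum()
            vx = (w * xa * xa).sum() - mx ** 2
            vy = (w * ya * ya).sum() - my ** 2
            cov = (w * xa * ya).sum() - mx * my
            vals.append(((2 * mx * my + c1) * (2 * cov + c2))
                        / ((mx ** 2 + my ** 2 + c1) * (vx + vy + c2)))
    return float(np.mean(vals))


def uqi_windows(x, y, k=8):
    """Direct per-window universal quality index, skipping zero denominators."""
    h, wd = x.shape
    vals = []
    for r in range(h - k + 1):
        for c in range(wd - k + 1):
            xa = x[r:r + k, c:c + k].ravel()
            ya = y[r:r + k, c:c + k].ravel()
            mx, my = xa.mean(), ya.mean()
            vx, vy = xa.var(), ya.var()
            cov = ((xa - mx) * (ya - my)).mean()
            den = (vx + vy) * (mx ** 2 + my ** 2)
            if den != 0:
                vals.append(4 * cov * mx * my / den)
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# kappa from hand-summed marginals
# ---------------------------------------------------------------------------

def kappa_by_hand(a, b):
    cats = sorted(set(list(a) + list(b)))
    n = len(a)
    po = sum(1 for x, y in zip(a, b) if x == y) / n
    pe = 0.0
    for c in cats:
        pa = sum(1 for x in a if x == c) / n
        pb = sum(1 for y in b if y == c) / n
        pe += pa * pb
    return (po - pe) / (1 - pe)
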