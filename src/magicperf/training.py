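"""Alternating discriminator/generator optimization and volumetric inference.

Each iteration takes one discriminator step per map type on real and
detached-fake pairs, then freezes the discriminators and takes one
generator step on the composite objective (adversarial + L1 + extrema +
multimodal).  Adam with beta1 = 0.5, beta2 = 0.999 and a constant learning
rate of 1e-4 for both sides.  A fixed validation subset, drawn once at the
start, is scored with the generator L1 after every epoch.

``infer_volume`` applies the trained generator slice by slice along a 1 mm
NCCT volume, yielding perfusion volumes at 1 mm axial spacing (the coarse
10 mm training grid is only a constraint of paired acquisition, not of
inference).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import losses as L
from .autograd import Tensor, concat
from .network import (Generator, ModelConfig, build_discriminators,
                      build_generator, generate_maps)
from .preprocess import MAP_RANGES, denormalize_map, skull_strip, window_hu

logger = logging.getLogger(__name__)


class TrainingError(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    """Optimization schedule; defaults mirror the full-scale recipe."""

    epochs: int = 50
    batch_size: int = 8
    lr_g: float = 1e-4
    lr_d: float = 1e-4
    adam_beta1: float = 0.5
    adam_beta2: float = 0.999
    val_images: int = 100
    seed: int = 0
    mml_scale: str = "printed"         # printed | physical
    saturating: bool = False           # saturating generator GAN term

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    @classmethod
    def tiny(cls, seed: int = 0, epochs: int = 5) -> "TrainConfig":
        """Desk-scale preset used throughout the test suite."""
        return cls(epochs=epochs, val_images=10, seed=seed)


class Adam:
    """Adam over a parameter list (decoupled per-tensor state)."""

    def __init__(self, params, lr: float, beta1: float = 0.5,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        if self.lr == 0.0:
            return
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p.data -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)


def _batch_arrays(samples, idx, map_types):
    x = np.stack([samples[i].x for i in idx]).astype(np.float32)
    reals = {m: np.stack([samples[i].maps[m] for i in idx])[:, None].astype(np.float32)
             for m in map_types}
    return L.unit_to_model(x).astype(np.float32), \
        {m: L.unit_to_model(v).astype(np.float32) for m, v in reals.items()}


def _set_requires_grad(model, flag: bool):
    for p in model.parameters():
        p.requires_grad = flag


def validation_l1(gen: Generator, samples, indices, map_types) -> float:
    """Mean generator L1 (model scale) over a fixed validation subset."""
    vals = []
    for i in indices:
        x, reals = _batch_arrays(samples, [i], map_types)
        fake = generate_maps(gen, x)
        vals.append(float(np.mean([np.abs(fake[m] - reals[m]).mean()
                                   for m in map_types])))
    return float(np.mean(vals))


def cvp_violation(gen: Generator, samples, indices, map_types,
                  masks=None) -> float:
    """Mean |cbv_hat - cbf_hat * mtt_hat| of synthesized maps on the
    normalized [0, 1] scale; the quantity the multimodal loss targets.

    ``masks`` (optional, indexed like ``samples``) restricts the average
    to brain tissue, where the Central Volume Principle is physiologically
    defined; background voxels carry no perfusion.
    """
    vals = []
    for i in indices:
        x, _ = _batch_arrays(samples, [i], map_types)
        fake = generate_maps(gen, x)
        cbf = (fake["CBF"][0, 0] + 1.0) / 2.0
        mtt = (fake["MTT"][0, 0] + 1.0) / 2.0
        cbv = (fake["CBV"][0, 0] + 1.0) / 2.0
        v = np.abs(cbf * mtt - cbv)
        if masks is not None:
            v = v[np.asarray(masks[i], bool)]
        vals.append(float(v.mean()))
    return float(np.mean(vals))


def train(samples, model_cfg: ModelConfig, train_cfg: TrainConfig,
          weights: L.LossWeights | None = None, out_dir=None):
    """Alternating GAN training; returns (generator, discriminators, history).

    History is a list of per-epoch dicts (mean training components plus the
    fixed-subset validation L1).  If ``out_dir`` is given, a JSONL log and
    final weight checkpoint are written there.
    """
    if len(samples) == 0:
        raise TrainingError("empty dataset")
    weights = weights or L.LossWeights()
    map_types = model_cfg.map_types
    rng = np.random.default_rng(train_cfg.seed)

    gen = build_generator(model_cfg, seed=int(rng.integers(2 ** 31 - 1)))
    discs = build_discriminators(model_cfg, seed=int(rng.integers(2 ** 31 - 1)))
    opt_g = Adam(gen.parameters(), train_cfg.lr_g,
                 train_cfg.adam_beta1, train_cfg.adam_beta2)
    opt_d = {m: Adam(d.parameters(), train_cfg.lr_d,
                     train_cfg.adam_beta1, train_cfg.adam_beta2)
             for m, d in discs.items()}

    n = len(samples)
    n_val = min(train_cfg.val_images, max(1, n // 5))
    val_idx = rng.choice(n, size=n_val, replace=False)
    train_idx = np.setdiff1d(np.arange(n), val_idx)
    if len(train_idx) == 0:
        raise TrainingError("no training samples left after validation split")

    log_path = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        log_path = out_dir / "training_log.jsonl"

    history = []
    for epoch in range(1, train_cfg.epochs + 1):
        order = rng.permutation(train_idx)
        epoch_report = {k: [] for k in
                        ("gan_g", "gan_d", "l1", "extrema", "multimodal", "total")}
        for b0 in range(0, len(order), train_cfg.batch_size):
            idx = order[b0:b0 + train_cfg.batch_size]
            x, reals = _batch_arrays(samples, idx, map_types)
            batch_id = f"epoch{epoch}_batch{b0 // train_cfg.batch_size}"

            # --- discriminator step on real and detached fake pairs -------
            fake_detached = generate_maps(gen, x)
            d_losses = []
            for m in map_types:
                d = discs[m]
                d.zero_grad()
                pr = d(np.concatenate([x, reals[m]], axis=1))
                pf = d(np.concatenate([x, fake_detached[m].astype(np.float32)],
                                      axis=1))
                ld = L.adversarial_loss(pr, pf, "discriminator")
                ld.backward()
                opt_d[m].step()
                d_losses.append(ld.item())
            gan_d = float(np.mean(d_losses))

            # --- generator step with discriminators frozen ----------------
            for d in discs.values():
                _set_requires_grad(d, False)
            gen.zero_grad()
            fake = gen(x)
            d_fake = {m: discs[m](concat([Tensor(x), fake[m]], axis=1))
                      for m in map_types}
            if train_cfg.saturating:
                gan_g = _saturating_g(d_fake)
            else:
                gan_g = L.adversarial_loss(None, d_fake, "generator")
            fake_list = [fake[m] for m in map_types]
            real_list = [reals[m] for m in map_types]
            l1 = L.l1_fidelity(fake_list, real_list)
            ext = L.extrema_loss(fake_list, real_list)
            mml = L.multimodal_loss(L.model_to_unit(fake["CBF"]),
                                    L.model_to_unit(fake["MTT"]),
                                    L.model_to_unit(reals["CBV"]),
                                    scale=train_cfg.mml_scale)
            total = L.total_objective(gan_g, l1, ext, mml, weights)
            if not np.isfinite(total.item()):
                raise TrainingError(
                    f"non-finite generator loss at {batch_id}: "
                    f"gan={gan_g.item()} l1={l1.item()} ext={ext.item()} "
                    f"mml={mml.item()}")
            total.backward()
            opt_g.step()
            for d in discs.values():
                _set_requires_grad(d, True)

            report = L.LossReport(gan_g=gan_g.item(), gan_d=gan_d,
                                  l1=l1.item(), extrema=ext.item(),
                                  multimodal=mml.item(), total=total.item())
            for k, v in report.as_dict().items():
                epoch_report[k].append(v)

        entry = {"epoch": epoch,
                 **{k: float(np.mean(v)) for k, v in epoch_report.items()},
                 "val_l1": validation_l1(gen, samples, val_idx, map_types)}
        history.append(entry)
        logger.info("epoch %d: %s", epoch, entry)
        if log_path is not None:
            with open(log_path, "a") as fh:
                fh.write(json.dumps(entry) + "\n")

    if out_dir is not None:
        save_checkpoint(out_dir / "checkpoint.npz", gen, discs, model_cfg,
                        train_cfg.seed)
    return gen, discs, history


def _saturating_g(d_fake) -> Tensor:
    """Printed (saturating) generator term: mean log(1 - D(G(x)))."""
    terms = []
    for pf in d_fake.values():
        pf = Tensor.as_tensor(pf).clip(L.EPS_PROB, 1.0 - L.EPS_PROB)
        terms.append((1.0 - pf).log().mean())
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total * (1.0 / len(terms))


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(path, gen, discs, model_cfg: ModelConfig, seed: int) -> None:
    from dataclasses import asdict
    arrays = {}
    for i, a in enumerate(gen.state_dict()):
        arrays[f"g_{i}"] = a
    for m, d in discs.items():
        for i, a in enumerate(d.state_dict()):
            arrays[f"d_{m}_{i}"] = a
    cfg = {k: (list(v) if isinstance(v, tuple) else v)
           for k, v in asdict(model_cfg).items()}
    np.savez_compressed(path, __meta__=json.dumps({"config": cfg, "seed": seed}),
                        **arrays)


def load_checkpoint(path):
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["__meta__"]))
    cfg = {k: (tuple(v) if isinstance(v, list) else v)
           for k, v in meta["config"].items()}
    model_cfg = ModelConfig(**cfg)
    gen = build_generator(model_cfg, seed=0)
    n_g = len(gen.state_dict())
    gen.load_state_dict([data[f"g_{i}"] for i in range(n_g)])
    discs = build_discriminators(model_cfg, seed=0)
    for m, d in discs.items():
        n_d = len(d.state_dict())
        d.load_state_dict([data[f"d_{m}_{i}"] for i in range(n_d)])
    return gen, discs, model_cfg


# ---------------------------------------------------------------------------
# volumetric inference
# ---------------------------------------------------------------------------

def infer_volume(gen: Generator, ncct, strip: bool = True):
    """Per-slice synthesis over a 1 mm NCCT volume.

    Every axial slice with both +-4 mm neighbors inside the volume gets a
    pseudo-RGB stack and an independent forward pass; outputs are
    denormalized to physical units and clipped to the physiological
    ranges.  Returns ``(maps, z_indices)`` where each map volume has one
    slice per valid index.
    """
    ncct = np.asarray(ncct)
    off = 4
    if ncct.shape[0] < 2 * off + 1:
        raise ValueError(
            f"volume of {ncct.shape[0]} slices is thinner than 9 mm")
    z_indices = list(range(off, ncct.shape[0] - off))
    out = {m: [] for m in gen.cfg.map_types}
    for z in z_indices:
        if strip:
            mask, center = skull_strip(ncct[z])
            channels = [window_hu(ncct[z - off]) * mask, center,
                        window_hu(ncct[z + off]) * mask]
        else:
            channels = [window_hu(ncct[z - off]), window_hu(ncct[z]),
                        window_hu(ncct[z + off])]
        x = L.unit_to_model(np.stack(channels)[None]).astype(np.float32)
        fake = generate_maps(gen, x)
        for m in gen.cfg.map_types:
            unit = np.clip((fake[m][0, 0] + 1.0) / 2.0, 0.0, 1.0)
            phys = denormalize_map(unit, MAP_RANGES[m])
            out[m].append(np.clip(phys, MAP_RANGES[m].lo, MAP_RANGES[m].hi))
    return {m: np.stack(v) for m, v in out.items()}, z_indices
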