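"""Model/Results interface over the synthesis pipeline.

``PerfusionGAN`` is constructed from a dataset of paired samples (or
directly from phantom cases); ``fit()`` runs the alternating adversarial
optimization and returns a ``PerfusionGANResults`` carrying the trained
networks, the loss history, and evaluation/prediction methods.
"""

from __future__ import annotations


import pandas as pd

from .losses import LossWeights
from .network import ModelConfig, count_parameters
from .training import (TrainConfig, cvp_violation, infer_volume,
                       load_checkpoint, save_checkpoint, validation_l1)


class PerfusionGAN:
    """Multitask image-to-image model mapping NCCT to four perfusion maps.

    Parameters
    ----------
    samples : list of PairedSample
        Normalized training units from :func:`magicperf.preprocess.pair_slices`.
    model_config : ModelConfig, optional
        Architecture; defaults to the full 256-px configuration.
    loss_weights : LossWeights, optional
        Composite-objective weights.
    """

    def __init__(self, samples, model_config: ModelConfig | None = None,
                 loss_weights: LossWeights | None = None):
        self.samples = list(samples)
        self.model_config = model_config or ModelConfig()
        self.loss_weights = loss_weights or LossWeights()

    @classmethod
    def from_phantoms(cls, cases, model_config: ModelConfig | None = None,
                      loss_weights: LossWeights | None = None,
                      augment_multiplier: int = 0, seed: int = 0):
        """Build the training set from phantom cases with the standard
        preprocessing (windowing, skull stripping, pairing, normalization,
        optional static augmentation)."""
        from .preprocess import expand_dataset, pair_slices
        cfg = model_config or ModelConfig()
        samples = []
        for i, case in enumerate(cases):
            samples.extend(pair_slices(case.ncct, case.maps, case.ctp_z_mm,
                                       case_id=f"case{i:04d}",
                                       image_size=cfg.image_size))
        if augment_multiplier > 0:
            samples = expand_dataset(samples, augment_multiplier, seed)
        return cls(samples, cfg, loss_weights)

    def fit(self, train_config: TrainConfig | None = None,
            out_dir=None) -> "PerfusionGANResults":
        from .training import train
        tc = train_config or TrainConfig()
        gen, discs, history = train(self.samples, self.model_config, tc,
                                    self.loss_weights, out_dir=out_dir)
        return PerfusionGANResults(self, gen, discs, history, tc)


class PerfusionGANResults:
    """Fitted synthesis model: trained networks plus training diagnostics."""

    def __init__(self, model: PerfusionGAN, generator, discriminators,
                 history, train_config: TrainConfig):
        self.model = model
        self.generator = generator
        self.discriminators = discriminators
        self.history = pd.DataFrame(history)
        self.train_config = train_config

    # -- prediction -----------------------------------------------------------
    def predict(self, ncct_volume, strip: bool = True):
        """Per-slice volumetric inference on a 1 mm NCCT volume; returns
        ``(maps, z_indices)`` in physical units."""
        return infer_volume(self.generator, ncct_volume, strip=strip)

    def set_pilo_ratio(self, map_type: str, ratio: float) -> None:
        self.generator.set_pilo_ratio(map_type, ratio)

    # -- evaluation -----------------------------------------------------------
    def evaluate(self, cases) -> pd.DataFrame:
        """SSIM/UQI table per map type and severity stratum."""
        from .metrics import evaluate_cohort
        return evaluate_cohort(self.generator, cases)

    def validation_l1(self, indices=None) -> float:
        idx = indices if indices is not None else range(len(self.model.samples))
        return validation_l1(self.generator, self.model.samples, idx,
                             self.model.model_config.map_types)

    def cvp_violation(self, indices=None, masks=None) -> float:
        idx = indices if indices is not None else range(len(self.model.samples))
        return cvp_violation(self.generator, self.model.samples, idx,
                             self.model.model_config.map_types, masks=masks)

    # -- persistence ----------------------------------------------------------
    def save(self, path) -> None:
        save_checkpoint(path, self.generator, self.discriminators,
                        self.model.model_config, self.train_config.seed)

    @classmethod
    def load(cls, path, samples=()) -> "PerfusionGANResults":
        gen, discs, model_cfg = load_checkpoint(path)
        model = PerfusionGAN(samples, model_cfg)
        return cls(model, gen, discs, [], TrainConfig(epochs=1))

    # -- reporting ------------------------------------------------------------
    def summary(self) -> str:
        cfg = self.model.model_config
        w = self.model.loss_weights
        n_g = count_parameters(self.generator)
        n_d = sum(count_parameters(d) for d in self.discriminators.values())
        lines = [
            "Perfusion synthesis GAN results",
            "=" * 47,
            f"{'image size':<28}{cfg.image_size}",
            f"{'map types':<28}{', '.join(cfg.map_types)}",
            f"{'generator parameters':<28}{n_g:,}",
            f"{'discriminator parameters':<28}{n_d:,}",
            f"{'training samples':<28}{len(self.model.samples)}",
            f"{'epochs':<28}{self.train_config.epochs}",
            f"{'batch size':<28}{self.train_config.batch_size}",
            f"{'lambda (L1, extrema, MML)':<28}"
            f"{w.lambda1:g}, {w.lambda2:g}, {w.lambda3:g}",
        ]
        if len(self.history):
            first, last = self.history.iloc[0], self.history.iloc[-1]
            lines += [
                "-" * 47,
                f"{'validation L1 (epoch 1)':<28}{first['val_l1']:.4f}",
                f"{'validation L1 (final)':<28}{last['val_l1']:.4f}",
                f"{'generator GAN loss (final)':<28}{last['gan_g']:.4f}",
                f"{'discriminator loss (final)':<28}{last['gan_d']:.4f}",
            ]
        return "\n".join(lines)

    def __repr__(self):
        return (f"<PerfusionGANResults: {len(self.history)} epochs, "
                f"{len(self.model.samples)} samples>")
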