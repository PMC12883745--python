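# Methods

## Problem and model

`magicperf` synthesizes the four standard CT-perfusion parameter maps —
cerebral blood volume (CBV, ml/100 g), cerebral blood flow (CBF,
ml/100 g/min), mean transit time (MTT, s) and time-to-peak (TTP, s) — from
non-contrast head CT (NCCT) alone, using a conditional image-to-image GAN.
The generator is a multitask U-Net: four shared encoding layers extract
anatomical features common to all map types, four private encoding layers
per map compress to a 1×1×512 bottleneck, and eight transposed-convolution
decoding layers with skip concatenations reconstruct each map. Each branch
ends in a physician-in-the-loop (PILO) layer, a 1×1 transposed convolution
that mixes the decoded perfusion channel with the three anatomical
(pseudo-RGB NCCT) channels; rescaling its channel weights trades
hemodynamic against anatomical content at inference time without
retraining. Each map type has an independent 70×70 PatchGAN discriminator
judging `[NCCT ‖ map]` stacks patch-wise.

The training objective combines four terms:

- **adversarial** — patch-wise binary cross-entropy, averaged over the
  N = 4 map types; the generator side uses the non-saturating
  `−log D(G(x))` form (a config flag restores the saturating form);
- **L1 fidelity** — mean absolute error between synthesized and real maps;
- **extrema** — squared error between min–max-normalized maps, weighted by
  `W = (minmax(real) − 0.5)²`, which emphasizes pixels far from the
  midrange — precisely the hypo-/hyper-perfused regions that carry the
  diagnosis;
- **multimodal** — `‖ CBF̂ ⊙ MTT̂ − CBV ‖₁` on normalized maps, an
  expression of the Central Volume Principle (CVP), CBV = CBF × MTT (with
  MTT in minutes for unit consistency), which couples the CBF and MTT
  branches through a shared physiological constraint.

Weights: `total = gan + λ₁·L1 + λ₂·extrema + λ₃·multimodal` with defaults
λ₁ = 100 (the pix2pix convention for the reconstruction term), λ₂ = 100,
λ₃ = 10. These are package defaults, logged with every run; no published
values exist for them.

The multimodal term is applied to [0, 1]-normalized maps exactly as the
product form above (`mml_scale: printed`). Note that on the normalized
scales implied by the physiological display ranges (CBF [0, 60],
MTT [0, 12], CBV [0, 4]) the unit-consistent relation is
`cbv_n = 3 · cbf_n · mtt_n`; the `mml_scale: physical` option provides that
variant. The printed form is the default because it is the form the loss
is defined with; the physical form is the one the phantom's ground-truth
maps satisfy exactly.

## Parameter accounting

The published totals (209,352,408 generator parameters; 11,063,044 for the
four discriminators) pin down the architecture conventions exactly: every
convolution carries a bias, normalization layers are parameter-free
(instance-style), the first shared conv and the bottleneck conv carry no
norm, decoder channels are (512, 512, 512, 512, 256, 128, 64, 1) with
skip-concatenated inputs (512, 1024, 1024, 1024, 1024, 512, 256, 128), and
the PILO layer is a biased 1×1 transposed conv with 4→1 channels
(5 parameters per branch). Per-layer subtotals: shared encoder 2,756,544;
each branch 51,648,966; each PatchGAN 2,765,761. `count_parameters` is
checked against an independent closed-form layer-arithmetic oracle in the
tests. Enabling affine normalization would change the totals and is
rejected by the config.

Because the discriminator input that reproduces the printed count is the
4-channel `[NCCT ‖ map]` stack, the real/fake "matrix of ones/zeros" is
interpreted as the patch-grid target labels, not as a fifth input channel.

## Numerical and design choices

- **Backend.** The networks run on a small tape-based reverse-mode
  autodiff engine over numpy (im2col convolutions, exact
  conv/conv-transpose adjoint pair, parameter-free instance norm). All
  primitives are verified against direct-loop forwards and central finite
  differences. Float32 weights; Adam (β₁ = 0.5, β₂ = 0.999), constant
  learning rate 1e-4 for both sides, batch size 8.
- **Final activation.** The decoder's last transposed conv is linear, the
  PILO layer mixes `[map ‖ NCCT]`, and Tanh follows the PILO layer, so the
  advertised output range [−1, 1] holds for the actual network output.
- **Initialization.** Gaussian mean 0, sd 0.02 (pix2pix convention),
  seeded — except the PILO layer, which uses a fan-in-aware
  `1/√(fan_in)` scale: its fan-in is 4, two orders of magnitude below the
  fan-ins the 0.02 convention is calibrated for, and with 0.02 the output
  magnitude starts ~25× too small for gradients to move the model at desk
  scale.
- **Freezing.** Each iteration takes one discriminator step per map type
  on real and detached-fake pairs, then one generator step with all
  discriminator parameters frozen (asserted by hashing in the tests).
- **Probability clipping.** Discriminator outputs are clipped to
  [1e-7, 1 − 1e-7] inside the log terms.
- **Degenerate maps.** A constant map's min–max normalization is defined
  as all-zeros with a logged warning (division guard); for a constant
  *real* map this makes the extrema weight 0.25 everywhere.
- **Validation.** A fixed subset (default 100 images, capped at 20% for
  small datasets) is drawn once before training; the generator L1 on it is
  recorded every epoch. Resampling each epoch would make curves
  incomparable.
- **Decoder activation** is ReLU (pix2pix convention; LeakyReLU 0.2 in all
  encoder and discriminator convs), switchable by config.

## Digital head phantom

The phantom supplies paired NCCT/CTP volumes with the structural features
the pipeline relies on, not radiographic realism:

- **Geometry.** Concentric ellipses per axial slice: skull ring 1000 HU,
  brain parenchyma 25–45 HU with smooth texture, paired ventricles 5 HU,
  air −1000 HU; additive Gaussian HU noise (default sd 2). Geometry is
  z-invariant; NCCT is sampled at 1 mm axially (101 slices by default) and
  the perfusion grid at 10 mm (10 slices, centered).
- **Baseline perfusion.** Band-limited Gaussian random fields, min–max
  scaled to CBF [30, 60] ml/100 g/min, MTT [3, 6] s, TTP [4, 10] s, then
  mirror-symmetrized across the mid-sagittal plane. Symmetrization makes
  the relative-CBF core rule exact by construction: a core scaled to
  < 30% of its own baseline is automatically < 30% of the mirrored
  contralateral value. MTT is capped at 240/CBF so the derived
  CBV = CBF·MTT/60 never exceeds its 4 ml/100 g ceiling (physiologically,
  high flow pairs with shorter transit). CBV is always *derived*, making
  the CVP an exact invariant (≤ 1e-6 everywhere in brain), and is
  recomputed after every lesion edit.
- **Lesions.** Spherical core-within-penumbra geometry on the CTP grid.
  Core: CBF × 0.2 (any fraction < 0.3 keeps the core rule exact), MTT
  doubled (capped at 12 s), TTP delayed; CBV consequently reduced.
  Penumbra ring: MTT × 1.5 (capped), CBF rescaled so CBV is preserved
  exactly, TTP delayed by > 6 s (the penumbra definition; the delay is
  encoded in TTP because the commercial Tmax map is never synthesized and
  the downstream consumers are the masks, which are stored explicitly).
  A mild 5 HU hypodensity is stamped into the NCCT core, mimicking early
  ischemic hypoattenuation and giving the generator an anatomical
  correlate to learn from.
- **Severity.** The mismatch ratio (total core pixels / total penumbra
  pixels over the volume) classifies cases as none (0), mild-to-moderate
  ((0, 0.5]) or severe (> 0.5); core-without-penumbra yields an infinite
  ratio, classified severe.

What the phantom does **not** emulate: CT physics (beam hardening, photon
statistics), anatomical variability, registration error between series,
and time-attenuation-curve hemodynamics. Tests passing on the phantom
therefore demonstrate the correctness of the pipeline's mechanics and the
physiological consistency of the synthesis objective — not clinical-grade
image quality on patient data, which would require the (undeposited)
clinical cohort and full-scale training.

## Desk-scale training protocol

Full-scale training (256 px, 209M parameters, tens of thousands of paired
slices, 50 epochs) is a multi-day accelerator workload and is not part of
the test surface. The canonical desk-scale configuration used by the test
suite and the acceptance script is: 64 px images, depth-6 generator with
8 base channels (~1.8M parameters), 5 phantom cases → 50 paired samples,
5 epochs, batch 8, fixed seed. Two properties are asserted there:

1. the fixed-subset validation L1 strictly decreases from epoch 1 to the
   final epoch;
2. enabling the multimodal term (λ₃ = 10 vs λ₃ = 0, same seed and epochs)
   lowers the mean CVP violation `|cbv̂ − cbf̂·mtt̂|` of synthesized maps,
   averaged inside the brain mask. The brain restriction is deliberate:
   the CVP is a tissue property and the background carries no perfusion,
   so including background pixels measures mostly how fast both runs
   learn the air/brain split.

At 35 optimizer steps these are direction checks, not convergence claims;
the effect sizes are small (relative differences of ~0.5%) but
reproducible across seeds.

## Image-quality metrics

SSIM uses an 11×11 Gaussian window (σ = 1.5) with stabilizers
c₁ = (0.01·L)², c₂ = (0.03·L)², L = 1 on [0, 1]-normalized maps; UQI uses
8×8 uniform sliding windows with zero stabilizers and skips (and counts)
zero-denominator windows. Both are evaluated on valid window positions
only and averaged — optionally over windows whose centers fall in a mask —
because whole-image moments would be insensitive to focal lesions; a
`global` mode computes the single-window statistic for completeness. On
identical windows, UQI equals SSIM with both constants zero (asserted
numerically). Cohort evaluation crops both maps to the brain bounding box
before scoring, so background air does not inflate the scores.

## Reader-agreement statistics

Paired ordinal ratings (rater × patient × question × arm) are pooled into
one two-arm comparison per question. Percent agreement carries a Wilson
score interval — this choice reproduces all published interval endpoints
at the study size n = 140 to the printed precision, which is why it is
fixed as the default. Cohen's kappa is unweighted, with an asymptotic
Fleiss–Cohen–Everitt standard error; when both margins degenerate to one
category the statistic is defined as 0 with a zero-width interval. When a
single margin is (nearly) constant, expected chance agreement approaches
observed agreement and kappa collapses toward zero even at 95% raw
agreement — the known imbalance pathology, and the reason both statistics
are always reported together. The power routine draws paired ratings from
`p_ij = κ·p_i·δ_ij + (1 − κ)·p_i·p_j` (common marginals, true kappa = κ)
and counts two-sided asymptotic z-test rejections of κ = 0; marginals are
an explicit input because the empirical tables they would come from are
not published.

## Known limitations

- The phantom's z-invariant geometry makes axial slices highly correlated;
  per-slice metrics on it are not independent samples.
- The numpy backend is single-threaded BLAS-bound; the full 256-px
  configuration builds and counts correctly but is not practical to train
  in this package.
- Checkpoints store raw weight arrays keyed by traversal order; they are
  tied to the exact architecture config they were saved with.
- `set_pilo_ratio` rescales relative to the weights at its first
  invocation; call it once with 0.5 to re-anchor after manual weight
  edits.
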