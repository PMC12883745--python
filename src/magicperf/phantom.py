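"""Digital head phantom: paired NCCT / CT-perfusion volumes with lesions.

The phantom provides the structure the synthesis method assumes, at desk
scale and fully seeded: a skull ring (~1000 HU) around brain parenchyma
(25-45 HU) with low-attenuation ventricles (5 HU) in air (-1000 HU), and
four perfusion maps on a coarser axial grid (10 mm vs 1 mm for NCCT)
coupled exactly by the Central Volume Principle, CBV = CBF * MTT / 60 with
MTT in seconds (the /60 makes the identity unit-consistent: ml/100g =
ml/100g/min * min).

Baseline perfusion is a smooth band-limited random field, mirror-symmetric
across the mid-sagittal plane so the relative-CBF core rule (core CBF
< 30% of the contralateral value) holds exactly by construction for any
core fraction below 0.3.  Focal lesions follow the ischemia conventions:
an infarct core (CBF scaled down hard, MTT/TTP elevated, CBV reduced) inside
a penumbra (TTP delayed by > 6 s, CBV preserved).  CBV is always recomputed
from CBF and MTT after an edit, keeping the coupling an exact invariant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage

logger = logging.getLogger(__name__)

MAP_TYPES = ("CBV", "CBF", "MTT", "TTP")

#: physiological display ranges, physical units per map type
PHYSIO_RANGES = {"CBF": (0.0, 60.0), "CBV": (0.0, 4.0),
                 "MTT": (0.0, 12.0), "TTP": (0.0, 25.0)}

#: baseline parenchyma ranges the generator draws from
BASELINE_RANGES = {"CBF": (30.0, 60.0), "MTT": (3.0, 6.0), "TTP": (4.0, 10.0)}

HU_AIR = -1000.0
HU_SKULL = 1000.0
HU_VENTRICLE = 5.0
HU_BRAIN_LO, HU_BRAIN_HI = 25.0, 45.0
CORE_HYPODENSITY_HU = 5.0     # early ischemic hypoattenuation in the core

NCCT_DZ_MM = 1.0
CTP_DZ_MM = 10.0


class PhantomSpecError(ValueError):
    pass


class LesionGeometryError(ValueError):
    pass


@dataclass(frozen=True)
class LesionSpec:
    """A spherical core-within-penumbra lesion on the CTP grid.

    ``center`` is (z_slice_index, row, col) in CTP-grid voxel coordinates;
    radii are in mm (in-plane spacing is 1 mm, axial spacing 10 mm).
    """

    center: tuple
    core_radius: float
    penumbra_radius: float
    cbf_core_fraction: float = 0.2
    delay_s: float = 8.0

    def __post_init__(self):
        if self.penumbra_radius < self.core_radius:
            raise PhantomSpecError(
                f"penumbra_radius {self.penumbra_radius} < core_radius "
                f"{self.core_radius}")
        if not 0.0 <= self.cbf_core_fraction < 0.3:
            raise PhantomSpecError(
                f"cbf_core_fraction must be in [0, 0.3) so the core satisfies "
                f"the relative CBF < 30% rule, got {self.cbf_core_fraction}")
        if self.delay_s <= 6.0:
            raise PhantomSpecError(
                f"delay_s must exceed 6 s (penumbra definition), got {self.delay_s}")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, noise and lesion description of one synthetic patient."""

    image_size: int = 256
    n_ncct_slices: int = 101
    n_ctp_slices: int = 10
    lesions: tuple = ()
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 32:
            raise PhantomSpecError(f"image_size must be >= 32, got {self.image_size}")
        if self.n_ncct_slices < 10 * self.n_ctp_slices:
            raise PhantomSpecError(
                f"n_ncct_slices ({self.n_ncct_slices}) must be >= 10 * "
                f"n_ctp_slices ({self.n_ctp_slices}) so the CTP grid embeds "
                f"in the NCCT grid")
        if self.noise_sd < 0:
            raise PhantomSpecError(f"noise_sd must be >= 0, got {self.noise_sd}")
        object.__setattr__(self, "lesions", tuple(self.lesions))

    @property
    def ctp_z_mm(self) -> np.ndarray:
        """Axial positions (mm = NCCT slice index) of the CTP slices,
        centered in the NCCT stack."""
        z0 = (self.n_ncct_slices - 1 - CTP_DZ_MM * (self.n_ctp_slices - 1)) / 2.0
        z0 = float(int(round(z0)))
        return z0 + CTP_DZ_MM * np.arange(self.n_ctp_slices)


@dataclass
class PhantomCase:
    """One synthetic patient: NCCT, four perfusion volumes, masks."""

    ncct: np.ndarray                    # (n_ncct, S, S) HU
    maps: dict                          # map type -> (n_ctp, S, S) physical units
    core_mask: np.ndarray               # bool, CTP grid
    penumbra_mask: np.ndarray           # bool, CTP grid
    brain_mask: np.ndarray              # bool, CTP grid
    spec: PhantomSpec

    @property
    def ctp_z_mm(self) -> np.ndarray:
        return self.spec.ctp_z_mm


# ---------------------------------------------------------------------------
# geometry and fields
# ---------------------------------------------------------------------------

def _ellipse(size: int, semi_r: float, semi_c: float,
             offset=(0.0, 0.0)) -> np.ndarray:
    rr, cc = np.mgrid[0:size, 0:size].astype(float)
    cr = (size - 1) / 2.0 + offset[0]
    cl = (size - 1) / 2.0 + offset[1]
    return ((rr - cr) / semi_r) ** 2 + ((cc - cl) / semi_c) ** 2 <= 1.0


def head_geometry(size: int) -> dict:
    """Boolean 2-D masks of the head compartments (z-invariant)."""
    outer = _ellipse(size, 0.44 * size, 0.37 * size)
    brain = _ellipse(size, 0.39 * size, 0.32 * size)
    vent_l = _ellipse(size, 0.07 * size, 0.03 * size, offset=(-0.02 * size, -0.05 * size))
    vent_r = _ellipse(size, 0.07 * size, 0.03 * size, offset=(-0.02 * size, +0.05 * size))
    ventricles = (vent_l | vent_r) & brain
    return {"outer": outer, "brain": brain, "skull": outer & ~brain,
            "ventricles": ventricles, "parenchyma": brain & ~ventricles}


def _mirror(field: np.ndarray) -> np.ndarray:
    """Reflect across the mid-sagittal plane (last axis)."""
    return field[..., ::-1]


def _smooth_unit_field(rng, shape, sigma_px) -> np.ndarray:
    """Band-limited noise, min-max rescaled to [0, 1], mirror-symmetric."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape),
                                sigma=(0.5,) + (sigma_px,) * 2, mode="nearest")
    f = 0.5 * (f + _mirror(f))
    lo, hi = f.min(), f.max()
    return (f - lo) / (hi - lo) if hi > lo else np.zeros(shape)


def baseline_maps(spec: PhantomSpec) -> dict:
    """Lesion-free perfusion fields on the CTP grid, zero outside brain.

    MTT is capped at 240/CBF so the derived CBV = CBF*MTT/60 never exceeds
    its 4 ml/100g physiological ceiling (high flow <-> shorter transit).
    """
    rng = np.random.default_rng(spec.seed)
    geom = head_geometry(spec.image_size)
    shape = (spec.n_ctp_slices, spec.image_size, spec.image_size)
    sigma = spec.image_size / 16.0
    brain = np.broadcast_to(geom["brain"], shape)

    fields = {}
    for m in ("CBF", "MTT", "TTP"):
        lo, hi = BASELINE_RANGES[m]
        fields[m] = lo + (hi - lo) * _smooth_unit_field(rng, shape, sigma)
    fields["MTT"] = np.minimum(fields["MTT"], 240.0 / fields["CBF"])
    fields["CBV"] = fields["CBF"] * fields["MTT"] / 60.0
    return {m: np.where(brain, fields[m], 0.0) for m in MAP_TYPES}


def _lesion_distance_mm(spec: PhantomSpec, lesion: LesionSpec,
                        grid: str) -> np.ndarray:
    """Distance (mm) from every voxel of the given grid to the lesion center."""
    cz, cr, cc = lesion.center
    s = spec.image_size
    cz_mm = spec.ctp_z_mm[int(cz)]
    if grid == "ctp":
        z_mm = spec.ctp_z_mm
    else:
        z_mm = NCCT_DZ_MM * np.arange(spec.n_ncct_slices)
    zz = (z_mm - cz_mm)[:, None, None]
    rr, cc_ = np.mgrid[0:s, 0:s].astype(float)
    d2 = zz ** 2 + (rr - cr)[None] ** 2 + (cc_ - cc)[None] ** 2
    return np.sqrt(d2)


def inject_lesion(case: PhantomCase, lesion: LesionSpec) -> PhantomCase:
    """Return a new case with the lesion applied.

    Core: CBF scaled by ``cbf_core_fraction``, MTT doubled (capped at its
    physiological ceiling), TTP delayed; CBV recomputed (reduced).
    Penumbra outside the core: MTT elevated by 1.5x (capped), CBF rescaled
    so CBV is preserved exactly, TTP delayed by ``delay_s``.  A mild
    hypodensity is stamped on the NCCT inside the core.  Masks are updated
    and the CBV = CBF*MTT/60 identity is recomputed inside the lesion.
    """
    spec = case.spec
    cz, cr, cc = lesion.center
    s = spec.image_size
    if not (0 <= cz < spec.n_ctp_slices and 0 <= cr < s and 0 <= cc < s):
        raise LesionGeometryError(
            f"lesion center {lesion.center} outside the CTP volume "
            f"({spec.n_ctp_slices} x {s} x {s})")

    dist = _lesion_distance_mm(spec, lesion, "ctp")
    brain = case.brain_mask
    core = (dist <= lesion.core_radius) & brain
    penumbra = (dist <= lesion.penumbra_radius) & brain

    cbf = case.maps["CBF"].copy()
    mtt = case.maps["MTT"].copy()
    ttp = case.maps["TTP"].copy()
    cbv_base = case.maps["CBV"]

    ring = penumbra & ~core
    mtt_ring = np.minimum(mtt[ring] * 1.5, PHYSIO_RANGES["MTT"][1])
    cbf[ring] = cbv_base[ring] * 60.0 / mtt_ring       # preserves CBV exactly
    mtt[ring] = mtt_ring
    ttp[ring] = np.minimum(ttp[ring] + lesion.delay_s, PHYSIO_RANGES["TTP"][1])

    cbf[core] = cbf[core] * lesion.cbf_core_fraction
    mtt[core] = np.minimum(mtt[core] * 2.0, PHYSIO_RANGES["MTT"][1])
    ttp[core] = np.minimum(ttp[core] + lesion.delay_s, PHYSIO_RANGES["TTP"][1])

    cbv = np.where(brain, cbf * mtt / 60.0, 0.0)

    ncct = case.ncct.copy()
    dist_ncct = _lesion_distance_mm(spec, lesion, "ncct")
    geom = head_geometry(s)
    core_ncct = (dist_ncct <= lesion.core_radius) & geom["parenchyma"][None]
    ncct[core_ncct] -= CORE_HYPODENSITY_HU

    return PhantomCase(
        ncct=ncct,
        maps={"CBV": cbv, "CBF": cbf, "MTT": mtt, "TTP": ttp},
        core_mask=case.core_mask | core,
        penumbra_mask=case.penumbra_mask | penumbra,
        brain_mask=brain,
        spec=spec,
    )


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Build a seeded phantom case; deterministic for a fixed spec."""
    rng = np.random.default_rng(spec.seed)
    s = spec.image_size
    geom = head_geometry(s)

    hu2d = np.full((s, s), HU_AIR)
    hu2d[geom["skull"]] = HU_SKULL
    hu2d[geom["ventricles"]] = HU_VENTRICLE
    tex = _smooth_unit_field(rng, (spec.n_ncct_slices, s, s), s / 16.0)
    ncct = np.broadcast_to(hu2d, (spec.n_ncct_slices, s, s)).copy()
    par = np.broadcast_to(geom["parenchyma"], ncct.shape)
    ncct[par] = HU_BRAIN_LO + (HU_BRAIN_HI - HU_BRAIN_LO) * tex[par]
    if spec.noise_sd > 0:
        ncct = ncct + rng.normal(0.0, spec.noise_sd, ncct.shape)

    maps = baseline_maps(replace(spec, lesions=()))
    shape = (spec.n_ctp_slices, s, s)
    case = PhantomCase(
        ncct=ncct,
        maps=maps,
        core_mask=np.zeros(shape, dtype=bool),
        penumbra_mask=np.zeros(shape, dtype=bool),
        brain_mask=np.broadcast_to(geom["brain"], shape).copy(),
        spec=spec,
    )
    for lesion in spec.lesions:
        case = inject_lesion(case, lesion)
    return case


def generate_cohort(n_cases: int, seed: int = 0, image_size: int = 256,
                    n_ncct_slices: int = 101, n_ctp_slices: int = 10,
                    lesion_probability: float = 0.65) -> list[PhantomCase]:
    """A mixed cohort spanning the three severity presentations."""
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n_cases):
        lesions = ()
        if rng.random() < lesion_probability:
            core_r = float(rng.uniform(3.0, 18.0))
            pen_r = float(rng.uniform(core_r, max(core_r * 1.1, 25.0)))
            s = image_size
            center = (int(rng.integers(2, n_ctp_slices - 2)),
                      int(rng.integers(int(0.35 * s), int(0.55 * s))),
                      int(rng.integers(int(0.3 * s), int(0.45 * s))))
            lesions = (LesionSpec(center=center, core_radius=core_r,
                                  penumbra_radius=pen_r,
                                  delay_s=float(rng.uniform(6.5, 12.0))),)
        spec = PhantomSpec(image_size=image_size, n_ncct_slices=n_ncct_slices,
                           n_ctp_slices=n_ctp_slices, lesions=lesions,
                           seed=int(rng.integers(0, 2 ** 31 - 1)))
        cases.append(generate_phantom(spec))
    return cases


# ---------------------------------------------------------------------------
# NIfTI dataset I/O
# ---------------------------------------------------------------------------

def _affine(dz_mm: float, z0_mm: float = 0.0) -> np.ndarray:
    aff = np.diag([1.0, 1.0, dz_mm, 1.0])
    aff[2, 3] = z0_mm
    return aff


def _save_vol(arr: np.ndarray, path, dz_mm: float, z0_mm: float = 0.0) -> None:
    import nibabel as nib
    data = arr.transpose(1, 2, 0)      # (z, r, c) -> (r, c, z)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(np.asarray(data), _affine(dz_mm, z0_mm))
    nib.save(img, str(path))


def _load_vol(path) -> np.ndarray:
    import nibabel as nib
    data = np.asanyarray(nib.load(str(path)).dataobj)
    return data.transpose(2, 0, 1)


def write_dataset(cases, out_dir) -> pd.DataFrame:
    """Write NIfTI volumes plus a CSV manifest; returns the manifest.

    Per case: the NCCT volume (1 mm axial), the four perfusion maps and
    the three masks (10 mm CTP grid) -> 8 volumes.  Severity is computed
    from the stored masks so the manifest column is reproducible from the
    volumes alone.
    """
    from pathlib import Path
    from .metrics import classify_severity, mmr_ratio

    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create dataset directory {out}: {exc}") from exc
    rows = []
    for i, case in enumerate(cases):
        cid = f"case{i:04d}"
        z0 = float(case.ctp_z_mm[0])
        paths = {"ncct": out / f"{cid}_ncct.nii.gz"}
        _save_vol(case.ncct, paths["ncct"], NCCT_DZ_MM)
        for m in MAP_TYPES:
            paths[m.lower()] = out / f"{cid}_{m.lower()}.nii.gz"
            _save_vol(case.maps[m], paths[m.lower()], CTP_DZ_MM, z0)
        for name, mask in (("core", case.core_mask),
                           ("penumbra", case.penumbra_mask),
                           ("brain", case.brain_mask)):
            paths[name] = out / f"{cid}_{name}_mask.nii.gz"
            _save_vol(mask, paths[name], CTP_DZ_MM, z0)
        ratio = mmr_ratio(case.core_mask, case.penumbra_mask)
        rows.append({
            "case_id": cid,
            **{k: str(v.name) for k, v in paths.items()},
            "n_lesions": len(case.spec.lesions),
            "core_px": int(case.core_mask.sum()),
            "penumbra_px": int(case.penumbra_mask.sum()),
            "mmr": ratio if np.isfinite(ratio) else np.inf,
            "severity": classify_severity(ratio).label,
            "image_size": case.spec.image_size,
            "n_ncct_slices": case.spec.n_ncct_slices,
            "n_ctp_slices": case.spec.n_ctp_slices,
            "seed": case.spec.seed,
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def read_dataset(in_dir) -> list[PhantomCase]:
    """Load a written dataset back into PhantomCase objects (voxel-exact)."""
    from pathlib import Path

    src = Path(in_dir)
    manifest = pd.read_csv(src / "manifest.csv")
    cases = []
    for _, row in manifest.iterrows():
        spec = PhantomSpec(image_size=int(row["image_size"]),
                           n_ncct_slices=int(row["n_ncct_slices"]),
                           n_ctp_slices=int(row["n_ctp_slices"]),
                           seed=int(row["seed"]))
        cases.append(PhantomCase(
            ncct=_load_vol(src / row["ncct"]),
            maps={m: _load_vol(src / row[m.lower()]) for m in MAP_TYPES},
            core_mask=_load_vol(src / row["core"]).astype(bool),
            penumbra_mask=_load_vol(src / row["penumbra"]).astype(bool),
            brain_mask=_load_vol(src / row["brain"]).astype(bool),
            spec=spec,
        ))
    return cases
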