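"""Phantom generator: physiological invariants, lesions, dataset round trip."""

import numpy as np
import pytest

from magicperf.metrics import classify_severity, mmr_ratio
from magicperf.phantom import (LesionGeometryError, LesionSpec, PhantomSpec,
                               PhantomSpecError, baseline_maps,
                               generate_phantom, inject_lesion, read_dataset,
                               write_dataset)


class TestSpecValidation:
    @pytest.mark.parametrize("kwargs,fragment", [
        (dict(image_size=16), "image_size"),
        (dict(n_ncct_slices=50, n_ctp_slices=10), "n_ncct_slices"),
        (dict(noise_sd=-1.0), "noise_sd"),
    ])
    def test_invalid_spec_names_violated_bound(self, kwargs, fragment):
        base = dict(image_size=64, n_ncct_slices=101, n_ctp_slices=10)
        base.update(kwargs)
        with pytest.raises(PhantomSpecError, match=fragment):
            PhantomSpec(**base)

    @pytest.mark.parametrize("kwargs", [
        dict(core_radius=10.0, penumbra_radius=5.0),
        dict(cbf_core_fraction=0.35),
        dict(delay_s=5.0),
    ])
    def test_invalid_lesion_rejected(self, kwargs):
        base = dict(center=(5, 32, 32), core_radius=4.0, penumbra_radius=10.0)
        with pytest.raises(PhantomSpecError):
            LesionSpec(**{**base, **kwargs})


class TestGeneratePhantom:
    def test_no_lesion_means_empty_masks(self, lesion_free_case):
        assert not lesion_free_case.core_mask.any()
        assert not lesion_free_case.penumbra_mask.any()

    def test_fixed_seed_is_bit_identical(self, small_spec, small_case):
        again = generate_phantom(small_spec)
        assert np.array_equal(again.ncct, small_case.ncct)
        for m in small_case.maps:
            assert np.array_equal(again.maps[m], small_case.maps[m])
        assert np.array_equal(again.core_mask, small_case.core_mask)

    def test_central_volume_principle_exact_in_brain(self, small_case):
        cvp = np.abs(small_case.maps["CBV"]
                     - small_case.maps["CBF"] * small_case.maps["MTT"] / 60.0)
        assert cvp[small_case.brain_mask].max() <= 1e-6

    def test_maps_within_physiological_ranges(self, small_case):
        for m, (lo, hi) in {"CBF": (0, 60), "CBV": (0, 4),
                            "MTT": (0, 12), "TTP": (0, 25)}.items():
            v = small_case.maps[m]
            assert v.min() >= lo and v.max() <= hi, m

    def test_hu_structure(self, small_case):
        ncct = small_case.ncct
        assert ncct.max() > 300                      # skull present
        corner = ncct[:, :4, :4]
        assert abs(corner.mean() - (-1000)) < 10     # background air

    def test_core_cbf_below_30pct_of_mirrored_contralateral(
            self, small_case, lesion_free_case):
        baseline_cbf = lesion_free_case.maps["CBF"]
        mirrored = baseline_cbf[..., ::-1]
        core = small_case.core_mask
        assert core.any()
        violations = small_case.maps["CBF"][core] >= 0.3 * mirrored[core]
        assert violations.sum() == 0

    def test_core_mask_subset_of_penumbra(self, small_case):
        assert not (small_case.core_mask & ~small_case.penumbra_mask).any()


class TestInjectLesion:
    def test_core_scaling_on_uniform_field(self, lesion_free_case):
        case = lesion_free_case
        uniform = {m: v.copy() for m, v in case.maps.items()}
        uniform["CBF"][:] = np.where(case.brain_mask, 50.0, 0.0)
        uniform["MTT"][:] = np.where(case.brain_mask, 4.0, 0.0)
        uniform["CBV"] = uniform["CBF"] * uniform["MTT"] / 60.0
        from dataclasses import replace as dc_replace
        base = dc_replace(case, maps=uniform)
        lesion = LesionSpec(center=(5, 28, 22), core_radius=5.0,
                            penumbra_radius=12.0, cbf_core_fraction=0.2)
        out = inject_lesion(base, lesion)
        assert out.core_mask.any()
        np.testing.assert_allclose(out.maps["CBF"][out.core_mask], 10.0)

    def test_penumbra_ttp_delay_clipped_to_range(self, lesion_free_case):
        maps = {m: v.copy() for m, v in lesion_free_case.maps.items()}
        maps["TTP"][:] = np.where(lesion_free_case.brain_mask, 6.0, 0.0)
        from dataclasses import replace as dc_replace
        base = dc_replace(lesion_free_case, maps=maps)
        out = inject_lesion(base, LesionSpec(center=(5, 28, 22), core_radius=3.0,
                                             penumbra_radius=12.0, delay_s=8.0))
        ring = out.penumbra_mask & ~out.core_mask
        np.testing.assert_allclose(out.maps["TTP"][ring], 14.0)
        assert out.maps["TTP"].max() <= 25.0

    def test_penumbra_preserves_cbv_and_masks_nest(self, small_case,
                                                   lesion_free_case):
        ring = small_case.penumbra_mask & ~small_case.core_mask
        base_cbv = lesion_free_case.maps["CBV"][ring]
        new_cbv = small_case.maps["CBV"][ring]
        assert np.all(np.abs(new_cbv - base_cbv) <= 0.1 * base_cbv + 1e-9)
        assert not (small_case.core_mask & ~small_case.penumbra_mask).any()

    def test_lesion_outside_volume_raises(self, lesion_free_case):
        with pytest.raises(LesionGeometryError):
            inject_lesion(lesion_free_case,
                          LesionSpec(center=(50, 28, 22), core_radius=3.0,
                                     penumbra_radius=9.0))


def test_severity_classes_span_all_three_when_sweeping_lesion_size():
    labels = set()
    for core_r, pen_r in [(0.0, 0.0), (4.0, 16.0), (14.0, 14.0)]:
        lesions = ()
        if core_r > 0:
            lesions = (LesionSpec(center=(5, 28, 22), core_radius=core_r,
                                  penumbra_radius=pen_r),)
        case = generate_phantom(PhantomSpec(image_size=64, n_ncct_slices=101,
                                            n_ctp_slices=10, lesions=lesions,
                                            seed=7))
        labels.add(classify_severity(
            mmr_ratio(case.core_mask, case.penumbra_mask)).label)
    assert labels == {"none", "mild_moderate", "severe"}


class TestDatasetIO:
    def test_round_trip_and_manifest(self, tmp_path, small_case,
                                     lesion_free_case):
        cases = [small_case, lesion_free_case]
        manifest = write_dataset(cases, tmp_path)
        assert len(manifest) == 2
        vol_files = [p for p in tmp_path.iterdir() if p.suffix == ".gz"]
        assert len(vol_files) == 16
        loaded = read_dataset(tmp_path)
        for orig, back in zip(cases, loaded):
            np.testing.assert_array_equal(orig.ncct, back.ncct)
            for m in orig.maps:
                np.testing.assert_array_equal(orig.maps[m], back.maps[m])
            np.testing.assert_array_equal(orig.core_mask, back.core_mask)

    def test_manifest_severity_matches_metrics_recompute(self, tmp_path,
                                                         small_case):
        manifest = write_dataset([small_case], tmp_path)
        expected = classify_severity(
            mmr_ratio(small_case.core_mask, small_case.penumbra_mask)).label
        assert manifest.loc[0, "severity"] == expected


def test_baseline_fields_are_mirror_symmetric():
    maps = baseline_maps(PhantomSpec(image_size=64, n_ncct_slices=101,
                                     n_ctp_slices=10, seed=3))
    for m, v in maps.items():
        np.testing.assert_allclose(v, v[..., ::-1], atol=1e-12, err_msg=m)
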