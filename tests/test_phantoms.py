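"""Phantom generation, margin expansion and cohort sampling."""

import numpy as np
import pytest

from protonselect.phantoms import (PTV1_MARGINS, PTV2_MARGINS, CaseParams,
                                   CohortSpec, MarginSpec, PhantomSizingError,
                                   expand_ctv_to_ptv, generate_cohort,
                                   generate_phantom)


def brute_force_expand(ctv, margins, spacing):
    """Per-voxel oracle: include v iff some CTV voxel lies within the
    direction-dependent margin along every axis."""
    dz, dy, dx = spacing
    out = np.zeros_like(ctv, bool)
    seeds = np.argwhere(ctv)
    for v in np.ndindex(ctv.shape):
        for s in seeds:
            ddz = (v[0] - s[0]) * dz   # + is inferior
            ddy = (v[1] - s[1]) * dy   # + is posterior
            ddx = (v[2] - s[2]) * dx   # + is patient-left
            ok_z = (-margins.mm("superior") - 1e-9 <= ddz <= margins.mm("inferior") + 1e-9)
            ok_y = (-margins.mm("anterior") - 1e-9 <= ddy <= margins.mm("posterior") + 1e-9)
            ok_x = (-margins.mm("right") - 1e-9 <= ddx <= margins.mm("left") + 1e-9)
            if ok_z and ok_y and ok_x:
                out[v] = True
                break
    return out


class TestMarginExpansion:
    def test_zero_margins_identity(self, rng):
        ctv = rng.random((8, 8, 8)) < 0.2
        ctv[4, 4, 4] = True
        margins = MarginSpec(0, 0, 0, 0, 0, 0)
        assert np.array_equal(expand_ctv_to_ptv(ctv, margins, (2.5, 2.5, 2.5)), ctv)

    def test_single_voxel_isotropic_margin_matches_brute_force(self):
        ctv = np.zeros((12, 12, 12), bool)
        ctv[6, 6, 6] = True
        margins = MarginSpec(1.0, 1.0, 1.0, 1.0, 1.0, 1.0)  # 10 mm everywhere
        spacing = (2.0, 2.0, 2.0)
        out = expand_ctv_to_ptv(ctv, margins, spacing)
        assert np.array_equal(out, brute_force_expand(ctv, margins, spacing))

    def test_ptv2_margins_layer_counts(self):
        # cube CTV, 2.5 mm spacing: posterior 5 mm -> 2 layers, anterior 7 mm -> 2
        ctv = np.zeros((20, 20, 20), bool)
        ctv[8:12, 8:12, 8:12] = True
        spacing = (2.5, 2.5, 2.5)
        out = expand_ctv_to_ptv(ctv, PTV2_MARGINS, spacing)
        ys = np.where(out.any(axis=(0, 2)))[0]
        assert ys.min() == 8 - int(np.floor(7.0 / 2.5))   # anterior face
        assert ys.max() == 11 + int(np.floor(5.0 / 2.5))  # posterior face
        zs = np.where(out.any(axis=(1, 2)))[0]
        assert zs.min() == 8 - 4 and zs.max() == 11 + 4   # 10 mm sup/inf
        assert np.array_equal(out, brute_force_expand(ctv, PTV2_MARGINS, spacing))

    def test_random_masks_match_brute_force(self, rng):
        for _ in range(5):
            ctv = rng.random((10, 10, 10)) < 0.08
            ctv[5, 5, 5] = True
            margins = MarginSpec(*rng.uniform(0.0, 0.8, 6).round(1))
            spacing = tuple(rng.uniform(1.5, 3.0, 3).round(1))
            out = expand_ctv_to_ptv(ctv, margins, spacing)
            assert np.array_equal(out, brute_force_expand(ctv, margins, spacing))

    def test_output_contains_input(self, rng):
        ctv = rng.random((10, 10, 10)) < 0.1
        ctv[3, 3, 3] = True
        out = expand_ctv_to_ptv(ctv, PTV1_MARGINS, (2.5, 2.5, 2.5))
        assert np.all(out[ctv])

    def test_empty_ctv_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            expand_ctv_to_ptv(np.zeros((5, 5, 5), bool), PTV1_MARGINS, (2, 2, 2))

    def test_negative_margin_rejected(self):
        with pytest.raises(ValueError):
            MarginSpec(-0.1, 1, 1, 1, 1, 1)


class TestGeneratePhantom:
    def test_deterministic_under_fixed_seed(self):
        a = generate_phantom(CaseParams(), seed=1)
        b = generate_phantom(CaseParams(), seed=1)
        assert np.array_equal(a.intensity, b.intensity)
        assert set(a.masks) == set(b.masks)
        for roi in a.masks:
            assert np.array_equal(a.masks[roi], b.masks[roi])

    def test_different_seeds_differ(self):
        a = generate_phantom(CaseParams(), seed=1)
        b = generate_phantom(CaseParams(), seed=2)
        assert not np.array_equal(a.masks["CTV1"], b.masks["CTV1"])

    def test_wall_is_subset_of_rectum(self, default_phantom):
        wall = default_phantom.masks["rectum_wall"]
        rectum = default_phantom.masks["rectum"]
        assert not np.any(wall & ~rectum)
        assert wall.sum() > 0

    def test_ctv_inside_ptv(self, default_phantom, dual_phantom):
        for ph in (default_phantom, dual_phantom):
            assert not np.any(ph.masks["CTV1"] & ~ph.masks["PTV1"])
        assert not np.any(dual_phantom.masks["CTV2"] & ~dual_phantom.masks["PTV2"])

    def test_posterior_margin_reaches_into_rectum(self):
        # the 0.5 cm posterior PTV1 margin must cross into the rectum
        ph = generate_phantom(CaseParams(), seed=2)
        assert np.sum(ph.masks["PTV1"] & ph.masks["rectum"]) > 0

    def test_required_rois_present(self, default_phantom, dual_phantom):
        for roi in ("PTV1", "CTV1", "rectum", "rectum_wall", "bladder"):
            assert roi in default_phantom.masks
        for roi in ("PTV2", "CTV2", "femur_L", "femur_R", "colon", "intestine"):
            assert roi in dual_phantom.masks

    def test_grids_share_shape_and_flag_valid(self, dual_phantom):
        dual_phantom.validate()
        assert dual_phantom.anticoagulant_use in (0, 1)

    def test_too_small_grid_names_roi(self):
        with pytest.raises(PhantomSizingError):
            generate_phantom(CaseParams(shape=(10, 10, 10)), seed=1)

    def test_wall_thickness_configurable(self):
        thin = generate_phantom(CaseParams(wall_thickness_mm=2.6), seed=5)
        thick = generate_phantom(CaseParams(wall_thickness_mm=6.0), seed=5)
        assert thick.masks["rectum_wall"].sum() > thin.masks["rectum_wall"].sum()


class TestGenerateCohort:
    def test_deterministic(self):
        spec = CohortSpec(n_cases=5, seed=7)
        a = generate_cohort(spec)
        b = generate_cohort(spec)
        for pa, pb in zip(a, b):
            assert pa.patient_id == pb.patient_id
            assert np.array_equal(pa.intensity, pb.intensity)
            assert pa.anticoagulant_use == pb.anticoagulant_use

    def test_single_case(self):
        assert len(generate_cohort(CohortSpec(n_cases=1, seed=0))) == 1

    def test_prevalence_converges(self):
        spec = CohortSpec(n_cases=400, seed=9, anticoagulant_prevalence=0.25,
                          # tiny grids are not valid phantoms; sample flags only
                          )
        from protonselect.phantoms import case_params_from_spec
        params = case_params_from_spec(spec)
        frac = np.mean([p.anticoagulant_use for p, _ in params])
        assert abs(frac - 0.25) <= 0.07  # binomial 99% interval at n=400

    def test_dual_fraction_converges(self):
        from protonselect.phantoms import case_params_from_spec
        spec = CohortSpec(n_cases=400, seed=9, fraction_dual_gradient=0.5)
        params = case_params_from_spec(spec)
        frac = np.mean([p.dual_gradient for p, _ in params])
        assert abs(frac - 0.5) <= 0.08

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n_cases=0)
        with pytest.raises(ValueError):
            CohortSpec(anticoagulant_prevalence=1.5)
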