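"""TFCE transform and permutation FWE machinery."""

import numpy as np
import pytest
import scipy.ndimage as ndi

from gutbraincov.structcov import DesignMatrix, StatMap, VolumeStack, make_gm_mask
from gutbraincov.tfce_inference import (
    PermutationScheme,
    TFCEParams,
    permutation_fwe,
    small_volume_correction,
    tfce_transform,
)


def naive_tfce(vals3d, mask, params):
    """Independent oracle: fresh connected-component labeling at every
    threshold, both tails."""
    out = np.zeros_like(vals3d)
    struct = (np.ones((3, 3, 3), bool) if params.connectivity == 26
              else ndi.generate_binary_structure(3, 1))
    for sign in (1.0, -1.0):
        tail = np.where(mask & (sign * vals3d > 0), sign * vals3d, 0.0)
        mx = tail.max()
        if mx <= 0:
            continue
        dh = params.dh if params.dh is not None else mx / params.n_steps
        for i in range(1, int(np.floor(mx / dh + 1e-12)) + 1):
            h = i * dh
            sup = tail >= h
            lab, _ = ndi.label(sup, structure=struct)
            sizes = np.bincount(lab.ravel())
            out[sup] += sign * (sizes[lab[sup]] ** params.extent_exponent) * \
                (h ** params.height_exponent) * dh
    return np.where(mask, out, np.nan)


def as_statmap(vals3d, mask=None):
    mask = np.ones(vals3d.shape, bool) if mask is None else mask
    return StatMap("t", np.where(mask, vals3d, np.nan), "test", mask,
                   affine=np.diag([2.0, 2.0, 2.0, 1.0]))


class TestTFCETransform:
    def test_zero_map_maps_to_zero(self):
        out = tfce_transform(as_statmap(np.zeros((6, 6, 6))))
        np.testing.assert_array_equal(out.values, 0.0)

    def test_single_voxel_closed_form(self):
        """Isolated peak of height h with E=0.5, H=2: TFCE -> h^3/3 as
        dh -> 0 (integral of x^2)."""
        h = 4.0
        vals = np.zeros((7, 7, 7))
        vals[3, 3, 3] = h
        params = TFCEParams(dh=h / 1000)
        out = tfce_transform(as_statmap(vals), params)
        assert out.values[3, 3, 3] == pytest.approx(h**3 / 3, rel=0.01)

    def test_translation_invariance_of_identical_blobs(self):
        vals = np.zeros((12, 12, 12))
        vals[2:4, 2:4, 2:4] = 3.0
        vals[8:10, 8:10, 8:10] = 3.0
        out = tfce_transform(as_statmap(vals)).values
        np.testing.assert_allclose(out[2:4, 2:4, 2:4], out[8:10, 8:10, 8:10])

    def test_sign_preserved_and_antisymmetric(self, rng):
        vals = rng.normal(0, 1, (8, 8, 8))
        out = tfce_transform(as_statmap(vals)).values
        out_neg = tfce_transform(as_statmap(-vals)).values
        np.testing.assert_allclose(out, -out_neg, atol=1e-12)
        assert np.all(np.sign(out[vals > 0]) >= 0)

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_naive_threshold_loop(self, rng, connectivity):
        params = TFCEParams(connectivity=connectivity)
        for _ in range(3):
            vals = rng.normal(0, 1.5, (12, 12, 12))
            mask = rng.random((12, 12, 12)) > 0.15
            got = tfce_transform(as_statmap(vals, mask), params).values
            want = naive_tfce(vals, mask, params)
            np.testing.assert_allclose(got[mask], want[mask], atol=1e-6)

    def test_monotone_under_scaling(self, rng):
        vals = np.abs(rng.normal(0, 1, (10, 10, 10)))
        a = tfce_transform(as_statmap(vals)).values
        b = tfce_transform(as_statmap(2.0 * vals)).values
        assert np.all(b >= a - 1e-9)


def _null_setup(rng, n=24, dims=(10, 10, 10)):
    data = rng.normal(0.5, 0.05, (n,) + dims)
    stack = VolumeStack([f"s{i}" for i in range(n)], data,
                        np.diag([2.0, 2.0, 2.0, 1.0]))
    mask = make_gm_mask(stack, 0.2)
    design = DesignMatrix(
        ["age", "sex", "global_gmv", "other_seed", "seed"],
        rng.normal(0, 1, (n, 5)),
        np.array(["non-obese", "obese"] * (n // 2)),
    )
    return stack, design, mask


class TestPermutationFWE:
    def test_minimum_p_and_p_range(self, rng):
        stack, design, mask = _null_setup(rng)
        res = permutation_fwe(stack, design, mask, "obese>non-obese",
                              scheme=PermutationScheme(99, rng_seed=0))
        for d in ("pos", "neg"):
            p = res.p_fwe[d].masked()
            assert np.nanmin(p) >= 1.0 / 100
            assert np.nanmax(p) <= 1.0
        assert res.p_fwe["pos"].n_permutations == 99

    def test_reproducible_given_seed(self, rng):
        stack, design, mask = _null_setup(rng, n=16, dims=(6, 6, 6))
        r1 = permutation_fwe(stack, design, mask, "obese>non-obese",
                             scheme=PermutationScheme(50, rng_seed=5))
        r2 = permutation_fwe(stack, design, mask, "obese>non-obese",
                             scheme=PermutationScheme(50, rng_seed=5))
        np.testing.assert_array_equal(r1.null_max["pos"], r2.null_max["pos"])
        np.testing.assert_array_equal(r1.p_fwe["pos"].values, r2.p_fwe["pos"].values)

    def test_p_monotone_in_observed_tfce(self, rng):
        stack, design, mask = _null_setup(rng, n=20, dims=(8, 8, 8))
        res = permutation_fwe(stack, design, mask, "obese>non-obese",
                              scheme=PermutationScheme(60, rng_seed=2))
        tf = res.tfce_obs.masked()
        p = res.p_fwe["pos"].masked()
        order = np.argsort(tf)
        assert np.all(np.diff(p[order]) <= 1e-12)

    def test_exhaustive_enumeration_for_tiny_n(self, rng):
        stack, design, mask = _null_setup(rng, n=6, dims=(4, 4, 4))
        with pytest.warns(UserWarning, match="exhaustively"):
            res = permutation_fwe(stack, design, mask, "obese>non-obese",
                                  scheme=PermutationScheme(5000, rng_seed=0))
        assert len(res.null_max["pos"]) == 720

    def test_group_exchange_strategy_runs(self, rng):
        stack, design, mask = _null_setup(rng, n=16, dims=(5, 5, 5))
        res = permutation_fwe(stack, design, mask, "obese>non-obese",
                              scheme=PermutationScheme(40, rng_seed=1,
                                                       strategy="group-exchange"))
        assert np.isfinite(res.null_max["pos"]).all()


class TestSmallVolumeCorrection:
    def test_whole_mask_sphere_reduces_to_whole_brain(self, rng):
        stack, design, mask = _null_setup(rng, n=20, dims=(6, 6, 6))
        res = permutation_fwe(stack, design, mask, "obese>non-obese",
                              scheme=PermutationScheme(80, rng_seed=3))
        svc = small_volume_correction(res, stack, (5.0, 5.0, 5.0), radius_mm=100.0)
        np.testing.assert_allclose(svc.values[mask], res.p_fwe["pos"].values[mask])

    def test_restricted_p_never_larger(self, rng):
        stack, design, mask = _null_setup(rng, n=20, dims=(8, 8, 8))
        res = permutation_fwe(stack, design, mask, "obese>non-obese",
                              scheme=PermutationScheme(80, rng_seed=4))
        center = (7.0, 7.0, 7.0)
        svc = small_volume_correction(res, stack, center, radius_mm=5.0)
        sel = ~np.isnan(svc.values)
        assert np.all(svc.values[sel] <= res.p_fwe["pos"].values[sel] + 1e-12)

    def test_single_voxel_sphere_matches_direct_count(self, rng):
        stack, design, mask = _null_setup(rng, n=20, dims=(8, 8, 8))
        res = permutation_fwe(stack, design, mask, "obese>non-obese",
                              scheme=PermutationScheme(80, rng_seed=6))
        center = (7.0, 7.0, 7.0)
        svc = small_volume_correction(res, stack, center, radius_mm=0.1)
        vox = np.unravel_index(np.nanargmin(np.where(np.isnan(svc.values), np.inf,
                                                     svc.values)), svc.values.shape)
        flat = np.flatnonzero(mask.ravel())
        col = np.where(flat == np.ravel_multi_index(vox, mask.shape))[0][0]
        obs = res.tfce_obs.values[vox]
        count = np.sum(res.null_tfce[:, col] >= obs)
        assert svc.values[vox] == pytest.approx((1 + count) / (80 + 1))

    def test_requires_null_maps(self, rng):
        stack, design, mask = _null_setup(rng, n=16, dims=(5, 5, 5))
        res = permutation_fwe(stack, design, mask, "obese>non-obese",
                              scheme=PermutationScheme(30, rng_seed=7),
                              keep_null_maps=False)
        with pytest.raises(ValueError, match="null TFCE"):
            small_volume_correction(res, stack, (4.0, 4.0, 4.0), radius_mm=3.0)
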