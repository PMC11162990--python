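import numpy as np
import pytest

from ngdwi.scheme import BValueScheme
from ngdwi.signals import CTRWParams, signal_ctrw, signal_monoexp, \
    MonoExpParams
from ngdwi.synthetic import (GroupParameterSpec, MetricSpec,
                             add_rician_noise, generate_cohort,
                             hg_like_specs, mibc_like_specs, perturb_mask,
                             render_signal, sample_parameter_maps)


def _sphere(shape=(12, 12, 12), r=4.0):
    g = np.ogrid[tuple(slice(0, s) for s in shape)]
    c = [s / 2 for s in shape]
    return sum(((x - ci) / r) ** 2 for x, ci in zip(g, c)) <= 1.0


def _ctrw_spec(scale=0.0, voxel_cv=0.0, **kw):
    params = {"S0": MetricSpec(100.0, scale, voxel_cv=voxel_cv),
              "D": MetricSpec(1.2e-3, scale * 1e-5, voxel_cv=voxel_cv),
              "alpha": MetricSpec(0.9, 0.0, voxel_cv=voxel_cv),
              "beta": MetricSpec(0.9, 0.0, voxel_cv=voxel_cv)}
    return GroupParameterSpec("CTRW", params, **kw)


def test_zero_variance_spec_gives_constant_maps():
    mask = _sphere()
    truth = sample_parameter_maps(_ctrw_spec(), mask.shape, mask,
                                  np.random.default_rng(0))
    for name, m in truth.items():
        vals = m[mask]
        assert np.ptp(vals) == 0
        assert np.all(np.isnan(m[~mask]))


def test_sample_mean_tracks_spec_location():
    """Law of large numbers: in-mask mean within 3 SE of the location."""
    mask = np.ones((30, 30, 12), bool)     # 10800 voxels
    spec = _ctrw_spec(voxel_cv=0.10)
    rng = np.random.default_rng(7)
    truth = sample_parameter_maps(spec, mask.shape, mask, rng)
    vals = truth["D"][mask]
    se = vals.std() / np.sqrt(vals.size)
    # smoothing correlates voxels; allow a generous effective-n margin
    assert abs(vals.mean() - 1.2e-3) < 3 * se * 5


def test_sampling_deterministic():
    mask = _sphere()
    t1 = sample_parameter_maps(_ctrw_spec(voxel_cv=0.1), mask.shape, mask,
                               np.random.default_rng(3))
    t2 = sample_parameter_maps(_ctrw_spec(voxel_cv=0.1), mask.shape, mask,
                               np.random.default_rng(3))
    for k in t1:
        np.testing.assert_array_equal(t1[k], t2[k])


def test_spec_validates_bounds():
    with pytest.raises(ValueError, match="bounds"):
        GroupParameterSpec("DKI", {"S0": MetricSpec(100.0),
                                   "D": MetricSpec(0.5),   # not in mm²/s
                                   "K": MetricSpec(0.8)})
    with pytest.raises(ValueError, match="missing"):
        GroupParameterSpec("DKI", {"S0": MetricSpec(100.0)})


def test_render_single_voxel_matches_forward(scheme):
    mask = np.zeros((3, 3, 1), bool)
    mask[1, 1, 0] = True
    truth = sample_parameter_maps(_ctrw_spec(), mask.shape, mask,
                                  np.random.default_rng(0))
    vol = render_signal(truth, scheme, "CTRW")
    expected = signal_ctrw(CTRWParams(100.0, 1.2e-3, 0.9, 0.9), scheme)
    np.testing.assert_allclose(vol[1, 1, 0], expected, rtol=1e-12)
    assert np.all(vol[0, 0, 0] == 0)


def test_render_ctrw_gaussian_limit_equals_monoexp(scheme):
    mask = _sphere((8, 8, 8), 3.0)
    params = {"S0": MetricSpec(80.0, 0.0, voxel_cv=0.0),
              "D": MetricSpec(1.0e-3, 0.0, voxel_cv=0.0),
              "alpha": MetricSpec(1.0, 0.0, voxel_cv=0.0),
              "beta": MetricSpec(1.0, 0.0, voxel_cv=0.0)}
    spec = GroupParameterSpec("CTRW", params)
    truth = sample_parameter_maps(spec, mask.shape, mask,
                                  np.random.default_rng(1))
    vol = render_signal(truth, scheme, "CTRW")
    mono = signal_monoexp(MonoExpParams(80.0, 1.0e-3), scheme)
    for sig in vol[mask]:
        np.testing.assert_allclose(sig, mono, rtol=1e-12)


def test_render_homogeneous_truth_gives_constant_b_slices(scheme):
    mask = _sphere((10, 10, 6), 3.0)
    truth = sample_parameter_maps(_ctrw_spec(), mask.shape, mask,
                                  np.random.default_rng(2))
    vol = render_signal(truth, scheme, "CTRW")
    for j in range(scheme.n):
        assert np.ptp(vol[..., j][mask]) == 0


def test_render_missing_map_errors(scheme):
    with pytest.raises(ValueError, match="missing"):
        render_signal({"S0": np.ones((2, 2, 2))}, scheme, "DKI")


def test_rician_infinite_snr_is_identity(rng):
    vol = rng.random((4, 4, 2, 5)) * 100
    out = add_rician_noise(vol, np.inf, rng)
    np.testing.assert_array_equal(out, vol)


def test_rician_zero_signal_has_rayleigh_mean():
    """S = 0 voxels follow a Rayleigh law with mean σ√(π/2)."""
    rng = np.random.default_rng(0)
    sigma = 2.0
    out = add_rician_noise(np.zeros(100_000), 50.0, rng, s0_ref=sigma * 50.0)
    expected = sigma * np.sqrt(np.pi / 2)
    assert out.mean() == pytest.approx(expected, rel=0.02)


def test_rician_deterministic():
    vol = np.full((3, 3, 1, 4), 10.0)
    o1 = add_rician_noise(vol, 20.0, np.random.default_rng(5), s0_ref=10.0)
    o2 = add_rician_noise(vol, 20.0, np.random.default_rng(5), s0_ref=10.0)
    np.testing.assert_array_equal(o1, o2)
    with pytest.raises(ValueError):
        add_rician_noise(vol, -1.0, np.random.default_rng(0))


def test_perturb_mask_zero_magnitude_is_identity():
    mask = _sphere()
    out = perturb_mask(mask, np.random.default_rng(0), magnitude=0.0)
    np.testing.assert_array_equal(out, mask)


def test_perturb_mask_respects_dice_floor():
    mask = _sphere((24, 24, 24), 8.0)
    rng = np.random.default_rng(1)
    out = perturb_mask(mask, rng, magnitude=0.3, dice_floor=0.85)
    inter = np.sum(out & mask)
    dice = 2 * inter / (out.sum() + mask.sum())
    assert 0.85 <= dice < 1.0


def test_perturb_mask_deterministic():
    mask = _sphere()
    o1 = perturb_mask(mask, np.random.default_rng(9))
    o2 = perturb_mask(mask, np.random.default_rng(9))
    np.testing.assert_array_equal(o1, o2)
    with pytest.raises(ValueError):
        perturb_mask(np.zeros((3, 3, 3), bool), np.random.default_rng(0))


def test_generate_cohort_structure_and_determinism(scheme):
    s0, s1 = mibc_like_specs("DKI")
    kw = dict(scheme=scheme, seed=4, shape=(12, 12, 6),
              radius_range=(1.5, 2.5), n_test_per_class=2)
    c1 = generate_cohort(3, s0, s1, **kw)
    c2 = generate_cohort(3, s0, s1, **kw)
    assert len(c1.patients) == 2 * 3 + 2 * 2
    assert sum(p.label for p in c1.subset("training")) == 3
    assert sum(p.label for p in c1.subset("testing")) == 2
    for p1, p2 in zip(c1.patients, c2.patients):
        np.testing.assert_array_equal(p1.dwi, p2.dwi)
        np.testing.assert_array_equal(p1.mask_b, p2.mask_b)
    with pytest.raises(ValueError):
        generate_cohort(1, s0, s1, scheme)


def test_mibc_like_contrast_lowers_diffusivity(scheme):
    """The injected class contrast shows up in the ground-truth maps with
    the designed sign: lower D and higher skew weight in class 1."""
    s0, s1 = mibc_like_specs("DKI")
    assert s1.params["D"].loc == pytest.approx(0.7 * s0.params["D"].loc)
    assert s1.skew_weight > s0.skew_weight
    h0, h1 = hg_like_specs()
    assert h1.params["f"].loc > h0.params["f"].loc


def test_necrosis_exclusion_mask_inside_voi(scheme):
    s0, s1 = mibc_like_specs("DKI")
    cohort = generate_cohort(4, s0, s1, scheme, seed=12, shape=(16, 16, 8),
                             radius_range=(3.0, 4.0), necrosis_prob=1.0)
    found = False
    for p in cohort.patients:
        if p.exclusion_mask is not None:
            found = True
            assert np.all(p.mask[p.exclusion_mask])
    assert found
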