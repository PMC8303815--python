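"""Regions, first-order/shape features, GLCM and the 62-vector assembly."""

import numpy as np
import pytest
from scipy import ndimage

from sonoskin import (FEATURE_NAMES, ClassAppearance, PhantomSpec,
                      attenuation_features, boundary_features, compute_glcm,
                      derive_regions, extract_features, generate_phantom,
                      glcm_descriptors, lesion_contrast_features,
                      shape_features, statistical_features)
from sonoskin.errors import RegionError
from sonoskin.features import GLCM_DESCRIPTORS_H, GLCM_DESCRIPTORS_V

from conftest import layers_of, square_mask


# --- region derivation ----------------------------------------------------

def test_boundary_lane_of_square_matches_enumeration(flat_layers):
    mask = square_mask(top=60, left=70, size=20)
    img = np.random.default_rng(0).uniform(0.2, 0.8, mask.shape)
    regions = derive_regions(img, mask, flat_layers, lane_width=2)
    # direct set arithmetic: pixels within Euclidean distance 2 of the
    # contour, on either side
    d_in = ndimage.distance_transform_edt(mask)
    d_out = ndimage.distance_transform_edt(~mask)
    lane = (mask & (d_in <= 2)) | (~mask & (d_out <= 2))
    assert np.array_equal(regions.boundary_lane, lane)
    # the inner lane is the 2-px frame just inside the square
    inner = mask & (d_in <= 2)
    assert inner.sum() == 20 * 20 - 16 * 16
    assert np.array_equal(regions.boundary_lane & mask, inner)


def test_lesion_touching_dermis_bottom_is_region_error(flat_layers):
    mask = square_mask(top=100, left=70, size=27)  # reaches row 127
    img = np.full(mask.shape, 0.5)
    with pytest.raises(RegionError):
        derive_regions(img, mask, flat_layers, lane_width=2)


def test_zero_lane_width_is_region_error(flat_layers):
    mask = square_mask()
    with pytest.raises(RegionError):
        derive_regions(np.full(mask.shape, 0.5), mask, flat_layers, lane_width=0)


def test_regions_are_disjoint_on_phantom(mm_sample):
    regions = derive_regions(mm_sample.image, mm_sample.truth_mask,
                             layers_of(mm_sample))
    assert not (regions.lesion & regions.dermis_under).any()
    assert not (regions.dermis_under & regions.boundary_lane).any()


# --- attenuation ----------------------------------------------------------

def test_flat_lesion_profile_has_zero_slope(flat_layers):
    mask = square_mask()
    img = np.full(mask.shape, 0.5)
    img[mask] = 0.3
    regions = derive_regions(img, mask, flat_layers)
    att = attenuation_features(img, regions)
    assert att[0] == pytest.approx(0.0, abs=1e-12)
    assert att[2] == pytest.approx(0.0, abs=1e-12)


def test_linear_ramp_recovers_slope(flat_layers):
    mask = square_mask()
    rows = np.arange(128)[:, None].astype(float)
    img = np.full((128, 160), 0.5) + 0.0 * rows
    a = 0.004
    ramp = a * rows * np.ones((1, 160))
    img = np.where(mask, 0.1 + ramp, 0.5)
    regions = derive_regions(img, mask, flat_layers)
    att = attenuation_features(img, regions)
    assert att[0] == pytest.approx(a, rel=1e-9)


def test_shadow_contrast_tracks_phantom_shadow(default_spec):
    def contrast_at(shadow):
        params = ClassAppearance(echogenicity=0.4, shadow=shadow)
        spec = PhantomSpec(class_params={**default_spec.class_params,
                                         "nevus": params})
        vals = []
        for seed in range(5):
            s = generate_phantom(spec, "nevus", seed=seed)
            regions = derive_regions(s.image, s.truth_mask, layers_of(s))
            vals.append(attenuation_features(s.image, regions)[1])
        return np.mean(vals)

    assert contrast_at(0.0) == pytest.approx(0.0, abs=0.06)
    assert contrast_at(0.5) > 0.1


# --- radial contrast ------------------------------------------------------

def test_dark_disk_in_bright_field_contrast(flat_layers):
    img = np.full((128, 160), 0.8)
    rr, cc = np.mgrid[0:128, 0:160]
    disk = (rr - 64) ** 2 + (cc - 80) ** 2 <= 18 ** 2
    img[disk] = 0.2
    regions = derive_regions(img, disk, flat_layers)
    het, mean = lesion_contrast_features(img, regions)
    assert mean == pytest.approx(0.6, abs=1e-12)
    assert het == pytest.approx(0.0, abs=1e-12)


def test_no_contrast_when_lesion_matches_background(flat_layers):
    img = np.full((128, 160), 0.5)
    mask = square_mask()
    regions = derive_regions(img, mask, flat_layers)
    het, mean = lesion_contrast_features(img, regions)
    assert mean == pytest.approx(0.0, abs=1e-12)


def test_mm_contrast_more_heterogeneous_than_nevus(default_spec):
    def mean_het(label):
        vals = []
        for seed in range(20):
            s = generate_phantom(default_spec, label, seed=seed)
            regions = derive_regions(s.image, s.truth_mask, layers_of(s))
            vals.append(lesion_contrast_features(s.image, regions)[0])
        return np.mean(vals)

    assert mean_het("MM") > mean_het("nevus")


# --- boundary formulas ----------------------------------------------------

def test_constant_regions_force_boundary_values():
    # formula contract on hand-built disjoint regions: LB all 0.6, L all 0.3
    from sonoskin.features import RegionTriplet
    shape = (128, 160)
    lesion = square_mask(shape, top=60, left=70, size=20)
    lane = square_mask(shape, top=56, left=66, size=28) & ~lesion
    under = square_mask(shape, top=90, left=70, size=10)
    img2 = np.full(shape, 0.45)
    img2[lesion] = 0.3
    img2[lane] = 0.6
    regions = RegionTriplet(lesion=lesion, dermis_under=under,
                            boundary_lane=lane,
                            dermis_band=np.ones(shape, dtype=bool),
                            centroid=(70.0, 80.0),
                            ray_angles=np.zeros(8), ray_radii=np.zeros(8))
    f = boundary_features(img2, regions)
    assert f[0] == pytest.approx(0.6)                  # idx6 avg(LB)
    assert f[1] == pytest.approx(0.0, abs=1e-12)       # idx7 std(LB)
    assert f[2] == pytest.approx(2.0)                  # idx8 avg(LB)/avg(L)
    assert f[4] == pytest.approx(0.5)  # idx10 (avg LB - avg L)/avg LB

    # exactly-representable constants give exact zero stds -> NaN policy
    img3 = np.full(shape, 0.5)
    img3[lesion] = 0.25
    f3 = boundary_features(img3, regions)
    assert np.isnan(f3[3])                             # idx9 0/0
    assert f3[2] == pytest.approx(2.0)


def test_boundary_formulas_match_naive_recomputation(flat_layers):
    rng = np.random.default_rng(1)
    for _ in range(20):
        mask = square_mask(top=40 + rng.integers(0, 30),
                           left=40 + rng.integers(0, 60),
                           size=12 + rng.integers(0, 12))
        img = rng.uniform(0.1, 0.9, mask.shape)
        regions = derive_regions(img, mask, flat_layers)
        f = boundary_features(img, regions)
        lb = img[regions.boundary_lane]
        le = img[regions.lesion]
        de = img[regions.dermis_under]
        sd = lambda v: v.std(ddof=1)
        expected = [lb.mean(), sd(lb), lb.mean() / le.mean(),
                    sd(lb) / sd(le), (lb.mean() - le.mean()) / lb.mean(),
                    (sd(de) - sd(le)) / sd(de), (sd(lb) - sd(le)) / sd(lb)]
        assert np.allclose(f, expected, rtol=1e-12)


def test_equal_stds_zero_heterogeneity_contrast(flat_layers):
    mask = square_mask()
    rng = np.random.default_rng(2)
    img = np.full(mask.shape, 0.5)
    regions = derive_regions(img, mask, flat_layers)
    vals = rng.uniform(0.2, 0.8, int(regions.lesion.sum()))
    img[regions.lesion] = vals
    # give D the same sample values (same std) by tiling
    d_n = int(regions.dermis_under.sum())
    img[regions.dermis_under] = np.resize(vals, d_n)
    f = boundary_features(img, regions)
    got_std_l = img[regions.lesion].std(ddof=1)
    got_std_d = img[regions.dermis_under].std(ddof=1)
    assert f[5] == pytest.approx((got_std_d - got_std_l) / got_std_d)


# --- statistical ----------------------------------------------------------

def test_symmetric_two_point_distribution_has_zero_skewness(flat_layers):
    mask = square_mask()
    img = np.full(mask.shape, 0.5)
    regions = derive_regions(img, mask, flat_layers)
    n = int(regions.lesion.sum())
    vals = np.where(np.arange(n) % 2 == 0, 0.2, 0.8)
    img[regions.lesion] = vals
    skew, kurt, _ = statistical_features(img, regions)
    assert skew == pytest.approx(0.0, abs=1e-12)
    assert kurt == pytest.approx(1.0, abs=1e-12)  # raw kurtosis of 2-point


def test_constant_region_entropy_zero(flat_layers):
    mask = square_mask()
    img = np.full(mask.shape, 0.5)
    regions = derive_regions(img, mask, flat_layers)
    _, _, entropy = statistical_features(img, regions)
    assert entropy == 0.0


def test_uniform_64_levels_entropy_is_6_bits(flat_layers):
    mask = square_mask(size=16)  # 256 px = 4 per level
    img = np.full(mask.shape, 0.5)
    regions = derive_regions(img, mask, flat_layers)
    n = int(regions.lesion.sum())
    levels = (np.arange(n) % 64) / 63.0
    img[regions.lesion] = levels * 0.5 + 0.25
    _, _, entropy = statistical_features(img, regions)
    assert entropy == pytest.approx(6.0, abs=1e-9)


# --- shape ----------------------------------------------------------------

def test_disk_shape_limits():
    rr, cc = np.mgrid[0:80, 0:80]
    disk = (rr - 40) ** 2 + (cc - 40) ** 2 <= 30 ** 2
    curv_std, circ, axis_ratio, pa, comp = shape_features(disk)
    assert 0.95 <= circ <= 1.05
    assert 1.0 <= axis_ratio <= 1.05
    assert curv_std < 0.01


def test_two_to_one_ellipse_axis_ratio():
    rr, cc = np.mgrid[0:90, 0:150]
    ell = ((rr - 45) / 30.0) ** 2 + ((cc - 75) / 60.0) ** 2 <= 1.0
    _, _, axis_ratio, _, _ = shape_features(ell)
    assert 1.9 <= axis_ratio <= 2.1


def test_shape_scaling_behaviour():
    rr, cc = np.mgrid[0:70, 0:70]
    small = ((rr - 35) / 12.0) ** 2 + ((cc - 35) / 20.0) ** 2 <= 1.0
    rr, cc = np.mgrid[0:140, 0:140]
    big = ((rr - 70) / 24.0) ** 2 + ((cc - 70) / 40.0) ** 2 <= 1.0
    fs, fb = shape_features(small), shape_features(big)
    assert fb[1] == pytest.approx(fs[1], rel=0.02)   # circularity scale-free
    assert fb[2] == pytest.approx(fs[2], rel=0.02)   # axis ratio scale-free
    assert fb[3] == pytest.approx(fs[3] / 2, rel=0.05)  # P/A halves


def test_shape_rotation_invariance(mm_sample):
    mask = mm_sample.truth_mask
    rows = np.nonzero(mask.any(axis=1))[0]
    cols = np.nonzero(mask.any(axis=0))[0]
    crop = mask[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
    pad = np.pad(crop, 10)
    f0 = shape_features(pad)
    f90 = shape_features(np.rot90(pad))
    assert np.allclose(f0, f90, rtol=0.03)


# --- GLCM -----------------------------------------------------------------

def brute_force_descriptors(M):
    """Literal double-loop implementation of all 13 statistics."""
    G = M.shape[0]
    px = M.sum(axis=1)
    py = M.sum(axis=0)
    mu_x = sum(i * px[i] for i in range(G))
    mu_y = sum(j * py[j] for j in range(G))
    sd_x = np.sqrt(sum((i - mu_x) ** 2 * px[i] for i in range(G)))
    sd_y = np.sqrt(sum((j - mu_y) ** 2 * py[j] for j in range(G)))
    out = dict.fromkeys(
        ["contrast", "correlation1", "correlation2", "dissimilarity",
         "energy", "entropy", "homogeneity1", "homogeneity2",
         "max_probability", "difference_variance", "difference_entropy",
         "infocorr1", "infocorr2"], 0.0)
    p_diff = np.zeros(G)
    for i in range(G):
        for j in range(G):
            p = M[i, j]
            out["contrast"] += (i - j) ** 2 * p
            out["dissimilarity"] += abs(i - j) * p
            out["energy"] += p * p
            if p > 0:
                out["entropy"] -= p * np.log2(p)
            out["homogeneity1"] += p / (1 + abs(i - j))
            out["homogeneity2"] += p / (1 + (i - j) ** 2)
            p_diff[abs(i - j)] += p
    out["max_probability"] = M.max()
    out["correlation1"] = sum((i - mu_x) * (j - mu_y) * M[i, j]
                              for i in range(G) for j in range(G)) / (sd_x * sd_y)
    out["correlation2"] = (sum(i * j * M[i, j] for i in range(G)
                               for j in range(G)) - mu_x * mu_y) / (sd_x * sd_y)
    mu_d = sum(k * p_diff[k] for k in range(G))
    out["difference_variance"] = sum((k - mu_d) ** 2 * p_diff[k] for k in range(G))
    out["difference_entropy"] = -sum(p_diff[k] * np.log2(p_diff[k])
                                     for k in range(G) if p_diff[k] > 0)
    hxy = -sum(M[i, j] * np.log(M[i, j]) for i in range(G) for j in range(G)
               if M[i, j] > 0)
    hxy1 = -sum(M[i, j] * np.log(px[i] * py[j]) for i in range(G)
                for j in range(G) if px[i] * py[j] > 0)
    hxy2 = -sum(px[i] * py[j] * np.log(px[i] * py[j]) for i in range(G)
                for j in range(G) if px[i] * py[j] > 0)
    hx = -sum(p * np.log(p) for p in px if p > 0)
    hy = -sum(p * np.log(p) for p in py if p > 0)
    out["infocorr1"] = (hxy - hxy1) / max(hx, hy)
    out["infocorr2"] = np.sqrt(max(0.0, 1 - np.exp(-2 * (hxy2 - hxy))))
    return out


def test_constant_region_glcm_is_diagonal_delta(flat_layers):
    img = np.full((128, 160), 0.5)
    mask = square_mask()
    M = compute_glcm(img, mask, "vertical", levels=8)
    assert M[0, 0] == 1.0 and M.sum() == 1.0


def test_two_by_two_hand_enumeration():
    img = np.array([[0.0, 1.0], [0.0, 1.0]])
    region = np.ones((2, 2), dtype=bool)
    M = compute_glcm(img, region, "horizontal", levels=2)
    assert M[0, 1] == pytest.approx(0.5)
    assert M[1, 0] == pytest.approx(0.5)
    assert M[0, 0] == M[1, 1] == 0.0


def test_glcm_normalized_on_random_regions(nevus_sample):
    M = compute_glcm(nevus_sample.image, nevus_sample.truth_mask, "vertical")
    assert M.sum() == pytest.approx(1.0)
    assert np.allclose(M, M.T)


def test_diagonal_matrix_descriptor_limits():
    M = np.diag([0.5, 0.3, 0.2])
    d = glcm_descriptors(M)
    assert d["contrast"] == 0.0 and d["dissimilarity"] == 0.0
    assert d["max_probability"] == 0.5


def test_uniform_matrix_closed_forms():
    G = 8
    M = np.full((G, G), 1.0 / G**2)
    d = glcm_descriptors(M)
    assert d["energy"] == pytest.approx(1.0 / G**2)
    assert d["entropy"] == pytest.approx(2 * np.log2(G))


@pytest.mark.parametrize("seed", range(10))
def test_descriptors_match_brute_force(seed):
    rng = np.random.default_rng(seed)
    G = rng.integers(3, 8)
    M = rng.uniform(0, 1, (G, G))
    M = M + M.T
    M /= M.sum()
    got = glcm_descriptors(M)
    want = brute_force_descriptors(M)
    for key in want:
        assert got[key] == pytest.approx(want[key], rel=1e-10), key


# --- assembly -------------------------------------------------------------

def test_feature_vector_has_62_entries_and_is_deterministic(nevus_sample):
    regions = derive_regions(nevus_sample.image, nevus_sample.truth_mask,
                             layers_of(nevus_sample))
    fv1 = extract_features(nevus_sample.image, regions)
    fv2 = extract_features(nevus_sample.image, regions)
    assert fv1.values.shape == (62,)
    assert len(FEATURE_NAMES) == 62
    assert np.array_equal(fv1.values, fv2.values)


def test_block_layout_matches_published_index_sets():
    # the four (region, direction) blocks must honour the printed per-
    # descriptor index sets: contrast at {21,29,42,50}, energy at {33,54},
    # infocorr2 at {41,62}, etc.
    def indices_of(desc):
        return [i + 1 for i, name in enumerate(FEATURE_NAMES)
                if i >= 20 and name.split("_")[1] == desc]

    assert indices_of("contrast") == [21, 29, 42, 50]
    assert indices_of("maxprob") == [25, 37, 46, 58]
    assert indices_of("diffvar") == [26, 38, 47, 59]
    assert indices_of("energy") == [33, 54]
    assert indices_of("infocorr2") == [41, 62]
    assert FEATURE_NAMES[61].endswith("dermis_v")
    assert len(GLCM_DESCRIPTORS_H) == 8 and len(GLCM_DESCRIPTORS_V) == 13


def test_lateral_mirroring_leaves_features_unchanged(nevus_sample):
    regions = derive_regions(nevus_sample.image, nevus_sample.truth_mask,
                             layers_of(nevus_sample))
    fv = extract_features(nevus_sample.image, regions)
    mirrored = nevus_sample.image[:, ::-1].copy()
    m_mask = nevus_sample.truth_mask[:, ::-1].copy()
    m_regions = derive_regions(mirrored, m_mask, layers_of(nevus_sample))
    m_fv = extract_features(mirrored, m_regions)
    # first-order and GLCM features are mirror-invariant (symmetrized GLCM)
    idx = np.r_[0:15, 20:62]
    assert np.allclose(fv.values[idx], m_fv.values[idx], rtol=1e-8,
                       atol=1e-10, equal_nan=True)


def test_glcm_contrast_increases_with_phantom_heterogeneity(default_spec):
    def mean_contrast(h):
        params = ClassAppearance(echogenicity=0.45, heterogeneity=h)
        spec = PhantomSpec(class_params={**default_spec.class_params,
                                         "nevus": params})
        vals = []
        for seed in range(20):
            s = generate_phantom(spec, "nevus", seed=seed)
            M = compute_glcm(s.image, s.truth_mask, "vertical")
            vals.append(glcm_descriptors(M)["contrast"])
        return np.mean(vals)

    c1, c2, c3 = mean_contrast(1.0), mean_contrast(1.6), mean_contrast(2.2)
    assert c1 < c2 < c3
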