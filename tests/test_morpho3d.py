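import math
from collections import deque

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spheromorph import (
    EllipsoidAxes,
    EmptySegmentationError,
    Mask3D,
    PhantomSpec,
    SegmentationParams,
    VoxelGrid,
    denoise_nlm,
    eccentricities,
    equivalent_ellipsoid,
    estimate_noise_sigma,
    hysteresis_segment,
    make_phantom_3d,
    measure_shape_3d,
    otsu_threshold,
    resample_isotropic,
    roundness_3d,
    segment_spheroid_3d,
    sphericity_3d,
    surface_area,
    thickness_and_diameter,
)

from conftest import rasterize_ellipsoid_mask


def brute_force_otsu(values, nbins=256):
    """Exhaustive intraclass-variance scan over all bin boundaries."""
    values = np.asarray(values, dtype=float).ravel()
    hist, edges = np.histogram(values, bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    h = hist.astype(float)
    best, best_thr = np.inf, None
    for k in range(1, nbins):
        w0, w1 = h[:k].sum(), h[k:].sum()
        if w0 == 0 or w1 == 0:
            continue
        m0 = (h[:k] * centers[:k]).sum() / w0
        m1 = (h[k:] * centers[k:]).sum() / w1
        intra = (h[:k] * (centers[:k] - m0) ** 2).sum() + (h[k:] * (centers[k:] - m1) ** 2).sum()
        if intra < best:
            best, best_thr = intra, centers[k - 1]
    return best_thr, best


def intraclass_variance(values, thr, nbins=256):
    values = np.asarray(values, dtype=float).ravel()
    hist, edges = np.histogram(values, bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    h = hist.astype(float)
    lo, hi = centers <= thr, centers > thr
    out = 0.0
    for sel in (lo, hi):
        w = h[sel].sum()
        if w > 0:
            m = (h[sel] * centers[sel]).sum() / w
            out += (h[sel] * (centers[sel] - m) ** 2).sum()
    return out


def bfs_hysteresis_oracle(data, low, high):
    """Flood fill from strong seeds through weak voxels, 26-connectivity."""
    weak = data >= low
    out = np.zeros(data.shape, dtype=bool)
    queue = deque(map(tuple, np.argwhere(data >= high)))
    for p in queue:
        out[p] = True
    offsets = [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1)
               for dx in (-1, 0, 1) if (dz, dy, dx) != (0, 0, 0)]
    while queue:
        z, y, x = queue.popleft()
        for dz, dy, dx in offsets:
            q = (z + dz, y + dy, x + dx)
            if (0 <= q[0] < data.shape[0] and 0 <= q[1] < data.shape[1]
                    and 0 <= q[2] < data.shape[2] and weak[q] and not out[q]):
                out[q] = True
                queue.append(q)
    return out


class TestResampleIsotropic:
    def test_extent_arithmetic(self):
        grid = VoxelGrid(np.zeros((100, 200, 200)), spacing=(2.0, 1.3, 1.3))
        iso = resample_isotropic(grid, 1.3)
        assert iso.spacing == (1.3, 1.3, 1.3)
        assert abs(iso.shape[0] - 100 * 2.0 / 1.3) <= 1
        assert iso.shape[1:] == (200, 200)

    def test_identity_when_already_isotropic(self):
        rng = np.random.default_rng(0)
        grid = VoxelGrid(rng.random((20, 20, 20)), spacing=(1.5, 1.5, 1.5))
        iso = resample_isotropic(grid, 1.5)
        np.testing.assert_array_equal(iso.data, grid.data)

    def test_volume_conserved_on_sphere(self):
        mask = rasterize_ellipsoid_mask((60, 60, 60), (2.0, 1.3, 1.3))
        grid = VoxelGrid(mask.data.astype(float), spacing=mask.spacing)
        before = mask.data.sum() * mask.voxel_volume
        iso = resample_isotropic(grid, 1.3)
        after = (iso.data > 0.5).sum() * iso.voxel_volume
        assert after == pytest.approx(before, rel=0.02)


class TestEstimateNoiseSigma:
    def test_known_sigma_recovered(self):
        rng = np.random.default_rng(5)
        grid = VoxelGrid(100 + rng.normal(0, 10, (64, 64, 64)), spacing=(1, 1, 1))
        assert 9.0 <= estimate_noise_sigma(grid) <= 11.0

    def test_noise_free_phantom_near_zero(self):
        mask = rasterize_ellipsoid_mask((30, 30, 30), (1.0, 1.0, 1.0))
        grid = VoxelGrid(np.where(mask.data, 200.0, 20.0), spacing=(1, 1, 1))
        assert estimate_noise_sigma(grid) <= 0.5

    def test_linearity_in_intensity(self):
        rng = np.random.default_rng(6)
        data = 50 + rng.normal(0, 7, (48, 48, 48))
        s1 = estimate_noise_sigma(VoxelGrid(data, spacing=(1, 1, 1)))
        s2 = estimate_noise_sigma(VoxelGrid(2 * data, spacing=(1, 1, 1)))
        assert s2 == pytest.approx(2 * s1, rel=0.05)


class TestDenoiseNLM:
    def test_zero_strength_is_identity(self):
        rng = np.random.default_rng(7)
        grid = VoxelGrid(rng.random((16, 16, 16)), spacing=(1, 1, 1))
        out = denoise_nlm(grid, sigma=5.0, strength=0.0)
        np.testing.assert_array_equal(out.data, grid.data)

    def test_background_noise_reduced_and_mean_preserved(self):
        spec = PhantomSpec(shape="sphere", axes=(60.0, 60.0, 60.0),
                           spacing=(1.5, 1.5, 1.5), levels=(30.0, 600.0, 600.0),
                           noise_sigma=15.0, seed=8)
        grid, truth = make_phantom_3d(spec)
        sigma = estimate_noise_sigma(grid)
        den = denoise_nlm(grid, sigma, strength=0.8)
        background = ~truth.mask.data
        assert grid.data[background].std() / den.data[background].std() >= 2.0
        assert den.data.mean() == pytest.approx(grid.data.mean(), rel=0.01)


class TestOtsuThreshold:
    def test_two_point_histogram(self):
        values = np.array([10.0] * 500 + [200.0] * 500)
        t = otsu_threshold(values)
        assert 10.0 < t < 200.0
        oracle_thr, oracle_val = brute_force_otsu(values)
        assert intraclass_variance(values, t) == pytest.approx(oracle_val, rel=1e-9, abs=1e-12)

    def test_gaussian_mixture_threshold_location(self):
        rng = np.random.default_rng(9)
        values = np.concatenate([rng.normal(30, 10, 5000), rng.normal(180, 10, 5000)])
        assert 80.0 <= otsu_threshold(values) <= 130.0

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            otsu_threshold(np.full(100, 3.0))

    def test_matches_brute_force_on_random_histograms(self):
        """The returned threshold attains exactly the brute-force
        intraclass-variance minimum over all histogram splits (thresholds
        themselves may sit elsewhere on a tie plateau, where every split is
        an equally optimal minimiser)."""
        rng = np.random.default_rng(10)
        for _ in range(25):
            values = np.concatenate([
                rng.normal(rng.uniform(10, 60), rng.uniform(2, 15), rng.integers(50, 400)),
                rng.normal(rng.uniform(120, 220), rng.uniform(5, 30), rng.integers(50, 400)),
            ])
            t = otsu_threshold(values)
            _, oracle_val = brute_force_otsu(values)
            assert intraclass_variance(values, t) == pytest.approx(oracle_val, rel=1e-12)
            assert values.min() < t < values.max()


class TestHysteresisSegment:
    def test_hand_traced_line(self):
        data = np.array([0.0, 5.0, 9.0, 2.0, 0.0]).reshape(1, 1, 5)
        mask = hysteresis_segment(VoxelGrid(data, spacing=(1, 1, 1)), low=4, high=8)
        np.testing.assert_array_equal(mask.data[0, 0], [False, True, True, False, False])

    def test_all_below_low_is_empty(self):
        grid = VoxelGrid(np.full((4, 4, 4), 1.0), spacing=(1, 1, 1))
        assert not hysteresis_segment(grid, low=4, high=8).data.any()

    def test_low_equals_high_is_single_threshold(self):
        rng = np.random.default_rng(11)
        data = rng.random((8, 8, 8))
        mask = hysteresis_segment(VoxelGrid(data, spacing=(1, 1, 1)), 0.5, 0.5)
        np.testing.assert_array_equal(mask.data, data >= 0.5)

    def test_low_above_high_rejected(self):
        grid = VoxelGrid(np.zeros((3, 3, 3)), spacing=(1, 1, 1))
        with pytest.raises(ValueError):
            hysteresis_segment(grid, low=2.0, high=1.0)

    def test_matches_bfs_oracle_on_random_grids(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            data = rng.random((10, 10, 10))
            mask = hysteresis_segment(VoxelGrid(data, spacing=(1, 1, 1)), 0.5, 0.85)
            np.testing.assert_array_equal(mask.data, bfs_hysteresis_oracle(data, 0.5, 0.85))


class TestSegmentSpheroid3D:
    def test_bivariate_sphere_dice(self, noisy_sphere_phantom):
        grid, truth = noisy_sphere_phantom
        mask = segment_spheroid_3d(grid)
        gt_iso = resample_isotropic(
            VoxelGrid(truth.mask.data.astype(float), spacing=grid.spacing), 1.3
        )
        gt = gt_iso.data > 0.5
        dice = 2 * (gt & mask.data).sum() / (gt.sum() + mask.data.sum())
        assert dice >= 0.97

    def test_trivariate_core_not_hollow(self):
        spec = PhantomSpec(shape="sphere", axes=(80.0, 80.0, 80.0),
                           spacing=(2.0, 1.3, 1.3), intensity_model="trivariate",
                           levels=(30.0, 300.0, 600.0), noise_sigma=50.0, seed=13)
        grid, truth = make_phantom_3d(spec)
        mask = segment_spheroid_3d(grid)
        gt_iso = resample_isotropic(
            VoxelGrid(truth.mask.data.astype(float), spacing=grid.spacing), 1.3
        )
        gt = gt_iso.data > 0.5
        dice = 2 * (gt & mask.data).sum() / (gt.sum() + mask.data.sum())
        assert dice >= 0.95
        # center voxel (dim core) is inside the mask, not a hollow shell
        assert mask.data[tuple(s // 2 for s in mask.data.shape)]

    def test_pure_noise_raises(self):
        rng = np.random.default_rng(14)
        grid = VoxelGrid(rng.normal(100, 10, (48, 48, 48)), spacing=(1, 1, 1))
        with pytest.raises(EmptySegmentationError):
            segment_spheroid_3d(grid)

    def test_constant_grid_rejected(self):
        with pytest.raises(ValueError):
            segment_spheroid_3d(VoxelGrid(np.full((20, 20, 20), 5.0), spacing=(1, 1, 1)))


class TestEquivalentEllipsoid:
    def test_solid_ellipsoid_moment_identity(self):
        mask = rasterize_ellipsoid_mask((100, 80, 50), (1.0, 1.0, 1.0))
        axes = equivalent_ellipsoid(mask)
        assert axes.a == pytest.approx(100, rel=0.02)
        assert axes.b == pytest.approx(80, rel=0.02)
        assert axes.c == pytest.approx(50, rel=0.02)

    def test_sphere_symmetry(self, sphere_mask):
        axes = equivalent_ellipsoid(sphere_mask)
        for v in (axes.a, axes.b, axes.c):
            assert v == pytest.approx(50, rel=0.02)

    def test_rotation_invariance(self):
        ref = None
        for angles in [(0, 0, 0), (30, 20, 10), (45, 0, 60)]:
            spec = PhantomSpec(shape="ellipsoid", axes=(100.0, 80.0, 50.0),
                               spacing=(1.0, 1.0, 1.0), noise_sigma=0.0,
                               rotation_deg=angles, seed=0)
            _, truth = make_phantom_3d(spec)
            axes = equivalent_ellipsoid(truth.mask)
            got = (axes.a, axes.b, axes.c)
            if ref is None:
                ref = got
            for x, y in zip(got, ref):
                assert x == pytest.approx(y, rel=0.02)

    def test_too_few_voxels_rejected(self):
        data = np.zeros((5, 5, 5), bool)
        data[2, 2, 2] = True
        with pytest.raises(ValueError):
            equivalent_ellipsoid(Mask3D(data, spacing=(1, 1, 1)))


class TestEccentricities:
    def test_sphere_is_zero(self):
        assert eccentricities(EllipsoidAxes(5, 5, 5)) == (0.0, 0.0)

    def test_closed_form_values(self):
        e1, e2 = eccentricities(EllipsoidAxes(100, 80, 50))
        assert e1 == pytest.approx(math.sqrt(1 - 0.25), rel=1e-12)
        assert e2 == pytest.approx(math.sqrt(1 - 2500 / 6400), rel=1e-12)

    def test_flat_limit_approaches_one(self):
        e1, e2 = eccentricities(EllipsoidAxes(100, 80, 1e-6))
        assert e1 == pytest.approx(1.0, abs=1e-9)
        assert e2 == pytest.approx(1.0, abs=1e-9)

    @given(st.floats(1, 100), st.floats(1, 100), st.floats(1, 100))
    @settings(deadline=None, max_examples=60)
    def test_ordering_e1_ge_e2(self, x, y, z):
        a, b, c = sorted((x, y, z), reverse=True)
        if c <= 0:
            return
        e1, e2 = eccentricities(EllipsoidAxes(a, b, c))
        assert 0.0 <= e2 <= e1 < 1.0 + 1e-12


class TestDescriptorFormulas:
    def test_sphere_normalizations_exact(self):
        for r in (0.1, 1.0, 3.7):
            vol = (4 / 3) * math.pi * r**3
            area = 4 * math.pi * r**2
            assert sphericity_3d(vol, area) == pytest.approx(1.0, rel=1e-12)
            d = 2 * r
            assert roundness_3d((math.pi / 6) * d**3, d) == pytest.approx(1.0, rel=1e-12)

    def test_ellipsoid_sphericity_below_one(self):
        # 2:1:1 ellipsoid, analytic prolate surface
        a, c = 2.0, 1.0  # polar semi-axis a along symmetry axis, equatorial c
        e = math.sqrt(1 - c**2 / a**2)
        surface = 2 * math.pi * c**2 * (1 + (a / (c * e)) * math.asin(e))
        vol = (4 / 3) * math.pi * a * c * c
        assert sphericity_3d(vol, surface) < 1.0

    def test_prolate_roundness_quarter(self):
        length = 4.0
        vol = (math.pi / 6) * length * (length / 2) ** 2
        assert roundness_3d(vol, length) == pytest.approx(0.25, rel=1e-12)

    def test_scale_invariance(self):
        vol, area = 2.3, 5.7
        for s in (0.1, 10.0):
            assert sphericity_3d(vol * s**3, area * s**2) == pytest.approx(
                sphericity_3d(vol, area), rel=1e-12
            )
            assert roundness_3d(vol * s**3, 1.9 * s) == pytest.approx(
                roundness_3d(vol, 1.9), rel=1e-12
            )

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            sphericity_3d(0.0, 1.0)
        with pytest.raises(ValueError):
            roundness_3d(1.0, 0.0)


class TestSurfaceArea:
    def test_sphere_mesh_accuracy(self, sphere_mask):
        true_mm2 = 4 * math.pi * 50**2 / 1e6
        assert surface_area(sphere_mask) == pytest.approx(true_mm2, rel=0.03)

    def test_ellipsoid_thomsen_accuracy(self):
        mask = rasterize_ellipsoid_mask((100, 80, 50), (1.0, 1.0, 1.0))
        p = 1.6075
        a, b, c = 100, 80, 50
        true_um2 = 4 * math.pi * (((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3) ** (1 / p)
        assert surface_area(mask) == pytest.approx(true_um2 / 1e6, rel=0.03)

    def test_voxel_face_counting_would_fail(self, sphere_mask):
        """Exposed-face counting carries a >30% staircase bias on a sphere —
        regression guard that the mesh estimator stays in use."""
        m = sphere_mask.data
        faces = 0
        for axis in range(3):
            faces += np.logical_xor(m, np.roll(m, 1, axis)).sum()
        naive_mm2 = faces * 1.0 / 1e6  # 1 µm² per face
        true_mm2 = 4 * math.pi * 50**2 / 1e6
        assert naive_mm2 / true_mm2 > 1.3
        assert surface_area(sphere_mask) == pytest.approx(true_mm2, rel=0.03)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            surface_area(Mask3D(np.zeros((5, 5, 5), bool), spacing=(1, 1, 1)))


class TestThicknessAndDiameter:
    def test_half_sphere_geometry(self):
        spec = PhantomSpec(shape="half_sphere", axes=(80.0, 80.0, 80.0),
                           spacing=(1.0, 1.0, 1.0), noise_sigma=0.0, seed=0)
        _, truth = make_phantom_3d(spec)
        thickness, diameter = thickness_and_diameter(truth.mask)
        assert thickness == pytest.approx(80, rel=0.02)
        assert diameter == pytest.approx(160, rel=0.02)

    def test_full_sphere_symmetry(self, sphere_mask):
        thickness, diameter = thickness_and_diameter(sphere_mask)
        assert thickness == pytest.approx(100, rel=0.02)
        assert diameter == pytest.approx(100, rel=0.02)

    def test_oblate_ellipsoid_closed_form(self):
        mask = rasterize_ellipsoid_mask((100, 100, 30), (1.0, 1.0, 1.0))
        thickness, diameter = thickness_and_diameter(mask)
        assert thickness == pytest.approx(60, rel=0.02)
        assert diameter == pytest.approx(200, rel=0.02)


class TestMeasureShape3D:
    def test_sphere_descriptor_suite(self, sphere_mask):
        m = measure_shape_3d(sphere_mask)
        true_vol = (4 / 3) * math.pi * 50**3 / 1e9
        assert m.volume_mm3 == pytest.approx(true_vol, rel=0.02)
        assert m.sphericity >= 0.95
        assert m.roundness >= 0.95
        assert m.e1 <= 0.15
        assert m.max_thickness_um == pytest.approx(m.max_diameter_um, rel=0.03)

    def test_oblate_series_monotone_descriptors(self):
        """Flattening a sphere monotonically lowers sphericity and roundness
        and raises e1."""
        sph, rnd, e1s = [], [], []
        for c in (60, 50, 40, 30, 20):
            mask = rasterize_ellipsoid_mask((60, 60, c), (1.0, 1.0, 1.0))
            m = measure_shape_3d(mask)
            sph.append(m.sphericity)
            rnd.append(m.roundness)
            e1s.append(m.e1)
        assert all(a > b for a, b in zip(sph, sph[1:]))
        assert all(a > b for a, b in zip(rnd, rnd[1:]))
        assert all(a < b for a, b in zip(e1s, e1s[1:]))
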