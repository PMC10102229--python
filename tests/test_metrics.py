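import math

import numpy as np
import pytest

from sycbct.io_volumes import SurfaceMesh, Volume
from sycbct.metrics import (
    DeviationReport,
    SsimParams,
    TissueMasks,
    align_icp,
    evaluate_pair,
    extract_surface,
    mae,
    point_to_surface_distance,
    psnr,
    segment_tissues,
    ssim,
    surface_deviation_rms,
)
from sycbct.phantom import AIR, HARD, SOFT
from sycbct.preprocess import RigidTransform


# --- independent oracles (kept deliberately naive) -----------------------


def oracle_mae(sy, ref, mask):
    total = 0.0
    n = 0
    for i in np.ndindex(sy.shape):
        if mask[i]:
            total += abs(sy[i] - ref[i])
            n += 1
    return total / n


def oracle_psnr(sy, ref, mask, f_max):
    se = 0.0
    n = 0
    for i in np.ndindex(sy.shape):
        if mask[i]:
            se += (sy[i] - ref[i]) ** 2
            n += 1
    return 10 * math.log10(f_max**2 / (se / n))


def oracle_ssim_global(sy, ref, mask, c1, c2):
    xs = [sy[i] for i in np.ndindex(sy.shape) if mask[i]]
    ys = [ref[i] for i in np.ndindex(ref.shape) if mask[i]]
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    vx = sum((x - mx) ** 2 for x in xs) / n
    vy = sum((y - my) ** 2 for y in ys) / n
    cov = sum((x - mx) * (y - my) for x, y in zip(xs, ys)) / n
    return ((2 * mx * my + c1) * (2 * cov + c2)) / ((mx**2 + my**2 + c1) * (vx + vy + c2))


class TestVoxelMetricOracles:
    def test_all_metrics_match_brute_force_on_random_volumes(self, rng):
        for _ in range(3):
            sy = rng.uniform(0, 2, size=(8, 8, 8))
            ref = rng.uniform(0, 2, size=(8, 8, 8))
            mask = rng.uniform(size=(8, 8, 8)) > 0.3
            np.testing.assert_allclose(mae(sy, ref, mask), oracle_mae(sy, ref, mask), rtol=1e-10)
            np.testing.assert_allclose(
                psnr(sy, ref, mask, f_max=2.0), oracle_psnr(sy, ref, mask, 2.0), rtol=1e-10
            )
            p = SsimParams(dynamic_range=2.0)
            np.testing.assert_allclose(
                ssim(sy, ref, mask, p),
                oracle_ssim_global(sy, ref, mask, p.c1_value, p.c2_value),
                rtol=1e-10,
            )

    def test_identity_reference_values(self, rng):
        # ideal values: MAE 0, SSIM 1, PSNR reported as identical (inf)
        v = rng.uniform(size=(6, 6, 6))
        assert mae(v, v) == 0.0
        assert ssim(v, v) == pytest.approx(1.0)
        assert math.isinf(psnr(v, v))

    def test_mae_toy_case(self):
        sy = np.array([[1.0, 2.0], [3.0, 4.0]]).reshape(2, 2, 1)
        ref = np.array([[1.0, 0.0], [0.0, 4.0]]).reshape(2, 2, 1)
        assert mae(sy, ref) == 1.25

    def test_constant_offset_mae(self, rng):
        v = rng.normal(size=(5, 5, 5))
        assert mae(v + 5.0, v) == pytest.approx(5.0)

    @pytest.mark.parametrize("ratio,expected_db", [(1.0, 0.0), (0.1, 20.0)])
    def test_psnr_closed_form(self, ratio, expected_db):
        # rmse = ratio * f_max -> 10 log10(1 / ratio^2)
        f_max = 3.0
        ref = np.zeros((4, 4, 4))
        sy = np.full((4, 4, 4), ratio * f_max)
        assert psnr(sy, ref, f_max=f_max) == pytest.approx(expected_db)

    def test_ssim_constant_volumes_closed_form(self):
        a, b = 0.4, 0.9
        p = SsimParams(dynamic_range=1.0)
        c1, c2 = p.c1_value, p.c2_value
        expected = (2 * a * b + c1) / (a * a + b * b + c1)  # variance terms give c2/c2
        got = ssim(np.full((4, 4, 4), a), np.full((4, 4, 4), b), p=p)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_ssim_never_exceeds_one(self, rng):
        for _ in range(10):
            sy = rng.normal(size=(6, 6, 6))
            ref = rng.normal(size=(6, 6, 6))
            assert ssim(sy, ref) <= 1.0

    def test_mae_ssim_symmetric_psnr_fmax_convention(self, rng):
        sy = rng.uniform(0, 1, size=(6, 6, 6))
        ref = rng.uniform(0, 1, size=(6, 6, 6))
        assert mae(sy, ref) == mae(ref, sy)
        assert ssim(sy, ref) == pytest.approx(ssim(ref, sy), rel=1e-12)
        assert psnr(sy, ref, f_max=1.0) == pytest.approx(psnr(ref, sy, f_max=1.0))

    def test_gaussian_window_mode_runs_and_bounded(self, rng):
        sy = rng.uniform(size=(12, 12, 12))
        assert ssim(sy, sy, p=SsimParams(dynamic_range=1.0, window="gaussian_11")) == pytest.approx(1.0)

    def test_empty_mask_rejected(self, rng):
        v = rng.normal(size=(3, 3, 3))
        with pytest.raises(ValueError, match="empty mask"):
            mae(v, v, np.zeros((3, 3, 3), dtype=bool))


class TestSegmentTissues:
    def test_phantom_midpoint_thresholds_recover_labels(self, clean_phantom):
        cfg, study, labels = clean_phantom
        a, s, h = cfg.intensity_map.cbct
        masks = segment_tissues(study.cbct, ((a + s) / 2, (s + h) / 2))
        np.testing.assert_array_equal(masks.hard, labels.labels == HARD)
        np.testing.assert_array_equal(masks.soft, labels.labels == SOFT)
        np.testing.assert_array_equal(masks.air, labels.labels == AIR)

    def test_partition_of_fov(self, rng):
        v = rng.uniform(0, 10, size=(6, 6, 6))
        masks = segment_tissues(v, (3.0, 7.0))
        assert not (masks.hard & masks.soft).any()
        assert masks.fov.all()

    def test_all_below_first_threshold(self):
        masks = segment_tissues(np.zeros((4, 4, 4)), (1.0, 2.0))
        assert masks.air.all() and not masks.soft.any() and not masks.hard.any()

    def test_unordered_thresholds_rejected(self):
        with pytest.raises(ValueError):
            segment_tissues(np.zeros((2, 2, 2)), (2.0, 1.0))


class TestEvaluatePair:
    def test_identity_report(self, clean_phantom, rng):
        cfg, study, labels = clean_phantom
        masks = TissueMasks(
            hard=labels.labels == HARD, soft=labels.labels == SOFT, air=labels.labels == AIR,
            source="phantom_labels",
        )
        rep = evaluate_pair(study.cbct, study.cbct, masks)
        for cls in ("hard", "soft", "air", "global"):
            assert rep.per_class[cls]["mae"] == 0.0
            assert rep.per_class[cls]["ssim"] == pytest.approx(1.0)
            assert math.isinf(rep.per_class[cls]["psnr"])
        assert rep.to_dict()["hard"]["psnr"] == "identical"

    def test_noise_on_soft_leaves_hard_mae_unchanged(self, clean_phantom, rng):
        cfg, study, labels = clean_phantom
        masks = TissueMasks(
            hard=labels.labels == HARD, soft=labels.labels == SOFT, air=labels.labels == AIR
        )
        sy = np.asarray(study.cbct.values).copy()
        sy[masks.soft] += rng.normal(0, 50, size=int(masks.soft.sum()))
        rep = evaluate_pair(sy, study.cbct, masks)
        assert rep.per_class["hard"]["mae"] == 0.0
        assert rep.per_class["soft"]["mae"] > 0.0

    def test_report_matches_standalone_ops(self, clean_phantom, rng):
        cfg, study, labels = clean_phantom
        masks = TissueMasks(
            hard=labels.labels == HARD, soft=labels.labels == SOFT, air=labels.labels == AIR
        )
        sy = np.asarray(study.cbct.values) + rng.normal(0, 10, size=study.cbct.shape)
        rep = evaluate_pair(sy, study.cbct, masks)
        for cls, m in masks.items():
            assert rep.per_class[cls]["mae"] == mae(sy, study.cbct, m)
            assert rep.per_class[cls]["ssim"] == ssim(sy, study.cbct, m)

    def test_tissue_ssim_ordering_on_realistic_phantom(self, noisy_phantom):
        # hard structures synthesized faithfully + soft/air noise ->
        # hard-tissue SSIM dominates, mirroring the clinical reading
        cfg, study, labels = noisy_phantom
        masks = TissueMasks(
            hard=labels.labels == HARD, soft=labels.labels == SOFT, air=labels.labels == AIR
        )
        rng = np.random.default_rng(0)
        ref = np.asarray(study.cbct.values)
        means = np.asarray(cfg.intensity_map.cbct)[labels.labels].astype(float)
        # faithful hard tissue: tracks the reference up to small noise;
        # soft/air: denoised class means (structure lost, as in synthesis)
        sy = means + rng.normal(0, 15, size=means.shape)
        sy[masks.hard] = ref[masks.hard] + rng.normal(0, 5, size=int(masks.hard.sum()))
        p = SsimParams(dynamic_range=float(np.ptp(study.cbct.values)))
        rep = evaluate_pair(sy, study.cbct, masks, p)
        assert rep.per_class["hard"]["ssim"] > rep.per_class["soft"]["ssim"]
        assert rep.per_class["hard"]["ssim"] > rep.per_class["air"]["ssim"]


def sphere_volume(n=32, r=10.0, spacing=0.5):
    c = (n - 1) / 2
    g = np.mgrid[:n, :n, :n]
    d = np.sqrt(((g - c) ** 2).sum(axis=0))
    return Volume((d <= r).astype(float), (spacing,) * 3)


class TestSurfaces:
    def test_sphere_vertex_radii(self):
        n, r, sp = 32, 10.0, 0.5
        mesh = extract_surface(sphere_volume(n, r, sp), 0.5)
        c = (n - 1) / 2 * sp
        radii = np.linalg.norm(mesh.vertices - c, axis=1)
        assert abs(radii.mean() - r * sp) < sp  # within one voxel
        assert mesh.n_faces > 0

    def test_constant_volume_rejected(self):
        with pytest.raises(ValueError):
            extract_surface(Volume(np.zeros((8, 8, 8)), (1, 1, 1)), 0.5)

    def test_vertices_inside_volume_bounds(self):
        vol = sphere_volume()
        mesh = extract_surface(vol, 0.5)
        upper = (np.array(vol.shape) - 1) * np.array(vol.spacing)
        assert (mesh.vertices >= 0).all() and (mesh.vertices <= upper).all()


class TestIcp:
    def test_identical_meshes_identity(self):
        mesh = extract_surface(sphere_volume(), 0.5)
        t = align_icp(mesh, mesh, iters=5)
        assert np.abs(t.translations).max() < 1e-6
        assert np.abs(t.rotations).max() < 1e-6

    def test_recovers_translation(self):
        mesh = extract_surface(sphere_volume(), 0.5)
        moved = SurfaceMesh(mesh.vertices + np.array([2.0, 0.0, 0.0]), mesh.faces)
        t = align_icp(moved, mesh, iters=50)
        np.testing.assert_allclose(t.translations, [-2.0, 0.0, 0.0], atol=0.05)

    def test_residual_monotone_nonincreasing(self):
        mesh = extract_surface(sphere_volume(), 0.5)
        moved = SurfaceMesh(mesh.vertices + np.array([1.0, 0.5, -0.3]), mesh.faces)
        _, residuals = align_icp(moved, mesh, iters=20, return_history=True)
        assert all(b <= a + 1e-12 for a, b in zip(residuals, residuals[1:]))

    def test_empty_mesh_rejected(self):
        empty = SurfaceMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
        mesh = extract_surface(sphere_volume(), 0.5)
        with pytest.raises(ValueError):
            align_icp(empty, mesh)


def slab_mesh(z: float, extent: float = 10.0, n: int = 11) -> SurfaceMesh:
    """Triangulated plane z = const."""
    xs = np.linspace(0, extent, n)
    vv, ff = [], []
    for i, x in enumerate(xs):
        for j, y in enumerate(xs):
            vv.append([x, y, z])
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            ff.append([a, a + 1, a + n])
            ff.append([a + 1, a + n + 1, a + n])
    return SurfaceMesh(np.array(vv, dtype=float), np.array(ff))


class TestSurfaceDeviation:
    def test_identical_meshes_zero(self):
        mesh = extract_surface(sphere_volume(), 0.5)
        rep = surface_deviation_rms(mesh, mesh)
        assert rep.overall_rms == pytest.approx(0.0, abs=1e-9)

    def test_parallel_slabs_offset(self):
        d = 0.7
        rep = surface_deviation_rms(slab_mesh(0.0), slab_mesh(d))
        assert rep.overall_rms == pytest.approx(d, abs=1e-6)

    def test_concentric_spheres(self):
        n, sp = 48, 0.5
        a = extract_surface(sphere_volume(n, 12.0, sp), 0.5)
        b = extract_surface(sphere_volume(n, 16.0, sp), 0.5)
        delta = (16.0 - 12.0) * sp
        rep = surface_deviation_rms(a, b)
        assert rep.overall_rms == pytest.approx(delta, abs=1.5 * sp)  # discretisation

    def test_regional_partition(self):
        mesh = extract_surface(sphere_volume(), 0.5)
        other = SurfaceMesh(mesh.vertices + np.array([0, 0, 0.4]), mesh.faces)
        upper = other.vertices[:, 2] > other.vertices[:, 2].mean()
        rep = surface_deviation_rms(mesh, other, regions={"upper": upper, "lower": ~upper})
        assert set(rep.per_region) == {"upper", "lower"}
        assert all(v >= 0 for v in rep.per_region.values())

    def test_empty_region_rejected(self):
        mesh = extract_surface(sphere_volume(), 0.5)
        with pytest.raises(ValueError, match="empty"):
            surface_deviation_rms(mesh, mesh, regions={"none": np.zeros(mesh.n_vertices, dtype=bool)})

    def test_point_to_surface_exact_on_plane(self):
        mesh = slab_mesh(0.0)
        pts = np.array([[5.0, 5.0, 2.0], [1.0, 9.0, -3.0]])
        np.testing.assert_allclose(point_to_surface_distance(pts, mesh), [2.0, 3.0], atol=1e-9)


class TestPerSliceMean:
    def test_constant_offset_matches_volume_value(self, rng):
        from sycbct.metrics import per_slice_mean

        v = rng.normal(size=(6, 6, 6))
        assert per_slice_mean(mae, v + 2.0, v) == pytest.approx(2.0)

    def test_slicewise_average_of_varying_error(self):
        from sycbct.metrics import per_slice_mean

        ref = np.zeros((4, 4, 3))
        sy = ref.copy()
        sy[:, :, 0] += 1.0
        sy[:, :, 2] += 3.0
        # per-slice MAEs are (1, 0, 3) -> mean 4/3; volume MAE is also 4/3
        assert per_slice_mean(mae, sy, ref) == pytest.approx(4 / 3)

    def test_masked_slices_skipped(self):
        from sycbct.metrics import per_slice_mean

        ref = np.zeros((4, 4, 3))
        sy = ref + 2.0
        mask = np.ones_like(ref, dtype=bool)
        mask[:, :, 1] = False
        assert per_slice_mean(mae, sy, ref, mask) == pytest.approx(2.0)
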