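import numpy as np
import pytest
import trimesh

from orbifab import phantom
from orbifab.metrology import (
    HeightMap,
    compute_rsm,
    compute_sa,
    compute_sk_family,
    deviation_map,
    fisher_ci,
    grouped_pearson_r,
    highpass_surface,
    pearson_r,
    read_heightmap,
    write_heightmap,
)

TABLE_X = [0.3, 0.2, 0.07]
TABLE_SA = ([49.52, 33.84, 16.69], [2.47, 1.38, 0.85])
TABLE_SPK = ([251.68, 168.63, 100.94], [12.66, 20.43, 8.33])
TABLE_RSM = ([544.83, 399.16, 228.56], [21.17, 56.03, 28.10])


def sinusoid(wavelength_mm, amplitude_um=20.0, size_mm=(4.0, 5.3), spacing=0.0078):
    nx = int(round(size_mm[0] / spacing)) + 1
    ny = int(round(size_mm[1] / spacing)) + 1
    x = np.arange(nx) * spacing
    z = amplitude_um * np.sin(2 * np.pi * x / wavelength_mm)
    return HeightMap(np.tile(z[:, None], (1, ny)), spacing)


class TestDeviationMap:
    def test_identical_points_zero(self):
        sph = trimesh.creation.icosphere(subdivisions=2, radius=10)
        dev = deviation_map(np.asarray(sph.vertices), sph)
        assert dev.mean_mm == pytest.approx(0, abs=1e-12)
        assert dev.sd_mm == pytest.approx(0, abs=1e-12)
        assert dev.fraction_in_tolerance == 1.0

    def test_inflated_sphere_positive_offset(self):
        sph = trimesh.creation.icosphere(subdivisions=3, radius=10)
        bigger = np.asarray(sph.vertices) * 1.005  # radius 10.05
        dev = deviation_map(bigger, sph)
        assert dev.mean_mm == pytest.approx(0.05, abs=0.005)
        assert dev.sd_mm < 0.01

    def test_symmetric_offsets_statistics(self):
        plate = phantom.make_test_mesh("plate", size_mm=20)
        top = np.asarray(plate.vertices)[:, 2].max()
        rng = np.random.default_rng(0)
        xy = rng.uniform(-5, 5, (100, 2))
        pts = np.column_stack([xy, np.full(100, top)])
        pts[:50, 2] += 0.1
        pts[50:, 2] -= 0.1
        dev = deviation_map(pts, plate)
        assert dev.mean_mm == pytest.approx(0.0, abs=1e-9)
        assert dev.range_mm == pytest.approx(0.2, abs=1e-9)
        assert dev.sd_mm == pytest.approx(0.1, abs=0.001)

    def test_agrees_with_brute_force_distances(self):
        mesh = trimesh.creation.icosphere(subdivisions=2, radius=5)
        rng = np.random.default_rng(1)
        pts = rng.normal(0, 4, (100, 3))
        dev = deviation_map(pts, mesh)
        tris = np.asarray(mesh.triangles)
        for p, d in zip(pts, dev.deviations_mm):
            cp = trimesh.triangles.closest_point(tris, np.tile(p, (len(tris), 1)))
            brute = np.linalg.norm(cp - p, axis=1).min()
            assert abs(abs(d) - brute) < 1e-9

    def test_empty_points_rejected(self):
        with pytest.raises(ValueError):
            deviation_map(np.zeros((0, 3)), trimesh.creation.box())


class TestHighpass:
    def test_tilted_plane_removed(self):
        nx = ny = 400
        x = np.arange(nx) * 0.0078
        hm = HeightMap(np.tile((5 + 3 * x)[:, None], (1, ny)), 0.0078)
        out = highpass_surface(hm)
        assert np.abs(out.heights_um).max() < 1e-6

    def test_short_wavelength_preserved(self):
        hm = sinusoid(0.1)
        out = highpass_surface(hm, cutoff_mm=1.0)
        amp = out.heights_um[50:-50].std() * np.sqrt(2)
        assert amp == pytest.approx(20.0, rel=0.02)

    def test_long_wavelength_attenuated(self):
        hm = sinusoid(5.0, size_mm=(10.0, 2.0))
        out = highpass_surface(hm, cutoff_mm=1.0)
        amp = out.heights_um[100:-100].std() * np.sqrt(2)
        assert amp < 2.0  # < 10% of 20 um

    def test_patch_smaller_than_cutoff_rejected(self):
        hm = HeightMap(np.zeros((50, 50)), 0.0078)
        with pytest.raises(ValueError, match="cutoff"):
            highpass_surface(hm, cutoff_mm=1.0)


class TestSa:
    def test_flat_zero(self):
        assert compute_sa(HeightMap(np.full((64, 64), 3.0), 0.01)) == 0.0

    def test_sinusoid_closed_form(self):
        hm = sinusoid(0.4992, amplitude_um=20.0)  # 64 samples per period
        assert compute_sa(hm) == pytest.approx(2 * 20.0 / np.pi, rel=0.005)

    def test_shift_and_scale_invariances(self):
        rng = np.random.default_rng(0)
        z = rng.normal(0, 5, (80, 80))
        hm = HeightMap(z, 0.01)
        assert compute_sa(HeightMap(z + 100, 0.01)) == pytest.approx(compute_sa(hm))
        assert compute_sa(HeightMap(3 * z, 0.01)) == pytest.approx(3 * compute_sa(hm))
        assert compute_sa(HeightMap(np.roll(z, 7, axis=0), 0.01)) == pytest.approx(
            compute_sa(hm)
        )


class TestSkFamily:
    def test_constant_surface_zeros(self):
        assert compute_sk_family(HeightMap(np.full((32, 32), 2.0), 0.01)) == (0, 0, 0)

    def test_symmetric_sinusoid_spk_equals_svk(self):
        hm = sinusoid(0.4992)
        spk, sk, svk = compute_sk_family(hm)
        assert spk == pytest.approx(svk, rel=0.02)
        assert sk > 0

    def test_two_level_surface_matches_independent_oracle(self):
        z = np.zeros((100, 100))
        z[:50] = 5.0
        z[50:] = -5.0
        spk, sk, svk = compute_sk_family(HeightMap(z, 0.01))

        # independent oracle coded straight from the secant construction on
        # the exact staircase material-ratio curve (tie windows averaged)
        h = np.sort(z.ravel())[::-1]
        n = h.size
        mr = (np.arange(n) + 0.5) / n
        w = int(round(0.4 * n))
        h0s, h1s = [], []
        dmin = min(h[j] - h[j + w] for j in range(n - w))
        for j in range(n - w):
            if h[j] - h[j + w] <= dmin + 1e-3 * (h[0] - h[-1]):
                slope = (h[j + w] - h[j]) / (mr[j + w] - mr[j])
                h0s.append(h[j] + slope * (0 - mr[j]))
                h1s.append(h[j] + slope * (1 - mr[j]))
        h0 = np.mean(h0s)
        h1 = np.mean(h1s)
        sk_o = h0 - h1
        above = h > h0
        below = h < h1
        smr1 = above.mean()
        smr2 = 1 - below.mean()
        spk_o = 2 * np.sum(h[above] - h0) / n / smr1 if smr1 > 0 else 0.0
        svk_o = 2 * np.sum(h1 - h[below]) / n / (1 - smr2) if smr2 < 1 else 0.0
        assert (spk, sk, svk) == pytest.approx((spk_o, sk_o, svk_o), abs=1e-9)

    def test_sa_bounded_by_sk_sum(self):
        for h in (0.07, 0.2, 0.3):
            hm = highpass_surface(
                phantom.make_stair_surface(phantom.StairSurfaceSpec(layer_height_mm=h, seed=1))
            )
            spk, sk, svk = compute_sk_family(hm)
            assert compute_sa(hm) <= spk + sk + svk


class TestRsm:
    def test_sinusoid_period(self):
        hm = sinusoid(0.4)  # 400 um wavelength
        rsm = compute_rsm(hm)
        assert abs(rsm - 400.0) <= hm.lateral_spacing_mm * 1000

    def test_stair_surface_period(self):
        spec = phantom.StairSurfaceSpec(layer_height_mm=0.2, noise_sd_um=0)
        hm = phantom.make_stair_surface(spec)
        expected = spec.layer_height_mm / np.sin(np.radians(spec.slope_deg)) * 1000
        assert compute_rsm(hm) == pytest.approx(expected, rel=0.02)

    def test_flat_with_subresolution_noise_rejected(self):
        rng = np.random.default_rng(0)
        hm = HeightMap(rng.normal(0, 0.1, (400, 200)), 0.0078)
        with pytest.raises(ValueError, match="insufficient"):
            compute_rsm(hm)


class TestCorrelation:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        res = pearson_r(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_zero(self):
        x = np.array([-1.0, 0.0, 1.0, 0.0])
        y = np.array([0.0, 1.0, 0.0, -1.0])
        assert pearson_r(x, y).r == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1], [1, 2, 3])

    def test_grouped_equals_expanded_exactly(self):
        for means, sds in (TABLE_SA, TABLE_SPK, TABLE_RSM):
            grouped = grouped_pearson_r(TABLE_X, means, sds, [3, 3, 3])
            xs, ys = [], []
            for x, m, s in zip(TABLE_X, means, sds):
                xs += [x, x, x]
                ys += [m - s, m, m + s]
            expanded = pearson_r(xs, ys)
            assert grouped.r == pytest.approx(expanded.r, abs=1e-12)
            assert grouped.ci_low == pytest.approx(expanded.ci_low, abs=1e-12)
            assert grouped.n == 9

    def test_equal_group_means_zero_r(self):
        res = grouped_pearson_r([0.1, 0.2, 0.3], [5, 5, 5], [1, 2, 3], [3, 3, 3])
        assert res.r == pytest.approx(0.0, abs=1e-12)

    def test_fisher_ci_symmetry_and_roundtrip(self):
        lo, hi = fisher_ci(0.0, 100)
        assert lo == pytest.approx(-hi, abs=1e-12)
        r = 0.73
        assert np.tanh(np.arctanh(r)) == pytest.approx(r, abs=1e-15)
        with pytest.raises(ValueError):
            fisher_ci(1.0, 10)


def test_heightmap_io_and_replica_flip(tmp_path):
    rng = np.random.default_rng(0)
    hm = HeightMap(rng.normal(0, 5, (40, 30)), 0.0078)
    write_heightmap(hm, tmp_path / "h.txt")
    back = read_heightmap(tmp_path / "h.txt")
    np.testing.assert_allclose(back.heights_um, hm.heights_um, atol=1e-12)
    assert back.lateral_spacing_mm == hm.lateral_spacing_mm
    flipped = read_heightmap(tmp_path / "h.txt", replica=True)
    np.testing.assert_allclose(flipped.heights_um, -hm.heights_um, atol=1e-12)
    # Sa invariant under replica inversion; Spk/Svk swap
    assert compute_sa(flipped) == pytest.approx(compute_sa(back))
    spk, _, svk = compute_sk_family(back)
    spk_f, _, svk_f = compute_sk_family(flipped)
    assert spk_f == pytest.approx(svk, rel=0.05)
    assert svk_f == pytest.approx(spk, rel=0.05)
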