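"""Spectral scale, autocorrelation, mesh curvature and (H, Γ) statistics."""

import numpy as np
import pytest
from scipy.optimize import brentq

from nestgrowth.benchmarks import (bandpass_noise_volume, cosine_mode_volume,
                                   gyroid_volume, plane_volume, sphere_volume)
from nestgrowth.field import ScalarField3D
from nestgrowth.morphometrics import (autocorrelation, curvatures, dominant_scale,
                                      extract_isosurface, h_g_histograms, hg_density)

#: location of the first local *maximum* at r > 0 of sinc(r) = sin(r)/r, the
#: second positive root of tan r = r (the first root, r ≈ 4.49, is the first
#: minimum).  The spherical-shell average of a single plane wave peaks at lag
#: r = FIRST_SINC_MAX / k, not at one wavelength.
FIRST_SINC_MAX = brentq(lambda r: np.tan(r) - r, 2 * np.pi + 1e-9,
                        2.5 * np.pi - 1e-9)


class TestDominantScale:
    def test_single_mode_recovered_within_a_bin(self):
        n, m = 64, 4
        vol = cosine_mode_volume((n, n, n), mode=(m, 0, 0))
        k_dom, l_dom = dominant_scale(vol)
        dk = 2 * np.pi / n
        assert abs(k_dom - 2 * np.pi * m / n) <= dk
        assert l_dom == pytest.approx(n / m, rel=dk / (2 * np.pi * m / n))

    def test_isotropic_superposition_same_peak(self):
        n, m = 64, 4
        vx = cosine_mode_volume((n, n, n), mode=(m, 0, 0)).values
        vy = cosine_mode_volume((n, n, n), mode=(0, m, 0)).values
        vz = cosine_mode_volume((n, n, n), mode=(0, 0, m)).values
        iso = ScalarField3D((vx + vy + vz) / 3.0)
        k_iso, _ = dominant_scale(iso)
        k_one, _ = dominant_scale(cosine_mode_volume((n, n, n), mode=(m, 0, 0)))
        assert k_iso == pytest.approx(k_one)

    def test_constant_volume_rejected(self):
        with pytest.raises(ValueError):
            dominant_scale(ScalarField3D(np.full((16, 16, 16), 0.5)))


class TestAutocorrelation:
    def test_lag_zero_normalization_and_bounds(self):
        vol = bandpass_noise_volume((32, 32, 32), center_length=8.0, rng_seed=3)
        ps = autocorrelation(vol, rescale_length=8.0)
        for lags, vals in (ps.corr_x, ps.corr_y, ps.corr_z, ps.corr_radial):
            assert vals[0] == pytest.approx(1.0)
            assert np.all(np.abs(vals) <= 1.0 + 1e-9)

    def test_cosine_axis_profile_closed_form(self):
        n, m = 64, 4
        k = 2 * np.pi * m / n
        vol = cosine_mode_volume((n, n, n), mode=(m, 0, 0))
        ps = autocorrelation(vol, rescale_length=2 * np.pi / k)
        lags, vals = ps.corr_x
        assert np.allclose(vals, np.cos(k * lags * (2 * np.pi / k)), atol=1e-10)
        # first maximum of the axis profile at one wavelength (rescaled lag 1)
        i = np.argmax(vals[1:]) + 1
        assert lags[i] == pytest.approx(1.0)

    def test_cosine_radial_profile_is_sinc(self):
        """Shell-averaging a plane wave gives sin(kr)/(kr); its first local
        maximum sits at kr = tan r = r root, not at one wavelength."""
        n, m = 64, 4
        k = 2 * np.pi * m / n
        vol = cosine_mode_volume((n, n, n), mode=(m, 0, 0))
        ps = autocorrelation(vol, rescale_length=2 * np.pi / k)
        expected = FIRST_SINC_MAX / k / (2 * np.pi / k)
        assert ps.first_max_location == pytest.approx(expected, abs=0.1)

    def test_single_axis_mode_flagged_anisotropic(self):
        vol = cosine_mode_volume((48, 48, 48), mode=(4, 0, 0))
        ps = autocorrelation(vol, rescale_length=12.0)
        assert ps.axis_has_peak[0]
        assert not ps.axis_has_peak[1] and not ps.axis_has_peak[2]
        assert not ps.isotropic

    def test_gyroid_flagged_isotropic(self):
        vol = gyroid_volume((64, 64, 64), 16.0)
        _, l_dom = dominant_scale(vol)
        ps = autocorrelation(vol, rescale_length=l_dom)
        assert ps.isotropic

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            autocorrelation(ScalarField3D(np.full((16, 16, 16), 0.2)), 1.0)


class TestIsosurface:
    def test_sphere_area(self, sphere_mesh):
        mesh, R = sphere_mesh["mesh"], sphere_mesh["radius"]
        assert mesh.vertex_area.sum() == pytest.approx(4 * np.pi * R**2, rel=0.05)
        assert not mesh.boundary_flag.any()  # closed surface
        assert mesh.euler_characteristic == 2

    def test_level_outside_range_rejected(self):
        vol = sphere_volume((32, 32, 32), 10.0)
        with pytest.raises(ValueError):
            extract_isosurface(vol, level=2.0)

    def test_open_mesh_boundary_flagged(self):
        vol = plane_volume((24, 24, 24))
        mesh = curvatures(extract_isosurface(vol, 0.5))
        assert mesh.boundary_flag.any()
        assert np.all(np.isnan(mesh.vertex_H[mesh.boundary_flag]))
        assert np.all(np.isfinite(mesh.vertex_H[mesh.interior]))


class TestCurvatures:
    def test_plane_is_flat(self):
        mesh = curvatures(extract_isosurface(plane_volume((24, 24, 24)), 0.5))
        H, G, _ = mesh.interior_samples()
        assert np.all(np.abs(H) < 1e-6)
        assert np.all(np.abs(G) < 1e-6)

    def test_sphere_closed_form(self, sphere_mesh):
        """Outward-oriented ball surface: H = +1/R and Γ = +1/R² (3% median)."""
        mesh, R = sphere_mesh["mesh"], sphere_mesh["radius"]
        H, G, _ = mesh.interior_samples()
        assert np.median(H) == pytest.approx(1.0 / R, rel=0.03)
        assert np.median(G) == pytest.approx(1.0 / R**2, rel=0.03)

    def test_refinement_reduces_sphere_error(self):
        """Halving the voxel size reduces the raw estimator's median |H - 1/R|.

        The raw (unsmoothed) mesh isolates the discretization error of the
        cotangent estimator itself; with smoothing enabled the residual is
        dominated by the smoothing bias, which does not vanish under
        refinement.
        """
        errs = []
        for n, h in ((32, 1.0), (64, 0.5)):
            vol = sphere_volume((n, n, n), radius=10.0, spacing=h)
            mesh = curvatures(extract_isosurface(vol, 0.5, smooth_iterations=0))
            H, _, _ = mesh.interior_samples()
            errs.append(np.median(np.abs(H - 0.1)))
        assert errs[1] < errs[0]

    def test_gauss_bonnet(self, sphere_mesh):
        """Total angle-deficit curvature of a closed mesh equals 2π·χ."""
        mesh = sphere_mesh["mesh"]
        total = np.nansum(mesh.vertex_Gamma * mesh.vertex_area)
        assert total == pytest.approx(2 * np.pi * mesh.euler_characteristic, rel=0.01)

    def test_rescaling_covariance(self):
        """Dividing coordinates by s multiplies H by s and Γ by s²."""
        vol = sphere_volume((48, 48, 48), 15.0)
        s = 7.5
        m1 = curvatures(extract_isosurface(vol, 0.5))
        m2 = curvatures(extract_isosurface(vol, 0.5, rescale_length=s))
        assert np.allclose(m2.vertex_H, m1.vertex_H * s, rtol=1e-9, atol=1e-12,
                           equal_nan=True)
        assert np.allclose(m2.vertex_Gamma, m1.vertex_Gamma * s**2, rtol=1e-9,
                           atol=1e-12, equal_nan=True)

    def test_gyroid_minimal_surface(self, gyroid_mesh):
        mesh, wavelength = gyroid_mesh["mesh"], gyroid_mesh["wavelength"]
        H, G, w = mesh.interior_samples()
        # H is rescaled by the wavelength; tolerance 0.02 * 2pi in those units
        assert abs(np.average(H, weights=w)) < 0.02 * 2 * np.pi
        assert np.average((G < 0), weights=w) > 0.9


class TestHGStatistics:
    def test_sphere_histograms(self, sphere_mesh):
        mesh, R = sphere_mesh["mesh"], sphere_mesh["radius"]
        hist = h_g_histograms(mesh, bin_width=0.01)
        assert hist.H_mode == pytest.approx(1.0 / R, abs=0.01)
        # negligible saddle area on a ball (a few % of vertices pick up
        # negative angle deficits from smoothing noise)
        assert hist.Gamma_negative_fraction < 0.05

    def test_too_few_vertices_rejected(self):
        vol = sphere_volume((16, 16, 16), 2.0, transition_width=1.5)
        mesh = curvatures(extract_isosurface(vol, 0.5))
        with pytest.raises(ValueError):
            h_g_histograms(mesh)
        with pytest.raises(ValueError):
            hg_density(mesh)

    def test_decile_levels_partition_mass(self, gyroid_mesh):
        mesh = gyroid_mesh["mesh"]
        dens = hg_density(mesh)
        levels = dens.decile_levels
        assert np.all(np.diff(levels) <= 0)
        # recompute sample densities with the same weighted-sample construction
        from scipy import stats

        H, G, w = mesh.interior_samples()
        rng = np.random.default_rng(0)
        idx = rng.choice(len(H), size=10000, replace=False, p=w / w.sum())
        kde = stats.gaussian_kde(np.vstack([H[idx], G[idx]]))
        sd = kde(np.vstack([H[idx], G[idx]]))
        masses = np.array([np.mean(sd >= lv) for lv in levels])
        assert np.allclose(masses, np.arange(1, 11) / 10.0, atol=0.02)

    def test_gyroid_density_concentrates_at_minimal_saddles(self, gyroid_mesh):
        """Gyroid mass hugs the H = 0 axis at Γ < 0."""
        dens = hg_density(gyroid_mesh["mesh"])
        i, j = np.unravel_index(np.argmax(dens.density), dens.density.shape)
        assert abs(dens.H_grid[i]) < 0.5    # rescaled units; axis spans ~±4
        assert dens.Gamma_grid[j] < 0.0

    def test_random_surface_spreads_wider_in_H_than_gyroid(self, gyroid_mesh):
        bp = bandpass_noise_volume((96, 96, 96), center_length=16.0, rng_seed=5)
        _, l_dom = dominant_scale(bp)
        bmesh = curvatures(extract_isosurface(bp, 0.5, rescale_length=l_dom))

        def h_iqr(mesh):
            H, _, w = mesh.interior_samples()
            order = np.argsort(H)
            cw = np.cumsum(w[order]) / w.sum()
            return np.interp(0.75, cw, H[order]) - np.interp(0.25, cw, H[order])

        assert h_iqr(bmesh) > h_iqr(gyroid_mesh["mesh"])

    def test_delta_sample_concentrates(self):
        """All-identical (H, Γ) samples put all KDE mass around that point."""
        from nestgrowth.morphometrics import TriangleMesh

        n = 200
        mesh = TriangleMesh(vertices=np.zeros((n, 3)), faces=np.zeros((0, 3), int),
                            boundary_flag=np.zeros(n, bool))
        mesh.vertex_H = np.full(n, 0.3)
        mesh.vertex_Gamma = np.full(n, -0.2)
        mesh.vertex_area = np.ones(n)
        dens = hg_density(mesh)
        i, j = np.unravel_index(np.argmax(dens.density), dens.density.shape)
        assert dens.H_grid[i] == pytest.approx(0.3, abs=1e-3)
        assert dens.Gamma_grid[j] == pytest.approx(-0.2, abs=1e-3)
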