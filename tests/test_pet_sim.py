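import numpy as np
import pytest

from pseudoct import (
    Modality,
    ReconConfig,
    ScannerGeometry,
    attenuation_factors,
    forward_project,
    osem_reconstruct,
    simulate_noncorrected_sinogram,
)
from pseudoct.pet_sim import back_project, scatter_surrogate, system_matrix, Sinogram, SinogramKind

from conftest import make_volume


GEOM = ScannerGeometry(n_angles=48, n_radial=96, radial_spacing_mm=2.0,
                       image_shape=(64, 64), image_spacing_mm=(2.0, 2.0))


def disc_volume(value=1.0, radius_mm=40.0, nz=1, geom=GEOM, modality=Modality.PET,
                antialias=1):
    nx, ny = geom.image_shape
    sx, sy = geom.image_spacing_mm
    disc = np.zeros((nx, ny))
    # optional supersampling so rim pixels carry fractional coverage
    for ox in range(antialias):
        for oy in range(antialias):
            x = (np.arange(nx) - (nx - 1) / 2 + (ox + 0.5) / antialias - 0.5) * sx
            y = (np.arange(ny) - (ny - 1) / 2 + (oy + 0.5) / antialias - 0.5) * sy
            xx, yy = np.meshgrid(x, y, indexing="ij")
            disc += (xx**2 + yy**2 <= radius_mm**2).astype(float)
    disc *= value / antialias**2
    vals = np.repeat(disc[:, :, None], nz, axis=2)
    return make_volume(vals, spacing=(sx, sy, 2.0), modality=modality)


class TestProjector:
    def test_zero_image_zero_sinogram(self):
        vol = disc_volume(0.0)
        assert forward_project(vol, GEOM).values.sum() == 0.0

    def test_single_voxel_mass_and_sinusoid_trace(self):
        nx, ny = GEOM.image_shape
        vals = np.zeros((nx, ny, 1))
        ix, iy = 40, 25
        vals[ix, iy, 0] = 1.0
        vol = make_volume(vals, spacing=(2.0, 2.0, 2.0), modality=Modality.PET)
        sino = forward_project(vol, GEOM).values[0]
        # per-angle total mass: sum_s P * bin_width = value * pixel_area
        pixel_area = 4.0
        for ia in range(GEOM.n_angles):
            mass = sino[ia].sum() * GEOM.radial_spacing_mm
            assert mass == pytest.approx(pixel_area, rel=0.02)
        # the trace follows s = x cos(theta) + y sin(theta)
        x = (ix - (nx - 1) / 2) * 2.0
        y = (iy - (ny - 1) / 2) * 2.0
        for ia, theta in enumerate(GEOM.angles):
            s_true = x * np.cos(theta) + y * np.sin(theta)
            s_peak = GEOM.radial_offsets_mm[np.argmax(sino[ia])]
            assert abs(s_peak - s_true) <= 1.5 * GEOM.radial_spacing_mm

    def test_uniform_disc_chord_profile(self):
        a, r = 2.0, 40.0
        vol = disc_volume(a, r, antialias=4)
        sino = forward_project(vol, GEOM).values[0]
        s = GEOM.radial_offsets_mm
        inside = np.abs(s) < 0.8 * r
        expected = a * 2.0 * np.sqrt(r**2 - s[inside] ** 2)
        for ia in range(0, GEOM.n_angles, 7):
            err = np.abs(sino[ia][inside] - expected) / expected
            assert err.max() < 0.02

    def test_adjointness(self):
        rng = np.random.default_rng(0)
        A = system_matrix(GEOM)
        for _ in range(5):
            x = rng.normal(size=A.shape[1])
            y = rng.normal(size=A.shape[0])
            lhs = float((A @ x) @ y)
            rhs = float(x @ (A.T @ y))
            assert abs(lhs - rhs) <= 1e-6 * max(abs(lhs), abs(rhs))

    def test_back_project_matches_matrix_adjoint(self):
        rng = np.random.default_rng(1)
        sino_vals = rng.random((1, GEOM.n_angles, GEOM.n_radial))
        sino = Sinogram(sino_vals, SinogramKind.EMISSION, GEOM)
        bp = back_project(sino, GEOM)
        A = system_matrix(GEOM)
        expected = (A.T @ sino_vals[0].ravel()).reshape(GEOM.image_shape)
        np.testing.assert_allclose(bp[:, :, 0], expected, atol=1e-12)


class TestAttenuationFactors:
    def test_zero_mu_unit_acf(self):
        mu = disc_volume(0.0, modality=Modality.MU)
        acf = attenuation_factors(mu, GEOM)
        np.testing.assert_allclose(acf.values, 1.0)

    def test_beer_lambert_through_water_disc(self):
        # 20 cm diameter water disc: central ray acf = exp(0.096 * 20);
        # the grid must be wide enough to contain the full disc
        geom = ScannerGeometry(n_angles=24, n_radial=160, radial_spacing_mm=2.0,
                               image_shape=(112, 112), image_spacing_mm=(2.0, 2.0))
        mu = disc_volume(0.096, radius_mm=100.0, geom=geom,
                         modality=Modality.MU, antialias=4)
        acf = attenuation_factors(mu, geom).values[0]
        centre = np.argmin(np.abs(geom.radial_offsets_mm))
        expected = np.exp(0.096 * 20.0)
        for ia in range(0, geom.n_angles, 5):
            assert acf[ia, centre] == pytest.approx(expected, rel=0.02)

    def test_doubling_mu_squares_acf(self):
        mu1 = disc_volume(0.05, radius_mm=50.0, modality=Modality.MU)
        mu2 = disc_volume(0.10, radius_mm=50.0, modality=Modality.MU)
        a1 = attenuation_factors(mu1, GEOM).values
        a2 = attenuation_factors(mu2, GEOM).values
        np.testing.assert_allclose(a2, a1**2, rtol=1e-10)

    def test_negative_mu_rejected(self):
        mu = disc_volume(1.0, modality=Modality.MU)
        mu.values[0, 0, 0] = -0.1
        with pytest.raises(ValueError, match="nonnegative"):
            attenuation_factors(mu, GEOM)


class TestSimulation:
    def test_no_scatter_no_mu_is_plain_projection(self):
        act = disc_volume(3.0, 30.0)
        mu0 = disc_volume(0.0, modality=Modality.MU)
        noncorr, scatter = simulate_noncorrected_sinogram(act, mu0, GEOM,
                                                          ReconConfig())
        np.testing.assert_allclose(noncorr.values,
                                   forward_project(act, GEOM).values)
        assert scatter.values.sum() == 0.0

    def test_scatter_fraction_by_construction(self):
        act = disc_volume(3.0, 30.0)
        mu = disc_volume(0.096, 45.0, modality=Modality.MU)
        cfg = ReconConfig(scatter_fraction=0.3)
        noncorr, scatter = simulate_noncorrected_sinogram(act, mu, GEOM, cfg)
        frac = scatter.values.sum() / noncorr.values.sum()
        assert frac == pytest.approx(0.3, abs=1e-6)

    def test_poisson_mode_reproducible(self):
        act = disc_volume(5.0, 30.0)
        mu = disc_volume(0.05, 45.0, modality=Modality.MU)
        cfg = ReconConfig(scatter_fraction=0.2, poisson_noise=True)
        n1, _ = simulate_noncorrected_sinogram(act, mu, GEOM, cfg, seed=77)
        n2, _ = simulate_noncorrected_sinogram(act, mu, GEOM, cfg, seed=77)
        np.testing.assert_array_equal(n1.values, n2.values)
        n3, _ = simulate_noncorrected_sinogram(act, mu, GEOM, cfg, seed=78)
        assert not np.array_equal(n1.values, n3.values)

    def test_poisson_requires_seed(self):
        act = disc_volume(5.0, 30.0)
        mu = disc_volume(0.05, 45.0, modality=Modality.MU)
        with pytest.raises(ValueError, match="seed"):
            simulate_noncorrected_sinogram(act, mu, GEOM,
                                           ReconConfig(poisson_noise=True))


@pytest.fixture(scope="module")
def slice_phantom():
    """Disc-in-disc activity with a bone annulus, one 64^2 slice."""
    act = disc_volume(4.0, 45.0)
    mu_soft = disc_volume(0.096, 60.0, modality=Modality.MU)
    nx, ny = GEOM.image_shape
    x = (np.arange(nx) - (nx - 1) / 2) * 2.0
    y = (np.arange(ny) - (ny - 1) / 2) * 2.0
    xx, yy = np.meshgrid(x, y, indexing="ij")
    rr = np.sqrt(xx**2 + yy**2)
    mu_vals = mu_soft.values.copy()
    mu_vals[(rr >= 52) & (rr <= 60), :] = 0.17  # skull-like annulus
    mu = make_volume(mu_vals, spacing=(2.0, 2.0, 2.0), modality=Modality.MU)
    return act, mu


class TestOsem:
    def test_self_consistent_recovery(self, slice_phantom):
        act, mu = slice_phantom
        cfg = ReconConfig(n_iterations=3, n_subsets=8, scatter_fraction=0.2)
        noncorr, scatter = simulate_noncorrected_sinogram(act, mu, GEOM, cfg)
        recon = osem_reconstruct(noncorr, mu, scatter, GEOM, cfg)
        inside = act.values > 0
        rmae = 100 * np.abs(recon.values[inside] - act.values[inside]).sum() \
            / act.values[inside].sum()
        assert rmae < 5.0

    def test_data_mismatch_non_increasing(self, slice_phantom):
        act, mu = slice_phantom
        cfg = ReconConfig(n_subsets=8, scatter_fraction=0.2)
        noncorr, scatter = simulate_noncorrected_sinogram(act, mu, GEOM, cfg)
        acf = attenuation_factors(mu, GEOM).values
        mismatches = []
        for n_it in (1, 2, 3, 4):
            c = ReconConfig(n_iterations=n_it, n_subsets=8, scatter_fraction=0.2)
            recon = osem_reconstruct(noncorr, mu, scatter, GEOM, c)
            model = forward_project(recon, GEOM).values / acf + scatter.values
            mismatches.append(np.abs(model - noncorr.values).sum())
        assert all(b <= a * (1 + 1e-9) for a, b in zip(mismatches, mismatches[1:]))

    def test_bone_omission_underestimates(self, slice_phantom):
        act, mu = slice_phantom
        cfg = ReconConfig(n_iterations=3, n_subsets=8, scatter_fraction=0.2)
        noncorr, scatter = simulate_noncorrected_sinogram(act, mu, GEOM, cfg)
        mu_noskull = mu.with_values(np.where(mu.values > 0.12, 0.096, mu.values))
        recon = osem_reconstruct(noncorr, mu_noskull, scatter, GEOM, cfg)
        inside = act.values > 0
        rme = 100 * (recon.values[inside] - act.values[inside]).sum() \
            / act.values[inside].sum()
        assert rme < 0.0

    def test_true_mu_beats_corrupted_mu(self, slice_phantom):
        act, mu = slice_phantom
        cfg = ReconConfig(n_iterations=3, n_subsets=8, scatter_fraction=0.2)
        noncorr, scatter = simulate_noncorrected_sinogram(act, mu, GEOM, cfg)
        inside = act.values > 0

        def rmae_with(m):
            r = osem_reconstruct(noncorr, m, scatter, GEOM, cfg)
            return np.abs(r.values[inside] - act.values[inside]).sum() \
                / act.values[inside].sum()

        base = rmae_with(mu)
        corruptions = [
            mu.with_values(np.where(mu.values > 0.12, 0.096, mu.values)),
            mu.with_values(0.9 * mu.values),
            mu.with_values(np.where(
                np.arange(mu.values.shape[1])[None, :, None] < 16, 0.0,
                mu.values)),
        ]
        for m in corruptions:
            assert rmae_with(m) >= base

    def test_nonnegativity_and_zero_support(self, slice_phantom):
        act, mu = slice_phantom
        cfg = ReconConfig(n_iterations=2, n_subsets=8, scatter_fraction=0.0)
        noncorr, scatter = simulate_noncorrected_sinogram(act, mu, GEOM, cfg)
        recon = osem_reconstruct(noncorr, mu, scatter, GEOM, cfg)
        assert np.all(recon.values >= 0)

    def test_subset_adjustment_warns(self, slice_phantom):
        act, mu = slice_phantom
        cfg = ReconConfig(n_iterations=1, n_subsets=21, scatter_fraction=0.0)
        noncorr, scatter = simulate_noncorrected_sinogram(act, mu, GEOM, cfg)
        with pytest.warns(UserWarning, match="subsets"):
            osem_reconstruct(noncorr, mu, scatter, GEOM, cfg)
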