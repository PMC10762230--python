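"""Sinogram assembly, filtered back-projection and the limited-angle baseline."""

import numpy as np
import pytest
from skimage.transform import iradon, radon

from rotomo.errors import ValidationError
from rotomo.phantom import (
    NoiseSpec,
    ProjectionFrame,
    ProjectionStack,
    Volume3D,
    make_phantom,
    render_rotation_video,
)
from rotomo.phantom import scaled_default_spec
from rotomo.reconstruct import (
    ReconConfig,
    Sinogram,
    build_sinogram,
    fbp_slice,
    limited_angle_reconstruct,
    reconstruct_volume,
    spatial_filter,
)


def centered_disk(n=128, radius=40.0, value=1.0):
    yy, xx = np.mgrid[:n, :n]
    c = (n - 1) / 2.0
    return ((yy - c) ** 2 + (xx - c) ** 2 <= radius**2) * value


@pytest.fixture(scope="module")
def clean_recon_video():
    """Noise-free 120-frame video of the 64³ default phantom."""
    spec = scaled_default_spec(64, seed=0)
    stack = render_rotation_video(
        spec, n_frames=120, total_angle=180.0, noise=NoiseSpec(0.0, 0.0)
    )
    return spec, stack


class TestBuildSinogram:
    def test_rows_are_frame_rows(self, clean_mini_video):
        sino = build_sinogram(clean_mini_video, clean_mini_video.truth_angles, row=24)
        assert np.array_equal(sino.data[5], clean_mini_video.frames[5].pixels[24])
        assert len(sino.angles) == len(clean_mini_video)

    def test_identical_frames_give_identical_rows(self):
        frame = ProjectionFrame(np.outer(np.arange(8.0), np.ones(8)), 1.0)
        stack = ProjectionStack([ProjectionFrame(frame.pixels, 1.0, i) for i in range(4)])
        sino = build_sinogram(stack, np.array([0.0, 10.0, 20.0, 30.0]), row=3)
        assert np.all(sino.data == sino.data[0])

    def test_180_one_degree_rows(self, mini_spec):
        stack = render_rotation_video(mini_spec, n_frames=180, total_angle=180.0)
        sino = build_sinogram(stack, stack.truth_angles, row=24)
        assert sino.data.shape[0] == 180
        assert np.allclose(sino.angles, np.arange(180.0))

    def test_duplicate_angles_are_merged(self):
        pix = [np.full((4, 4), float(i)) for i in range(3)]
        stack = ProjectionStack([ProjectionFrame(p, 1.0, i) for i, p in enumerate(pix)])
        sino = build_sinogram(stack, np.array([0.0, 0.01, 45.0]), row=1)
        assert sino.data.shape[0] == 2
        assert np.allclose(sino.data[0], 0.5)  # mean of frames 0 and 1

    def test_angle_count_mismatch_raises(self, clean_mini_video):
        with pytest.raises(ValidationError):
            build_sinogram(clean_mini_video, np.arange(3.0), row=0)


class TestFbpSlice:
    def test_zero_sinogram_reconstructs_to_zero(self):
        sino = Sinogram(np.zeros((10, 32)), np.arange(0, 180, 18.0))
        assert not fbp_slice(sino).any()

    def test_disk_reconstruction_error(self):
        # forward model from skimage.radon = independent oracle
        disk = centered_disk()
        theta = np.arange(180.0)
        sino = Sinogram(radon(disk, theta=theta).T, theta)
        rec = fbp_slice(sino, ReconConfig(filter="hann"))
        n = disk.shape[0]
        yy, xx = np.mgrid[:n, :n]
        c = (n - 1) / 2.0
        inner = (yy - c) ** 2 + (xx - c) ** 2 <= (0.9 * 40.0) ** 2
        rmse = np.sqrt(np.mean((rec[inner] - 1.0) ** 2))
        assert rmse <= 0.05

    def test_radon_half_turn_symmetry(self):
        # R(theta + 180, p) = R(theta, -p): reconstructing from the shifted
        # representation must agree with the original
        disk = centered_disk(n=64, radius=20.0)
        theta = np.arange(0, 180, 4.0)
        rows = radon(disk, theta=theta).T
        rec_a = fbp_slice(Sinogram(rows, theta))
        rec_b = fbp_slice(Sinogram(rows[:, ::-1], theta + 180.0))
        scale = np.sqrt(np.mean(rec_a**2))
        assert np.sqrt(np.mean((rec_a - rec_b) ** 2)) <= 0.01 * max(scale, 1e-9)

    def test_matches_skimage_iradon(self):
        # dual-route check against the established FBP implementation
        disk = centered_disk(n=129, radius=40.0)  # odd size: shared center
        theta = np.arange(180.0)
        sino = radon(disk, theta=theta)
        mine = fbp_slice(Sinogram(sino.T, theta), ReconConfig(filter="hann",
                                                              circle_mask=False))
        theirs = iradon(sino, theta=theta, filter_name="hann", circle=False,
                        output_size=129)
        n = disk.shape[0]
        yy, xx = np.mgrid[:n, :n]
        c = (n - 1) / 2.0
        inner = (yy - c) ** 2 + (xx - c) ** 2 <= 50.0**2
        assert np.sqrt(np.mean((mine[inner] - theirs[inner]) ** 2)) <= 0.01

    def test_fewer_than_two_angles_rejected(self):
        with pytest.raises(ValidationError):
            fbp_slice(Sinogram(np.ones((1, 16)), np.array([0.0])))

    def test_fourier_slice_consistency(self):
        # 1D FT of a projection equals the central slice of the 2D FT of the
        # object; checked on the reconstruction of a noise-free disk
        disk = centered_disk(n=128, radius=30.0)
        theta = np.arange(180.0)
        rows = radon(disk, theta=theta).T
        rec = fbp_slice(Sinogram(rows, theta), ReconConfig(filter="ramp"))
        proj_ft = np.abs(np.fft.rfft(rows[0]))
        slice_ft = np.abs(np.fft.rfft(rec.sum(axis=1)))  # reproject at 0 deg
        band = slice(1, 20)  # low-frequency band below the filter roll-off
        num = np.linalg.norm(proj_ft[band] - slice_ft[band])
        den = np.linalg.norm(proj_ft[band])
        assert num / den <= 0.15

    def test_linearity(self):
        disk = centered_disk(n=64, radius=18.0)
        theta = np.arange(0, 180, 6.0)
        rows = radon(disk, theta=theta).T
        rec1 = fbp_slice(Sinogram(rows, theta))
        rec3 = fbp_slice(Sinogram(3.0 * rows, theta))
        assert np.allclose(rec3, 3.0 * rec1, atol=1e-10)


class TestReconstructVolume:
    def test_row_independence_is_bit_exact(self, clean_recon_video):
        spec, stack = clean_recon_video
        vol = reconstruct_volume(stack, stack.truth_angles)
        for row in (10, 32):
            sino = build_sinogram(stack, stack.truth_angles, row=row)
            alone = fbp_slice(
                Sinogram(sino.data / stack.pixel_size, sino.angles)
            )
            assert np.array_equal(vol.data[row], alone)

    def test_round_trip_against_phantom(self, clean_recon_video):
        spec, stack = clean_recon_video
        truth = make_phantom(spec)
        vol = reconstruct_volume(stack, stack.truth_angles)
        rmse = np.sqrt(np.mean((vol.data - truth.data) ** 2))
        assert rmse <= 0.10 * truth.data.max()

    def test_zero_stack_reconstructs_to_zero(self):
        frames = [ProjectionFrame(np.zeros((16, 16)), 1.0, i) for i in range(10)]
        stack = ProjectionStack(frames)
        vol = reconstruct_volume(stack, np.arange(0, 180, 18.0))
        assert not vol.data.any()


class TestLimitedAngle:
    def test_full_range_equals_full_reconstruction(self, clean_recon_video):
        spec, stack = clean_recon_video
        full = reconstruct_volume(stack, stack.truth_angles)
        lim = limited_angle_reconstruct(stack, stack.truth_angles,
                                        angular_range=180.0)
        assert np.array_equal(full.data, lim.data)

    def test_output_dimensions_match_full(self, clean_recon_video):
        spec, stack = clean_recon_video
        full = reconstruct_volume(stack, stack.truth_angles)
        lim = limited_angle_reconstruct(stack, stack.truth_angles,
                                        angular_range=160.0)
        assert lim.data.shape == full.data.shape

    def test_missing_cone_elongates_the_nucleus(self, clean_recon_video):
        # the unsampled 20-degree wedge removes Fourier components along the
        # in-plane axis orthogonal to the covered fan, stretching structures
        # along that axis; the full-angle reconstruction stays isotropic
        spec, stack = clean_recon_video
        full = reconstruct_volume(stack, stack.truth_angles)
        lim = limited_angle_reconstruct(stack, stack.truth_angles,
                                        angular_range=160.0)
        c = (spec.grid_size - 1) / 2.0
        iv = int(round(c))
        ia = ib = int(round(c + 1.06 / spec.voxel_size))  # nucleus center

        def fwhm(profile, base=0.3):
            p = np.clip(np.asarray(profile, float) - base, 0, None)
            half = p.max() / 2
            above = np.flatnonzero(p >= half)
            lo, hi = above[0], above[-1]
            left = lo - (p[lo] - half) / max(p[lo] - p[lo - 1], 1e-9)
            right = hi + (p[hi] - half) / max(p[hi] - p[hi + 1], 1e-9)
            return right - left

        def elongation(vol):
            extent_a = fwhm(vol.data[iv, :, ib])
            extent_b = fwhm(vol.data[iv, ia, :])
            return extent_a / extent_b

        assert elongation(lim) >= 1.03
        assert abs(elongation(full) - 1.0) <= 0.02

    def test_empty_angular_range_rejected(self, clean_recon_video):
        spec, stack = clean_recon_video
        with pytest.raises(ValidationError):
            limited_angle_reconstruct(stack, stack.truth_angles, angular_range=-1.0)


class TestSpatialFilter:
    def test_zero_sigma_no_mask_is_identity(self, mini_phantom):
        out = spatial_filter(mini_phantom, sigma=0.0, mask=False)
        assert np.array_equal(out.data, mini_phantom.data)

    def test_intensity_preserved_inside_cylinder(self, mini_phantom):
        out = spatial_filter(mini_phantom, sigma=2.0, mask=True)
        # the cell sits well inside the inscribed cylinder, so smoothing
        # moves almost no mass across the mask
        assert out.data.sum() == pytest.approx(mini_phantom.data.sum(), rel=0.02)

    def test_high_frequency_energy_decreases(self, mini_phantom):
        out = spatial_filter(mini_phantom, sigma=1.0, mask=False)

        def hf_energy(vol):
            spec3 = np.abs(np.fft.fftn(vol))
            freqs = [np.fft.fftfreq(s) for s in vol.shape]
            grid = np.meshgrid(*freqs, indexing="ij")
            hf = np.sqrt(sum(g**2 for g in grid)) > 0.25  # above half-Nyquist
            return spec3[hf].sum()

        assert hf_energy(out.data) < hf_energy(mini_phantom.data)
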