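import numpy as np
import pytest

from fetalvol.image_model import (
    FormatError,
    LabelMap,
    VolumeImage,
    read_labels,
    read_volume,
    resample_isotropic,
    resample_labels_isotropic,
    write_labels,
    write_volume,
)


class TestIO:
    def test_volume_round_trip(self, tmp_path, rng):
        v = VolumeImage(
            rng.normal(size=(10, 10, 10)).astype(np.float32),
            spacing=(1.8, 1.4, 2.5),
            origin=(-9.0, -7.0, -12.5),
        )
        p = tmp_path / "v.nii.gz"
        write_volume(v, p)
        v2 = read_volume(p)
        np.testing.assert_array_equal(v2.voxels, v.voxels)
        np.testing.assert_allclose(v2.spacing, v.spacing, atol=1e-6)
        np.testing.assert_allclose(v2.origin, v.origin, atol=1e-5)

    def test_voxel_volume_from_header(self, tmp_path, rng):
        v = VolumeImage(rng.normal(size=(10, 10, 10)), spacing=(1.8, 1.4, 2.5))
        p = tmp_path / "v.nii.gz"
        write_volume(v, p)
        assert read_volume(p).voxel_volume_mm3 == pytest.approx(1.8 * 1.4 * 2.5)

    def test_labels_round_trip_exact(self, tmp_path, rng):
        lab = LabelMap(
            rng.integers(0, 5, size=(7, 8, 9)).astype(np.uint8), spacing=(1, 1, 1)
        )
        p = tmp_path / "l.nii.gz"
        write_labels(lab, p)
        lab2 = read_labels(p)
        np.testing.assert_array_equal(lab2.labels, lab.labels)
        assert lab2.class_names == lab.class_names
        assert np.issubdtype(lab2.labels.dtype, np.integer)

    def test_non_3d_file_rejected(self, tmp_path):
        import nibabel as nib

        p = tmp_path / "flat.nii.gz"
        nib.save(nib.Nifti1Image(np.zeros((5, 5), dtype=np.float32), np.eye(4)), p)
        with pytest.raises(FormatError):
            read_volume(p)

    def test_missing_file_and_bad_path(self, tmp_path, rng):
        with pytest.raises((FileNotFoundError, OSError)):
            read_volume(tmp_path / "absent.nii.gz")
        v = VolumeImage(rng.normal(size=(4, 4, 4)), spacing=(1, 1, 1))
        with pytest.raises(OSError):
            write_volume(v, tmp_path)  # a directory, not a file


class TestValidation:
    @pytest.mark.parametrize("spacing", [(0, 1, 1), (1, -2, 1), (1, 1)])
    def test_bad_spacing_rejected(self, spacing, rng):
        with pytest.raises(ValueError):
            VolumeImage(rng.normal(size=(4, 4, 4)), spacing=spacing)

    def test_labels_outside_alphabet_rejected(self):
        with pytest.raises(ValueError):
            LabelMap(np.full((3, 3, 3), 9, dtype=np.uint8), spacing=(1, 1, 1))


class TestResample:
    def test_identity_when_already_isotropic(self, rng):
        v = VolumeImage(rng.normal(size=(8, 8, 8)), spacing=(2.0, 2.0, 2.0))
        out = resample_isotropic(v, 2.0)
        np.testing.assert_array_equal(out.voxels, v.voxels)

    def test_constant_volume_stays_constant(self):
        v = VolumeImage(np.full((9, 11, 7), 3.5), spacing=(1.8, 1.4, 2.5))
        out = resample_isotropic(v, 1.5, mode="linear")
        np.testing.assert_allclose(out.voxels, 3.5, rtol=1e-6)

    def test_extent_preserved_within_one_voxel(self, rng):
        v = VolumeImage(rng.normal(size=(20, 30, 12)), spacing=(1.8, 1.4, 2.5))
        out = resample_isotropic(v, 1.0)
        old = np.array(v.shape) * np.array(v.spacing)
        new = np.array(out.shape) * 1.0
        assert np.all(np.abs(old - new) <= 1.0)

    def test_nonpositive_target_rejected(self, rng):
        v = VolumeImage(rng.normal(size=(4, 4, 4)), spacing=(1, 1, 1))
        with pytest.raises(ValueError):
            resample_isotropic(v, 0.0)

    def _sphere_labels(self, spacing, radius=12.0, half=20.0):
        ax = [
            (np.arange(int(2 * half / s)) + 0.5) * s - half for s in spacing
        ]
        X, Y, Z = np.meshgrid(*ax, indexing="ij", sparse=True)
        inside = (X**2 + Y**2 + Z**2) <= radius**2
        return LabelMap(inside.astype(np.uint8), tuple(spacing))

    def test_nearest_resampling_preserves_sphere_volume(self):
        lab = self._sphere_labels((1.8, 1.4, 2.5))
        vol0 = np.count_nonzero(lab.labels) * lab.voxel_volume_mm3
        out = resample_labels_isotropic(lab, 0.9)
        vol1 = np.count_nonzero(out.labels == 1) * out.voxel_volume_mm3
        assert set(np.unique(out.labels)) <= set(np.unique(lab.labels))
        assert abs(vol1 - vol0) / vol0 < 0.05

    def test_resampled_volume_converges_to_analytic(self):
        # ellipsoid mask: voxel-count volume error must shrink as the grid
        # refines (checked at two resolutions against the closed form)
        a, b, c = 14.0, 10.0, 8.0
        analytic = 4 / 3 * np.pi * a * b * c

        def discretized(target):
            ax = [(np.arange(int(40 / target)) + 0.5) * target - 20 for _ in range(3)]
            X, Y, Z = np.meshgrid(*ax, indexing="ij", sparse=True)
            inside = (X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2 <= 1
            return np.count_nonzero(inside) * target**3

        err_coarse = abs(discretized(2.5) - analytic) / analytic
        err_fine = abs(discretized(1.0) - analytic) / analytic
        assert err_fine < err_coarse
        assert err_fine < 0.01
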