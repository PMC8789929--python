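"""Cropping, intensity normalization, resolution simulation, external hooks."""

import numpy as np
import pytest

from deephips.core import (
    LabelMap,
    VolumePair,
    load_label_map,
    load_volume_pair,
    save_label_map,
    save_volume_pair,
)
from deephips.preprocess import (
    CropBox,
    DegenerateInputError,
    ExternalStep,
    crop,
    downsample_upsample,
    paste_back,
    run_external_steps,
    zscore_normalize,
)


class TestZScore:
    def test_mean_zero_sd_one(self, rng):
        out = zscore_normalize(rng.normal(3.0, 2.5, size=(8, 8, 8)))
        assert abs(out.mean()) < 1e-6
        assert abs(out.std() - 1) < 1e-6

    def test_affine_invariance(self, rng):
        x = rng.normal(size=(6, 6, 6))
        assert zscore_normalize(3.2 * x + 7) == pytest.approx(zscore_normalize(x))

    def test_two_voxel_hand_case(self):
        assert zscore_normalize(np.array([0.0, 2.0])) == pytest.approx([-1.0, 1.0])

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError, match="variance"):
            zscore_normalize(np.full((4, 4, 4), 3.0))


class TestCrop:
    @pytest.fixture
    def vp(self, rng):
        return VolumePair(rng.normal(size=(2, 10, 12, 14)), spacing=(1, 1, 1))

    def test_full_volume_box_is_identity(self, vp):
        box = CropBox((0, 10), (0, 12), (0, 14))
        out = crop(vp, box)
        assert np.array_equal(out.data, vp.data)
        assert np.allclose(out.affine, vp.affine)

    def test_round_trip_paste_back(self, vp):
        box = CropBox((2, 6), (3, 9), (4, 10))
        cropped = crop(vp, box)
        cropped.data += 5.0
        pasted = paste_back(vp, cropped, box)
        assert np.allclose(pasted.data[:, 2:6, 3:9, 4:10], vp.data[:, 2:6, 3:9, 4:10] + 5)
        mask = np.ones_like(vp.data, dtype=bool)
        mask[:, 2:6, 3:9, 4:10] = False
        assert np.array_equal(pasted.data[mask], vp.data[mask])

    def test_origin_metadata_updated(self, vp):
        box = CropBox((2, 6), (3, 9), (4, 10))
        out = crop(vp, box)
        world_origin_of_crop = vp.affine @ np.array([2, 3, 4, 1.0])
        assert np.allclose(out.affine @ np.array([0, 0, 0, 1.0]), world_origin_of_crop)

    def test_out_of_bounds(self, vp):
        with pytest.raises(IndexError, match="outside"):
            crop(vp, CropBox((2, 11), (0, 4), (0, 4)))

    def test_label_map_crop_keeps_integers(self, rng):
        lm = LabelMap(rng.integers(0, 4, size=(8, 8, 8)).astype(np.int32))
        out = crop(lm, CropBox((1, 5), (2, 6), (0, 4)))
        assert out.data.dtype == lm.data.dtype
        assert np.array_equal(out.data, lm.data[1:5, 2:6, 0:4])

    def test_side_box_separates_structures(self):
        # two blobs at known coordinates: a left-half box sees only the left one
        labels = np.zeros((16, 8, 8), dtype=np.int32)
        labels[2:5, 3:6, 3:6] = 1  # left structure (low x)
        labels[11:14, 3:6, 3:6] = 2  # right structure (high x)
        lm = LabelMap(labels)
        left = crop(lm, CropBox((0, 8), (0, 8), (0, 8), side="left"))
        assert set(np.unique(left.data)) == {0, 1}

    def test_padded_to_multiple(self):
        box = CropBox((3, 12), (5, 11), (0, 7))
        padded = box.padded_to_multiple(8, (32, 32, 32))
        for lo, hi in (padded.x, padded.y, padded.z):
            assert (hi - lo) % 8 == 0
            assert 0 <= lo < hi <= 32
        # padded box still contains the original
        assert padded.x[0] <= 3 and padded.x[1] >= 12


class TestResolutionSimulation:
    def test_constant_image_unchanged(self):
        x = np.full((16, 16, 16), 2.5)
        out = downsample_upsample(x, 2)
        assert out == pytest.approx(x, abs=1e-6)

    def test_low_frequency_sinusoid_recovered(self):
        # one cycle across 32 voxels is far below the coarse grid's Nyquist
        n = 32
        i = np.arange(n)
        x = np.sin(2 * np.pi * i / n)[:, None, None] * np.ones((1, n, n))
        out = downsample_upsample(x, 2)
        core = (slice(4, -4),) * 3  # ignore boundary extrapolation
        rms = np.sqrt(np.mean((out[core] - x[core]) ** 2))
        assert rms / np.sqrt(np.mean(x[core] ** 2)) < 0.02

    def test_sharp_edge_blurred(self):
        x = np.zeros((16, 16, 16))
        x[8:] = 1.0
        out = downsample_upsample(x, 2)
        grad_in = np.abs(np.diff(x, axis=0)).max()
        grad_out = np.abs(np.diff(out, axis=0))[6:10].max()
        assert grad_out < grad_in

    def test_invalid_factor(self):
        with pytest.raises(ValueError, match="factor"):
            downsample_upsample(np.zeros((8, 8, 8)), 1)


class TestExternalSteps:
    def test_all_disabled_is_identity(self, tmp_path):
        paths = {"t1": str(tmp_path / "a.nii")}
        steps = [ExternalStep("denoise", "doesnotexist {input} {output}", enabled=False)]
        out, prov = run_external_steps(paths, steps)
        assert out == paths
        assert prov == []

    def test_stub_commands_record_provenance(self, tmp_path):
        src = tmp_path / "t1.txt"
        src.write_text("data")
        steps = [
            ExternalStep("denoise", "cp {input} {output}"),
            ExternalStep("bias", "cp {input} {output}"),
            ExternalStep("register", "cp {input} {output}"),
        ]
        out, prov = run_external_steps({"t1": str(src)}, steps)
        assert len(prov) == 3
        assert [p["step"] for p in prov] == ["denoise", "bias", "register"]
        with open(out["t1"]) as fh:
            assert fh.read() == "data"

    def test_misordered_steps_warn(self, tmp_path, caplog):
        src = tmp_path / "x.txt"
        src.write_text("d")
        steps = [
            ExternalStep("bias", "cp {input} {output}"),
            ExternalStep("denoise", "cp {input} {output}"),
        ]
        with caplog.at_level("WARNING"):
            run_external_steps({"t1": str(src)}, steps)
        assert any("canonical order" in r.message for r in caplog.records)

    def test_missing_executable(self, tmp_path):
        steps = [ExternalStep("denoise", "no-such-binary-xyz {input} {output}")]
        with pytest.raises(EnvironmentError, match="no-such-binary-xyz"):
            run_external_steps({"t1": str(tmp_path / "a")}, steps)


class TestNiftiRoundTrip:
    def test_volume_pair_affine_preserved(self, tmp_path, rng):
        aff = np.diag([0.5, 0.5, 0.5, 1.0])
        aff[:3, 3] = (10.0, -7.0, 3.0)
        vp = VolumePair(rng.normal(size=(2, 8, 8, 8)), (0.5, 0.5, 0.5), aff)
        save_volume_pair(vp, tmp_path / "t1.nii.gz", tmp_path / "t2.nii.gz")
        back = load_volume_pair(tmp_path / "t1.nii.gz", tmp_path / "t2.nii.gz")
        assert np.allclose(back.affine, aff, atol=1e-6)
        assert np.allclose(back.data, vp.data)

    def test_label_map_round_trip(self, tmp_path, rng):
        lm = LabelMap(rng.integers(0, 5, size=(6, 6, 6)).astype(np.int32))
        save_label_map(lm, tmp_path / "lab.nii.gz")
        back = load_label_map(tmp_path / "lab.nii.gz")
        assert np.array_equal(back.data, lm.data)
        assert np.allclose(back.affine, lm.affine, atol=1e-6)
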