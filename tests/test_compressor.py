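import numpy as np
import pytest

from neurovol.compressor import (ChecksumError, TrainConfig, artifact_metrics,
                                 decompress, load_artifact, save_artifact,
                                 train_end_to_end)
from neurovol.inr_siren import SirenConfig
from neurovol.metrics import MetricRecord
from neurovol.neural_sr import SRConfig
from neurovol.spectral_downsample import ScaleSpec
from neurovol.volume_io import Patch

SIREN = SirenConfig(layers=3, neurons=10)
SR = SRConfig(channels=4)
HALF = ScaleSpec.isotropic(0.5)


@pytest.fixture(scope="module")
def trained(smooth_patch_16_module):
    tc = TrainConfig(epochs=60, seed=0, log_every=10)
    return train_end_to_end(smooth_patch_16_module, HALF, SIREN, SR, tc), \
        smooth_patch_16_module


@pytest.fixture(scope="module")
def smooth_patch_16_module():
    from neurovol.phantom import PhantomSpec, make_phantom
    vol = make_phantom(PhantomSpec(shape=(16, 16, 16), kind="gaussian_blobs",
                                   n_structures=2, seed=3))
    return Patch(origin=(0, 0, 0), size=16, data=vol.data)


class TestTraining:
    def test_constant_patch_converges(self):
        # Adam on an L1 loss settles into a limit cycle whose amplitude
        # scales with the learning rate, so the degenerate constant target
        # is checked at a small step size
        patch = Patch(origin=(0, 0, 0), size=8, data=np.full((8, 8, 8), 0.5))
        _, hist = train_end_to_end(patch, HALF, SIREN, SR,
                                   TrainConfig(epochs=200, learning_rate=5e-4,
                                               seed=1, log_every=50))
        assert hist.loss[-1] < 1e-3

    def test_loss_strictly_decreases(self, trained):
        (_, hist), _ = trained
        assert hist.loss[-1] < hist.loss[0]

    def test_history_quality_improves_with_loss(self, trained):
        (_, hist), _ = trained
        assert hist.psnr_db[-1] > hist.psnr_db[0]
        assert hist.ssim[-1] > hist.ssim[0]
        assert hist.loss[0] == max(hist.loss)

    def test_gradients_reach_both_modules(self, smooth_patch_16_module):
        """One optimization step changes weights in the SIREN and the SR net."""
        from neurovol.inr_siren import build_siren
        from neurovol.neural_sr import build_sr
        tc = TrainConfig(epochs=1, seed=0)
        before_siren = build_siren(SIREN, seed=tc.seed).flat_weights()
        before_sr = build_sr(SR, seed=tc.seed + 1).flat_weights()
        artifact, _ = train_end_to_end(smooth_patch_16_module, HALF, SIREN, SR, tc)
        assert not np.allclose(artifact.siren_weights, before_siren.astype(np.float32))
        assert not np.allclose(artifact.sr_weights, before_sr.astype(np.float32))

    def test_determinism(self, smooth_patch_16_module):
        tc = TrainConfig(epochs=5, seed=4)
        a, _ = train_end_to_end(smooth_patch_16_module, HALF, SIREN, SR, tc)
        b, _ = train_end_to_end(smooth_patch_16_module, HALF, SIREN, SR, tc)
        np.testing.assert_array_equal(a.siren_weights, b.siren_weights)
        np.testing.assert_array_equal(a.sr_weights, b.sr_weights)

    def test_aux_lr_loss_changes_training(self, smooth_patch_16_module):
        tc0 = TrainConfig(epochs=5, seed=4)
        tc1 = TrainConfig(epochs=5, seed=4, aux_lr_loss_weight=0.5)
        a, _ = train_end_to_end(smooth_patch_16_module, HALF, SIREN, SR, tc0)
        b, _ = train_end_to_end(smooth_patch_16_module, HALF, SIREN, SR, tc1)
        assert not np.array_equal(a.siren_weights, b.siren_weights)


class TestArtifact:
    def test_total_counts(self, trained):
        (artifact, _), _ = trained
        from neurovol.inr_siren import count_params
        from neurovol.neural_sr import count_sr_params
        assert artifact.total_params == count_params(SIREN) + count_sr_params(SR)
        assert artifact.total_bits == artifact.total_params * 32

    def test_decompress_matches_training_reconstruction(self, trained):
        (artifact, hist), patch = trained
        recon = decompress(artifact, patch.data.shape)
        np.testing.assert_array_equal(recon.data, hist.final_reconstruction)

    def test_decompress_default_shape(self, trained):
        (artifact, _), _ = trained
        assert decompress(artifact).shape == (16, 16, 16)

    def test_serialization_round_trip_bit_exact(self, trained, tmp_path):
        (artifact, _), patch = trained
        path = tmp_path / "a.nvz"
        save_artifact(path, artifact)
        back = load_artifact(path)
        np.testing.assert_array_equal(back.siren_weights, artifact.siren_weights)
        np.testing.assert_array_equal(back.sr_weights, artifact.sr_weights)
        assert back.scale == artifact.scale
        assert back.siren_config == artifact.siren_config
        np.testing.assert_array_equal(decompress(back).data,
                                      decompress(artifact).data)

    def test_tampered_payload_raises_checksum_error(self, trained, tmp_path):
        (artifact, _), _ = trained
        path = tmp_path / "a.nvz"
        save_artifact(path, artifact)
        blob = bytearray(path.read_bytes())
        blob[len(blob) // 2] ^= 0xFF
        path.write_bytes(bytes(blob))
        with pytest.raises(ChecksumError):
            load_artifact(path)

    def test_metrics_bundle(self, trained):
        (artifact, _), patch = trained
        rec = artifact_metrics(artifact, patch)
        assert isinstance(rec, MetricRecord)
        n_vox = 16 ** 3
        assert rec.cr_percent == (1 - artifact.total_params / n_vox) * 100
        assert rec.bitrate_bpp == artifact.total_params * 32 / n_vox
        assert -1 <= rec.ssim <= 1 and np.isfinite(rec.psnr_db)

    def test_identical_reconstruction_ssim_one(self):
        from neurovol.metrics import ssim
        rng = np.random.default_rng(0)
        a = rng.random((8, 8, 8))
        assert ssim(a, a.copy()) == pytest.approx(1.0)

    def test_nonfinite_loss_aborts_with_diagnostics(self):
        patch = Patch(origin=(0, 0, 0), size=8,
                      data=np.full((8, 8, 8), 0.5))
        tc = TrainConfig(learning_rate=1e200, epochs=5, seed=0)
        with pytest.raises(FloatingPointError, match="epoch"):
            train_end_to_end(patch, HALF, SIREN, SR, tc)

    def test_history_csv_logging(self, trained, tmp_path):
        (_, hist), _ = trained
        path = tmp_path / "hist.csv"
        hist.to_csv(path)
        lines = path.read_text().splitlines()
        assert lines[0] == "epoch,loss,psnr_db,ssim"
        assert len(lines) == len(hist.loss) + 1
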