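"""Surrogate architecture, losses, and staged-training contracts."""

import numpy as np
import pytest

from skullbeam import nn
from skullbeam.surrogate import (LstmConvCell, SurrogateDataset, SurrogateNet,
                                 SurrogateSpec, TrainConfig, directional_scan,
                                 encoder_weight_hash, lambda_focus,
                                 lambda_skull, loss_abs, loss_field,
                                 loss_phase, train_surrogate, transfer_weights)


@pytest.fixture(scope="module")
def net32():
    nn.set_seed(7)
    return SurrogateNet(SurrogateSpec(grid_n=32, n_elements=16))


class TestDirectionalScan:
    def test_output_shapes_all_directions(self, rng):
        nn.set_seed(1)
        img = nn.Tensor(rng.standard_normal((2, 8, 8)))
        for d in ("down", "up", "right", "left"):
            lstm = nn.LSTM(8)
            y, state = directional_scan(img, lstm, d)
            assert y.shape == (2, 8, 8)
            assert state[0][0].shape == (2, 8)

    def test_reverse_scan_equals_flipped_forward_scan_with_shared_weights(self, rng):
        """Reversing the input along the scan axis and reversing the output
        reproduces the opposite-direction scan when weights are shared."""
        nn.set_seed(2)
        lstm = nn.LSTM(8)
        x = rng.standard_normal((1, 8, 8))
        down, _ = directional_scan(nn.Tensor(x), lstm, "down")
        up_of_flip, _ = directional_scan(nn.Tensor(x[:, ::-1, :].copy()), lstm, "up")
        assert np.allclose(down.data, up_of_flip.data[:, ::-1, :])

    def test_rejects_non_square(self, rng):
        with pytest.raises(ValueError):
            directional_scan(nn.Tensor(rng.standard_normal((1, 4, 6))),
                             nn.LSTM(4), "down")


class TestLstmConvCell:
    def test_down_cell_halves_spatial_size(self, rng):
        nn.set_seed(3)
        cell = LstmConvCell(16, "down")
        y, states = cell(nn.Tensor(rng.standard_normal((2, 1, 16, 16))))
        assert y.shape == (2, 1, 8, 8)
        assert len(states) == 4

    def test_up_cell_doubles_spatial_size(self, rng):
        nn.set_seed(3)
        cell = LstmConvCell(16, "up")
        y, _ = cell(nn.Tensor(rng.standard_normal((2, 1, 16, 16))))
        assert y.shape == (2, 1, 32, 32)

    def test_eval_mode_is_deterministic(self, rng):
        nn.set_seed(3)
        cell = LstmConvCell(8, "down", dropout=0.5)
        cell.eval()
        x = nn.Tensor(rng.standard_normal((1, 1, 8, 8)))
        assert np.array_equal(cell(x)[0].data, cell(x)[0].data)


class TestLossSchedule:
    def test_early_epochs_are_uniform(self):
        assert lambda_skull(1) == 0.5
        assert lambda_skull(3) == 0.5
        assert lambda_focus(3) == 0.5

    def test_schedule_after_switch(self):
        assert lambda_skull(5) == 0.5
        assert lambda_skull(6) == 0.25
        assert lambda_focus(6) == 0.75
        assert lambda_skull(10) == 0.5 ** 6

    def test_weights_sum_to_one_and_decay(self):
        vals = [lambda_skull(t) for t in range(1, 30)]
        assert all(lambda_skull(t) + lambda_focus(t) == 1.0 for t in range(1, 30))
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_uniform_epoch_reduces_to_half_mse(self, rng):
        pred = nn.Tensor(rng.random((2, 1, 16, 16)))
        gt = rng.random((2, 1, 16, 16))
        loss = loss_field(pred, gt, epoch=3, split_row=6)
        assert loss.item() == pytest.approx(0.5 * np.mean((pred.data - gt) ** 2))

    def test_zero_for_perfect_prediction(self, rng):
        gt = rng.random((1, 1, 16, 16))
        for epoch in (1, 5, 9):
            assert loss_field(nn.Tensor(gt), gt, epoch, 6).item() == 0.0


class TestScalarLosses:
    def test_abs_loss_examples(self, rng):
        assert loss_abs(nn.Tensor([[2.0]]), np.array([[2.0]])).item() == 0.0
        assert loss_abs(nn.Tensor([[3.0]]), np.array([[2.0]])).item() == 1.0
        a, b = rng.random((4, 1)), rng.random((4, 1))
        assert loss_abs(nn.Tensor(a), b).item() == pytest.approx(np.abs(a - b).mean())

    def test_phase_loss_examples(self, rng):
        z = np.zeros((2, 16))
        assert loss_phase(nn.Tensor(z), z).item() == 0.0
        assert loss_phase(nn.Tensor(z + 0.3), z).item() == pytest.approx(0.3)
        a, b = rng.random((3, 16)), rng.random((3, 16))
        assert loss_phase(nn.Tensor(a), b).item() == pytest.approx(np.abs(a - b).mean())


class TestForwardPasses:
    def test_output_shapes(self, net32, rng):
        net32.eval()
        out = net32(rng.random((2, 1, 32, 32)))
        assert out["field"].shape == (2, 1, 32, 32)
        assert out["phase"].shape == (2, 16)
        assert out["abs_pressure"].shape == (2, 1)

    def test_field_bounded_and_phase_fractional(self, net32, rng):
        net32.eval()
        out = net32(rng.random((1, 1, 32, 32)))
        assert 0.0 <= out["field"].data.min() and out["field"].data.max() <= 1.0
        assert 0.0 <= out["phase"].data.min() and out["phase"].data.max() <= 1.0

    def test_absolute_field_is_product(self, net32, rng):
        net32.eval()
        out = net32(rng.random((1, 1, 32, 32)))
        absolute = out["field"].data[0, 0] * out["abs_pressure"].data[0, 0]
        assert absolute.max() == pytest.approx(
            out["field"].data.max() * out["abs_pressure"].data[0, 0])

    def test_eval_determinism(self, net32, rng):
        net32.eval()
        x = rng.random((1, 1, 32, 32))
        a = net32.forward_field(x)[0].data
        b = net32.forward_field(x)[0].data
        assert np.array_equal(a, b)


class TestTraining:
    @staticmethod
    def _toy_dataset(rng, n=6, g=32, n_el=16):
        return SurrogateDataset(
            canvas=rng.random((n, g, g)),
            field=rng.random((n, g, g)) * 0.5,
            peak_pa=rng.random(n) * 1e6,
            phase_frac=rng.random((n, n_el)),
        )

    def test_frozen_encoder_and_history(self, rng):
        nn.set_seed(11)
        net = SurrogateNet(SurrogateSpec(grid_n=32, n_elements=16))
        train = self._toy_dataset(rng)
        cfg = TrainConfig(batch_size=3, epochs_field=1, epochs_phase=1,
                          epochs_abs=1, seed=0)
        hist = train_surrogate(net, train, None, cfg)
        h_field = hist["encoder_hash"]["field"]
        assert h_field[0] != h_field[1]  # stage 1 does update the encoder
        for stage in ("phase", "abs"):
            before, after = hist["encoder_hash"][stage]
            assert before == after
        assert len(hist["stages"]["field"]) == 1

    def test_single_sample_loss_drops(self, rng):
        nn.set_seed(13)
        net = SurrogateNet(SurrogateSpec(grid_n=32, n_elements=16, dropout=0.0))
        x = rng.random((1, 1, 32, 32))
        y = rng.random((1, 1, 32, 32)) * 0.3
        opt = nn.Adam(net.field_parameters(), lr=5e-2)
        net.train()
        first = last = None
        for _ in range(30):
            opt.zero_grad()
            pred, _, _ = net.forward_field(nn.Tensor(x))
            loss = loss_field(pred, y, 3, net.spec.split_row)
            loss.backward()
            opt.step()
            first = first if first is not None else loss.item()
            last = loss.item()
        assert last < 0.7 * first

    def test_layer_transfer_copies_shared_weights(self):
        nn.set_seed(17)
        src = SurrogateNet(SurrogateSpec(grid_n=32, n_elements=16, n_lstm_layers=1))
        dst = SurrogateNet(SurrogateSpec(grid_n=32, n_elements=16, n_lstm_layers=4))
        transfer_weights(src, dst)
        src_lstm = src.encoder[0].lstms[0]
        dst_lstm = dst.encoder[0].lstms[0]
        assert np.array_equal(src_lstm.wx[0].data, dst_lstm.wx[0].data)
        assert dst_lstm.n_layers == 4
        assert np.array_equal(src.field_head.weight.data, dst.field_head.weight.data)
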