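"""Multi-task LSTM-Conv surrogate for transcranial focusing.

The network maps a normalized input canvas (skull + element marks + target +
waveguides) to three decoupled outputs:

* the normalized phase-corrected pressure field (encoder-decoder with skip
  connections, final sigmoid),
* the absolute peak pressure scalar (decoded from the bottleneck "reduced
  embedding"), so that absolute field = normalized field x peak, and
* the per-element phase correction vector, as delays expressed in fractions
  of a drive period in [0, 1) (decoded from the first encoder cell's output
  through three further LSTM-Conv cells and fully-connected layers).

Each LSTM-Conv cell scans its single-channel input with four LSTMs (top-down,
bottom-up, left-right, right-left; hidden size = row length), concatenates the
four scans as channels, then applies conv(4->8), conv(8->16) with x2 down- or
up-sampling, and a 1x1 conv back to one channel, with batch-norm + ReLU after
every convolution and dropout 0.2. Final (h, c) LSTM states are resized and
handed to the next cell's scans.

Training is staged: the field head first (weighted MSE with an adaptive
skull/focus row split), then the phase and absolute-pressure heads with the
encoder frozen. Adam with plateau-based learning-rate decay throughout.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field as dc_field

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "SurrogateSpec", "TrainConfig", "SurrogateDataset",
    "LstmConvCell", "SurrogateNet", "directional_scan",
    "lambda_skull", "lambda_focus", "loss_field", "loss_abs", "loss_phase",
    "train_surrogate", "encoder_weight_hash", "transfer_weights",
]

DIRECTIONS = ("down", "up", "right", "left")


# ---------------------------------------------------------------------------
# architecture


def directional_scan(image: Tensor, lstm: nn.LSTM, direction: str, state=None):
    """Scan a (B, H, W) image with an LSTM along one of four directions.

    The orthogonal axis is the sequence axis: "down"/"up" feed rows top-to-
    bottom / bottom-to-top, "right"/"left" feed columns. Outputs keep the
    spatial layout of the input (each sequence step writes its original
    row/column position). Returns the (B, H, W) feature map and the final
    LSTM state.
    """
    if image.shape[-1] != image.shape[-2]:
        raise ValueError("directional scans require square inputs")
    h = image.shape[1]
    transposed = direction in ("right", "left")
    img = image.swap_last2() if transposed else image
    order = range(h - 1, -1, -1) if direction in ("up", "left") else range(h)
    seq = [img[:, t, :] for t in order]
    outs, state = lstm(seq, state)
    if direction in ("up", "left"):
        outs = outs[::-1]
    y = nn.stack_rows(outs, axis=1)
    if transposed:
        y = y.swap_last2()
    return y, state


def _resize_state(state, new_size: int):
    """Resize per-layer (h, c) LSTM state vectors for the next cell."""
    (h0, _) = state[0]
    cur = h0.shape[1]
    if new_size == cur:
        return state
    if new_size == cur // 2:
        op = nn.resize_half_vec
    elif new_size == cur * 2:
        op = nn.resize_double_vec
    else:
        raise ValueError(f"cannot resize state {cur} -> {new_size}")
    return [(op(h), op(c)) for h, c in state]


class LstmConvCell(nn.Module):
    """One LSTM-Conv cell: four directional scans + three conv layers."""

    def __init__(self, input_size: int, mode: str, n_lstm_layers: int = 1,
                 dropout: float = 0.2):
        super().__init__()
        if mode not in ("down", "up"):
            raise ValueError("mode must be 'down' or 'up'")
        self.input_size = input_size
        self.mode = mode
        self.lstms = [nn.LSTM(input_size, n_lstm_layers) for _ in DIRECTIONS]
        self.conv1 = nn.Conv2d(4, 8, 3, padding=1)
        self.bn1 = nn.BatchNorm2d(8)
        stride = 2 if mode == "down" else 1
        self.conv2 = nn.Conv2d(8, 16, 3, stride=stride, padding=1)
        self.bn2 = nn.BatchNorm2d(16)
        self.conv3 = nn.Conv2d(16, 1, 1)
        self.bn3 = nn.BatchNorm2d(1)
        self.dropout = nn.Dropout(dropout)

    @property
    def output_size(self) -> int:
        return self.input_size // 2 if self.mode == "down" else self.input_size * 2

    def forward(self, x: Tensor, states=None):
        """x: (B, 1, H, H) -> (y (B, 1, H', H'), final states per direction)."""
        if x.shape[-1] != self.input_size:
            raise ValueError(f"expected input size {self.input_size}, got {x.shape[-1]}")
        img = x[:, 0]
        maps, out_states = [], []
        for k, d in enumerate(DIRECTIONS):
            st = None
            if states is not None:
                st = _resize_state(states[k], self.input_size)
            y, st = directional_scan(img, self.lstms[k], d, st)
            maps.append(y)
            out_states.append(st)
        feat = nn.stack_rows(maps, axis=1)  # (B, 4, H, H)
        h = self.bn1(self.conv1(feat)).relu()
        if self.mode == "up":
            h = nn.upsample2(h)
        # dropout acts on the 16-channel features, where zeroing units
        # regularizes without deleting the cell's whole (single-channel)
        # output signal
        h = self.dropout(self.bn2(self.conv2(h)).relu())
        y = self.bn3(self.conv3(h)).relu()
        return y, out_states


@dataclass
class SurrogateSpec:
    """Architecture hyperparameters.

    ``grid_n`` must be divisible by 32 (five x2 stages). ``split_row``
    separates the transducer/skull rows from the focal region in the field
    loss and scales with resolution (row 180 of 512 at full scale).
    """

    grid_n: int = 128
    n_elements: int = 40
    n_lstm_layers: int = 1
    dropout: float = 0.2
    fc_hidden: int = 64
    abs_scale_pa: float = 1e6
    split_row: int | None = None

    def __post_init__(self) -> None:
        if self.grid_n % 32 != 0:
            raise ValueError("grid_n must be divisible by 32")
        if self.split_row is None:
            self.split_row = round(180 / 512 * self.grid_n)


class SurrogateNet(nn.Module):
    """Encoder-decoder with skip connections plus phase and pressure heads."""

    def __init__(self, spec: SurrogateSpec):
        super().__init__()
        self.spec = spec
        g = spec.grid_n
        enc_sizes = [g >> k for k in range(5)]          # g .. g/16
        dec_sizes = [g >> (5 - k) for k in range(5)]    # g/32 .. g/2
        self.encoder = [LstmConvCell(s, "down", spec.n_lstm_layers, spec.dropout)
                        for s in enc_sizes]
        self.decoder = [LstmConvCell(s, "up", spec.n_lstm_layers, spec.dropout)
                        for s in dec_sizes]
        # skip merges: concat(decoder feature, encoder feature) -> 1 channel
        self.skip_convs = [nn.Conv2d(2, 1, 1) for _ in range(4)]
        self.field_head = nn.Conv2d(1, 1, 1)

        ph_sizes = [g >> k for k in range(1, 4)]        # g/2, g/4, g/8
        self.phase_cells = [LstmConvCell(s, "down", spec.n_lstm_layers, spec.dropout)
                            for s in ph_sizes]
        ph_flat = (g >> 4) ** 2
        self.phase_fc1 = nn.Linear(ph_flat, spec.fc_hidden)
        self.phase_fc2 = nn.Linear(spec.fc_hidden, spec.n_elements)

        s_bott = g >> 5
        self.abs_conv = nn.Conv2d(1, 8, 3, padding=1)
        self.abs_fc1 = nn.Linear(8 * s_bott * s_bott, spec.fc_hidden)
        self.abs_fc2 = nn.Linear(spec.fc_hidden, 1)

    # -- forward passes ----------------------------------------------------

    def encode(self, x: Tensor):
        """Returns (encoder outputs e1..e5, final states, first cell output)."""
        outs, states = [], None
        h = x
        for cell in self.encoder:
            h, states = cell(h, states)
            outs.append(h)
        return outs, states

    def forward_field(self, x):
        """Canvas (B, 1, g, g) -> (normalized field, reduced embedding,
        first encoder cell output)."""
        x = x if isinstance(x, Tensor) else Tensor(x)
        enc, states = self.encode(x)
        embedding = enc[-1]
        h = embedding
        for k, cell in enumerate(self.decoder):
            if k > 0:
                skip = enc[4 - k]
                h = self.skip_convs[k - 1](nn.concat([h, skip], axis=1))
            h, states = cell(h, states)
        field = self.field_head(h).sigmoid()
        return field, embedding, enc[0]

    def forward_phase(self, first_cell_output: Tensor) -> Tensor:
        """First encoder cell output -> per-element delay fractions in [0, 1)."""
        h, states = first_cell_output, None
        for cell in self.phase_cells:
            h, states = cell(h, states)
        b = h.shape[0]
        flat = h.reshape(b, -1)
        return self.phase_fc2(self.phase_fc1(flat).relu()).sigmoid()

    def forward_abs_pressure(self, embedding: Tensor) -> Tensor:
        """Reduced embedding -> absolute peak pressure in Pa (B, 1)."""
        h = self.abs_conv(embedding).relu()
        b = h.shape[0]
        flat = h.reshape(b, -1)
        out = self.abs_fc2(self.abs_fc1(flat).relu())
        return out * self.spec.abs_scale_pa

    def forward(self, x):
        field, emb, first = self.forward_field(x)
        return {
            "field": field,
            "phase": self.forward_phase(first),
            "abs_pressure": self.forward_abs_pressure(emb),
        }

    # -- parameter groups --------------------------------------------------

    def encoder_parameters(self):
        return [p for cell in self.encoder for p in cell.parameters()]

    def field_parameters(self):
        ps = self.encoder_parameters()
        for cell in self.decoder:
            ps += cell.parameters()
        for cv in self.skip_convs:
            ps += cv.parameters()
        ps += self.field_head.parameters()
        return ps

    def phase_parameters(self):
        ps = []
        for cell in self.phase_cells:
            ps += cell.parameters()
        ps += self.phase_fc1.parameters() + self.phase_fc2.parameters()
        return ps

    def abs_parameters(self):
        return (self.abs_conv.parameters() + self.abs_fc1.parameters()
                + self.abs_fc2.parameters())


# ---------------------------------------------------------------------------
# losses


def lambda_skull(epoch: int) -> float:
    """Adaptive weight on the transducer/skull rows of the field loss.

    1-based epoch index: 0.5 while epoch < 5, then 0.5**(epoch - 4), so the
    skull region is progressively de-emphasized in favour of the focal
    region as training proceeds.
    """
    if epoch < 1:
        raise ValueError("epochs are 1-based")
    return 0.5 if epoch < 5 else 0.5 ** (epoch - 4)


def lambda_focus(epoch: int) -> float:
    return 1.0 - lambda_skull(epoch)


def _field_weights(grid_n: int, split_row: int, epoch: int) -> np.ndarray:
    w = np.full((1, 1, grid_n, 1), lambda_focus(epoch))
    w[:, :, :split_row, :] = lambda_skull(epoch)
    return w


def loss_field(pred: Tensor, gt: np.ndarray, epoch: int, split_row: int) -> Tensor:
    """Row-weighted MSE between predicted and ground-truth normalized fields."""
    gt = np.asarray(gt, dtype=np.float64)
    if pred.shape != gt.shape:
        raise ValueError("field shape mismatch")
    w = _field_weights(pred.shape[-2], split_row, epoch)
    diff = pred - Tensor(gt)
    return (diff * diff * Tensor(w)).mean()


def loss_abs(pred: Tensor, gt: np.ndarray) -> Tensor:
    """L1 on absolute peak pressure (mean over the batch)."""
    return (pred - Tensor(np.asarray(gt, dtype=np.float64).reshape(pred.shape))).abs().mean()


def loss_phase(pred: Tensor, gt: np.ndarray) -> Tensor:
    """Mean absolute error over the per-element phase vector."""
    return (pred - Tensor(np.asarray(gt, dtype=np.float64))).abs().mean()


# ---------------------------------------------------------------------------
# training


@dataclass
class SurrogateDataset:
    """Training arrays: canvases and their three decoupled targets."""

    canvas: np.ndarray        # (N, g, g) in [0, 1]
    field: np.ndarray         # (N, g, g) normalized, max 1
    peak_pa: np.ndarray       # (N,)
    phase_frac: np.ndarray    # (N, n_elements) delays as period fractions

    def __len__(self) -> int:
        return len(self.canvas)

    def subset(self, idx) -> "SurrogateDataset":
        return SurrogateDataset(self.canvas[idx], self.field[idx],
                                self.peak_pa[idx], self.phase_frac[idx])


@dataclass
class TrainConfig:
    lr: float = 2e-4
    plateau_factor: float = 0.1
    plateau_patience: int = 2
    plateau_threshold: float = 1e-3
    batch_size: int = 16
    epochs_field: int = 20
    epochs_phase: int = 15
    epochs_abs: int = 10
    seed: int = 0
    stages: tuple[str, ...] = ("field", "phase", "abs")
    history: list = dc_field(default_factory=list)


def encoder_weight_hash(model: SurrogateNet) -> str:
    """SHA-256 over the encoder parameter bytes (frozen-encoder audit)."""
    h = hashlib.sha256()
    for p in model.encoder_parameters():
        h.update(np.ascontiguousarray(p.data).tobytes())
    return h.hexdigest()


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    idx = rng.permutation(n)
    for k in range(0, n, batch_size):
        yield idx[k:k + batch_size]


def _stage_loss(model: SurrogateNet, stage: str, x: np.ndarray,
                data: SurrogateDataset, idx: np.ndarray, epoch: int) -> Tensor:
    xb = Tensor(x[idx])
    if stage == "field":
        pred, _, _ = model.forward_field(xb)
        return loss_field(pred, data.field[idx][:, None], epoch, model.spec.split_row)
    # phase / abs stages: the frozen encoder runs detached, so no gradient
    # (and no update) ever reaches its weights
    enc, _ = model.encode(xb)
    if stage == "phase":
        pred = model.forward_phase(enc[0].detach())
        return loss_phase(pred, data.phase_frac[idx])
    pred = model.forward_abs_pressure(enc[-1].detach())
    return loss_abs(pred, data.peak_pa[idx, None])


def train_surrogate(model: SurrogateNet, train: SurrogateDataset,
                    val: SurrogateDataset | None, config: TrainConfig) -> dict:
    """Staged training: field decoder first, then phase and absolute-pressure
    decoders with the encoder frozen (asserted by weight hash). Returns a
    history dict with per-epoch train/val losses and the encoder hashes."""
    rng = np.random.default_rng(config.seed)
    nn.set_seed(config.seed + 1)
    x = train.canvas[:, None]  # (N, 1, g, g)
    xv = val.canvas[:, None] if val is not None else None

    history: dict = {"stages": {}, "encoder_hash": {}}
    epochs_per_stage = {"field": config.epochs_field, "phase": config.epochs_phase,
                        "abs": config.epochs_abs}
    params_per_stage = {"field": model.field_parameters,
                        "phase": model.phase_parameters,
                        "abs": model.abs_parameters}

    for stage in config.stages:
        opt = nn.Adam(params_per_stage[stage](), lr=config.lr)
        sched = nn.ReduceLROnPlateau(opt, config.plateau_factor,
                                     config.plateau_patience, config.plateau_threshold)
        hash_before = encoder_weight_hash(model)
        rows = []
        for epoch in range(1, epochs_per_stage[stage] + 1):
            model.train()
            if stage != "field":
                # frozen encoder: inference mode throughout (batch-norm
                # statistics included), weights audited by hash below
                for cell in model.encoder:
                    for m in cell.modules():
                        m.training = False
            losses = []
            for idx in _batches(len(train), config.batch_size, rng):
                opt.zero_grad()
                loss = _stage_loss(model, stage, x, train, idx, epoch)
                loss.backward()
                opt.step()
                losses.append(loss.item())
            train_loss = float(np.mean(losses))
            val_loss = np.nan
            if val is not None:
                model.eval()
                # validation monitored at a fixed epoch index so the
                # adaptive-weight schedule does not change the scale the
                # plateau scheduler compares across epochs
                vl = _stage_loss(model, stage, xv, val, np.arange(len(val)), 1)
                val_loss = vl.item()
                sched.step(val_loss)
            else:
                sched.step(train_loss)
            rows.append({"epoch": epoch, "train_loss": train_loss,
                         "val_loss": val_loss, "lr": opt.lr})
        history["stages"][stage] = rows
        history["encoder_hash"][stage] = (hash_before, encoder_weight_hash(model))
    model.eval()
    return history


def transfer_weights(src: SurrogateNet, dst: SurrogateNet) -> None:
    """Copy every shared-shape parameter from ``src`` into ``dst``.

    Supports the 1-layer -> 4-layer LSTM transfer: LSTM layers present in
    both models are copied (layer 0 of a deeper stack inherits the trained
    single-layer weights); extra layers keep their fresh initialization.
    """
    src_mods = [m for m in src.modules() if isinstance(m, nn.LSTM)]
    dst_mods = [m for m in dst.modules() if isinstance(m, nn.LSTM)]
    if len(src_mods) != len(dst_mods):
        raise ValueError("architectures do not align")
    for ms, md in zip(src_mods, dst_mods):
        for layer in range(min(ms.n_layers, md.n_layers)):
            md.wx[layer].data = ms.wx[layer].data.copy()
            md.wh[layer].data = ms.wh[layer].data.copy()
            md.b[layer].data = ms.b[layer].data.copy()
    src_other = [p for p in src.parameters()]
    dst_other = [p for p in dst.parameters()]
    src_lstm_ids = {id(p) for m in src_mods for p in m.parameters()}
    dst_lstm_ids = {id(p) for m in dst_mods for p in m.parameters()}
    src_rest = [p for p in src_other if id(p) not in src_lstm_ids]
    dst_rest = [p for p in dst_other if id(p) not in dst_lstm_ids]
    for ps, pd in zip(src_rest, dst_rest):
        if ps.shape == pd.shape:
            pd.data = ps.data.copy()
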