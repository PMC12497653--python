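"""The neural-waveform-demixing (NWD) U-Net and its training loop.

A sequential 1-D U-Net with four contraction blocks (2x temporal decimation,
convolution, batch norm, ReLU) and four expansion blocks (transposed
convolution, batch norm, ReLU, 2x linear interpolation), with skip
connections concatenating contraction outputs at matching temporal
resolutions.  Input traces (900 samples, stimulus onset at sample 100) are
right-padded to 912 so the four decimations divide evenly, and cropped back
on output.  A fixed linear time-ramp channel accompanies the trace so the
translation-equivariant convolutions can reference absolute window position
(the PSC initiation window is defined in absolute time).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..kernels import TRIAL_SAMPLES
from .layers import SGD, BatchNorm1d, Conv1d, Decimate2, ReLU, Sequential, UpsampleLinear2

PAD_TO = 912  # smallest multiple of 16 >= 900


@dataclass
class NWDConfig:
    """Architecture, training and preprocessing settings for NWD.

    ``kinetics`` selects the synaptic-current preset (excitatory currents
    are faster than inhibitory ones) used when generating training data.
    ``initiation_window_ms`` is the admissible PSC onset window after
    stimulus onset; PSCs initiating outside it are confounds the network
    must suppress.  ``t_monotone`` is the sample index after which the
    demixed output is forced to decay monotonically (default: end of the
    initiation window plus three rise-time constants).
    """

    channels: tuple = (8, 16, 24, 32)
    kernel_size: int = 9
    kinetics: str = "inhibitory"
    initiation_window_ms: tuple = (3.0, 12.0)
    t_monotone: int = 424
    batch_size: int = 64
    learning_rate: float = 0.01
    momentum: float = 0.9
    epochs: int = 40
    n_train: int = 50000
    negative_fraction: float = 0.1
    norm_floor: float = 1.0     # pA; per-trace amplitude normalization floor
    seed: int = 0
    # training-data generative settings (see nwd.data)
    psc_count_probs: tuple = (0.35, 0.35, 0.2, 0.1)
    amp_range: tuple = (15.0, 1000.0)   # log-uniform charge range, pA*ms
    gp_sigma_scale: float = 2.0
    gp_lengthscale_ms: float = 1.0
    noise_var_range: tuple = (1.0, 9.0)

    def validate(self):
        if len(self.channels) != 4:
            raise ValueError("the architecture uses exactly four contraction blocks")
        if not 0 <= self.t_monotone < TRIAL_SAMPLES:
            raise ValueError("t_monotone must lie within the trial window")
        if self.kinetics not in ("excitatory", "inhibitory"):
            raise ValueError("kinetics preset must be 'excitatory' or 'inhibitory'")


class UNet1D:
    """Sequential U-Net mapping a (B, 2, 912) input to a (B, 1, 912) output."""

    def __init__(self, cfg: NWDConfig, rng: np.random.Generator | None = None):
        cfg.validate()
        rng = np.random.default_rng(cfg.seed) if rng is None else rng
        c1, c2, c3, c4 = cfg.channels
        k = cfg.kernel_size

        def cblock(c_in, c_out):
            return Sequential(Decimate2(), Conv1d(c_in, c_out, k, rng),
                              BatchNorm1d(c_out), ReLU())

        def eblock(c_in, c_out):
            return Sequential(Conv1d(c_in, c_out, k, rng), BatchNorm1d(c_out),
                              ReLU(), UpsampleLinear2())

        self.down = [cblock(2, c1), cblock(c1, c2), cblock(c2, c3), cblock(c3, c4)]
        self.up = [
            eblock(c4, c4),            # 57 -> 114, concat d3
            eblock(c4 + c3, c3),       # 114 -> 228, concat d2
            eblock(c3 + c2, c2),       # 228 -> 456, concat d1
            eblock(c2 + c1, c1),       # 456 -> 912
        ]
        self.head = Conv1d(c1, 1, 1, rng)
        self._skip_channels = (c1, c2, c3)
        self.cfg = cfg

    # -- parameter plumbing -------------------------------------------------

    def _modules(self):
        return self.down + self.up + [self.head]

    def params(self):
        return [p for m in self._modules() for p in m.params()]

    def grads(self):
        return [g for m in self._modules() for g in m.grads()]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params()))

    # -- forward / backward -------------------------------------------------

    def forward(self, x, train=True):
        d1 = self.down[0].forward(x, train)
        d2 = self.down[1].forward(d1, train)
        d3 = self.down[2].forward(d2, train)
        d4 = self.down[3].forward(d3, train)
        e1 = self.up[0].forward(d4, train)
        e2 = self.up[1].forward(np.concatenate([e1, d3], axis=1), train)
        e3 = self.up[2].forward(np.concatenate([e2, d2], axis=1), train)
        e4 = self.up[3].forward(np.concatenate([e3, d1], axis=1), train)
        return self.head.forward(e4, train)

    def backward(self, dy):
        c1, c2, c3 = self._skip_channels
        c4 = self.cfg.channels[3]
        de4 = self.head.backward(dy)
        dcat3 = self.up[3].backward(de4)
        de3, dd1_a = dcat3[:, :c2], dcat3[:, c2:]
        dcat2 = self.up[2].backward(de3)
        de2, dd2_a = dcat2[:, :c3], dcat2[:, c3:]
        dcat1 = self.up[1].backward(de2)
        de1, dd3_a = dcat1[:, :c4], dcat1[:, c4:]
        dd4 = self.up[0].backward(de1)
        dd3 = self.down[3].backward(dd4) + dd3_a
        dd2 = self.down[2].backward(dd3) + dd2_a
        dd1 = self.down[1].backward(dd2) + dd1_a
        return self.down[0].backward(dd1)

    # -- trace-level interface ---------------------------------------------

    def predict(self, traces: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Forward pass on raw (K, 900) traces, normalization handled here."""
        x, scales = prepare_input(traces, self.cfg)
        out = np.empty((x.shape[0], TRIAL_SAMPLES))
        for lo in range(0, x.shape[0], batch_size):
            y = self.forward(x[lo : lo + batch_size], train=False)
            out[lo : lo + batch_size] = y[:, 0, :TRIAL_SAMPLES]
        return out * scales[:, None]

    # -- persistence ---------------------------------------------------------

    def save(self, path, extra: dict | None = None):
        """Single-file checkpoint: weights + config + any extra metadata."""
        from dataclasses import asdict
        import json

        blobs = {f"param_{i}": p for i, p in enumerate(self.params())}
        for j, m in enumerate(self._modules()):
            for l in getattr(m, "layers", [m]):
                if isinstance(l, BatchNorm1d):
                    blobs[f"rmean_{j}_{id(l) % 10**6}"] = l.running_mean
                    blobs[f"rvar_{j}_{id(l) % 10**6}"] = l.running_var
        cfg_json = json.dumps(asdict(self.cfg) | (extra or {}), default=str)
        np.savez(path, __config__=np.frombuffer(cfg_json.encode(), dtype=np.uint8), **blobs)

    @classmethod
    def load(cls, path):
        import json

        data = np.load(path)
        cfg_dict = json.loads(bytes(data["__config__"]).decode())
        known = {f.name for f in NWDConfig.__dataclass_fields__.values()}
        cfg = NWDConfig(**{k: tuple(v) if isinstance(v, list) else v
                           for k, v in cfg_dict.items() if k in known})
        model = cls(cfg)
        for i, p in enumerate(model.params()):
            p[...] = data[f"param_{i}"]
        bn_keys = sorted(k for k in data.files if k.startswith("rmean_"))
        bns = [l for m in model._modules() for l in getattr(m, "layers", [m])
               if isinstance(l, BatchNorm1d)]
        # running stats restored positionally (module order is deterministic)
        for bn, key in zip(bns, bn_keys):
            bn.running_mean[...] = data[key]
            bn.running_var[...] = data[key.replace("rmean_", "rvar_")]
        return model


# ---------------------------------------------------------------------------
# preprocessing and training


_TIME_RAMP = np.linspace(-1.0, 1.0, PAD_TO)


def prepare_input(traces: np.ndarray, cfg: NWDConfig):
    """Normalize traces and stack the positional channel; returns (x, scales)."""
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    scales = np.maximum(np.abs(traces).max(axis=1), cfg.norm_floor)
    padded = np.zeros((traces.shape[0], PAD_TO))
    padded[:, :TRIAL_SAMPLES] = traces / scales[:, None]
    ramp = np.broadcast_to(_TIME_RAMP, padded.shape)
    return np.stack([padded, ramp], axis=1), scales


def train(
    model: UNet1D,
    inputs: np.ndarray,
    targets: np.ndarray,
    cfg: NWDConfig | None = None,
    rng: np.random.Generator | None = None,
    val_fraction: float = 0.0,
    verbose: bool = False,
):
    """Train by SGD on the mean-squared error to the clean target component.

    Inputs and targets are raw (K, 900) traces; each pair is normalized by
    the input's amplitude scale.  Returns (loss_history, val_history).
    Raises on NaN loss (divergence).
    """
    cfg = model.cfg if cfg is None else cfg
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    if inputs.shape[0] == 0:
        raise ValueError("empty training set")
    x, scales = prepare_input(inputs, cfg)
    t = np.zeros((targets.shape[0], PAD_TO))
    t[:, :TRIAL_SAMPLES] = targets / scales[:, None]

    n_val = int(val_fraction * x.shape[0])
    if n_val:
        x_val, t_val = x[-n_val:], t[-n_val:]
        x, t = x[:-n_val], t[:-n_val]
    opt = SGD(model.params(), model.grads(), lr=cfg.learning_rate, momentum=cfg.momentum)
    n = x.shape[0]
    history, val_history = [], []
    for epoch in range(cfg.epochs):
        # step decay: drop the learning rate for the final polishing epochs
        frac = epoch / max(cfg.epochs - 1, 1)
        opt.lr = cfg.learning_rate * (0.3 if frac >= 0.6 else 1.0) * (
            0.3 if frac >= 0.85 else 1.0)
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for lo in range(0, n, cfg.batch_size):
            sel = order[lo : lo + cfg.batch_size]
            if sel.size < 2:
                continue  # batch norm needs more than one example
            out = model.forward(x[sel], train=True)
            diff = out[:, 0] - t[sel]
            loss = float(np.mean(diff**2))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged (NaN/inf loss) at epoch {epoch}"
                )
            dy = (2.0 / diff.size) * diff[:, None, :]
            model.backward(dy)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        history.append(epoch_loss / max(n_batches, 1))
        if n_val:
            pred = _forward_eval(model, x_val)
            val_history.append(float(np.mean((pred[:, 0] - t_val) ** 2)))
        if verbose:
            msg = f"[nwd] epoch {epoch + 1}/{cfg.epochs} loss={history[-1]:.5f}"
            if n_val:
                msg += f" val={val_history[-1]:.5f}"
            print(msg)
    return history, val_history


def _forward_eval(model, x, batch_size=256):
    outs = [model.forward(x[lo : lo + batch_size], train=False)
            for lo in range(0, x.shape[0], batch_size)]
    return np.concatenate(outs, axis=0)
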