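"""3D U-Net-style encoder-decoder for volumetric 4-class annotation.

The network maps a 40^3 single-channel density block to per-voxel softmax
probabilities over (helix, sheet, nucleotide, unassigned) for the central
20^3 cube. Architecture: ``levels`` encoder blocks of two same-padded 3^3
convolutions + ReLU followed by 2^3 max-pooling, a two-convolution
bottleneck, and a mirrored decoder using nearest-neighbour upsampling and
skip concatenations; a final 1^3 convolution produces 4 channels, center
cropped to the output cube before the softmax.

Everything — forward pass, backpropagation, Adam — is implemented on NumPy
arrays (channels-last, float32) with im2col/matmul convolutions, so training
and inference are fully deterministic for a fixed seed on one device. The
loss is weighted cross-entropy: voxel weights come from the training mask
(0 on excluded voxels, ~16:1 in favour of structural classes elsewhere) and
the loss is normalized by the total weight.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .training_data import (INPUT_SIZE, OUTPUT_SIZE, Segment, TrainingSample,
                            center_sample, sample_training_example)

__all__ = [
    "NetworkConfig",
    "Network",
    "build_network",
    "loss",
    "train",
    "save_checkpoint",
    "load_network",
    "voxel_accuracy",
]


@dataclass
class NetworkConfig:
    input_size: int = INPUT_SIZE
    output_size: int = OUTPUT_SIZE
    n_classes: int = 4
    levels: int = 3
    base_channels: int = 32
    learning_rate: float = 1e-4
    steps: int = 40000
    batch_segments: int = 100
    positive_weight: float = 16.0
    eval_every: int = 100
    lr_decay: str = "cosine"  # "cosine" (to 10% of base) or "none"
    warmup_steps: int = 30    # linear learning-rate ramp at the start
    grad_clip: float = 1.0    # global gradient-norm clip; 0 disables
    relu_slope: float = 0.01  # leaky rectifier slope; keeps units recoverable

    def __post_init__(self) -> None:
        if self.input_size % (2 ** self.levels) != 0:
            raise ValueError(
                f"input size {self.input_size} not divisible by 2^levels={2**self.levels}")
        if (self.input_size - self.output_size) % 2 != 0:
            raise ValueError("input/output size difference must be even")


# ---------------------------------------------------------------------------
# primitive layers (channels-last volumes, float32)

_OFFSETS = [(dz, dy, dx) for dz in range(3) for dy in range(3) for dx in range(3)]


def _conv3_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray
                   ) -> Tuple[np.ndarray, np.ndarray]:
    """Same-padded 3^3 convolution via 27 per-offset GEMMs.

    ``W`` has shape (27*cin, cout), kernel-offset-major / channel-minor.
    Returns (output, padded input) — the padded input is reused by backward.
    """
    d, h, w, cin = x.shape
    cout = W.shape[1]
    xp = np.pad(x, ((1, 1), (1, 1), (1, 1), (0, 0)))
    Wk = W.reshape(27, cin, cout)
    y = np.empty((d * h * w, cout), dtype=np.float32)
    y[:] = b
    for k, (oz, oy, ox) in enumerate(_OFFSETS):
        sl = xp[oz:oz + d, oy:oy + h, ox:ox + w, :].reshape(-1, cin)
        y += sl @ Wk[k]
    return y.reshape(d, h, w, cout), xp


def _conv3_backward(dy: np.ndarray, xp: np.ndarray, W: np.ndarray, cin: int
                    ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of a same-padded 3^3 convolution: (dx, dW, db)."""
    d, h, w, cout = dy.shape
    dy_flat = dy.reshape(-1, cout)
    Wk = W.reshape(27, cin, cout)
    dW = np.empty_like(Wk)
    db = dy_flat.sum(axis=0)
    dxp = np.zeros_like(xp)
    for k, (oz, oy, ox) in enumerate(_OFFSETS):
        sl = xp[oz:oz + d, oy:oy + h, ox:ox + w, :].reshape(-1, cin)
        dW[k] = sl.T @ dy_flat
        dxp[oz:oz + d, oy:oy + h, ox:ox + w, :] += (dy_flat @ Wk[k].T).reshape(d, h, w, cin)
    dx = dxp[1:-1, 1:-1, 1:-1, :]
    return dx, dW.reshape(27 * cin, cout), db


def _pool_forward(x: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """2^3 max pooling; returns (pooled, argmax over the 8 window positions)."""
    d, h, w, c = x.shape
    r = x.reshape(d // 2, 2, h // 2, 2, w // 2, 2, c)
    r = r.transpose(0, 2, 4, 6, 1, 3, 5).reshape(d // 2, h // 2, w // 2, c, 8)
    idx = r.argmax(axis=-1)
    y = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
    return y, idx


def _pool_backward(dy: np.ndarray, idx: np.ndarray, in_shape: tuple) -> np.ndarray:
    d, h, w, c = in_shape
    scatter = np.zeros(dy.shape + (8,), dtype=dy.dtype)
    np.put_along_axis(scatter, idx[..., None], dy[..., None], axis=-1)
    scatter = scatter.reshape(d // 2, h // 2, w // 2, c, 2, 2, 2)
    return scatter.transpose(0, 4, 1, 5, 2, 6, 3).reshape(d, h, w, c)


def _upsample(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=0).repeat(2, axis=1).repeat(2, axis=2)


def _upsample_backward(dy: np.ndarray) -> np.ndarray:
    d, h, w, c = dy.shape
    return dy.reshape(d // 2, 2, h // 2, 2, w // 2, 2, c).sum(axis=(1, 3, 5))


def _relu(x: np.ndarray, slope: float = 0.01) -> np.ndarray:
    return np.where(x > 0, x, slope * x)


# ---------------------------------------------------------------------------
# network

class Network:
    """U-Net with parameters in a flat name->array dict (all float32)."""

    def __init__(self, cfg: NetworkConfig, params: Dict[str, np.ndarray]):
        self.cfg = cfg
        self.params = params

    # -- construction -------------------------------------------------------

    @staticmethod
    def _layer_plan(cfg: NetworkConfig) -> List[Tuple[str, int, int]]:
        """(name, cin, cout) for every 3^3 convolution, in forward order."""
        plan = []
        cin = 1
        for l in range(cfg.levels):
            c = cfg.base_channels * (2 ** l)
            plan.append((f"enc{l}_conv1", cin, c))
            plan.append((f"enc{l}_conv2", c, c))
            cin = c
        c = cfg.base_channels * (2 ** cfg.levels)
        plan.append(("bott_conv1", cin, c))
        plan.append(("bott_conv2", c, c))
        cin = c
        for l in reversed(range(cfg.levels)):
            c = cfg.base_channels * (2 ** l)
            plan.append((f"dec{l}_conv1", cin + c, c))
            plan.append((f"dec{l}_conv2", c, c))
            cin = c
        return plan

    def parameter_count(self) -> int:
        return sum(p.size for p in self.params.values())

    # -- forward ------------------------------------------------------------

    def _crop_schedule(self) -> List[int]:
        """Concat-region size per decoder level.

        Only the central ``output_size`` cube is ever read from the decoder,
        so each decoder level needs just that region plus a 2-voxel halo per
        convolution. The computed values are the sizes of the (centered)
        concat regions actually convolved; outputs are exact on the central
        ``output_size`` cube and identical to full-volume computation there.
        """
        cfg = self.cfg
        sizes = [cfg.input_size // (2 ** l) for l in range(cfg.levels + 1)]
        concat = []
        req = cfg.output_size
        for l in range(cfg.levels):
            c = min(sizes[l], req + 4)
            if (sizes[l] - c) % 2:
                c = min(sizes[l], c + 1)
            concat.append(c)
            req = c // 2
        return concat

    @staticmethod
    def _center(size: int, crop: int) -> slice:
        start = (size - crop) // 2
        return slice(start, start + crop)

    def _forward(self, x: np.ndarray, want_cache: bool
                 ) -> Tuple[np.ndarray, Optional[dict]]:
        cfg = self.cfg
        P = self.params
        cache: dict = {"acts": {}} if want_cache else None
        h = x[..., None].astype(np.float32) if x.ndim == 3 else x.astype(np.float32)
        skips = []
        for l in range(cfg.levels):
            for k in (1, 2):
                name = f"enc{l}_conv{k}"
                y, xp = _conv3_forward(h, P[name + "_W"], P[name + "_b"])
                if want_cache:
                    cache["acts"][name] = (xp, y)
                h = _relu(y, cfg.relu_slope)
            skips.append(h)
            h, idx = _pool_forward(h)
            if want_cache:
                cache["acts"][f"pool{l}"] = (idx, skips[-1].shape)
        for name in ("bott_conv1", "bott_conv2"):
            y, xp = _conv3_forward(h, P[name + "_W"], P[name + "_b"])
            if want_cache:
                cache["acts"][name] = (xp, y)
            h = _relu(y, cfg.relu_slope)
        concat_sizes = self._crop_schedule()
        for l in reversed(range(cfg.levels)):
            c = concat_sizes[l]
            # pre-upsample crop (parity-adjusted), then trim to the concat size
            cc = c // 2
            if (h.shape[0] - cc) % 2:
                cc = min(h.shape[0], cc + 1)
            pre = self._center(h.shape[0], cc)
            up = _upsample(h[pre, pre, pre, :])
            up_full_shape = up.shape
            post = self._center(up.shape[0], c)
            up = up[post, post, post, :]
            skip = skips[l]
            ssl = self._center(skip.shape[0], c)
            hcat = np.concatenate([up, skip[ssl, ssl, ssl, :]], axis=-1)
            if want_cache:
                cache["acts"][f"crops{l}"] = (h.shape, pre, up_full_shape, post,
                                              skip.shape, ssl,
                                              hcat.shape[-1] - skip.shape[-1])
            h = hcat
            for k in (1, 2):
                name = f"dec{l}_conv{k}"
                y, xp = _conv3_forward(h, P[name + "_W"], P[name + "_b"])
                if want_cache:
                    cache["acts"][name] = (xp, y)
                h = _relu(y, cfg.relu_slope)
        fsl = self._center(h.shape[0], cfg.output_size)
        h_fin = h[fsl, fsl, fsl, :]
        logits = h_fin @ P["final_W"] + P["final_b"]
        if want_cache:
            cache["final_in"] = h_fin
            cache["final_crop"] = (h.shape, fsl)
        return logits, cache

    def forward_sample(self, x: np.ndarray) -> np.ndarray:
        """Probabilities (out^3, 4) for one input block (in^3)."""
        if x.shape != (self.cfg.input_size,) * 3:
            raise ValueError(f"expected input shape {(self.cfg.input_size,)*3}, got {x.shape}")
        logits, _ = self._forward(x, want_cache=False)
        return _softmax(logits)

    def forward(self, batch: np.ndarray) -> np.ndarray:
        """Probabilities for a batch (N, in^3) -> (N, out^3, 4)."""
        batch = np.asarray(batch)
        if batch.ndim == 3:
            return self.forward_sample(batch)[None]
        return np.stack([self.forward_sample(b) for b in batch])

    # -- backward -----------------------------------------------------------

    def loss_and_grad(self, sample: TrainingSample
                      ) -> Tuple[float, Dict[str, np.ndarray]]:
        cfg = self.cfg
        P = self.params
        logits, cache = self._forward(sample.input, want_cache=True)
        probs = _softmax(logits)
        value, dlogits = _weighted_ce(probs, sample.target, sample.weight)

        grads = {k: np.zeros_like(v) for k, v in P.items()}
        h_final = cache["final_in"]
        dl_flat = dlogits.reshape(-1, cfg.n_classes)
        grads["final_W"] += h_final.reshape(-1, h_final.shape[-1]).T @ dl_flat
        grads["final_b"] += dl_flat.sum(axis=0)
        pre_shape, fsl = cache["final_crop"]
        dh = np.zeros(pre_shape, dtype=np.float32)
        dh[fsl, fsl, fsl, :] = dlogits @ P["final_W"].T

        plan = {name: (cin, cout) for name, cin, cout in self._layer_plan(cfg)}

        def back_conv(name: str, dh: np.ndarray) -> np.ndarray:
            xp, y = cache["acts"][name]
            dh = dh * np.where(y > 0, np.float32(1.0), np.float32(cfg.relu_slope))
            cin, _ = plan[name]
            dx, dW, db = _conv3_backward(dh, xp, P[name + "_W"], cin)
            grads[name + "_W"] += dW
            grads[name + "_b"] += db
            return dx

        skip_grads: Dict[int, np.ndarray] = {}
        for l in range(cfg.levels):
            dh = back_conv(f"dec{l}_conv2", dh)
            dh = back_conv(f"dec{l}_conv1", dh)
            h_shape, pre, up_shape, post, skip_shape, ssl, n_up = cache["acts"][f"crops{l}"]
            dup, dsk = dh[..., :n_up], dh[..., n_up:]
            dskip = np.zeros(skip_shape, dtype=np.float32)
            dskip[ssl, ssl, ssl, :] = dsk
            skip_grads[l] = dskip
            dup_full = np.zeros(up_shape, dtype=np.float32)
            dup_full[post, post, post, :] = dup
            dpre = _upsample_backward(dup_full)
            dh = np.zeros(h_shape, dtype=np.float32)
            dh[pre, pre, pre, :] = dpre
        dh = back_conv("bott_conv2", dh)
        dh = back_conv("bott_conv1", dh)
        for l in reversed(range(cfg.levels)):
            idx, in_shape = cache["acts"][f"pool{l}"]
            dh = _pool_backward(dh, idx, in_shape)
            dh = dh + skip_grads[l]
            dh = back_conv(f"enc{l}_conv2", dh)
            dh = back_conv(f"enc{l}_conv1", dh)
        return value, grads


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _weighted_ce(probs: np.ndarray, target: np.ndarray, weight: np.ndarray
                 ) -> Tuple[float, np.ndarray]:
    """Weighted cross-entropy and its gradient w.r.t. the logits."""
    wsum = float(weight.sum())
    if wsum == 0.0:
        return 0.0, np.zeros_like(probs)
    p_true = (probs * target).sum(axis=-1)
    p_true = np.maximum(p_true, 1e-12)
    value = float((weight * -np.log(p_true)).sum() / wsum)
    dlogits = weight[..., None] * (probs - target) / wsum
    return value, dlogits.astype(np.float32)


def loss(pred: np.ndarray, target: np.ndarray, weights: np.ndarray) -> float:
    """Weight-normalized cross-entropy of predicted probabilities."""
    value, _ = _weighted_ce(np.asarray(pred, dtype=np.float64), target, weights)
    return value


def build_network(cfg: NetworkConfig, rng: np.random.Generator) -> Network:
    """He-initialized network; identical parameters for identical seeds."""
    params: Dict[str, np.ndarray] = {}
    for name, cin, cout in Network._layer_plan(cfg):
        fan_in = 27 * cin
        params[name + "_W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                         size=(fan_in, cout)).astype(np.float32)
        params[name + "_b"] = np.zeros(cout, dtype=np.float32)
    cfin = cfg.base_channels
    params["final_W"] = rng.normal(0.0, np.sqrt(2.0 / cfin),
                                   size=(cfin, cfg.n_classes)).astype(np.float32)
    params["final_b"] = np.zeros(cfg.n_classes, dtype=np.float32)
    return Network(cfg, params)


# ---------------------------------------------------------------------------
# optimizer and training loop

class _Adam:
    def __init__(self, params: Dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: Dict[str, np.ndarray], grads: Dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for k, p in params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            p -= (self.lr * (self.m[k] / bc1)
                  / (np.sqrt(self.v[k] / bc2) + self.eps)).astype(p.dtype)


def voxel_accuracy(net: Network, segments: Sequence[Segment]) -> float:
    """Fraction of correctly classified non-excluded voxels on center crops."""
    correct = total = 0
    for seg in segments:
        s = center_sample(seg)
        probs = net.forward_sample(s.input)
        pred = probs.argmax(axis=-1)
        truth = s.target.argmax(axis=-1)
        keep = s.weight > 0
        correct += int((pred[keep] == truth[keep]).sum())
        total += int(keep.sum())
    return correct / total if total else float("nan")


def train(net: Network, train_segs: Sequence[Segment], eval_segs: Sequence[Segment],
          cfg: Optional[NetworkConfig] = None, rng: Optional[np.random.Generator] = None,
          checkpoint_path: Optional[str] = None) -> Dict[str, list]:
    """SGD loop: per step, one augmented sample from each of ``batch_segments``
    drawn segments, one Adam update. Returns the training history."""
    cfg = cfg or net.cfg
    rng = rng or np.random.default_rng()
    if not train_segs:
        raise ValueError("training set is empty")
    opt = _Adam(net.params, cfg.learning_rate)
    history: Dict[str, list] = {"step": [], "train_loss": [],
                                "eval_step": [], "eval_loss": [], "eval_accuracy": []}
    n = len(train_segs)
    for step in range(cfg.steps):
        lr = cfg.learning_rate
        if cfg.lr_decay == "cosine":
            frac = step / max(1, cfg.steps - 1)
            lr *= 0.1 + 0.9 * 0.5 * (1 + np.cos(np.pi * frac))
        if cfg.warmup_steps > 0 and step < cfg.warmup_steps:
            lr *= (step + 1) / cfg.warmup_steps
        opt.lr = lr
        idxs = rng.choice(n, size=cfg.batch_segments, replace=n < cfg.batch_segments)
        total_loss = 0.0
        grads_sum: Dict[str, np.ndarray] = {k: np.zeros_like(v)
                                            for k, v in net.params.items()}
        for i in idxs:
            sample = sample_training_example(train_segs[int(i)], rng)
            value, grads = net.loss_and_grad(sample)
            total_loss += value
            for k in grads_sum:
                grads_sum[k] += grads[k]
        inv = 1.0 / len(idxs)
        for k in grads_sum:
            grads_sum[k] *= inv
        if cfg.grad_clip > 0:
            gnorm = float(np.sqrt(sum(float((g ** 2).sum())
                                      for g in grads_sum.values())))
            if gnorm > cfg.grad_clip:
                scale = cfg.grad_clip / gnorm
                for k in grads_sum:
                    grads_sum[k] *= scale
        opt.step(net.params, grads_sum)
        history["step"].append(step)
        history["train_loss"].append(total_loss * inv)
        if eval_segs and (step + 1) % cfg.eval_every == 0:
            ev_loss = 0.0
            for seg in eval_segs:
                s = center_sample(seg)
                probs = net.forward_sample(s.input)
                ev_loss += loss(probs, s.target, s.weight)
            history["eval_step"].append(step)
            history["eval_loss"].append(ev_loss / len(eval_segs))
            history["eval_accuracy"].append(voxel_accuracy(net, eval_segs))
            if checkpoint_path is not None:
                save_checkpoint(net, checkpoint_path)
    if checkpoint_path is not None:
        save_checkpoint(net, checkpoint_path)
    return history


# ---------------------------------------------------------------------------
# checkpoints

_CHECKPOINT_VERSION = 1


def save_checkpoint(net: Network, path: str) -> None:
    """Single-file archive: parameter tensors + config (versioned)."""
    meta = json.dumps({"version": _CHECKPOINT_VERSION, "config": asdict(net.cfg)})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **net.params)


def load_network(path: str) -> Network:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("version") != _CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta.get('version')}")
        cfg = NetworkConfig(**meta["config"])
        params = {k: data[k] for k in data.files if k != "__meta__"}
    return Network(cfg, params)
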