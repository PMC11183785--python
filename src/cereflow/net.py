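"""Dense-block 3D U-Net for vessel segmentation, in pure numpy.

The segmentation model is a symmetric encoder-decoder 3D U-Net whose
convolution stages are dense blocks: each dense convolution unit applies
batch normalization, ReLU, a 3x3x3 convolution producing ``growth_rate``
feature maps, and dropout, and its input is the concatenation of all prior
feature maps of the block.  2x2x2 max-pooling downsamples between encoder
levels; 2x2x2 transposed convolutions upsample in the decoder, with skip
concatenation from the matching encoder level.  A 1x1x1 convolution and a
softmax produce per-voxel class probabilities; masks are the per-voxel
argmax (exact ties assigned to background).

Training minimizes a composite loss — softmax cross-entropy plus Dice loss
on the foreground channel — with Adam at batch size 1.  No patching and no
data augmentation are used; inputs are center-cropped or zero-padded to the
fixed network input dimensions.

Everything (initialization, dropout, shuffling) is seeded, so a training
run is bit-reproducible.  Convolutions are evaluated as im2col GEMMs with
analytic gradients; forward/backward of a miniature configuration on a
64x64x32 volume takes well under a second per step on one CPU, which is the
scale the phantom experiments use.
"""

from __future__ import annotations

import copy
import dataclasses

import numpy as np

from .io import SegmentationMask
from .pcmra import PcmraVolume

__all__ = [
    "NetworkConfig",
    "TrainConfig",
    "DenseUNet",
    "center_crop_or_pad",
    "restore_dims",
    "build_dense_unet",
    "composite_loss",
    "train_model",
    "predict_mask",
]

_DT = np.float32
_BN_EPS = 1e-5
_DICE_EPS = 1e-5


@dataclasses.dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    ``input_dims`` is (z, y, x) and must be divisible by ``2**(levels-1)``
    so the pooling pyramid closes.  Defaults follow the clinical recipe
    (224x192x64 input, dropout 0.1, two classes); depth/growth/stem are
    configuration choices and the test-scale experiments use much smaller
    values.
    """

    input_dims: tuple[int, int, int] = (64, 192, 224)
    levels: int = 4
    convs_per_dense_block: int = 2
    growth_rate: int = 12
    stem_filters: int = 16
    dropout: float = 0.1
    n_classes: int = 2

    def __post_init__(self) -> None:
        if self.levels < 1 or self.convs_per_dense_block < 1:
            raise ValueError("levels and convs_per_dense_block must be >= 1")
        if self.growth_rate < 1 or self.stem_filters < 1:
            raise ValueError("growth_rate and stem_filters must be >= 1")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        div = 2 ** (self.levels - 1)
        if any(d % div != 0 or d < div for d in self.input_dims):
            raise ValueError(
                f"input_dims {self.input_dims} must be divisible by {div} "
                f"(levels={self.levels})"
            )


@dataclasses.dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 1
    epochs: int = 300
    ce_w: float = 1.0
    dice_w: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size != 1:
            raise ValueError("only batch_size=1 is supported")


# ---------------------------------------------------------------------------
# crop / pad


def center_crop_or_pad(volume: np.ndarray, target_dims) -> np.ndarray:
    """Center-crop or zero-pad a 3D grid to *target_dims*, per axis.

    Cropping removes equal margins, with the extra voxel taken from the
    high-index side on odd differences; padding adds zeros symmetrically
    with the extra voxel on the high-index side.
    """
    out = volume
    for ax, target in enumerate(target_dims):
        size = out.shape[ax]
        if size > target:
            lo = (size - target) // 2
            out = np.take(out, np.arange(lo, lo + target), axis=ax)
        elif size < target:
            pad_lo = (target - size) // 2
            pad_hi = target - size - pad_lo
            pads = [(0, 0)] * out.ndim
            pads[ax] = (pad_lo, pad_hi)
            out = np.pad(out, pads)
    return out


def restore_dims(volume: np.ndarray, original_dims) -> np.ndarray:
    """Invert :func:`center_crop_or_pad`: map a network-sized grid back to
    the original dimensions (cropped-away regions return as zeros)."""
    return center_crop_or_pad(volume, original_dims)


# ---------------------------------------------------------------------------
# layers


def _im2col(x: np.ndarray) -> np.ndarray:
    """(C, D, H, W) -> (27*C, D*H*W) patch matrix for a 3x3x3 same conv.

    Row block ``o`` (offset-major) holds the input shifted by the o-th
    kernel offset; built from plain slice copies, which is far cheaper
    than a strided window gather.
    """
    c, d, h, w = x.shape
    n = d * h * w
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
    cols = np.empty((27 * c, n), dtype=x.dtype)
    o = 0
    for dz in range(3):
        for dy in range(3):
            for dx in range(3):
                cols[o * c:(o + 1) * c] = xp[
                    :, dz:dz + d, dy:dy + h, dx:dx + w
                ].reshape(c, n)
                o += 1
    return cols


class Conv3:
    """3x3x3 same-padding convolution as an im2col GEMM.

    Weights are stored (cout, 27*cin), column index = offset*cin + cin_idx,
    matching the offset-major patch matrix layout.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        fan_in = cin * 27
        self.W = (rng.standard_normal((cout, fan_in)) * np.sqrt(2.0 / fan_in)).astype(_DT)
        self.b = np.zeros(cout, dtype=_DT)
        self.cin, self.cout = cin, cout

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        spatial = x.shape[1:]
        cols = _im2col(x)
        out = self.W @ cols + self.b[:, None]
        return out.reshape(self.cout, *spatial)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        spatial = dout.shape[1:]
        dflat = dout.reshape(self.cout, -1)
        cols = _im2col(self._x)
        self.dW = (dflat @ cols.T).astype(_DT)
        self.db = dflat.sum(axis=1).astype(_DT)
        # grad wrt input = correlation of dout with the spatially flipped,
        # channel-transposed kernel
        Wk = self.W.reshape(self.cout, 3, 3, 3, self.cin)
        Wflip = Wk[:, ::-1, ::-1, ::-1, :]
        W2 = np.ascontiguousarray(Wflip.transpose(4, 1, 2, 3, 0)).reshape(
            self.cin, 27 * self.cout
        )
        dcols = _im2col(dout)
        dx = (W2 @ dcols).reshape(self.cin, *spatial)
        self._x = None
        return dx

    def params(self):
        return [("W", self), ("b", self)]


class Conv1:
    """1x1x1 convolution (channel mixing)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.W = (rng.standard_normal((cin, cout)) * np.sqrt(2.0 / cin)).astype(_DT)
        self.b = np.zeros(cout, dtype=_DT)
        self.cin, self.cout = cin, cout

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        spatial = x.shape[1:]
        out = (x.reshape(self.cin, -1).T @ self.W + self.b).T
        return out.reshape(self.cout, *spatial)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        spatial = dout.shape[1:]
        dflat = dout.reshape(self.cout, -1).T
        xflat = self._x.reshape(self.cin, -1).T
        self.dW = (xflat.T @ dflat).astype(_DT)
        self.db = dflat.sum(axis=0).astype(_DT)
        dx = (dflat @ self.W.T).T.reshape(self.cin, *spatial)
        self._x = None
        return np.ascontiguousarray(dx)

    def params(self):
        return [("W", self), ("b", self)]


class BatchNorm:
    def __init__(self, c: int):
        self.gamma = np.ones(c, dtype=_DT)
        self.beta = np.zeros(c, dtype=_DT)
        self.run_mean = np.zeros(c, dtype=np.float64)
        self.run_var = np.ones(c, dtype=np.float64)
        self.momentum = 0.1

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mu = x.mean(axis=(1, 2, 3))
            var = x.var(axis=(1, 2, 3))
            self.run_mean = (1 - self.momentum) * self.run_mean + self.momentum * mu
            self.run_var = (1 - self.momentum) * self.run_var + self.momentum * var
        else:
            mu, var = self.run_mean, self.run_var
        ivar = 1.0 / np.sqrt(var + _BN_EPS)
        xhat = (x - mu[:, None, None, None]) * ivar[:, None, None, None]
        if training:
            self._xhat, self._ivar = xhat.astype(_DT), ivar
        return (self.gamma[:, None, None, None] * xhat + self.beta[:, None, None, None]).astype(_DT)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, ivar = self._xhat, self._ivar
        n = dout[0].size
        self.dgamma = (dout * xhat).sum(axis=(1, 2, 3)).astype(_DT)
        self.dbeta = dout.sum(axis=(1, 2, 3)).astype(_DT)
        dxhat = dout * self.gamma[:, None, None, None]
        s1 = dxhat.sum(axis=(1, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(1, 2, 3), keepdims=True)
        dx = (ivar[:, None, None, None] / n) * (n * dxhat - s1 - xhat * s2)
        self._xhat = None
        return dx.astype(_DT)

    def params(self):
        return [("gamma", self), ("beta", self)]


class MaxPool2:
    def forward(self, x: np.ndarray) -> np.ndarray:
        c, d, h, w = x.shape
        blocks = x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
        flat = np.ascontiguousarray(blocks.transpose(0, 1, 3, 5, 2, 4, 6)).reshape(
            c, d // 2, h // 2, w // 2, 8
        )
        self._arg = flat.argmax(axis=-1)
        self._in_shape = x.shape
        return flat.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        c, d2, h2, w2 = dout.shape
        flat = np.zeros((c, d2, h2, w2, 8), dtype=_DT)
        np.put_along_axis(flat, self._arg[..., None], dout[..., None], axis=-1)
        blocks = flat.reshape(c, d2, h2, w2, 2, 2, 2).transpose(0, 1, 4, 2, 5, 3, 6)
        self._arg = None
        return np.ascontiguousarray(blocks).reshape(self._in_shape)


class ConvTranspose2:
    """2x2x2 stride-2 transposed convolution (learned upsampling)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        fan_in = cin
        self.W = (rng.standard_normal((cin, cout, 2, 2, 2)) * np.sqrt(2.0 / fan_in)).astype(_DT)
        self.b = np.zeros(cout, dtype=_DT)
        self.cin, self.cout = cin, cout

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        d, h, w = x.shape[1:]
        t = np.tensordot(x, self.W, axes=(0, 0))  # (d, h, w, cout, 2, 2, 2)
        out = np.ascontiguousarray(t.transpose(3, 0, 4, 1, 5, 2, 6)).reshape(
            self.cout, 2 * d, 2 * h, 2 * w
        )
        return out + self.b[:, None, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d2, h2, w2 = dout.shape[1:]
        d, h, w = d2 // 2, h2 // 2, w2 // 2
        blocks = np.ascontiguousarray(
            dout.reshape(self.cout, d, 2, h, 2, w, 2).transpose(1, 3, 5, 0, 2, 4, 6)
        )  # (d, h, w, cout, 2, 2, 2)
        self.dW = np.tensordot(self._x, blocks, axes=([1, 2, 3], [0, 1, 2])).astype(_DT)
        self.db = dout.sum(axis=(1, 2, 3)).astype(_DT)
        dx = np.tensordot(blocks, self.W, axes=([3, 4, 5, 6], [1, 2, 3, 4]))
        self._x = None
        return np.ascontiguousarray(dx.transpose(3, 0, 1, 2)).astype(_DT)

    def params(self):
        return [("W", self), ("b", self)]


class DenseUnit:
    """BN -> ReLU -> 3x3x3 conv (growth_rate maps) -> dropout."""

    def __init__(self, cin: int, growth: int, dropout: float, rng: np.random.Generator):
        self.bn = BatchNorm(cin)
        self.conv = Conv3(cin, growth, rng)
        self.p = dropout

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        h = self.bn.forward(x, training)
        self._relu_mask = h > 0
        h = h * self._relu_mask
        h = self.conv.forward(h)
        if training and self.p > 0:
            self._drop = (rng.random(h.shape) >= self.p).astype(_DT) / (1.0 - self.p)
            h = h * self._drop
        else:
            self._drop = None
        return h

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._drop is not None:
            dout = dout * self._drop
            self._drop = None
        dh = self.conv.backward(dout)
        dh = dh * self._relu_mask
        self._relu_mask = None
        return self.bn.backward(dh)

    def params(self):
        return self.bn.params() + self.conv.params()


class DenseBlock:
    """Dense connectivity: every unit sees the concatenation of all prior
    feature maps of the block; the block output is the full concatenation."""

    def __init__(self, cin: int, n_units: int, growth: int, dropout: float,
                 rng: np.random.Generator):
        self.units = []
        ch = cin
        for _ in range(n_units):
            self.units.append(DenseUnit(ch, growth, dropout, rng))
            ch += growth
        self.cin, self.cout = cin, ch

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        feats = [x]
        for unit in self.units:
            inp = np.concatenate(feats, axis=0) if len(feats) > 1 else feats[0]
            feats.append(unit.forward(inp, training, rng))
        self._channels = [f.shape[0] for f in feats]
        return np.concatenate(feats, axis=0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        splits = np.cumsum(self._channels)[:-1]
        g_feats = list(np.split(dout, splits, axis=0))
        g_feats = [np.ascontiguousarray(g) for g in g_feats]
        for i in range(len(self.units) - 1, -1, -1):
            dinp = self.units[i].backward(g_feats[i + 1])
            in_splits = np.cumsum(self._channels[: i + 1])[:-1]
            parts = np.split(dinp, in_splits, axis=0) if i > 0 else [dinp]
            for j, part in enumerate(parts):
                g_feats[j] = g_feats[j] + part
        return g_feats[0]

    def params(self):
        out = []
        for u in self.units:
            out.extend(u.params())
        return out


# ---------------------------------------------------------------------------
# the model


class DenseUNet:
    """Symmetric dense-block 3D U-Net; see module docstring."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        self.cfg = cfg
        self.seed = seed
        rng = np.random.default_rng(seed)
        L = cfg.levels
        self.stem = Conv3(1, cfg.stem_filters, rng)
        self.enc_blocks, self.pools, skip_ch = [], [], []
        ch = cfg.stem_filters
        for _ in range(L - 1):
            blk = DenseBlock(ch, cfg.convs_per_dense_block, cfg.growth_rate,
                             cfg.dropout, rng)
            self.enc_blocks.append(blk)
            skip_ch.append(blk.cout)
            self.pools.append(MaxPool2())
            ch = blk.cout
        self.bottleneck = DenseBlock(ch, cfg.convs_per_dense_block,
                                     cfg.growth_rate, cfg.dropout, rng)
        ch = self.bottleneck.cout
        self.upconvs, self.dec_blocks = [], []
        for lvl in range(L - 2, -1, -1):
            up = ConvTranspose2(ch, max(ch // 2, 1), rng)
            self.upconvs.append(up)
            ch = up.cout + skip_ch[lvl]
            blk = DenseBlock(ch, cfg.convs_per_dense_block, cfg.growth_rate,
                             cfg.dropout, rng)
            self.dec_blocks.append(blk)
            ch = blk.cout
        self.head = Conv1(ch, cfg.n_classes, rng)
        self._skip_ch = skip_ch
        self._drop_rng = np.random.default_rng(seed + 1)

    # -- plumbing ----------------------------------------------------------

    def _layers(self):
        yield self.stem
        for b in self.enc_blocks:
            yield b
        yield self.bottleneck
        for u in self.upconvs:
            yield u
        for b in self.dec_blocks:
            yield b
        yield self.head

    def parameters(self):
        """List of (owner, attribute-name) pairs for every trainable array."""
        out = []
        for layer in self._layers():
            if hasattr(layer, "params"):
                out.extend((owner, name) for name, owner in layer.params())
        return out

    @property
    def n_parameters(self) -> int:
        return int(sum(getattr(o, n).size for o, n in self.parameters()))

    def describe(self) -> dict:
        """Architecture descriptor: per-stage channel counts and shapes."""
        dims = np.asarray(self.cfg.input_dims)
        stages = [{"stage": "stem", "out_channels": self.stem.cout,
                   "dims": dims.tolist()}]
        for i, blk in enumerate(self.enc_blocks):
            stages.append({"stage": f"encoder{i}", "out_channels": blk.cout,
                           "dims": dims.tolist()})
            dims = dims // 2
            stages.append({"stage": f"pool{i}", "out_channels": blk.cout,
                           "dims": dims.tolist()})
        stages.append({"stage": "bottleneck",
                       "out_channels": self.bottleneck.cout, "dims": dims.tolist()})
        for i, (up, blk) in enumerate(zip(self.upconvs, self.dec_blocks)):
            dims = dims * 2
            stages.append({"stage": f"upconv{i}", "out_channels": up.cout,
                           "dims": dims.tolist()})
            stages.append({"stage": f"decoder{i}", "out_channels": blk.cout,
                           "dims": dims.tolist()})
        stages.append({"stage": "head", "out_channels": self.cfg.n_classes,
                       "dims": dims.tolist()})
        return {
            "config": dataclasses.asdict(self.cfg),
            "stages": stages,
            "n_parameters": self.n_parameters,
            "n_maxpool": len(self.pools),
            "n_transposed_conv": len(self.upconvs),
        }

    # -- forward / backward --------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Input (z, y, x) float grid -> logits (n_classes, z, y, x)."""
        if x.shape != tuple(self.cfg.input_dims):
            raise ValueError(
                f"input dims {x.shape} != network dims {self.cfg.input_dims}"
            )
        rng = self._drop_rng
        h = self.stem.forward(x[np.newaxis].astype(_DT))
        skips = []
        for blk, pool in zip(self.enc_blocks, self.pools):
            h = blk.forward(h, training, rng)
            skips.append(h)
            h = pool.forward(h)
        h = self.bottleneck.forward(h, training, rng)
        for up, blk, skip in zip(self.upconvs, self.dec_blocks, reversed(skips)):
            h = up.forward(h)
            h = np.concatenate([skip, h], axis=0)
            blk._concat_split = skip.shape[0]
            h = blk.forward(h, training, rng)
        return self.head.forward(h)

    def backward(self, dlogits: np.ndarray) -> None:
        g = self.head.backward(dlogits.astype(_DT))
        skip_grads = []
        for up, blk in zip(reversed(self.upconvs), reversed(self.dec_blocks)):
            g = blk.backward(g)
            split = blk._concat_split
            skip_grads.append(np.ascontiguousarray(g[:split]))
            g = up.backward(np.ascontiguousarray(g[split:]))
        g = self.bottleneck.backward(g)
        for blk, pool, gskip in zip(
            reversed(self.enc_blocks), reversed(self.pools), skip_grads
        ):
            g = pool.backward(g)
            g = blk.backward(g + gskip)
        self.stem.backward(g)

    def predict_probs(self, x: np.ndarray) -> np.ndarray:
        logits = self.forward(x, training=False)
        return softmax(logits)

    def state(self):
        """Deep copy of all trainable arrays and BN running stats."""
        return copy.deepcopy(
            [
                (getattr(o, n).copy()) for o, n in self.parameters()
            ]
            + [
                (bn.run_mean.copy(), bn.run_var.copy())
                for bn in self._batchnorms()
            ]
        )

    def load_state(self, state) -> None:
        params = self.parameters()
        for (o, n), arr in zip(params, state[: len(params)]):
            setattr(o, n, arr.copy())
        for bn, (m, v) in zip(self._batchnorms(), state[len(params):]):
            bn.run_mean, bn.run_var = m.copy(), v.copy()

    def _batchnorms(self):
        for layer in self._layers():
            if isinstance(layer, DenseBlock):
                for u in layer.units:
                    yield u.bn


def build_dense_unet(cfg: NetworkConfig, seed: int = 0) -> DenseUNet:
    """Construct a seeded dense-block 3D U-Net; ``model.describe()`` reports
    per-stage channel counts, spatial dims and the parameter count."""
    return DenseUNet(cfg, seed=seed)


# ---------------------------------------------------------------------------
# loss


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


def composite_loss(
    probs: np.ndarray,
    target,
    ce_w: float = 1.0,
    dice_w: float = 1.0,
) -> float:
    """Composite loss: mean softmax cross-entropy plus foreground Dice loss.

    ``probs`` is (n_classes, z, y, x) with per-voxel probabilities summing
    to 1; ``target`` a binary mask grid.  DiceLoss = 1 - (2*sum(p1*t)+eps) /
    (sum(p1)+sum(t)+eps) with eps = 1e-5.
    """
    t = target.labels if isinstance(target, SegmentationMask) else np.asarray(target)
    t = t.astype(np.float64)
    if probs.shape[1:] != t.shape:
        raise ValueError(f"probs spatial dims {probs.shape[1:]} != target {t.shape}")
    p = np.clip(probs.astype(np.float64), 1e-12, 1.0)
    p_true = np.where(t > 0.5, p[1], p[0])
    ce = -np.log(p_true).mean()
    p1 = p[1]
    inter = (p1 * t).sum()
    denom = p1.sum() + t.sum() + _DICE_EPS
    dice_loss = 1.0 - (2.0 * inter + _DICE_EPS) / denom
    return float(ce_w * ce + dice_w * dice_loss)


def _loss_and_dlogits(logits: np.ndarray, t: np.ndarray, ce_w: float, dice_w: float):
    """Loss value and analytic gradient wrt the logits."""
    p = softmax(logits.astype(np.float64))
    n = t.size
    tf = t.astype(np.float64)
    onehot = np.stack([1.0 - tf, tf])
    ce = -(onehot * np.log(np.clip(p, 1e-12, 1.0))).sum(axis=0).mean()
    d_ce = (p - onehot) / n

    p1 = p[1]
    inter = (p1 * tf).sum()
    denom = p1.sum() + tf.sum() + _DICE_EPS
    dice_loss = 1.0 - (2.0 * inter + _DICE_EPS) / denom
    # dL/dp1, then through the softmax jacobian
    g1 = -(2.0 * tf * denom - (2.0 * inter + _DICE_EPS)) / denom**2
    gdot = g1 * p1  # sum_j g_j p_j with g0 = 0
    d_dice = np.stack([p[0] * (-gdot), p1 * (g1 - gdot)])

    loss = ce_w * ce + dice_w * dice_loss
    dlogits = ce_w * d_ce + dice_w * d_dice
    return float(loss), dlogits.astype(_DT)


# ---------------------------------------------------------------------------
# training / inference


class _Adam:
    def __init__(self, params, lr: float):
        self.params = params
        self.lr = lr
        self.t = 0
        self.m = [np.zeros_like(getattr(o, n), dtype=np.float64) for o, n in params]
        self.v = [np.zeros_like(getattr(o, n), dtype=np.float64) for o, n in params]
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self) -> None:
        if self.lr == 0:
            return
        self.t += 1
        for i, (o, n) in enumerate(self.params):
            g = getattr(o, "d" + n)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g.astype(np.float64) ** 2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            upd = self.lr * mhat / (np.sqrt(vhat) + self.eps)
            setattr(o, n, (getattr(o, n) - upd).astype(_DT))


def _as_grid(x) -> np.ndarray:
    if isinstance(x, PcmraVolume):
        return x.intensity
    if isinstance(x, SegmentationMask):
        return x.labels
    return np.asarray(x)


def normalize_input(grid: np.ndarray) -> np.ndarray:
    """Per-volume standardization of the PCMRA intensities."""
    g = np.asarray(grid, dtype=np.float64)
    std = g.std()
    return ((g - g.mean()) / (std if std > 0 else 1.0)).astype(_DT)


def _dice_score(pred: np.ndarray, truth: np.ndarray) -> float:
    denom = pred.sum() + truth.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(pred, truth).sum() / denom)


def train_model(
    model: DenseUNet,
    tcfg: TrainConfig,
    train_set,
    val_set=(),
    verbose: bool = False,
) -> dict:
    """Train with Adam on the composite loss; fully seeded.

    *train_set*/*val_set* are sequences of (PCMRA-like grid, mask) pairs at
    the network input dimensions.  Per-epoch training loss and, when a
    validation set is given, validation loss and Dice are logged; the
    parameters of the best-validation-Dice epoch are restored at the end.
    Returns the history dict.
    """
    if not len(train_set):
        raise ValueError("train_set is empty")
    dims = tuple(model.cfg.input_dims)
    pairs = []
    for img, msk in list(train_set) + list(val_set):
        gi, gm = _as_grid(img), _as_grid(msk)
        if gi.shape != dims or gm.shape != dims:
            raise ValueError(
                f"case dims {gi.shape}/{gm.shape} do not match network "
                f"input dims {dims}"
            )
        pairs.append((normalize_input(gi), gm.astype(np.uint8)))
    train_pairs = pairs[: len(train_set)]
    val_pairs = pairs[len(train_set):]

    model._drop_rng = np.random.default_rng(tcfg.seed + 1)
    shuffle_rng = np.random.default_rng(tcfg.seed)
    opt = _Adam(model.parameters(), tcfg.learning_rate)
    history = {"train_loss": [], "val_loss": [], "val_dice": [], "best_epoch": None}
    best_dice, best_state = -1.0, None

    for epoch in range(tcfg.epochs):
        order = shuffle_rng.permutation(len(train_pairs))
        losses = []
        for i in order:
            x, t = train_pairs[i]
            logits = model.forward(x, training=True)
            loss, dlogits = _loss_and_dlogits(logits, t, tcfg.ce_w, tcfg.dice_w)
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        history["train_loss"].append(float(np.mean(losses)))
        if val_pairs:
            vlosses, vdices = [], []
            for x, t in val_pairs:
                logits = model.forward(x, training=False)
                vloss, _ = _loss_and_dlogits(logits, t, tcfg.ce_w, tcfg.dice_w)
                pred = softmax(logits)[1] > 0.5
                vlosses.append(vloss)
                vdices.append(_dice_score(pred, t))
            history["val_loss"].append(float(np.mean(vlosses)))
            history["val_dice"].append(float(np.mean(vdices)))
            if history["val_dice"][-1] > best_dice:
                best_dice = history["val_dice"][-1]
                best_state = model.state()
                history["best_epoch"] = epoch
        if verbose:
            msg = f"epoch {epoch + 1}/{tcfg.epochs} loss {history['train_loss'][-1]:.4f}"
            if val_pairs:
                msg += f" val_dice {history['val_dice'][-1]:.4f}"
            print(msg)
    if best_state is not None:
        model.load_state(best_state)
    return history


def save_model(model: DenseUNet, path) -> None:
    """Serialize weights + architecture to an .npz checkpoint."""
    import json

    arrays = {f"param_{i}": getattr(o, n) for i, (o, n) in enumerate(model.parameters())}
    for i, bn in enumerate(model._batchnorms()):
        arrays[f"bn_mean_{i}"] = bn.run_mean
        arrays[f"bn_var_{i}"] = bn.run_var
    arrays["config_json"] = np.frombuffer(
        json.dumps(dataclasses.asdict(model.cfg)).encode(), dtype=np.uint8
    )
    arrays["seed"] = np.array([model.seed])
    np.savez(path, **arrays)


def load_model(path) -> DenseUNet:
    import json

    with np.load(path) as data:
        cfg_dict = json.loads(bytes(data["config_json"]).decode())
        cfg_dict["input_dims"] = tuple(cfg_dict["input_dims"])
        model = DenseUNet(NetworkConfig(**cfg_dict), seed=int(data["seed"][0]))
        for i, (o, n) in enumerate(model.parameters()):
            setattr(o, n, data[f"param_{i}"].copy())
        for i, bn in enumerate(model._batchnorms()):
            bn.run_mean = data[f"bn_mean_{i}"].copy()
            bn.run_var = data[f"bn_var_{i}"].copy()
    return model


def predict_mask(model: DenseUNet, pcmra) -> SegmentationMask:
    """Segment a PCMRA volume: crop/pad to network dims, forward pass with
    dropout disabled, per-voxel argmax (ties -> background), and mapping
    back to the original grid."""
    grid = _as_grid(pcmra)
    orig = grid.shape
    x = center_crop_or_pad(normalize_input(grid), model.cfg.input_dims)
    probs = model.predict_probs(x)
    labels = (probs[1] > probs[0]).astype(np.uint8)
    labels = restore_dims(labels, orig)
    spacing = (
        pcmra.spacing if isinstance(pcmra, PcmraVolume) else np.ones(3)
    )
    return SegmentationMask(labels=labels, spacing=np.asarray(spacing, dtype=float))
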