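"""A small residual convolutional network in pure numpy.

The building block is the residual mapping ``y = F(x, {W_i}) + x`` with
``F`` a conv-ReLU-conv stack of 3x3 filters; downsampling uses stride-2
convolutions with filter doubling, and the shortcut across a dimension
change is an identity map on the stride-2 subsampled input, zero-padded
over the new channels.  The head is global average pooling, a fully
connected layer and a softmax over the two diagnostic classes - the
architecture family of deep residual classifiers, scaled to desk size and
trained from scratch.

Convolutions run through im2col/col2im with numpy matrix products; every
layer implements an explicit backward pass, and training uses stochastic
gradient descent with momentum.  Data layout is ``(N, C, H, W)``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigurationError


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, tuple]:
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    windows = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    _, _, oh, ow, _, _ = windows.shape
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * k * k)
    return np.ascontiguousarray(cols), (oh, ow)


def _col2im(dcols: np.ndarray, x_shape: tuple, k: int, stride: int, pad: int,
            out_hw: tuple[int, int]) -> np.ndarray:
    n, c, h, w = x_shape
    oh, ow = out_hw
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    d6 = dcols.reshape(n, oh, ow, c, k, k).transpose(0, 3, 4, 5, 1, 2)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += d6[:, :, i, j]
    return dxp[:, :, pad:pad + h, pad:pad + w]


class Conv3x3:
    """3x3 convolution, padding 1, configurable stride; He-initialized."""

    def __init__(self, in_c: int, out_c: int, stride: int = 1,
                 rng: np.random.Generator | None = None, zero_init: bool = False):
        rng = rng or np.random.default_rng()
        fan_in = in_c * 9
        scale = 0.0 if zero_init else np.sqrt(2.0 / fan_in)
        self.weight = rng.normal(0.0, 1.0, (out_c, in_c, 3, 3)) * scale
        self.bias = np.zeros(out_c)
        self.stride = stride
        self.params = [self.weight, self.bias]
        self.grads = [np.zeros_like(self.weight), np.zeros_like(self.bias)]
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols, (oh, ow) = _im2col(x, 3, self.stride, 1)
        wmat = self.weight.reshape(self.weight.shape[0], -1)
        out = cols @ wmat.T + self.bias
        n = x.shape[0]
        self._cache = (x.shape, cols, (oh, ow))
        return out.reshape(n, oh, ow, -1).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x_shape, cols, out_hw = self._cache
        n, out_c = dy.shape[0], dy.shape[1]
        dout = dy.transpose(0, 2, 3, 1).reshape(-1, out_c)
        wmat = self.weight.reshape(out_c, -1)
        self.grads[0][...] = (dout.T @ cols).reshape(self.weight.shape)
        self.grads[1][...] = dout.sum(axis=0)
        dcols = dout @ wmat
        return _col2im(dcols, x_shape, 3, self.stride, 1, out_hw)


class BatchNorm2d:
    """Per-channel batch normalization with running statistics for inference."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self.training = True
        self._acc = None

    def begin_calibration(self) -> None:
        self._acc = [0, 0.0, 0.0]  # pixel count, sum, sum of squares per channel

    def end_calibration(self) -> None:
        count, total, total_sq = self._acc
        mean = total / count
        self.running_mean = mean
        self.running_var = total_sq / count - mean**2
        self._acc = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            if self._acc is not None:
                self._acc[0] += x.shape[0] * x.shape[2] * x.shape[3]
                self._acc[1] += x.sum(axis=(0, 2, 3))
                self._acc[2] += (x**2).sum(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)[None, :, None, None]
        self._xhat = (x - mean[None, :, None, None]) / self._std
        return self.gamma[None, :, None, None] * self._xhat + self.beta[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.grads[0][...] = (dy * self._xhat).sum(axis=(0, 2, 3))
        self.grads[1][...] = dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma[None, :, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
        s2 = (dxhat * self._xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return (dxhat - s1 / m - self._xhat * s2 / m) / self._std


class _Branch:
    """conv -> BN -> ReLU -> conv -> BN residual mapping F(x).

    A zero-initialized branch maps anything to exactly zero, so the
    enclosing block reduces to the identity.
    """

    def __init__(self, in_c: int, out_c: int, stride: int, rng, zero_init: bool = False):
        self.conv1 = Conv3x3(in_c, out_c, stride, rng, zero_init=zero_init)
        self.bn1 = BatchNorm2d(out_c)
        self.conv2 = Conv3x3(out_c, out_c, 1, rng, zero_init=zero_init)
        self.bn2 = BatchNorm2d(out_c)
        self.params = self.conv1.params + self.bn1.params + self.conv2.params + self.bn2.params
        self.grads = self.conv1.grads + self.bn1.grads + self.conv2.grads + self.bn2.grads
        self._relu_mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.bn1.forward(self.conv1.forward(x))
        self._relu_mask = h > 0
        return self.bn2.forward(self.conv2.forward(h * self._relu_mask))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dh = self.conv2.backward(self.bn2.backward(dy)) * self._relu_mask
        return self.conv1.backward(self.bn1.backward(dh))


class ResidualBlock:
    """y = F(x) + x; with the branch weights zeroed this is the identity map."""

    def __init__(self, channels: int, rng, zero_init: bool = False):
        self.branch = _Branch(channels, channels, 1, rng, zero_init=zero_init)
        self.params = self.branch.params
        self.grads = self.branch.grads

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.branch.forward(x) + x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.branch.backward(dy) + dy


class DownsampleBlock:
    """Stride-2 residual block doubling the channels.

    The shortcut is an identity on the stride-2 subsampled input, zero-padded
    across the added channels - no learned projection.
    """

    def __init__(self, in_c: int, rng):
        self.in_c, self.out_c = in_c, 2 * in_c
        self.branch = _Branch(in_c, self.out_c, 2, rng)
        self.params = self.branch.params
        self.grads = self.branch.grads

    def forward(self, x: np.ndarray) -> np.ndarray:
        f = self.branch.forward(x)
        shortcut = np.zeros_like(f)
        sub = x[:, :, ::2, ::2]
        shortcut[:, : self.in_c, : sub.shape[2], : sub.shape[3]] = sub
        self._x_shape = x.shape
        return f + shortcut

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = self.branch.backward(dy)
        dshort = np.zeros(self._x_shape)
        sub = dshort[:, :, ::2, ::2]
        dshort[:, :, ::2, ::2] = dy[:, : self.in_c, : sub.shape[2], : sub.shape[3]]
        return dx + dshort


class ReLU:
    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class ResidualNet:
    """Stem conv -> residual stages -> global average pool -> FC -> softmax.

    Stage ``s`` (s >= 2) starts with a stride-2 downsampling block that
    doubles the channel count; every stage then stacks ``blocks_per_stage``
    identity residual blocks.  ``n_stages`` and ``blocks_per_stage`` set the
    depth; parameter count grows strictly with either.
    """

    def __init__(self, in_channels: int = 3, base_channels: int = 8,
                 n_stages: int = 2, blocks_per_stage: int = 1, n_classes: int = 2,
                 seed: int = 0):
        if n_stages < 1 or blocks_per_stage < 1 or base_channels < 1:
            raise ConfigurationError("n_stages, blocks_per_stage, base_channels must be >= 1")
        rng = np.random.default_rng(seed)
        self.stem = Conv3x3(in_channels, base_channels, 1, rng)
        self.stem_bn = BatchNorm2d(base_channels)
        self.stem_relu = ReLU()
        self.blocks: list = []
        channels = base_channels
        for stage in range(n_stages):
            if stage > 0:
                self.blocks.append(DownsampleBlock(channels, rng))
                channels *= 2
            for _ in range(blocks_per_stage):
                self.blocks.append(ResidualBlock(channels, rng))
        self.out_channels = channels
        self.fc_weight = rng.normal(0.0, np.sqrt(1.0 / channels), (n_classes, channels))
        self.fc_bias = np.zeros(n_classes)
        self.n_classes = n_classes

    # -- parameter plumbing ------------------------------------------------
    @property
    def params(self) -> list:
        ps = list(self.stem.params) + list(self.stem_bn.params)
        for b in self.blocks:
            ps.extend(b.params)
        ps.extend([self.fc_weight, self.fc_bias])
        return ps

    def batchnorm_layers(self) -> list[BatchNorm2d]:
        layers = [self.stem_bn]
        for b in self.blocks:
            branch = getattr(b, "branch", None)
            if branch is not None:
                layers.extend([branch.bn1, branch.bn2])
        return layers

    def set_training(self, training: bool) -> None:
        """Switch batch-norm layers between batch and running statistics."""
        for bn in self.batchnorm_layers():
            bn.training = training

    def calibrate_batchnorm(self, x_batches) -> None:
        """Replace BN running statistics with exact moments over the given
        batches (run in training mode, no parameter updates)."""
        self.set_training(True)
        for bn in self.batchnorm_layers():
            bn.begin_calibration()
        for xb in x_batches:
            self.feature_maps(xb)
        for bn in self.batchnorm_layers():
            bn.end_calibration()
        self.set_training(False)

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params))

    def _grads(self) -> list:
        gs = list(self.stem.grads) + list(self.stem_bn.grads)
        for b in self.blocks:
            gs.extend(b.grads)
        gs.extend([self._fc_wgrad, self._fc_bgrad])
        return gs

    # -- forward/backward --------------------------------------------------
    def feature_maps(self, x: np.ndarray) -> np.ndarray:
        """Final convolutional feature maps (N, C, h, w), before the head.

        The head applies a ReLU before global average pooling; CAMs are
        computed on these rectified maps (:meth:`head_features`).
        """
        h = self.stem_relu.forward(self.stem_bn.forward(self.stem.forward(x)))
        for b in self.blocks:
            h = b.forward(h)
        return h

    def head_features(self, x: np.ndarray) -> np.ndarray:
        """Rectified final feature maps: the maps the GAP head actually pools."""
        return np.maximum(self.feature_maps(x), 0.0)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities (N, n_classes)."""
        fmap = self.feature_maps(x)
        self._fmap_shape = fmap.shape
        self._head_mask = fmap > 0
        pooled = (fmap * self._head_mask).mean(axis=(2, 3))
        self._pooled = pooled
        logits = pooled @ self.fc_weight.T + self.fc_bias
        z = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(z)
        self._probs = ez / ez.sum(axis=1, keepdims=True)
        return self._probs

    def backward_from_probs(self, y: np.ndarray) -> None:
        n = len(y)
        dlogits = self._probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        self._fc_wgrad = dlogits.T @ self._pooled
        self._fc_bgrad = dlogits.sum(axis=0)
        dpooled = dlogits @ self.fc_weight
        _, c, hh, ww = self._fmap_shape
        dfmap = np.broadcast_to(
            dpooled[:, :, None, None] / (hh * ww), self._fmap_shape
        ) * self._head_mask
        for b in reversed(self.blocks):
            dfmap = b.backward(dfmap)
        self.stem.backward(self.stem_bn.backward(self.stem_relu.backward(dfmap)))

    def loss_and_backward(self, x: np.ndarray, y: np.ndarray) -> float:
        """Mean cross-entropy on integer class labels; accumulates gradients."""
        probs = self.forward(x)
        n = x.shape[0]
        loss = float(-np.log(np.clip(probs[np.arange(n), y], 1e-12, None)).mean())
        self.backward_from_probs(y)
        return loss

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x).argmax(axis=1)


class SGDMomentum:
    """Classical momentum: v <- momentum * v + grad; p <- p - lr * v."""

    def __init__(self, model: ResidualNet, learning_rate: float, momentum: float = 0.9):
        self.model = model
        self.lr = learning_rate
        self.momentum = momentum
        self._velocity = [np.zeros_like(p) for p in model.params]

    def step(self) -> None:
        for p, g, v in zip(self.model.params, self.model._grads(), self._velocity):
            v *= self.momentum
            v += g
            p -= self.lr * v
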