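"""Minimal float32 CNN backend: layers, U-Net assembly, Adam.

Self-contained NumPy implementation sized for 2D single-channel
segmentation.  Convolutions run as per-tap BLAS GEMMs on contiguous views
of the padded grid (see Conv2D.forward); everything is deterministic given
the seed, and histories are bit-reproducible per NumPy/BLAS build.  Layout
is NHWC throughout.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np
from scipy.linalg.blas import sgemm


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Conv2D:
    """Same-padded kxk convolution with optional ReLU; weights (k, k, cin, cout).

    Implemented as k*k shifted GEMMs over the padded input — much cheaper in
    NumPy than an explicit im2col gather at these channel counts.
    """

    def __init__(self, k: int, cin: int, cout: int, rng: np.random.Generator,
                 relu: bool = True):
        self.k, self.cin, self.cout, self.relu = k, cin, cout, relu
        fan_in = k * k * cin
        scale = np.sqrt(2.0 / fan_in) if relu else np.sqrt(1.0 / fan_in)
        self.W = (rng.standard_normal((k, k, cin, cout)) * scale).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.need_dx = True  # input-layer convs skip the dx GEMMs
        self._x2: Optional[np.ndarray] = None
        self._mask: Optional[np.ndarray] = None
        self._xshape: Optional[Tuple[int, ...]] = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        # Shifting a padded row-major image grid by a tap offset (di, dj) is a
        # *contiguous* 1D slide of di*Wp + dj pixels, so each tap is one BLAS
        # GEMM on contiguous views with beta=1 accumulation — no gather copies.
        n, h, w, c = x.shape
        self._xshape = x.shape
        x = np.ascontiguousarray(x, dtype=np.float32)
        k = self.k
        if k == 1:
            self._x2 = x.reshape(-1, c)
            y = (self._x2 @ self.W[0, 0] + self.b).reshape(n, h, w, self.cout)
        else:
            p = k // 2
            hp, wp = h + 2 * p, w + 2 * p
            xp = np.zeros((n, hp, wp, c), dtype=np.float32)
            xp[:, p:p + h, p:p + w] = x
            self._x2 = xp.reshape(-1, c)
            total = n * hp * wp
            span = total - 2 * p * wp - 2 * p
            out = np.zeros((total, self.cout), dtype=np.float32)
            out_t = out[:span].T  # Fortran-order view for in-place accumulation
            for i in range(k):
                for j in range(k):
                    xs = self._x2[i * wp + j:i * wp + j + span]
                    # out[:span] += xs @ W[i,j], computed transposed in F order
                    sgemm(1.0, self.W[i, j].T, xs.T, beta=1.0, c=out_t,
                          overwrite_c=1)
            y = out.reshape(n, hp, wp, self.cout)[:, :h, :w] + self.b
        if self.relu:
            np.maximum(y, 0.0, out=y)
            self._mask = y > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._xshape
        k = self.k
        if self.relu:
            dy = dy * self._mask
        if k == 1:
            dym = np.ascontiguousarray(dy.reshape(-1, self.cout))
            self.db[...] = dym.sum(axis=0)
            self.dW[0, 0] = self._x2.T @ dym
            dx = (dym @ self.W[0, 0].T).reshape(n, h, w, c)
        else:
            p = k // 2
            hp, wp = h + 2 * p, w + 2 * p
            total = n * hp * wp
            span = total - 2 * p * wp - 2 * p
            dyw = np.zeros((n, hp, wp, self.cout), dtype=np.float32)
            dyw[:, :h, :w] = dy  # embed at the output anchoring of forward
            d2 = dyw.reshape(-1, self.cout)
            self.db[...] = dy.sum(axis=(0, 1, 2))
            dsrc = d2[:span]
            dxp = np.zeros((total, c), dtype=np.float32) if self.need_dx else None
            for i in range(k):
                for j in range(k):
                    delta = i * wp + j
                    xs = self._x2[delta:delta + span]
                    self.dW[i, j] = xs.T @ dsrc
                    if self.need_dx:
                        # dxp[delta:delta+span] += dsrc @ W[i,j].T (transposed, F order)
                        sgemm(1.0, self.W[i, j], dsrc.T, beta=1.0,
                              c=dxp[delta:delta + span].T, overwrite_c=1)
            dx = (dxp.reshape(n, hp, wp, c)[:, p:p + h, p:p + w]
                  if self.need_dx else None)
        self._x2 = None
        self._mask = None
        return dx

    def parameters(self):
        return [(self.W, self.dW), (self.b, self.db)]


class MaxPool2:
    """2x2 stride-2 max pooling; gradient routed to the (first) argmax."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        m = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        m = np.ascontiguousarray(m).reshape(n, h // 2, w // 2, c, 4)
        self._idx = m.argmax(axis=-1)
        self._shape = (n, h, w, c)
        return np.take_along_axis(m, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        dm = np.zeros((n, h // 2, w // 2, c, 4), dtype=np.float32)
        np.put_along_axis(dm, self._idx[..., None], dy[..., None], axis=-1)
        dm = dm.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return np.ascontiguousarray(dm).reshape(n, h, w, c)


class Upsample2:
    """Nearest-neighbor 2x upsampling; gradient is the 2x2 block sum."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = dy.shape
        return dy.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class Dropout:
    """Inverted dropout, active only in training mode."""

    def __init__(self, rate: float):
        self.rate = rate
        self._mask = None

    def forward(self, x: np.ndarray, training: bool, rng: Optional[np.random.Generator]):
        if not training or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape, dtype=np.float32) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask


class UNet:
    """Encoder-decoder with skip connections, dropout at the two deepest
    levels, and a single-channel sigmoid output.

    ``depth`` encoder levels of ``convs_per_block`` 3x3 ReLU convolutions
    (``base_filters`` doubling per level) each followed by 2x2 max pooling;
    a bottleneck block; a mirrored decoder of nearest-neighbor upsampling,
    skip concatenation, and convolution blocks; and a final 1x1 convolution
    through a sigmoid.
    """

    def __init__(self, depth: int, base_filters: int, dropout_rate: float,
                 seed: int, input_size: int = 256, in_channels: int = 1,
                 convs_per_block: int = 2):
        if depth < 2:
            raise ValueError("depth must be >= 2")
        if input_size % (2 ** depth) != 0:
            raise ValueError(
                f"input size {input_size} not divisible by 2^depth={2 ** depth}"
            )
        self.depth = depth
        self.base_filters = base_filters
        self.input_size = input_size
        self.in_channels = in_channels
        self.convs_per_block = convs_per_block
        self.dropout_rate = dropout_rate
        self.seed = seed
        rng = np.random.default_rng(seed)

        def block(cin: int, cout: int) -> List[Conv2D]:
            convs = [Conv2D(3, cin, cout, rng)]
            for _ in range(convs_per_block - 1):
                convs.append(Conv2D(3, cout, cout, rng))
            return convs

        self.enc_blocks: List[List[Conv2D]] = []
        cin = in_channels
        for lvl in range(depth):
            cout = base_filters * (2 ** lvl)
            self.enc_blocks.append(block(cin, cout))
            cin = cout
        self.bottleneck = block(cin, base_filters * (2 ** depth))
        # dropout at the two deepest levels: deepest encoder block, bottleneck
        self.enc_dropout = Dropout(dropout_rate)
        self.bot_dropout = Dropout(dropout_rate)

        self.dec_blocks: List[List[Conv2D]] = []
        cin = base_filters * (2 ** depth)
        for lvl in reversed(range(depth)):
            skip_ch = base_filters * (2 ** lvl)
            self.dec_blocks.append(block(cin + skip_ch, skip_ch))
            cin = skip_ch
        self.final = Conv2D(1, cin, 1, rng, relu=False)

        self.pools = [MaxPool2() for _ in range(depth)]
        self.ups = [Upsample2() for _ in range(depth)]
        self.enc_blocks[0][0].need_dx = False

    # -- bookkeeping -------------------------------------------------------

    def _all_convs(self) -> List[Conv2D]:
        convs: List[Conv2D] = []
        for blk in self.enc_blocks:
            convs.extend(blk)
        convs.extend(self.bottleneck)
        for blk in self.dec_blocks:
            convs.extend(blk)
        convs.append(self.final)
        return convs

    def parameters(self):
        out = []
        for conv in self._all_convs():
            out.extend(conv.parameters())
        return out

    def n_parameters(self) -> int:
        return sum(int(w.size) for w, _ in self.parameters())

    def get_weights(self) -> dict:
        out = {}
        for i, conv in enumerate(self._all_convs()):
            out[f"conv{i:02d}_W"] = conv.W.copy()
            out[f"conv{i:02d}_b"] = conv.b.copy()
        return out

    def set_weights(self, weights: dict) -> None:
        for i, conv in enumerate(self._all_convs()):
            conv.W[...] = weights[f"conv{i:02d}_W"]
            conv.b[...] = weights[f"conv{i:02d}_b"]

    # -- forward / backward ------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False,
                rng: Optional[np.random.Generator] = None) -> np.ndarray:
        """Input (n, s, s, 1) in [0, 1] -> probabilities (n, s, s, 1)."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        self._skip_channels = []
        self._skips = []
        h = x
        for lvl in range(self.depth):
            for conv in self.enc_blocks[lvl]:
                h = conv.forward(h)
            if lvl == self.depth - 1:
                h = self.enc_dropout.forward(h, training, rng)
            self._skip_channels.append(h.shape[-1])
            self._skips.append(h)
            h = self.pools[lvl].forward(h)
        for conv in self.bottleneck:
            h = conv.forward(h)
        h = self.bot_dropout.forward(h, training, rng)
        for i, lvl in enumerate(reversed(range(self.depth))):
            h = self.ups[i].forward(h)
            h = np.concatenate([self._skips[lvl], h], axis=-1)
            for conv in self.dec_blocks[i]:
                h = conv.forward(h)
        z = self.final.forward(h)
        self._z = z
        return _sigmoid(z)

    def backward(self, dz: np.ndarray) -> None:
        """Backpropagate from the gradient w.r.t. the final logits."""
        dh = self.final.backward(dz)
        dskips = [None] * self.depth
        for i in reversed(range(self.depth)):  # shallowest decoder block first
            lvl = self.depth - 1 - i
            for conv in reversed(self.dec_blocks[i]):
                dh = conv.backward(dh)
            skip_ch = self._skip_channels[lvl]
            dskips[lvl] = dh[..., :skip_ch]
            dh = self.ups[i].backward(dh[..., skip_ch:])
        dh = self.bot_dropout.backward(dh)
        for conv in reversed(self.bottleneck):
            dh = conv.backward(dh)
        for lvl in reversed(range(self.depth)):
            dh = self.pools[lvl].backward(dh)
            dh = dh + dskips[lvl]
            if lvl == self.depth - 1:
                dh = self.enc_dropout.backward(dh)
            for conv in reversed(self.enc_blocks[lvl]):
                dh = conv.backward(dh)


class Adam:
    """Adam optimizer over a UNet's parameters (beta1=0.9, beta2=0.999)."""

    def __init__(self, net: UNet, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.net = net
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(w) for w, _ in net.parameters()]
        self.v = [np.zeros_like(w) for w, _ in net.parameters()]

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for (w, g), m, v in zip(self.net.parameters(), self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            w -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
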