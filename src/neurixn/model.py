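"""The interaction decoder: a compact CNN that classifies attended side
(left/right) from 30-channel band-enhanced region signals by learning
*pairwise interactions* between the 10 cortical regions.

Architecture (input ``30 x T``, all convolutions bias-free):

1. temporal convolution — 4 kernels of shape ``(1, 31)``, same padding,
   giving 4 feature maps of ``30 x T``; batch normalization over batch and
   time per (map, channel).
2. per-map grouped pointwise convolution collapsing each region's 3 band
   channels to 1 (10 groups of size 3), then a depthwise temporal
   convolution (10 groups, kernel 31): 4 maps of ``10 x T`` region signals.
3. interaction stage — element-wise product of all C(10,2) = 45 region
   pairs per map: 4 maps of ``45 x T``.
4. depthwise spatial convolution of shape ``(45, 1)``: one 45-vector
   ("spatial filter") per map, each row constrained to max Euclidean norm 1;
   batch norm, ELU, average pooling ``(1, 4)`` (64 Hz -> 16 Hz), dropout.
5. separable convolution: depthwise temporal kernel of length 16, then a
   pointwise mix to 4 channels; batch norm, ELU, average pooling ``(1, 8)``,
   dropout.
6. flatten -> bias-free linear map to 2 units -> softmax.

The 4 spatial filters of stage 4 are the interpretable objects: they state
which linear combinations of region-pair interactions drive the decision.

The network is implemented directly in numpy with hand-written
backpropagation (verified against numerical gradients in the test suite);
training lives in :mod:`neurixn.training`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft
from numpy.lib.stride_tricks import sliding_window_view

from .data_model import PairIndex, make_pair_index


@dataclass
class ModelConfig:
    """Hyperparameters of the interaction decoder (defaults as deployed)."""

    n_regions: int = 10
    n_bands: int = 3
    n_temporal_maps: int = 4  # F1
    temporal_kernel_len: int = 31
    n_spatial_filters: int = 4  # F2 == F1 (depthwise pairing)
    pool1: int = 4
    pool2: int = 8
    separable_kernel_len: int = 16
    separable_pointwise_out: int = 4
    dropout_p: float = 0.5
    maxnorm: float = 1.0
    fs: float = 64.0
    n_classes: int = 2
    bn_momentum: float = 0.1
    bn_eps: float = 1e-5
    #: stage-1 batch-norm scope: "map" normalizes each temporal map over
    #: (batch, channels, time), preserving inter-channel amplitude ratios;
    #: "channel" normalizes each (map, channel) over (batch, time)
    bn1_scope: str = "map"

    def __post_init__(self) -> None:
        if self.temporal_kernel_len % 2 != 1:
            raise ValueError("temporal_kernel_len must be odd (symmetric same padding)")
        if self.n_spatial_filters != self.n_temporal_maps:
            raise ValueError("depthwise pairing requires n_spatial_filters == n_temporal_maps")

    @property
    def n_channels(self) -> int:
        return self.n_regions * self.n_bands

    @property
    def n_pairs(self) -> int:
        return self.n_regions * (self.n_regions - 1) // 2

    @property
    def pooled_fs(self) -> float:
        """Effective sampling rate after the first average pooling."""
        return self.fs / self.pool1


@dataclass
class SpatialFilterSet:
    """The learned 4 x 45 interaction weights of a (trained) model."""

    filters: np.ndarray  # (n_spatial_filters, 45)
    pair_index: PairIndex
    model_id: str = ""
    fold_id: int = -1
    participant_id: str = ""


def interaction_stage(region_signals: np.ndarray, pair_index: PairIndex) -> np.ndarray:
    """Element-wise products of all unordered region pairs.

    ``region_signals`` is ``(10, T)`` (or ``(..., 10, T)``); row ``k`` of the
    output is the pointwise product of the two region rows of
    ``pair_index.pairs[k]``, giving ``(..., 45, T)``.
    """
    x = np.asarray(region_signals)
    # recover region positions from the lexicographic pair order: the order of
    # first appearance of codes equals the region_order the index was built from
    codes: list[str] = []
    for a, b in pair_index.pairs:
        if a not in codes:
            codes.append(a)
        if b not in codes:
            codes.append(b)
    pos = {c: i for i, c in enumerate(codes)}
    if x.shape[-2] != len(codes):
        raise ValueError(f"expected {len(codes)} region rows, got {x.shape[-2]}")
    I = np.array([pos[a] for a, _ in pair_index.pairs])
    J = np.array([pos[b] for _, b in pair_index.pairs])
    return x[..., I, :] * x[..., J, :]


def _elu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))


def _elu_grad(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.where(x > 0, 1.0, y + 1.0)


class InteractionDecoder:
    """Numpy implementation of the interaction CNN (forward + backprop).

    Parameters are stored in ``self.params``; batch-norm running statistics
    in ``self.running``.  ``window_len`` is the input length T the model was
    built for.
    """

    def __init__(
        self,
        config: ModelConfig,
        window_len: int,
        seed: int = 0,
        dtype: type = np.float32,
    ):
        self.config = config
        self.window_len = int(window_len)
        self.dtype = np.dtype(dtype)
        cfg = config
        self.T1 = self.window_len // cfg.pool1
        self.T2 = self.T1 // cfg.pool2
        if self.T1 < 1 or self.T2 < 1:
            raise ValueError(f"window of {window_len} samples too short for pooling")
        self.pair_index = make_pair_index()
        I, J = np.triu_indices(cfg.n_regions, k=1)
        self._I, self._J = I, J
        # for the interaction backward pass: pair rows in which region r is
        # the first / second member
        self._rows_i = [np.flatnonzero(I == r) for r in range(cfg.n_regions)]
        self._rows_j = [np.flatnonzero(J == r) for r in range(cfg.n_regions)]
        # FFT geometry for the temporal correlations of stages 1-2
        h1p = cfg.temporal_kernel_len // 2
        self._n1 = scipy.fft.next_fast_len(self.window_len + 2 * h1p + cfg.temporal_kernel_len)
        self._phase = np.exp(
            -2j * np.pi * np.arange(self._n1 // 2 + 1) * h1p / self._n1
        ).astype(np.complex64 if self.dtype == np.float32 else np.complex128)
        rng = np.random.default_rng(seed)
        F, C, R = cfg.n_temporal_maps, cfg.n_channels, cfg.n_regions
        K1, K5, G = cfg.temporal_kernel_len, cfg.separable_kernel_len, cfg.separable_pointwise_out
        P = cfg.n_pairs

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(self.dtype)

        W4 = he((F, P), P)
        norms = np.linalg.norm(W4, axis=1, keepdims=True)
        W4 = W4 / np.maximum(norms / cfg.maxnorm, 1.0)
        dt = self.dtype
        bn1_shape = (F,) if cfg.bn1_scope == "map" else (F, C)
        self.params: dict[str, np.ndarray] = {
            "W1": he((F, K1), K1),
            "g1": np.ones(bn1_shape, dt),
            "b1": np.zeros(bn1_shape, dt),
            "W2p": he((F, R, cfg.n_bands), cfg.n_bands),
            "W2d": he((F, R, K1), K1),
            "W4": W4.astype(dt),
            "g4": np.ones(F, dt),
            "b4": np.zeros(F, dt),
            "W5d": he((F, K5), K5),
            "W5p": he((G, F), F),
            "g5": np.ones(G, dt),
            "b5": np.zeros(G, dt),
            # zero-initialized readout: the first optimizer steps grow the
            # classifier toward whatever features already discriminate,
            # instead of amplifying random feature directions
            "W6": np.zeros((cfg.n_classes, G * self.T2), dt),
        }
        self.running = {
            "m1": np.zeros(bn1_shape, dt),
            "v1": np.ones(bn1_shape, dt),
            "m4": np.zeros(F, dt),
            "v4": np.ones(F, dt),
            "m5": np.zeros(G, dt),
            "v5": np.ones(G, dt),
        }

    # -- helpers ----------------------------------------------------------

    def copy(self) -> "InteractionDecoder":
        dup = InteractionDecoder(self.config, self.window_len, dtype=self.dtype)
        dup.params = {k: v.copy() for k, v in self.params.items()}
        dup.running = {k: v.copy() for k, v in self.running.items()}
        return dup

    def state_dict(self) -> dict:
        return {
            "params": {k: v.copy() for k, v in self.params.items()},
            "running": {k: v.copy() for k, v in self.running.items()},
        }

    def load_state_dict(self, state: dict) -> None:
        self.params = {k: v.copy() for k, v in state["params"].items()}
        self.running = {k: v.copy() for k, v in state["running"].items()}

    def _bn(self, x, g, b, m_key, axes, train):
        eps = self.config.bn_eps
        bshape = tuple(1 if i in axes else s for i, s in enumerate(x.shape))
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            mom = self.config.bn_momentum
            self.running["m" + m_key] = (1 - mom) * self.running["m" + m_key] + mom * mu
            self.running["v" + m_key] = (1 - mom) * self.running["v" + m_key] + mom * var
        else:
            mu = self.running["m" + m_key]
            var = self.running["v" + m_key]
        invstd = 1.0 / np.sqrt(var + eps)
        xhat = (x - mu.reshape(bshape)) * invstd.reshape(bshape)
        y = g.reshape(bshape) * xhat + b.reshape(bshape)
        cache = (xhat, invstd, g, bshape, axes)
        return y, cache

    @staticmethod
    def _bn_backward(dy, cache):
        xhat, invstd, g, bshape, axes = cache
        m = np.prod([dy.shape[i] for i in axes])
        dg = (dy * xhat).sum(axis=axes)
        db = dy.sum(axis=axes)
        dxhat = dy * g.reshape(bshape)
        s1 = dxhat.sum(axis=axes, keepdims=True)
        s2 = (dxhat * xhat).sum(axis=axes, keepdims=True)
        dx = invstd.reshape(bshape) * (dxhat - s1 / m - xhat * s2 / m)
        return dx, dg, db

    # -- forward ----------------------------------------------------------

    def forward(
        self,
        x: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
        return_cache: bool = False,
    ):
        """Class probabilities ``(B, 2)`` for a batch of windows ``(B, 30, T)``."""
        cfg = self.config
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 2:
            x = x[None]
        B, C, T = x.shape
        if C != cfg.n_channels:
            raise ValueError(f"expected {cfg.n_channels} input channels, got {C}")
        if T != self.window_len:
            raise ValueError(f"model built for T={self.window_len}, got {T}")
        p = self.params
        K1 = cfg.temporal_kernel_len
        h1p = K1 // 2
        # temporal (cross-)correlations are done in the frequency domain:
        # corr(w, xpad)[t] = sum_k w[k] xpad[t+k] = irfft(conj(W) * X)[t]
        n1 = self._n1

        # stage 1: temporal convolution + BN
        xpad = np.pad(x, ((0, 0), (0, 0), (h1p, h1p)))
        Xf = scipy.fft.rfft(xpad, n=n1)  # (B, C, nf)
        W1f = scipy.fft.rfft(p["W1"], n=n1)  # (F, nf)
        z1 = scipy.fft.irfft(np.conj(W1f)[None, :, None, :] * Xf[:, None, :, :], n=n1)[..., :T]
        bn1_axes = (0, 2, 3) if cfg.bn1_scope == "map" else (0, 3)
        h1, bn1c = self._bn(z1, p["g1"], p["b1"], "1", bn1_axes, train)

        # stage 2: grouped pointwise (3 bands -> 1 per region), depthwise temporal
        F, R = cfg.n_temporal_maps, cfg.n_regions
        h1r = h1.reshape(B, F, R, cfg.n_bands, T)
        z2 = np.einsum("bfrst,frs->bfrt", h1r, p["W2p"], optimize=True)
        z2pad = np.pad(z2, ((0, 0), (0, 0), (0, 0), (h1p, h1p)))
        Z2f = scipy.fft.rfft(z2pad, n=n1)  # (B, F, R, nf)
        W2df = scipy.fft.rfft(p["W2d"], n=n1)  # (F, R, nf)
        u = scipy.fft.irfft(np.conj(W2df)[None] * Z2f, n=n1)[..., :T]

        # stage 3: all-pairs interaction
        ui = u[:, :, self._I, :]
        uj = u[:, :, self._J, :]
        v = ui * uj  # (B, F, 45, T)

        # stage 4: depthwise spatial filters + BN + ELU + pool + dropout
        s = np.einsum("bfpt,fp->bft", v, p["W4"], optimize=True)
        h4, bn4c = self._bn(s, p["g4"], p["b4"], "4", (0, 2), train)
        e4 = _elu(h4)
        T1 = self.T1
        p4 = e4[:, :, : T1 * cfg.pool1].reshape(B, F, T1, cfg.pool1).mean(axis=3)
        if train:
            mask4 = ((rng.random(p4.shape) >= cfg.dropout_p) / (1.0 - cfg.dropout_p)).astype(self.dtype)
        else:
            mask4 = np.ones_like(p4)
        d4 = p4 * mask4

        # stage 5: separable convolution + BN + ELU + pool + dropout
        K5 = cfg.separable_kernel_len
        lp, rp = K5 // 2, K5 - 1 - K5 // 2
        d4pad = np.pad(d4, ((0, 0), (0, 0), (lp, rp)))
        win5 = sliding_window_view(d4pad, K5, axis=2)  # (B, F, T1, K5)
        h5d = np.einsum("bftk,fk->bft", win5, p["W5d"], optimize=True)
        h5 = np.einsum("bft,gf->bgt", h5d, p["W5p"], optimize=True)
        h5n, bn5c = self._bn(h5, p["g5"], p["b5"], "5", (0, 2), train)
        e5 = _elu(h5n)
        G = cfg.separable_pointwise_out
        T2 = self.T2
        p5 = e5[:, :, : T2 * cfg.pool2].reshape(B, G, T2, cfg.pool2).mean(axis=3)
        if train:
            mask5 = ((rng.random(p5.shape) >= cfg.dropout_p) / (1.0 - cfg.dropout_p)).astype(self.dtype)
        else:
            mask5 = np.ones_like(p5)
        d5 = p5 * mask5

        # stage 6: flatten -> bias-free linear -> softmax
        flat = d5.reshape(B, -1)
        logits = flat @ p["W6"].T
        z = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(z)
        probs = ez / ez.sum(axis=1, keepdims=True)

        if not return_cache:
            return probs
        cache = dict(
            x=x, Xf=Xf, n1=n1, bn1c=bn1c, h1r=h1r, z2=z2, Z2f=Z2f, u=u, ui=ui, uj=uj,
            v=v, bn4c=bn4c, h4=h4, e4=e4, mask4=mask4, d4=d4, win5=win5, h5d=h5d,
            bn5c=bn5c, h5n=h5n, e5=e5, mask5=mask5, flat=flat, probs=probs,
            shapes=dict(z1=z1.shape, v=v.shape, u=u.shape),
        )
        return probs, cache

    # -- loss and gradients ------------------------------------------------

    def loss_and_grads(
        self, x: np.ndarray, y: np.ndarray, rng: np.random.Generator
    ) -> tuple[float, dict[str, np.ndarray]]:
        """Mean cross-entropy loss and gradients for a batch (training mode)."""
        cfg = self.config
        p = self.params
        probs, c = self.forward(x, train=True, rng=rng, return_cache=True)
        B = probs.shape[0]
        y = np.asarray(y, dtype=int)
        loss = -float(np.mean(np.log(probs[np.arange(B), y] + 1e-12)))

        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B

        g: dict[str, np.ndarray] = {}
        g["W6"] = dlogits.T @ c["flat"]
        dflat = dlogits @ p["W6"]
        G, T2, T1 = cfg.separable_pointwise_out, self.T2, self.T1
        dd5 = dflat.reshape(B, G, T2)
        dp5 = dd5 * c["mask5"]
        de5 = np.zeros_like(c["e5"])
        de5[:, :, : T2 * cfg.pool2] = np.repeat(dp5 / cfg.pool2, cfg.pool2, axis=2)
        dh5n = de5 * _elu_grad(c["h5n"], c["e5"])
        dh5, g["g5"], g["b5"] = self._bn_backward(dh5n, c["bn5c"])
        g["W5p"] = np.einsum("bgt,bft->gf", dh5, c["h5d"], optimize=True)
        dh5d = np.einsum("bgt,gf->bft", dh5, p["W5p"], optimize=True)
        g["W5d"] = np.einsum("bftk,bft->fk", c["win5"], dh5d, optimize=True)
        K5 = cfg.separable_kernel_len
        lp, rp = K5 // 2, K5 - 1 - K5 // 2
        gpad5 = np.pad(dh5d, ((0, 0), (0, 0), (rp, lp)))
        gwin5 = sliding_window_view(gpad5, K5, axis=2)
        dd4 = np.einsum("bftk,fk->bft", gwin5, p["W5d"][:, ::-1], optimize=True)

        dp4 = dd4 * c["mask4"]
        de4 = np.zeros_like(c["e4"])
        de4[:, :, : T1 * cfg.pool1] = np.repeat(dp4 / cfg.pool1, cfg.pool1, axis=2)
        dh4 = de4 * _elu_grad(c["h4"], c["e4"])
        ds, g["g4"], g["b4"] = self._bn_backward(dh4, c["bn4c"])
        g["W4"] = np.einsum("bfpt,bft->fp", c["v"], ds, optimize=True)
        dv = np.einsum("bft,fp->bfpt", ds, p["W4"], optimize=True)

        # product rule: each region feeds 9 pairs; gather per region
        dvuj = dv * c["uj"]
        dvui = dv * c["ui"]
        du = np.empty_like(c["u"])
        for r in range(cfg.n_regions):
            du[:, :, r, :] = dvuj[:, :, self._rows_i[r], :].sum(axis=2) + dvui[
                :, :, self._rows_j[r], :
            ].sum(axis=2)

        K1 = cfg.temporal_kernel_len
        T = self.window_len
        n1 = c["n1"]
        Duf = scipy.fft.rfft(du, n=n1)
        g["W2d"] = scipy.fft.irfft((np.conj(Duf) * c["Z2f"]).sum(axis=0), n=n1)[..., :K1]
        # upstream grad: correlate the (h1p-delayed) grad with the flipped kernel
        W2dflipf = scipy.fft.rfft(p["W2d"][:, :, ::-1], n=n1)
        dz2 = scipy.fft.irfft(np.conj(W2dflipf)[None] * (Duf * self._phase), n=n1)[..., :T]
        g["W2p"] = np.einsum("bfrst,bfrt->frs", c["h1r"], dz2, optimize=True)
        dh1r = np.einsum("bfrt,frs->bfrst", dz2, p["W2p"], optimize=True)
        dh1 = dh1r.reshape(c["shapes"]["z1"])
        dz1, g["g1"], g["b1"] = self._bn_backward(dh1, c["bn1c"])
        Dz1f = scipy.fft.rfft(dz1, n=n1)
        g["W1"] = scipy.fft.irfft(
            np.einsum("bfcm,bcm->fm", np.conj(Dz1f), c["Xf"], optimize=True), n=n1
        )[..., :K1]
        return loss, g

    def project_maxnorm(self) -> None:
        """Project spatial-filter rows back inside the max-norm ball."""
        W4 = self.params["W4"]
        norms = np.linalg.norm(W4, axis=1, keepdims=True)
        np.divide(W4, np.maximum(norms / self.config.maxnorm, 1.0), out=W4)


def build_model(
    config: ModelConfig, window_len: int = 320, seed: int = 0, dtype: type = np.float32
) -> InteractionDecoder:
    """Construct an interaction decoder for windows of ``window_len`` samples.

    ``dtype`` sets the arithmetic precision; single precision is the default
    (ample for SGD training), double is useful for gradient verification.
    """
    return InteractionDecoder(config, window_len, seed=seed, dtype=dtype)


def forward(model: InteractionDecoder, batch: np.ndarray) -> np.ndarray:
    """Evaluation-mode class probabilities ``(B, 2)`` for ``(B, 30, T)`` windows."""
    return model.forward(batch, train=False)


def extract_spatial_filters(model: InteractionDecoder, **meta) -> SpatialFilterSet:
    """The 4 x 45 depthwise spatial kernels, columns aligned to the pair index."""
    return SpatialFilterSet(
        filters=model.params["W4"].copy(), pair_index=model.pair_index, **meta
    )


def set_spatial_filters(model: InteractionDecoder, filters: np.ndarray) -> None:
    filters = np.asarray(filters, dtype=model.dtype)
    if filters.shape != model.params["W4"].shape:
        raise ValueError(f"expected shape {model.params['W4'].shape}, got {filters.shape}")
    model.params["W4"] = filters.copy()


def count_parameters(model: InteractionDecoder) -> int:
    """Total trainable scalars.

    Closed form per stage (defaults, T = 320): temporal kernels F*K1 = 124;
    BN1 affine 2*F = 8 (per-map scope); grouped pointwise F*10*3 = 120;
    depthwise temporal F*10*K1 = 1240; spatial filters F*45 = 180; BN4
    affine 2*F = 8; separable depthwise F*K5 = 64 and pointwise G*F = 16;
    BN5 affine 2*G = 8; classifier 2*G*T2 = 80 — total 1848.
    """
    return int(sum(v.size for v in model.params.values()))
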