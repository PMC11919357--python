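"""The segmentation-denoising network (ESDM).

A shared five-stage encoder feeds two task decoders. Stages 1-2 are strided
convolution blocks; stages 3-5 are separable convolutional transformer (SCT)
stages: a strided downsampling convolution followed by SCT blocks, each the
pre-norm composition of an SCT attention layer (query/key/value sequences
from pointwise + depthwise convolutions) and a depthwise feed-forward
network. The denoising decoder upsamples with stride-2 deconvolutions and
fuses squeeze-and-excitation-gated encoder skips through a depthwise-
separable projection; it is normalisation-free, following common practice in
image-restoration decoders. The segmentation decoder is a lightweight
cascade of bilinear upsamplings and per-pixel linear decoder blocks.

Ablation switches (``enable_denoise_decoder``, ``enable_seg_decoder``,
``use_skip``, ``use_se``) and the filter-size scalings reproduce every
variant of the reference complexity study from configuration alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .nn import (ChannelLayerNorm, Conv2d, ConvTranspose2d, Dense,
                 DepthwiseConv2d, InstanceNorm, LayerNorm, Module, SEBlock)

__all__ = [
    "ModelConfig", "ComplexityReport", "EsdmModel", "build_model",
    "count_parameters", "sct_qkv_projection", "multi_head_self_attention",
    "dw_ffn", "se_block", "linear_decoder_block",
    "DEFAULT_FILTERS", "SMOKE_FILTERS",
]

DEFAULT_FILTERS = (32, 64, 128, 256, 256)
SMOKE_FILTERS = (8, 16, 32, 64, 64)


@dataclass
class ModelConfig:
    """Architecture hyperparameters; the defaults are the reference build."""

    filter_sizes: tuple = DEFAULT_FILTERS
    sct_counts: tuple = (1, 2, 2)
    heads: tuple = (4, 8, 8)
    input_shape: tuple = (256, 256, 1)
    enable_denoise_decoder: bool = True
    enable_seg_decoder: bool = True
    use_skip: bool = True
    use_se: bool = True
    n_classes: int = 3
    seed: int = 0

    def __post_init__(self):
        self.filter_sizes = tuple(int(f) for f in self.filter_sizes)
        self.sct_counts = tuple(int(n) for n in self.sct_counts)
        self.heads = tuple(int(h) for h in self.heads)
        self.input_shape = tuple(int(s) for s in self.input_shape)
        if len(self.filter_sizes) != 5 or len(self.sct_counts) != 3 \
                or len(self.heads) != 3:
            raise ValueError("expect 5 filter sizes, 3 SCT counts, 3 head "
                             "counts")
        h, w = self.input_shape[0], self.input_shape[1]
        if h % 32 or w % 32:
            raise ValueError("input height/width must be divisible by 2^5")
        for fs, nh in zip(self.filter_sizes[2:], self.heads):
            if fs % nh:
                raise ValueError(f"channels {fs} not divisible by heads {nh}")
        if not (self.enable_denoise_decoder or self.enable_seg_decoder):
            raise ValueError("at least one decoder must be enabled")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ComplexityReport:
    trainable_parameters: int
    parameters_m: float
    breakdown: dict
    macs: int
    flops: int
    flops_convention: str = "1 multiply-add = 1 MAC = 2 FLOPs"
    input_shape: tuple = (256, 256, 1)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# functional building blocks (also exposed for unit testing)
# ---------------------------------------------------------------------------

def _flatten_hw(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, HW, C), row-major over (H, W)."""
    n, c = x.shape[0], x.shape[1]
    return ad.transpose(ad.reshape(x, (n, c, -1)), (0, 2, 1))


def _unflatten_hw(x: Tensor, h: int, w: int) -> Tensor:
    n, _, c = x.shape
    return ad.reshape(ad.transpose(x, (0, 2, 1)), (n, c, h, w))


class QkvProjection(Module):
    """Pointwise + depthwise convolution producing one attention sequence."""

    def __init__(self, c: int, rng):
        self.pw = Conv2d(c, c, 1, rng)
        self.dw = DepthwiseConv2d(c, 3, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return _flatten_hw(self.dw(self.pw(x)))


def sct_qkv_projection(x: Tensor, proj_q: QkvProjection,
                       proj_k: QkvProjection, proj_v: QkvProjection):
    """Generate Q, K, V sequences (HW x C) from an H x W x C feature map."""
    return proj_q(x), proj_k(x), proj_v(x)


def multi_head_self_attention(q: Tensor, k: Tensor, v: Tensor, heads: int,
                              out_proj: Dense | None = None,
                              return_attention: bool = False):
    """Scaled dot-product attention with channel-split heads.

    ``q, k, v`` are (N, HW, C); the per-head dimensionality C/heads is the
    softmax scaling dimensionality.
    """
    n, hw, c = q.shape
    if c % heads:
        raise ValueError(f"channels {c} not divisible by heads {heads}")
    dh = c // heads

    def split(t):
        return ad.transpose(ad.reshape(t, (n, hw, heads, dh)), (0, 2, 1, 3))

    qh, kh, vh = split(q), split(k), split(v)
    scores = ad.mul(ad.matmul(qh, ad.transpose(kh, (0, 1, 3, 2))),
                    1.0 / math.sqrt(dh))
    attn = ad.softmax(scores, axis=-1)
    out = ad.matmul(attn, vh)
    out = ad.reshape(ad.transpose(out, (0, 2, 1, 3)), (n, hw, c))
    if out_proj is not None:
        out = out_proj(out)
    if return_attention:
        return out, attn
    return out


class SCTLayer(Module):
    def __init__(self, c: int, heads: int, rng):
        self.proj_q = QkvProjection(c, rng)
        self.proj_k = QkvProjection(c, rng)
        self.proj_v = QkvProjection(c, rng)
        self.out_proj = Dense(c, c, rng)
        # residual branch starts at identity: attention switches on smoothly
        self.out_proj.weight.data[:] = 0.0
        self.heads = heads

    def __call__(self, x: Tensor) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        q, k, v = sct_qkv_projection(x, self.proj_q, self.proj_k, self.proj_v)
        y = multi_head_self_attention(q, k, v, self.heads, self.out_proj)
        return _unflatten_hw(y, h, w)


class DWFFN(Module):
    """Feed-forward with pointwise expansion (4C), depthwise 3x3, GeLU."""

    def __init__(self, c: int, rng):
        self.pw1 = Conv2d(c, 4 * c, 1, rng)
        self.dw = DepthwiseConv2d(4 * c, 3, rng)
        self.pw2 = Conv2d(4 * c, c, 1, rng)
        self.pw2.weight.data[:] = 0.0      # residual branch starts at identity

    def __call__(self, x: Tensor) -> Tensor:
        return self.pw2(ad.gelu(self.dw(self.pw1(x))))


def dw_ffn(x: Tensor, block: DWFFN) -> Tensor:
    return block(x)


def se_block(x: Tensor, block: SEBlock) -> Tensor:
    return block(x)


class SCTBlock(Module):
    """Pre-norm residual SCT layer + pre-norm residual DW-FFN."""

    def __init__(self, c: int, heads: int, rng):
        self.norm1 = ChannelLayerNorm(c)
        self.attn = SCTLayer(c, heads, rng)
        self.norm2 = ChannelLayerNorm(c)
        self.ffn = DWFFN(c, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = ad.add(x, self.attn(self.norm1(x)))
        return ad.add(x, self.ffn(self.norm2(x)))


class LinearDecoderBlock(Module):
    """Per-pixel two-layer projection: LP2(GeLU(LN(LP1(x))))."""

    def __init__(self, c: int, rng):
        if c % 2:
            raise ValueError("linear decoder block needs even channels")
        self.lp1 = Dense(c, c // 2, rng)
        self.norm = LayerNorm(c // 2)
        self.lp2 = Dense(c // 2, c, rng)

    def __call__(self, x: Tensor) -> Tensor:
        # x is NCHW; projections act on the channel axis per pixel
        y = ad.transpose(x, (0, 2, 3, 1))
        y = self.lp2(ad.gelu(self.norm(self.lp1(y))))
        return ad.transpose(y, (0, 3, 1, 2))


def linear_decoder_block(x: Tensor, block: LinearDecoderBlock) -> Tensor:
    return block(x)


# ---------------------------------------------------------------------------
# encoder / decoders
# ---------------------------------------------------------------------------

class _StemBlock(Module):
    """Stride-2 convolution block: down conv + refine conv, each LN + GeLU."""

    def __init__(self, cin: int, cout: int, rng):
        self.conv1 = Conv2d(cin, cout, 3, rng, stride=2)
        self.norm1 = InstanceNorm(cout)
        self.conv2 = Conv2d(cout, cout, 3, rng)
        self.norm2 = InstanceNorm(cout)

    def __call__(self, x: Tensor) -> Tensor:
        x = ad.gelu(self.norm1(self.conv1(x)))
        return ad.gelu(self.norm2(self.conv2(x)))


class _Downsample(Module):
    def __init__(self, cin: int, cout: int, rng):
        self.conv = Conv2d(cin, cout, 3, rng, stride=2)
        self.norm = InstanceNorm(cout)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.gelu(self.norm(self.conv(x)))


class Encoder(Module):
    def __init__(self, cfg: ModelConfig, rng):
        fs, counts, heads = cfg.filter_sizes, cfg.sct_counts, cfg.heads
        self.stem1 = _StemBlock(cfg.input_shape[2], fs[0], rng)
        self.stem2 = _StemBlock(fs[0], fs[1], rng)
        self.downs = []
        self.stages = []
        cin = fs[1]
        for i in range(3):
            self.downs.append(_Downsample(cin, fs[2 + i], rng))
            self.stages.append([SCTBlock(fs[2 + i], heads[i], rng)
                                for _ in range(counts[i])])
            cin = fs[2 + i]

    def __call__(self, x: Tensor) -> list[Tensor]:
        skips = []
        x = self.stem1(x)
        skips.append(x)
        x = self.stem2(x)
        skips.append(x)
        for down, blocks in zip(self.downs, self.stages):
            x = down(x)
            for blk in blocks:
                x = blk(x)
            skips.append(x)
        return skips                      # stages 1..5, last is bottleneck


class _SkipFusion(Module):
    """SE gate + depthwise-separable projection of an encoder skip."""

    def __init__(self, c_skip: int, c_dec: int, rng, use_se: bool):
        self.se = SEBlock(c_skip, rng) if use_se else None
        self.dw = DepthwiseConv2d(c_skip, 3, rng)
        self.pw = Conv2d(c_skip, c_dec, 1, rng)
        self.pw.weight.data[:] = 0.0       # fusion branch starts neutral

    def __call__(self, skip: Tensor, x: Tensor) -> Tensor:
        if self.se is not None:
            skip = self.se(skip)
        return ad.add(x, self.pw(self.dw(skip)))


class DenoiseDecoder(Module):
    """Five deconvolution stages; shallow stages mirror the two-conv stems."""

    REFINE = (1, 1, 1, 2, 2)

    def __init__(self, cfg: ModelConfig, rng):
        fs = cfg.filter_sizes
        outs = [fs[4], fs[3], fs[2], fs[1], fs[0]]
        skips = [fs[3], fs[2], fs[1], fs[0]]
        self.deconvs = []
        self.fusions = []
        self.refines = []
        cin = fs[4]
        for i, cout in enumerate(outs):
            self.deconvs.append(ConvTranspose2d(cin, cout, 3, rng))
            if cfg.use_skip and i < 4:
                self.fusions.append(_SkipFusion(skips[i], cout, rng,
                                                cfg.use_se))
            else:
                self.fusions.append(None)
            self.refines.append([Conv2d(cout, cout, 3, rng)
                                 for _ in range(self.REFINE[i])])
            cin = cout
        self.pre_head = Conv2d(fs[0], fs[0], 3, rng)
        self.head = Conv2d(fs[0], 1, 3, rng)
        self.head.weight.data[:] = 0.0     # neutral initial output

    def __call__(self, skips: list[Tensor]) -> Tensor:
        x = skips[-1]
        enc = [skips[3], skips[2], skips[1], skips[0]]
        for i, deconv in enumerate(self.deconvs):
            x = ad.gelu(deconv(x))
            if self.fusions[i] is not None:
                x = self.fusions[i](enc[i], x)
            for conv in self.refines[i]:
                x = ad.gelu(conv(x))
        x = ad.gelu(self.pre_head(x))
        return self.head(x)


class SegDecoder(Module):
    """Bilinear cascade of linear decoder blocks at a fixed narrow width.

    Encoder features of stages 1-3 are fused (added) into the cascade at
    their native resolutions, entirely parameter-free: the working width
    equals the stage-3 channel count, and narrower stages are aligned by
    zero-padding their channels (the classic parameter-free shortcut).
    """

    def __init__(self, cfg: ModelConfig, rng):
        fs = cfg.filter_sizes
        self.norm = ChannelLayerNorm(fs[4])
        self.reduce = Dense(fs[4], fs[2], rng)
        self.blocks = [LinearDecoderBlock(fs[2], rng) for _ in range(4)]
        self.head = Conv2d(fs[2], cfg.n_classes, 3, rng)
        # zero-init head: neutral initial logits, well-conditioned early steps
        self.head.weight.data[:] = 0.0
        self.width = fs[2]

    def _fuse(self, x: Tensor, skip: Tensor) -> Tensor:
        c = skip.shape[1]
        if c < self.width:
            zeros = Tensor(np.zeros(
                (skip.shape[0], self.width - c) + skip.shape[2:],
                dtype=skip.data.dtype))
            skip = ad.concat([skip, zeros], axis=1)
        return ad.add(x, skip)

    def __call__(self, skips: list[Tensor]) -> Tensor:
        x = self.norm(skips[-1])
        y = ad.transpose(x, (0, 2, 3, 1))
        x = ad.transpose(self.reduce(y), (0, 3, 1, 2))
        for i, blk in enumerate(self.blocks):
            x = ad.upsample_bilinear2x(x)
            if i >= 1:                    # stage 3, 2, 1 resolutions
                x = self._fuse(x, skips[3 - i])
            x = blk(x)
        # predict at the cascade's half resolution, then upsample the
        # logits: interpolated decisions suppress pixel-level speckle flicker
        return ad.upsample_bilinear2x(self.head(x))


class EsdmModel(Module):
    def __init__(self, cfg: ModelConfig):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.encoder = Encoder(cfg, rng)
        self.denoise_decoder = (DenoiseDecoder(cfg, rng)
                                if cfg.enable_denoise_decoder else None)
        self.seg_decoder = (SegDecoder(cfg, rng)
                            if cfg.enable_seg_decoder else None)

    def __call__(self, x: Tensor):
        """Forward pass: (N,1,H,W) -> (denoised (N,1,H,W) | None,
        logits (N,K,H,W) | None)."""
        skips = self.encoder(x)
        den = (self.denoise_decoder(skips)
               if self.denoise_decoder is not None else None)
        seg = (self.seg_decoder(skips)
               if self.seg_decoder is not None else None)
        return den, seg

    def predict(self, x: np.ndarray):
        """Inference on a numpy batch; denoised output clipped to [0, 1]."""
        with ad.no_grad():
            den, seg = self(Tensor(np.asarray(x, dtype=np.float32)))
        den_np = np.clip(den.data, 0.0, 1.0) if den is not None else None
        seg_np = seg.data if seg is not None else None
        return den_np, seg_np


def build_model(cfg: ModelConfig) -> EsdmModel:
    """Instantiate the network described by ``cfg`` (seeded weights)."""
    return EsdmModel(cfg)


# ---------------------------------------------------------------------------
# complexity accounting
# ---------------------------------------------------------------------------

def _conv_macs(cin, cout, k, h, w, groups=1):
    return k * k * (cin // groups) * cout * h * w


def _model_macs(cfg: ModelConfig) -> int:
    fs, counts, heads = cfg.filter_sizes, cfg.sct_counts, cfg.heads
    h, w = cfg.input_shape[0], cfg.input_shape[1]
    macs = 0
    # encoder
    res = [(h // 2 ** (i + 1), w // 2 ** (i + 1)) for i in range(5)]
    macs += _conv_macs(cfg.input_shape[2], fs[0], 3, *res[0])
    macs += _conv_macs(fs[0], fs[0], 3, *res[0])
    macs += _conv_macs(fs[0], fs[1], 3, *res[1])
    macs += _conv_macs(fs[1], fs[1], 3, *res[1])
    cin = fs[1]
    for i in range(3):
        c = fs[2 + i]
        hh, ww = res[2 + i]
        macs += _conv_macs(cin, c, 3, hh, ww)
        hw = hh * ww
        per_block = (3 * (_conv_macs(c, c, 1, hh, ww)
                          + _conv_macs(c, c, 3, hh, ww, groups=c))
                     + 2 * hw * hw * c          # QK^T and attn @ V
                     + hw * c * c               # output projection
                     + _conv_macs(c, 4 * c, 1, hh, ww)
                     + _conv_macs(4 * c, 4 * c, 3, hh, ww, groups=4 * c)
                     + _conv_macs(4 * c, c, 1, hh, ww))
        macs += counts[i] * per_block
        cin = c
    if cfg.enable_denoise_decoder:
        outs = [fs[4], fs[3], fs[2], fs[1], fs[0]]
        skips = [fs[3], fs[2], fs[1], fs[0]]
        dres = [res[3], res[2], res[1], res[0], (h, w)]
        cin = fs[4]
        for i, cout in enumerate(outs):
            hh, ww = dres[i]
            macs += _conv_macs(cin, cout, 3, hh, ww)
            if cfg.use_skip and i < 4:
                e = skips[i]
                if cfg.use_se:
                    macs += e * (e // 8) * 2
                macs += _conv_macs(e, e, 3, hh, ww, groups=e)
                macs += _conv_macs(e, cout, 1, hh, ww)
            macs += DenoiseDecoder.REFINE[i] * _conv_macs(cout, cout, 3,
                                                          hh, ww)
            cin = cout
        macs += _conv_macs(fs[0], fs[0], 3, h, w)
        macs += _conv_macs(fs[0], 1, 3, h, w)
    if cfg.enable_seg_decoder:
        c = fs[2]
        hh, ww = res[4]
        macs += fs[4] * c * hh * ww
        for i in range(4):
            hh, ww = hh * 2, ww * 2
            macs += (c * (c // 2) + (c // 2) * c) * hh * ww
        macs += _conv_macs(c, cfg.n_classes, 3, h, w)
    return int(macs)


def count_parameters(model: EsdmModel) -> ComplexityReport:
    """Exact trainable-parameter count with per-component breakdown and an
    analytic multiply-accumulate estimate for the configured input shape."""
    breakdown = {"encoder": model.encoder.n_parameters()}
    if model.denoise_decoder is not None:
        breakdown["denoise_decoder"] = model.denoise_decoder.n_parameters()
    if model.seg_decoder is not None:
        breakdown["seg_decoder"] = model.seg_decoder.n_parameters()
    total = model.n_parameters()
    assert total == sum(breakdown.values())
    macs = _model_macs(model.cfg)
    return ComplexityReport(
        trainable_parameters=total,
        parameters_m=round(total / 1e6, 3),
        breakdown=breakdown,
        macs=macs,
        flops=2 * macs,
        input_shape=tuple(model.cfg.input_shape),
    )
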