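"""The SGB-Net architecture.

Three cooperating branches over a shared residual backbone:

* **Backbone** — ResNet-style encoder (stem max-pool and classifier
  removed) producing side outputs β1, β2, β3 and deepest features α4 at
  strides {2, 4, 8, 16} with channels {64, 128, 256, 512}.
* **Feature-guided network** — the scale-adaptive (SA) module aggregates
  fine/medium/coarse kernels plus a global descriptor on α4; attention
  enhancement (AE) blocks then decode by gating low-level side outputs
  with channel attention derived from pooled low- and high-level
  descriptors.
* **Boundary network** — boundary refinement (BR) blocks compute a
  channel-aligned projection A(β), a sigmoid attention map τ and a
  residual refinement R(β) = Conv(τ) + A(β); stages cascade bottom-up
  over adjacent side outputs.

Because of poor semantic continuity at the deepest level, α4 feeds only
the SA module — never the AE low-level inputs or the boundary network.
The fused head T0, boundary head T1 and feature-guided head T2 are each
full-resolution probability maps.

Every block can return a trace of its intermediate quantities so each
formula is unit-testable in isolation.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field
from io import BytesIO
from typing import Optional

import numpy as np

from . import nn
from .nn import Tensor

VARIANTS = ("resnet", "bnet", "resnet_wsa", "resnet_wae", "fsnet", "sgbnet")

CHECKPOINT_SCHEMA = "sgbnet-checkpoint-v1"


class ValidationError(ValueError):
    pass


@dataclass
class ModelConfig:
    """Channel-width and depth configuration.

    Defaults give the full-size model; tests shrink the widths to keep
    toy forwards cheap.  ``blocks`` counts residual units per backbone
    stage (the classic 34-layer encoder uses (3, 4, 6, 3); the default
    keeps one per stage, which preserves every architectural contract at
    a fraction of the cost).
    """

    channels: tuple = (64, 128, 256, 512)
    blocks: tuple = (1, 1, 1, 1)
    sa_width: int = 64
    ae_widths: tuple = (256, 128, 64)
    br_width: int = 64
    fuse_width: int = 64
    use_bn: bool = True


@dataclass
class FeaturePyramid:
    beta1: Tensor
    beta2: Tensor
    beta3: Tensor
    alpha4: Tensor
    strides: tuple = (2, 4, 8, 16)
    channels: tuple = (64, 128, 256, 512)

    def levels(self):
        return (self.beta1, self.beta2, self.beta3, self.alpha4)


@dataclass
class ScaleAdaptiveTrace:
    beta5: Tensor
    delta3: Tensor
    delta1: Tensor
    gamma1: Tensor
    gamma3: Tensor
    gamma5: Tensor
    eta: Tensor
    mu: Tensor
    kappa: Tensor
    rho_g: Tensor
    rho: Tensor
    alpha_sa: Tensor


@dataclass
class AETrace:
    a_low: Tensor
    a_high: Tensor
    gate: Tensor
    gamma_out: Tensor
    eta_ae: Tensor


@dataclass
class BoundaryTrace:
    a_proj: Tensor = None
    tau: Tensor = None
    r_out: Tensor = None
    gamma_sum: Tensor = None
    gamma_y1: Tensor = None
    gamma_y2: Tensor = None
    eta_out: Tensor = None


@dataclass
class NetworkOutputs:
    t0: Tensor
    t1: Tensor
    t2: Tensor
    traces: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

class ConvBlock(nn.Module):
    """Conv → (BN) → optional ReLU; bias only when BN is off."""

    def __init__(self, cin, cout, kernel, rng, stride=1, relu=True,
                 use_bn=True, init_std=None):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, kernel, rng, stride=stride,
                              bias=not use_bn, init_std=init_std)
        self.bn = nn.BatchNorm2d(cout) if use_bn else nn.Identity()
        self.relu = relu

    def forward(self, x):
        x = self.bn(self.conv(x))
        return nn.relu(x) if self.relu else x


class BasicBlock(nn.Module):
    """Two 3×3 convolutions with an additive skip (1×1 when shapes change)."""

    def __init__(self, cin, cout, rng, stride=1, use_bn=True):
        super().__init__()
        self.conv1 = ConvBlock(cin, cout, 3, rng, stride=stride, use_bn=use_bn)
        self.conv2 = ConvBlock(cout, cout, 3, rng, relu=False, use_bn=use_bn)
        if stride != 1 or cin != cout:
            self.skip = ConvBlock(cin, cout, 1, rng, stride=stride,
                                  relu=False, use_bn=use_bn)
        else:
            self.skip = nn.Identity()

    def forward(self, x):
        return nn.relu(self.conv2(self.conv1(x)) + self.skip(x))


class Backbone(nn.Module):
    """Residual encoder without stem max-pool or classification head."""

    def __init__(self, rng, cfg: ModelConfig, n_stages: int = 4):
        super().__init__()
        c = cfg.channels
        self.n_stages = n_stages
        self.stem = ConvBlock(1, c[0], 7, rng, stride=2, use_bn=cfg.use_bn)
        self.stages = []
        cin = c[0]
        for i in range(n_stages):
            stride = 1 if i == 0 else 2
            blocks = [BasicBlock(cin, c[i], rng, stride=stride, use_bn=cfg.use_bn)]
            for _ in range(cfg.blocks[i] - 1):
                blocks.append(BasicBlock(c[i], c[i], rng, use_bn=cfg.use_bn))
            stage = nn.Sequential(*blocks)
            setattr(self, f"stage{i + 1}", stage)
            self.stages.append(stage)
            cin = c[i]

    def forward(self, x) -> FeaturePyramid:
        _check_divisible(x)
        feats = []
        h = self.stem(x)
        for stage in self.stages:
            h = stage(h)
            feats.append(h)
        while len(feats) < 4:
            feats.append(None)
        return FeaturePyramid(*feats[:4])


def _check_divisible(x, by=16):
    h, w = x.data.shape[2], x.data.shape[3]
    if h % by or w % by:
        raise ValidationError(
            f"input spatial size {h}x{w} must be divisible by {by}")


class ScaleAdaptive(nn.Module):
    """Multi-kernel aggregation with global-context fusion on α4.

    Fine (two 1×1), medium (two 3×3) and coarse (5×5) branches are
    aligned to α4's resolution, summed to η, used to reweight a 1×1
    projection μ of α4, concatenated to κ, and fused with an up-sampled
    global average descriptor ρ.
    """

    def __init__(self, cin, rng, width=64, use_bn=True):
        super().__init__()
        self.width = width
        bn = use_bn
        self.conv_b5 = ConvBlock(cin, width, 5, rng, use_bn=bn)
        self.conv_g3a = ConvBlock(width, width, 3, rng, use_bn=bn)
        self.conv_g3b = ConvBlock(width, width, 3, rng, use_bn=bn)
        self.conv_g1a = ConvBlock(width, width, 1, rng, use_bn=bn)
        self.conv_g1b = ConvBlock(width, width, 1, rng, use_bn=bn)
        self.conv_g5 = ConvBlock(width, width, 5, rng, use_bn=bn)
        self.conv_mu = ConvBlock(cin, width, 1, rng, relu=False, use_bn=bn)
        self.conv_rho = nn.Conv2d(cin, 4 * width, 1, rng)

    @property
    def out_channels(self):
        return 4 * self.width

    def forward(self, alpha4) -> ScaleAdaptiveTrace:
        h, w = alpha4.data.shape[2], alpha4.data.shape[3]
        beta5 = self.conv_b5(alpha4)
        delta3 = nn.max_pool2(beta5)
        gamma3 = self.conv_g3b(self.conv_g3a(delta3))
        delta1 = nn.max_pool2(gamma3)
        gamma1 = self.conv_g1b(self.conv_g1a(delta1))
        gamma5 = self.conv_g5(beta5)
        gamma1_up = nn.resize_bilinear(gamma1, h, w)
        gamma3_up = nn.resize_bilinear(gamma3, h, w)
        eta = gamma1_up + gamma3_up + gamma5
        mu = self.conv_mu(alpha4) * eta
        kappa = nn.concat([gamma1_up, gamma3_up, gamma5, mu], axis=1)
        rho_g = nn.global_avg_pool(alpha4)
        rho = nn.resize_bilinear(self.conv_rho(rho_g), h, w)
        alpha_sa = kappa + rho
        return ScaleAdaptiveTrace(beta5, delta3, delta1, gamma1_up, gamma3_up,
                                  gamma5, eta, mu, kappa, rho_g, rho, alpha_sa)


class AEBlock(nn.Module):
    """Channel-attention decoder block.

    Gates a 3×3 reduction of the low-level side output with a sigmoid of
    summed pooled descriptors (average-pooled low, max-pooled high), then
    fuses with the up-sampled high-level input and up-samples once more.
    """

    def __init__(self, c_low, c_high, width, rng, use_bn=True):
        super().__init__()
        self.width = width
        self.conv_low_desc = nn.Conv2d(c_low, width, 1, rng)
        self.conv_high_desc = nn.Conv2d(c_high, width, 1, rng)
        self.conv_gate = nn.Conv2d(width, width, 1, rng)
        self.conv_low = ConvBlock(c_low, width, 3, rng, use_bn=use_bn)
        self.conv_high_proj = nn.Conv2d(c_high, width, 1, rng)

    def forward(self, beta_low, high, fuse_high=None, force_gate=None) -> AETrace:
        """`high` drives the attention descriptor (αSA for the first
        block, the previous γout afterwards); `fuse_high` is the feature
        map fused into ηAE (αSA for the first block, the previous ηAE
        afterwards — they share channel width by construction)."""
        if fuse_high is None:
            fuse_high = high
        hl, wl = beta_low.data.shape[2], beta_low.data.shape[3]
        hh, wh = high.data.shape[2], high.data.shape[3]
        if (hl, wl) != (2 * hh, 2 * wh):
            raise ValidationError(
                f"AE block expects adjacent levels: low {hl}x{wl} vs "
                f"high {hh}x{wh}")
        a_low = nn.relu(self.conv_low_desc(nn.global_avg_pool(beta_low)))
        a_high = nn.relu(self.conv_high_desc(nn.global_max_pool(high)))
        gate = nn.sigmoid(self.conv_gate(a_low + a_high))
        if force_gate is not None:   # test hook (bias → ±inf limit)
            gate = Tensor(np.full_like(gate.data, force_gate))
        gamma_out = gate * self.conv_low(beta_low)
        fused = nn.resize_bilinear(self.conv_high_proj(fuse_high), hl, wl)
        eta_ae = nn.resize_bilinear(gamma_out + fused, 2 * hl, 2 * wl)
        return AETrace(a_low, a_high, gate, gamma_out, eta_ae)


class BRBlock(nn.Module):
    """Boundary refinement: A(β) = Conv1×1(β), τ = σ(BN(Conv3×3(A))),
    R(β) = Conv3×3(τ) + A(β).

    Batch norm follows the projection and refinement convolutions too
    (configurable), which keeps the cascaded feature products bounded;
    a zeroed refinement convolution still reproduces A(β) exactly since
    BN maps an all-zero input to zero under fresh statistics.
    """

    def __init__(self, cin, width, rng, use_bn=True):
        super().__init__()
        self.proj = ConvBlock(cin, width, 1, rng, relu=False, use_bn=use_bn)
        self.conv_tau = nn.Conv2d(width, width, 3, rng)
        self.bn_tau = nn.BatchNorm2d(width)
        self.refine = ConvBlock(width, width, 3, rng, relu=False, use_bn=use_bn)

    def forward(self, beta_i) -> BoundaryTrace:
        a_proj = self.proj(beta_i)
        tau = nn.sigmoid(self.bn_tau(self.conv_tau(a_proj)))
        r_out = self.refine(tau) + a_proj
        return BoundaryTrace(a_proj=a_proj, tau=tau, r_out=r_out)


class BoundaryStage(nn.Module):
    """One cascade stage over adjacent refined features.

    γsum = up(r_deep) ⊕ r_shallow, γy1 = r_shallow ⊗ γsum,
    γy2 = r_deep ⊗ down(γsum), ηout = R(Concat{γy1, up(γy2)}).
    """

    def __init__(self, width, rng, use_bn=True):
        super().__init__()
        self.refine = BRBlock(2 * width, width, rng, use_bn=use_bn)

    def forward(self, r_shallow, r_deep) -> BoundaryTrace:
        hs, ws = r_shallow.data.shape[2], r_shallow.data.shape[3]
        hd, wd = r_deep.data.shape[2], r_deep.data.shape[3]
        if (hs, ws) != (2 * hd, 2 * wd):
            raise ValidationError(
                f"boundary stage expects adjacent resolutions, got shallow "
                f"{hs}x{ws} vs deep {hd}x{wd}")
        gamma_sum = nn.resize_bilinear(r_deep, hs, ws) + r_shallow
        gamma_y1 = r_shallow * gamma_sum
        gamma_y2 = r_deep * nn.max_pool2(gamma_sum)
        cat = nn.concat([gamma_y1, nn.resize_bilinear(gamma_y2, hs, ws)], axis=1)
        inner = self.refine(cat)
        return BoundaryTrace(a_proj=inner.a_proj, tau=inner.tau,
                             r_out=inner.r_out, gamma_sum=gamma_sum,
                             gamma_y1=gamma_y1, gamma_y2=gamma_y2,
                             eta_out=inner.r_out)


class BoundaryNetwork(nn.Module):
    """Bottom-up cascade over side outputs β1..β3 (α4 is never used).

    Stage 1 combines R(β1) with R(β2); stage 2 combines R(β2) with
    R(β3); stage 3 combines the two stage outputs — the only adjacency-
    consistent three-stage chain over three side outputs.  The final
    output sits at β1's resolution.
    """

    def __init__(self, channels, width, rng, use_bn=True):
        super().__init__()
        c1, c2, c3 = channels[:3]
        self.br1 = BRBlock(c1, width, rng, use_bn=use_bn)
        self.br2 = BRBlock(c2, width, rng, use_bn=use_bn)
        self.br3 = BRBlock(c3, width, rng, use_bn=use_bn)
        self.stage1 = BoundaryStage(width, rng, use_bn=use_bn)
        self.stage2 = BoundaryStage(width, rng, use_bn=use_bn)
        self.stage3 = BoundaryStage(width, rng, use_bn=use_bn)

    def forward(self, pyramid: FeaturePyramid):
        t1 = self.br1(pyramid.beta1)
        t2 = self.br2(pyramid.beta2)
        t3 = self.br3(pyramid.beta3)
        s1 = self.stage1(t1.r_out, t2.r_out)
        s2 = self.stage2(t2.r_out, t3.r_out)
        s3 = self.stage3(s1.eta_out, s2.eta_out)
        return s3.eta_out, [t1, t2, t3, s1, s2, s3]


class FuseHeads(nn.Module):
    """EQ = up(γout_last + ηAE_last + ηout_last) and the three heads.

    The three inputs are 1×1-projected to a common width, bilinearly
    aligned to the finest resolution among them, summed, and classified;
    each head is σ(Conv1×1(·)) up-sampled to the target shape.  Head
    weights start near zero so an untrained network is maximally
    uncertain (≈ 0.5) everywhere.
    """

    HEAD_INIT_STD = 0.01

    def __init__(self, c_gamma, c_eta_ae, c_eta_out, width, rng):
        super().__init__()
        self.proj_gamma = nn.Conv2d(c_gamma, width, 1, rng)
        self.proj_ae = nn.Conv2d(c_eta_ae, width, 1, rng)
        self.proj_bd = nn.Conv2d(c_eta_out, width, 1, rng)
        self.head_t0 = nn.Conv2d(width, 1, 1, rng, init_std=self.HEAD_INIT_STD)
        self.head_t1 = nn.Conv2d(c_eta_out, 1, 1, rng, init_std=self.HEAD_INIT_STD)
        self.head_t2 = nn.Conv2d(c_eta_ae, 1, 1, rng, init_std=self.HEAD_INIT_STD)

    def forward(self, gamma_out_last, eta_ae_last, eta_out_last, target_shape):
        th, tw = target_shape
        parts = [self.proj_gamma(gamma_out_last),
                 self.proj_ae(eta_ae_last),
                 self.proj_bd(eta_out_last)]
        fh = max(p.data.shape[2] for p in parts)
        fw = max(p.data.shape[3] for p in parts)
        aligned = [nn.resize_bilinear(p, fh, fw) for p in parts]
        eq = aligned[0] + aligned[1] + aligned[2]
        t0 = nn.resize_bilinear(nn.sigmoid(self.head_t0(eq)), th, tw)
        t1 = nn.resize_bilinear(nn.sigmoid(self.head_t1(eta_out_last)), th, tw)
        t2 = nn.resize_bilinear(nn.sigmoid(self.head_t2(eta_ae_last)), th, tw)
        return t0, t1, t2, eq


class PlainDecoder(nn.Module):
    """Baseline decoder: 1×1-project every pyramid level, align to the
    shallowest resolution, sum, refine with one 3×3, classify."""

    HEAD_INIT_STD = 0.01

    def __init__(self, in_channels, width, rng, use_bn=True):
        super().__init__()
        self.projs = []
        for i, c in enumerate(in_channels):
            proj = nn.Conv2d(c, width, 1, rng)
            setattr(self, f"proj{i}", proj)
            self.projs.append(proj)
        self.refine = ConvBlock(width, width, 3, rng, use_bn=use_bn)
        self.head = nn.Conv2d(width, 1, 1, rng, init_std=self.HEAD_INIT_STD)

    def forward(self, feats, target_shape):
        th, tw = target_shape
        fh = max(f.data.shape[2] for f in feats)
        fw = max(f.data.shape[3] for f in feats)
        acc = None
        for proj, f in zip(self.projs, feats):
            p = nn.resize_bilinear(proj(f), fh, fw)
            acc = p if acc is None else acc + p
        out = nn.sigmoid(self.head(self.refine(acc)))
        return nn.resize_bilinear(out, th, tw)


# ---------------------------------------------------------------------------
# the full model
# ---------------------------------------------------------------------------

class SGBNet(nn.Module):
    """Configurable three-branch segmentation network.

    ``variant`` selects the ablation wiring:

    * ``resnet`` — backbone + plain decoder.
    * ``bnet`` — backbone (3 stages) + boundary network.
    * ``resnet_wsa`` — backbone + SA module + plain decoder.
    * ``resnet_wae`` — backbone + AE decoder (high input = α4).
    * ``fsnet`` — backbone + SA + AE (the feature-guided network).
    * ``sgbnet`` — feature-guided + boundary networks with fused heads.
    """

    HEAD_INIT_STD = 0.01

    def __init__(self, variant="sgbnet", seed=0, config: ModelConfig = None,
                 pretrained=False):
        super().__init__()
        if variant not in VARIANTS:
            raise ValidationError(
                f"unknown variant {variant!r}; choose from {VARIANTS}")
        self.variant = variant
        self.seed = seed
        self.config = cfg = config or ModelConfig()
        rng = np.random.default_rng(seed)
        c = cfg.channels

        n_stages = 3 if variant == "bnet" else 4
        self.backbone = Backbone(rng, cfg, n_stages=n_stages)

        self.sa = None
        self.ae_blocks = []
        self.boundary = None
        self.decoder = None
        self.fuse = None

        if variant in ("resnet_wsa", "fsnet", "sgbnet"):
            self.sa = ScaleAdaptive(c[3], rng, width=cfg.sa_width,
                                    use_bn=cfg.use_bn)
        if variant in ("resnet_wae", "fsnet", "sgbnet"):
            c_high0 = self.sa.out_channels if self.sa is not None else c[3]
            lows = (c[2], c[1], c[0])
            highs = (c_high0, cfg.ae_widths[0], cfg.ae_widths[1])
            for i, (cl, ch, wd) in enumerate(zip(lows, highs, cfg.ae_widths)):
                blk = AEBlock(cl, ch, wd, rng, use_bn=cfg.use_bn)
                setattr(self, f"ae{i + 1}", blk)
                self.ae_blocks.append(blk)
        if variant in ("bnet", "sgbnet"):
            self.boundary = BoundaryNetwork(c, cfg.br_width, rng,
                                            use_bn=cfg.use_bn)

        if variant in ("resnet", "resnet_wsa"):
            in_ch = list(c[:3]) + [self.sa.out_channels if self.sa else c[3]]
            self.decoder = PlainDecoder(in_ch, cfg.fuse_width, rng,
                                        use_bn=cfg.use_bn)
        elif variant in ("resnet_wae", "fsnet"):
            self.head_t2 = nn.Conv2d(cfg.ae_widths[-1], 1, 1, rng,
                                     init_std=self.HEAD_INIT_STD)
        elif variant == "bnet":
            self.head_t0 = nn.Conv2d(cfg.br_width, 1, 1, rng,
                                     init_std=self.HEAD_INIT_STD)
            self.head_t1 = nn.Conv2d(cfg.br_width, 1, 1, rng,
                                     init_std=self.HEAD_INIT_STD)
        else:  # sgbnet
            self.fuse = FuseHeads(cfg.ae_widths[-1], cfg.ae_widths[-1],
                                  cfg.br_width, cfg.fuse_width, rng)

        if pretrained:
            self._load_pretrained()

    # -- pretrained stem (optional, never required) --------------------
    def _load_pretrained(self):
        """Adapt ImageNet weights when a torchvision install provides
        them; silently keep the seeded initialisation otherwise.  The
        RGB stem filters are summed to accept 1-channel input."""
        try:  # pragma: no cover - exercised only where torch exists
            import torch  # noqa: F401
            from torchvision.models import resnet34
            ref = resnet34(weights="IMAGENET1K_V1")
            stem_w = ref.conv1.weight.detach().numpy().sum(axis=1, keepdims=True)
            if stem_w.shape == self.backbone.stem.conv.weight.data.shape:
                self.backbone.stem.conv.weight.data = stem_w.astype(np.float32)
        except Exception:
            pass

    # -- forward --------------------------------------------------------
    def forward(self, x, return_traces=False) -> NetworkOutputs:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        if x.ndim == 2:
            x = nn.reshape(x, (1, 1) + x.data.shape)
        elif x.ndim == 3:
            x = nn.reshape(x, (x.data.shape[0], 1) + x.data.shape[1:])
        _check_divisible(x)
        target = (x.data.shape[2], x.data.shape[3])
        traces = {}
        pyr = self.backbone(x)

        sa_trace = None
        high = pyr.alpha4
        if self.sa is not None:
            sa_trace = self.sa(pyr.alpha4)
            high = sa_trace.alpha_sa
            if return_traces:
                traces["sa"] = sa_trace

        ae_traces = []
        if self.ae_blocks:
            lows = (pyr.beta3, pyr.beta2, pyr.beta1)
            fuse_high = high
            for blk, low in zip(self.ae_blocks, lows):
                tr = blk(low, high, fuse_high)
                ae_traces.append(tr)
                high = tr.gamma_out
                fuse_high = tr.eta_ae
            if return_traces:
                traces["ae"] = ae_traces

        eta_out_last = None
        if self.boundary is not None:
            eta_out_last, br_traces = self.boundary(pyr)
            if return_traces:
                traces["br"] = br_traces

        v = self.variant
        if v in ("resnet", "resnet_wsa"):
            feats = [pyr.beta1, pyr.beta2, pyr.beta3,
                     sa_trace.alpha_sa if sa_trace else pyr.alpha4]
            t0 = self.decoder(feats, target)
            t1 = t2 = t0
        elif v in ("resnet_wae", "fsnet"):
            t2 = nn.resize_bilinear(
                nn.sigmoid(self.head_t2(ae_traces[-1].eta_ae)), *target)
            t0 = t1 = t2
        elif v == "bnet":
            t0 = nn.resize_bilinear(
                nn.sigmoid(self.head_t0(eta_out_last)), *target)
            t1 = nn.resize_bilinear(
                nn.sigmoid(self.head_t1(eta_out_last)), *target)
            t2 = t0
        else:  # sgbnet
            t0, t1, t2, eq = self.fuse(ae_traces[-1].gamma_out,
                                       ae_traces[-1].eta_ae,
                                       eta_out_last, target)
            if return_traces:
                traces["eq"] = eq
        return NetworkOutputs(t0=t0, t1=t1, t2=t2, traces=traces)

    # -- checkpointing --------------------------------------------------
    def save_checkpoint(self, path):
        """Single zip archive: JSON metadata + one .npy per array."""
        meta = {
            "schema": CHECKPOINT_SCHEMA,
            "variant": self.variant,
            "seed": self.seed,
            "config": {
                "channels": list(self.config.channels),
                "blocks": list(self.config.blocks),
                "sa_width": self.config.sa_width,
                "ae_widths": list(self.config.ae_widths),
                "br_width": self.config.br_width,
                "fuse_width": self.config.fuse_width,
                "use_bn": self.config.use_bn,
            },
        }
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("meta.json", json.dumps(meta, sort_keys=True))
            for key, arr in self.state_dict().items():
                buf = BytesIO()
                np.save(buf, arr)
                zf.writestr(f"arrays/{key}.npy", buf.getvalue())

    @classmethod
    def load_checkpoint(cls, path, variant=None):
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            if meta.get("schema") != CHECKPOINT_SCHEMA:
                raise ValidationError(
                    f"unsupported checkpoint schema {meta.get('schema')!r}")
            if variant is not None and meta["variant"] != variant:
                raise ValidationError(
                    f"checkpoint stores variant {meta['variant']!r}, "
                    f"requested {variant!r}")
            cfgd = meta["config"]
            cfg = ModelConfig(
                channels=tuple(cfgd["channels"]), blocks=tuple(cfgd["blocks"]),
                sa_width=cfgd["sa_width"], ae_widths=tuple(cfgd["ae_widths"]),
                br_width=cfgd["br_width"], fuse_width=cfgd["fuse_width"],
                use_bn=cfgd["use_bn"])
            model = cls(variant=meta["variant"], seed=meta["seed"], config=cfg)
            state = {}
            for name in zf.namelist():
                if name.startswith("arrays/"):
                    key = name[len("arrays/"):-len(".npy")]
                    state[key] = np.load(BytesIO(zf.read(name)))
            model.load_state_dict(state)
        return model


# -- functional entry points ------------------------------------------------

def backbone_forward(image, pretrained=False, seed=0,
                     config: ModelConfig = None) -> FeaturePyramid:
    """Run only the encoder on a 1×H×W (or N×1×H×W) image."""
    cfg = config or ModelConfig()
    rng = np.random.default_rng(seed)
    bb = Backbone(rng, cfg)
    x = image if isinstance(image, Tensor) else Tensor(np.asarray(image))
    if x.ndim == 2:
        x = nn.reshape(x, (1, 1) + x.data.shape)
    elif x.ndim == 3:
        x = nn.reshape(x, (1,) + x.data.shape)
    return bb(x)
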