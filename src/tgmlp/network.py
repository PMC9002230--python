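"""The two-branch TGMLP U-Net: stem, encoders, decoders, fusion, accountant.

Layout
------
A three-convolution stem extracts initial features at full resolution.  Two
branches then run in parallel:

* the **global branch** (2 encoders / 2 decoders) sees the whole map and
  models long-range structure at moderate depth;
* the **local branch** splits the stem output into a ``local_patch_grid`` x
  ``local_patch_grid`` grid of patches and runs a deeper 5-encoder /
  5-decoder pyramid on every patch with shared parameters, recovering fine
  detail the global branch smooths over.

Each encoder is ``conv(stride) -> TGMLP block -> 1x1 conv -> +residual``;
each decoder is ``3x3 conv -> transposed conv (x2) -> +skip``.  Branch
outputs are added and a 1x1 convolution produces per-pixel class scores.

The reference configuration's channel widths are not dictated by the
architecture; they were fixed once so that the learnable-parameter count and
the multiply-accumulate count at 128x128 land on the published budget of the
model (3.03 M parameters, 1.9 G MACs), which is the only width evidence
available.  All widths, partition sizes and ablation switches are exposed in
:class:`NetworkConfig`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from . import autodiff as ad
from .lgp import TGMLPBlock, LP_KERNELS


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class StageConfig:
    """One encoder stage: width, stride, partition count and ablation switches."""

    channels: int
    downsample: int = 2
    partition_h: int = 2
    use_tm: bool = True
    use_lgp: bool = True
    use_gate: bool = True

    def validate(self):
        if self.channels < 1:
            raise ValueError("stage channels must be positive")
        if self.downsample not in (1, 2):
            raise ValueError("downsample must be 1 or 2")
        if self.partition_h < 1:
            raise ValueError("partition_h must be positive")


@dataclass
class NetworkConfig:
    in_channels: int = 1
    stem_channels: int = 24
    global_stages: list[StageConfig] = field(default_factory=list)
    local_stages: list[StageConfig] = field(default_factory=list)
    local_patch_grid: int = 4
    num_classes: int = 2
    input_size: int = 128
    bn_eps: float = 1e-6
    bn_momentum: float = 0.1

    def validate(self):
        if len(self.global_stages) != 2:
            raise ValueError("global branch must have exactly 2 stages")
        if len(self.local_stages) != 5:
            raise ValueError("local branch must have exactly 5 stages")
        for st in self.global_stages + self.local_stages:
            st.validate()
        if self.input_size % self.local_patch_grid:
            raise ValueError("input size must be divisible by the patch grid")
        for extent, st in zip(self.global_extents(), self.global_stages):
            if st.use_lgp and extent % st.partition_h:
                raise ValueError(
                    f"global stage extent {extent} not divisible by partition_h "
                    f"{st.partition_h}")
        for extent, st in zip(self.local_extents(), self.local_stages):
            if extent < 1:
                raise ValueError("local pyramid downsamples below 1 pixel")
            if st.use_lgp and extent % st.partition_h:
                raise ValueError(
                    f"local stage extent {extent} not divisible by partition_h "
                    f"{st.partition_h}")

    # -- extent bookkeeping -------------------------------------------------
    def global_extents(self, input_size: int | None = None) -> list[int]:
        e = input_size or self.input_size
        out = []
        for st in self.global_stages:
            if e % st.downsample:
                raise ValueError(f"extent {e} not divisible by stride {st.downsample}")
            e //= st.downsample
            out.append(e)
        return out

    def local_extents(self, input_size: int | None = None) -> list[int]:
        e = (input_size or self.input_size) // self.local_patch_grid
        out = []
        for st in self.local_stages:
            if e % st.downsample:
                raise ValueError(f"extent {e} not divisible by stride {st.downsample}")
            e //= st.downsample
            out.append(e)
        return out

    # -- (de)serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        d["global_stages"] = [StageConfig(**s) for s in d.get("global_stages", [])]
        d["local_stages"] = [StageConfig(**s) for s in d.get("local_stages", [])]
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


REFERENCE_GLOBAL_CHANNELS = (32, 80)
REFERENCE_LOCAL_CHANNELS = (24, 48, 64, 64, 64)
REFERENCE_LOCAL_DOWNSAMPLE = (2, 2, 2, 2, 1)


def reference_config(input_size: int = 128, *, use_tm: bool = True,
                     use_lgp: bool = True, use_gate: bool = True) -> NetworkConfig:
    """The reference TGMLP U-Net configuration at a given input size.

    Partition counts are chosen per stage so partitions are 2x2 at 128x128
    (clamped to the full extent at smaller sizes). The three boolean switches
    give the ablation lattice: backbone only, +TM, +TM+LGP, +TM+LGP+GM.
    """
    cfg = NetworkConfig(input_size=input_size)
    cfg.global_stages = [StageConfig(channels=c) for c in REFERENCE_GLOBAL_CHANNELS]
    cfg.local_stages = [
        StageConfig(channels=c, downsample=d)
        for c, d in zip(REFERENCE_LOCAL_CHANNELS, REFERENCE_LOCAL_DOWNSAMPLE)]
    for st, extent in zip(cfg.global_stages, cfg.global_extents()):
        st.partition_h = max(extent // 2, 1)
    for st, extent in zip(cfg.local_stages, cfg.local_extents()):
        st.partition_h = max(extent // 2, 1)
    for st in cfg.global_stages + cfg.local_stages:
        st.use_tm, st.use_lgp, st.use_gate = use_tm, use_lgp, use_gate
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class ConvBNReLU(nn.Module):
    def __init__(self, c_in, c_out, kernel=3, stride=1, padding=1, *,
                 rng, bn_eps=1e-6, bn_momentum=0.1):
        super().__init__()
        self.conv = nn.Conv2d(c_in, c_out, kernel, stride, padding, rng=rng)
        self.bn = nn.BatchNorm2d(c_out, eps=bn_eps, momentum=bn_momentum)

    def forward(self, x):
        return ad.relu(self.bn(self.conv(x)))


class Stem(nn.Module):
    """Three 3x3 conv+BN+ReLU layers at full resolution."""

    def __init__(self, c_in, c_out, *, rng, bn_eps=1e-6, bn_momentum=0.1):
        super().__init__()
        self.layers = nn.ModuleList(
            ConvBNReLU(c_in if i == 0 else c_out, c_out, rng=rng,
                       bn_eps=bn_eps, bn_momentum=bn_momentum)
            for i in range(3))

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Encoder(nn.Module):
    """conv(stride) -> TGMLP block -> 1x1 conv -> residual add."""

    def __init__(self, c_in, stage: StageConfig, extent: int, *, rng,
                 bn_eps=1e-6, bn_momentum=0.1):
        super().__init__()
        c = stage.channels
        self.pre = ConvBNReLU(c_in, c, stride=stage.downsample, rng=rng,
                              bn_eps=bn_eps, bn_momentum=bn_momentum)
        self.has_block = stage.use_tm or stage.use_lgp
        if self.has_block:
            self.block = TGMLPBlock(
                c, extent, extent, stage.partition_h,
                use_tm=stage.use_tm, use_lgp=stage.use_lgp, use_gate=stage.use_gate,
                rng=rng, bn_eps=bn_eps, bn_momentum=bn_momentum)
        self.proj = nn.Conv2d(c, c, 1, rng=rng)

    def forward(self, x):
        y = self.pre(x)
        t = self.block(y) if self.has_block else y
        return self.proj(t) + y


class Decoder(nn.Module):
    """3x3 conv (channel reduction) -> optional x2 deconvolution -> +skip."""

    def __init__(self, c_in, c_out, upsample: bool, *, rng,
                 bn_eps=1e-6, bn_momentum=0.1):
        super().__init__()
        self.conv = ConvBNReLU(c_in, c_out, rng=rng, bn_eps=bn_eps,
                               bn_momentum=bn_momentum)
        self.upsample = upsample
        if upsample:
            self.up = nn.ConvTranspose2x2(c_out, c_out, rng=rng)

    def forward(self, x, skip):
        y = self.conv(x)
        if self.upsample:
            y = self.up(y)
        if y.shape != skip.shape:
            raise ValueError(
                f"decoder skip mismatch: got {skip.shape}, expected {y.shape}")
        return y + skip


class _Branch(nn.Module):
    """A symmetric encoder/decoder pyramid with skip connections."""

    def __init__(self, c_in, stages: list[StageConfig], extents: list[int], *,
                 rng, bn_eps, bn_momentum):
        super().__init__()
        self.encoders = nn.ModuleList()
        c_prev = c_in
        for st, extent in zip(stages, extents):
            self.encoders.append(Encoder(c_prev, st, extent, rng=rng,
                                         bn_eps=bn_eps, bn_momentum=bn_momentum))
            c_prev = st.channels
        self.decoders = nn.ModuleList()
        channels = [c_in] + [st.channels for st in stages]
        ups = [st.downsample == 2 for st in stages]
        for i in range(len(stages), 0, -1):
            self.decoders.append(Decoder(channels[i], channels[i - 1], ups[i - 1],
                                         rng=rng, bn_eps=bn_eps,
                                         bn_momentum=bn_momentum))

    def forward(self, x):
        skips = [x]
        for enc in self.encoders:
            x = enc(x)
            skips.append(x)
        for i, dec in enumerate(self.decoders):
            x = dec(x, skips[len(self.encoders) - 1 - i])
        return x


class LocalBranch(nn.Module):
    """Patch-parallel pyramid: grid^2 patches, shared parameters, re-stitched."""

    def __init__(self, c_in, stages, extents, grid: int, *, rng, bn_eps, bn_momentum):
        super().__init__()
        self.grid = grid
        self.pyramid = _Branch(c_in, stages, extents, rng=rng,
                               bn_eps=bn_eps, bn_momentum=bn_momentum)

    def forward(self, x):
        n, c, H, W = x.shape
        g = self.grid
        if H % g or W % g:
            raise ValueError(f"extent ({H},{W}) not divisible by patch grid {g}")
        ph, pw = H // g, W // g
        folded = (x.reshape((n, c, g, ph, g, pw))
                   .transpose((0, 2, 4, 1, 3, 5))
                   .reshape((n * g * g, c, ph, pw)))
        out = self.pyramid(folded)
        return (out.reshape((n, g, g, c, ph, pw))
                   .transpose((0, 3, 1, 4, 2, 5))
                   .reshape((n, c, H, W)))


class TGMLPUNet(nn.Module):
    """Full model: stem -> {global, local} -> add -> 1x1 classifier."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        super().__init__()
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)
        kw = dict(bn_eps=config.bn_eps, bn_momentum=config.bn_momentum)
        s = config.stem_channels
        self.stem = Stem(config.in_channels, s, rng=rng, **kw)
        self.global_branch = _Branch(s, config.global_stages,
                                     config.global_extents(), rng=rng, **kw)
        self.local_branch = LocalBranch(s, config.local_stages,
                                        config.local_extents(),
                                        config.local_patch_grid, rng=rng, **kw)
        self.classifier = nn.Conv2d(s, config.num_classes, 1, rng=rng)

    def forward(self, x):
        feats = self.stem(ad.as_tensor(x))
        fused = self.global_branch(feats) + self.local_branch(feats)
        return self.classifier(fused)

    def gates(self) -> list[tuple[str, str, np.ndarray]]:
        """(branch, stage, [g_c, g_h, g_w]) for every learnable gate vector."""
        rows = []
        for branch_name, branch in (("global", self.global_branch),
                                    ("local", self.local_branch.pyramid)):
            for i, enc in enumerate(branch.encoders):
                if enc.has_block and enc.block.use_tm and enc.block.core.gates.learnable:
                    rows.append((branch_name, f"encoder{i + 1}",
                                 enc.block.core.gates.numpy()))
        return rows


# ---------------------------------------------------------------------------
# budget accountant
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelBudget:
    parameters: int
    macs: int

    @property
    def params_m(self) -> float:
        return self.parameters / 1e6

    @property
    def flops_g(self) -> float:
        """MACs in units of 1e9, the '1 MAC = 1 FLOP' reporting convention."""
        return self.macs / 1e9


def count_parameters(config: NetworkConfig) -> int:
    """Exact learnable-scalar count (builds the model; init is cheap)."""
    return TGMLPUNet(config, seed=0).num_parameters()


def _block_macs(st: StageConfig, C: int, E: int, mult: int) -> int:
    pix = E * E * mult
    total = 0
    if st.use_tm:
        total += C * C * pix + 2 * C * E * pix  # channel + high + wide FCs
    if st.use_lgp:
        L = (E // st.partition_h) ** 2 * C
        total += 2 * L * L * mult               # the two GP full connections
        total += sum(k * k for k in LP_KERNELS) * C * C * pix
    return total


def count_macs(config: NetworkConfig, input_size: int | None = None) -> int:
    """Multiply-accumulates of one forward pass at ``input_size``.

    Convention: one MAC per scalar multiply inside convolutions and full
    connections; biases, normalisation, activations, pooling and residual
    adds are excluded.
    """
    S = input_size or config.input_size
    s, nc = config.stem_channels, config.num_classes
    total = 9 * (config.in_channels * s + 2 * s * s) * S * S
    for stages, extents, mult, c_in in (
            (config.global_stages, config.global_extents(S), 1, s),
            (config.local_stages, config.local_extents(S),
             config.local_patch_grid ** 2, s)):
        c_prev = c_in
        for st, E in zip(stages, extents):
            C = st.channels
            pix = E * E * mult
            total += 9 * c_prev * C * pix          # strided 3x3 conv
            total += _block_macs(st, C, E, mult)
            total += C * C * pix                   # 1x1 projection
            c_prev = C
        channels = [c_in] + [st.channels for st in stages]
        ups = [st.downsample == 2 for st in stages]
        dec_extents = list(reversed(extents))
        for i, E_in in zip(range(len(stages), 0, -1), dec_extents):
            pix = E_in * E_in * mult
            total += 9 * channels[i] * channels[i - 1] * pix
            if ups[i - 1]:
                total += 4 * channels[i - 1] * channels[i - 1] * pix
    total += s * nc * S * S
    return total


def budget(config: NetworkConfig, input_size: int | None = None) -> ModelBudget:
    return ModelBudget(parameters=count_parameters(config),
                       macs=count_macs(config, input_size))


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: TGMLPUNet, path) -> None:
    state = model.state_dict()
    meta = json.dumps({"config": model.config.to_dict(),
                       "hash": model.config.config_hash()})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> TGMLPUNet:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        state = {k: archive[k] for k in archive.files if k != "__meta__"}
    config = NetworkConfig.from_dict(meta["config"])
    if config.config_hash() != meta["hash"]:
        raise ValueError("checkpoint config hash mismatch")
    model = TGMLPUNet(config, seed=0)
    model.load_state_dict(state)
    return model
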