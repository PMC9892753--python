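"""3D high-resolution backbone: parallel multi-resolution conv streams with
repeated fusion.

Branch ``r`` (1-based) runs at ``1 / 2**(r-1)`` of the input resolution with
``base_channels * 2**(r-1)`` channels.  Each stage applies one residual basic
module per branch followed by all-pairs fusion (stride-2 convs downward,
nearest-neighbour upsampling + 1x1x1 conv upward, summed, ReLU).  New
branches are spawned by stride-2 transition convs at the start of a stage.
Two output modes: ``hr_keep`` returns the full-resolution branch unchanged;
``hr_fuse`` upsamples every branch to full resolution, maps each to a common
channel width with a 1x1x1 conv, and sums.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import BasicModule, BatchNorm3d, Conv3d, Module, Tensor, tape
from .nn.tape import receptive_field  # noqa: F401  (re-exported probe)

__all__ = ["HRNetConfig", "HRNet3D", "build_backbone", "fuse_output",
           "receptive_field"]


@dataclass
class HRNetConfig:
    """Desk-scale default: 3 branches, 8 base channels, 2 fusion stages."""

    n_branches: int = 3
    base_channels: int = 8
    n_stages: int = 2
    output_mode: str = "hr_fuse"
    fuse_channels: int | None = None    # defaults to base_channels
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_branches < 1 or self.base_channels < 1 or self.n_stages < 0:
            raise ValueError("invalid backbone config")
        if self.output_mode not in ("hr_keep", "hr_fuse"):
            raise ValueError(f"unknown output mode {self.output_mode!r}")
        if self.n_stages < self.n_branches - 1:
            raise ValueError(
                f"need n_stages >= n_branches - 1 to spawn every branch "
                f"(got {self.n_stages} < {self.n_branches - 1})"
            )

    def branch_channels(self, r: int) -> int:
        """Channels of 1-based branch r: base * 2**(r-1)."""
        return self.base_channels * 2 ** (r - 1)

    def to_dict(self) -> dict:
        return {
            "n_branches": self.n_branches,
            "base_channels": self.base_channels,
            "n_stages": self.n_stages,
            "output_mode": self.output_mode,
            "fuse_channels": self.fuse_channels,
            "seed": self.seed,
        }


class _Transition(Module):
    """Spawn the next (half-resolution, double-channel) branch."""

    def __init__(self, cin: int, cout: int, rng):
        super().__init__()
        self.conv = Conv3d(cin, cout, 3, stride=2, pad=1, rng=rng, bias=False)
        self.bn = BatchNorm3d(cout)

    def __call__(self, x: Tensor) -> Tensor:
        return tape.relu(self.bn(self.conv(x)))


class _Fuse(Module):
    """All-pairs exchange between the current branches."""

    def __init__(self, channels: list[int], rng):
        super().__init__()
        self.n = len(channels)
        self.paths: dict[tuple[int, int], list[Module]] = {}
        mods: list[Module] = []
        for dst in range(self.n):
            for src in range(self.n):
                if src == dst:
                    continue
                if src < dst:  # downsample by repeated stride-2 convs
                    chain = []
                    c = channels[src]
                    for step in range(dst - src):
                        c_out = channels[dst] if step == dst - src - 1 else c
                        chain.append(Conv3d(c, c_out, 3, stride=2, pad=1,
                                            rng=rng, bias=False))
                        chain.append(BatchNorm3d(c_out))
                        c = c_out
                    self.paths[(src, dst)] = chain
                else:          # upsample + 1x1x1 channel map
                    chain = [Conv3d(channels[src], channels[dst], 1, rng=rng,
                                    bias=False), BatchNorm3d(channels[dst])]
                    self.paths[(src, dst)] = chain
                mods.extend(chain)
        self.add_children("path", mods)

    def __call__(self, branches: list[Tensor]) -> list[Tensor]:
        out = []
        for dst in range(self.n):
            acc = branches[dst]
            for src in range(self.n):
                if src == dst:
                    continue
                chain = self.paths[(src, dst)]
                h = branches[src]
                if src > dst:
                    h = tape.upsample_nearest(h, 2 ** (src - dst))
                for layer in chain:
                    h = layer(h)
                acc = tape.add(acc, h)
            out.append(tape.relu(acc))
        return out


class HRNet3D(Module):
    """The backbone network; ``forward`` returns the multi-branch pyramid."""

    def __init__(self, config: HRNetConfig, in_channels: int = 1):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        c0 = config.base_channels
        self.stem = BasicModule(in_channels, c0, rng)
        transitions: list[Module] = []
        stages: list[Module] = []
        fuses: list[Module] = []
        self._plan: list[dict] = []
        n_active = 1
        for s in range(config.n_stages):
            spawn = n_active < config.n_branches
            if spawn:
                transitions.append(_Transition(config.branch_channels(n_active),
                                               config.branch_channels(n_active + 1),
                                               rng))
                n_active += 1
            chans = [config.branch_channels(r + 1) for r in range(n_active)]
            blocks = [BasicModule(c, c, rng) for c in chans]
            stages.extend(blocks)
            fuse = _Fuse(chans, rng) if n_active > 1 else None
            if fuse is not None:
                fuses.append(fuse)
            self._plan.append({"spawn": spawn, "n_active": n_active,
                               "blocks": blocks, "fuse": fuse,
                               "transition": transitions[-1] if spawn else None})
        self.add_children("transition", transitions)
        self.add_children("stage", stages)
        self.add_children("fuse", fuses)
        # output heads for hr_fuse: one 1x1x1 conv per branch to common width
        fc = config.fuse_channels or config.base_channels
        heads = [Conv3d(config.branch_channels(r + 1), fc, 1, rng=rng)
                 for r in range(config.n_branches)]
        self.fuse_heads = heads
        self.add_children("fuse_head", heads)
        self.fuse_channels = fc

    # -- forward ----------------------------------------------------------
    def check_input_shape(self, spatial: tuple[int, int, int]) -> None:
        div = 2 ** (self.config.n_branches - 1)
        bad = [s for s in spatial if s % div]
        if bad:
            need = [int(np.ceil(s / div) * div - s) for s in spatial]
            raise ValueError(
                f"spatial dims {spatial} must be divisible by {div}; "
                f"pad by {tuple(need)} voxels (z, y, x)"
            )

    def forward(self, x: Tensor | np.ndarray) -> list[Tensor]:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        if x.data.ndim == 3:
            x = Tensor(x.data[None], requires_grad=x.requires_grad, op=x.op)
        self.check_input_shape(x.data.shape[-3:])
        branches = [self.stem(x)]
        for step in self._plan:
            if step["spawn"]:
                branches.append(step["transition"](branches[-1]))
            branches = [blk(b) for blk, b in zip(step["blocks"], branches)]
            if step["fuse"] is not None:
                branches = step["fuse"](branches)
        return branches

    __call__ = forward

    def fuse_output(self, pyramid: list[Tensor], mode: str | None = None) -> Tensor:
        mode = mode or self.config.output_mode
        if mode == "hr_keep":
            return pyramid[0]
        if mode != "hr_fuse":
            raise ValueError(f"unknown output mode {mode!r}")
        out = None
        for r, t in enumerate(pyramid):
            if r > 0:
                t = tape.upsample_nearest(t, 2 ** r)
            t = self.fuse_heads[r](t)
            out = t if out is None else tape.add(out, t)
        return out


def build_backbone(config: HRNetConfig, in_channels: int = 1) -> HRNet3D:
    """Construct the backbone; parameter count is a pure function of config."""
    return HRNet3D(config, in_channels)


def fuse_output(model: HRNet3D, pyramid: list[Tensor], mode: str) -> Tensor:
    return model.fuse_output(pyramid, mode)
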