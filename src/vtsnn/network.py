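"""Fully-spiking U-net (U-VTSNN) for spike-plane-to-spike-plane mapping.

The network consumes one binary spike plane per time step and emits one
binary plane per step; membrane state carried inside every spiking
neuron is the only memory across steps. Every activation in the forward
path is a spiking neuron and every convolution is bias-free, so the
network is quiescent on zero input and all inter-layer signals are
strictly binary.

Downsampling is a stride-2 convolution followed by a spiking neuron;
upsampling is nearest-neighbour (binarity-preserving) followed by a
convolution and neuron; skip connections concatenate spike planes —
addition of spike maps is only ever performed as synaptic current inside
a neuron. The readout is a 1x1 convolution with its own low-threshold
neuron (V_th = 0.077 against 1.0 in the body).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np

from . import _autodiff as ad
from .codec import SpikePlaneStack
from .neuron import NeuronConfig

__all__ = ["NetworkSpec", "SpikingModel", "build_uvtsnn", "forward"]


@dataclass
class NetworkSpec:
    """Architecture hyper-parameters of the spiking U-net.

    time_steps: number of spike planes T processed per image.
    in_channels: channels per time step (1 for grayscale; C for
        multi-channel images encoded channel-independently, giving C*T
        planes in total).
    depth: number of stride-2 encoder levels.
    base_channels: channel width at full resolution; doubles per level.
    """

    time_steps: int = 8
    in_channels: int = 1
    depth: int = 2
    base_channels: int = 16
    body_neuron: NeuronConfig = field(default_factory=lambda: NeuronConfig(v_threshold=1.0))
    head_neuron: NeuronConfig = field(default_factory=lambda: NeuronConfig(v_threshold=0.077))
    skip_mode: str = "concatenate"

    def __post_init__(self):
        if self.depth < 1 or self.base_channels < 1:
            raise ValueError("depth and base_channels must be >= 1")
        if self.skip_mode != "concatenate":
            raise ValueError("only concatenative skips are supported")

    @property
    def in_planes(self) -> int:
        return self.time_steps * self.in_channels

    def to_dict(self) -> dict:
        return {"time_steps": self.time_steps, "in_channels": self.in_channels,
                "depth": self.depth, "base_channels": self.base_channels,
                "body_neuron": self.body_neuron.to_dict(),
                "head_neuron": self.head_neuron.to_dict(),
                "skip_mode": self.skip_mode}

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        d = dict(d)
        d["body_neuron"] = NeuronConfig.from_dict(d["body_neuron"])
        d["head_neuron"] = NeuronConfig.from_dict(d["head_neuron"])
        return cls(**d)


class _ConvSpike:
    """Bias-free convolution followed by a spiking neuron with state."""

    def __init__(self, rng, c_in: int, c_out: int, kernel: int, stride: int,
                 neuron: NeuronConfig, name: str, upsample: bool = False):
        fan_in = c_in * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        self.weight = ad.Tensor(rng.normal(0.0, std, (c_out, c_in, kernel, kernel)),
                                requires_grad=True)
        self.kernel = kernel
        self.stride = stride
        self.padding = kernel // 2
        self.neuron = neuron
        self.name = name
        self.upsample = upsample

    def step(self, x: ad.Tensor, u: ad.Tensor | None):
        if self.upsample:
            x = ad.upsample_nearest(x, 2)
        current = ad.conv2d(x, self.weight, stride=self.stride, padding=self.padding)
        if u is None:
            u = ad.Tensor(np.zeros_like(current.data))
        # charge (IF accumulate / LIF leak), fire, soft reset
        cfg = self.neuron
        if cfg.kind.value == "LIF":
            u = ad.add(u, ad.scale(ad.sub(current, u), 1.0 / cfg.tau))
        else:
            u = ad.add(u, current)
        spikes = ad.spike(u, cfg.v_threshold, cfg.surrogate_scale)
        u = ad.sub(u, ad.scale(spikes, cfg.v_threshold))
        return spikes, u


class SpikingModel:
    """A built U-VTSNN: ordered spiking layers plus their weights.

    Two initialisation schemes are available. ``"he"`` is plain
    fan-in-scaled Gaussian init. ``"identity"`` (the default through
    :func:`build_uvtsnn`) additionally wires an exact copy path through
    the full-resolution branch — stem channel 0 takes a centre tap of
    weight V_th on the input, the last skip-fusion layer copies that
    channel, and the 1x1 head reads it with weight equal to its own
    threshold — so the untrained network reproduces its input stack
    bit-for-bit (the firing rule has h(0) = 1 and the soft reset leaves
    exactly zero residual when the drive equals the threshold). A
    denoiser initialised at the identity starts from the noisy input's
    own fidelity and only has to learn noise suppression, which matters
    at short training budgets.
    """

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator,
                 init: str = "identity"):
        self.spec = spec
        c, d = spec.base_channels, spec.depth
        widths = [c * 2 ** i for i in range(d + 1)]
        self.stem = _ConvSpike(rng, spec.in_channels, widths[0], 3, 1,
                               spec.body_neuron, "stem")
        self.downs, self.refines, self.ups, self.fuses = [], [], [], []
        for i in range(1, d + 1):
            self.downs.append(_ConvSpike(rng, widths[i - 1], widths[i], 3, 2,
                                         spec.body_neuron, f"down{i}"))
            self.refines.append(_ConvSpike(rng, widths[i], widths[i], 3, 1,
                                           spec.body_neuron, f"refine{i}"))
        for i in range(d, 0, -1):
            self.ups.append(_ConvSpike(rng, widths[i], widths[i - 1], 3, 1,
                                       spec.body_neuron, f"up{i}", upsample=True))
            self.fuses.append(_ConvSpike(rng, 2 * widths[i - 1], widths[i - 1], 3, 1,
                                         spec.body_neuron, f"fuse{i}"))
        self.head = _ConvSpike(rng, widths[0], spec.in_channels, 1, 1,
                               spec.head_neuron, "head")
        self.layers = ([self.stem]
                       + [l for pair in zip(self.downs, self.refines) for l in pair]
                       + [l for pair in zip(self.ups, self.fuses) for l in pair]
                       + [self.head])
        self.last_trace: dict[str, dict] | None = None
        if init == "identity":
            self._wire_identity_path(widths[0])
        elif init != "he":
            raise ValueError(f"unknown init scheme {init!r}")

    def _wire_identity_path(self, c0: int) -> None:
        """Make the first C channels of the full-resolution branch exact
        copies of the C input channels, terminating in the head; see
        class docstring."""
        spec = self.spec
        C = spec.in_channels
        if c0 < C:
            raise ValueError("identity init needs base_channels >= in_channels")
        # Tap weight 1.1 * V_th: every input spike fires the unit, and the
        # soft-reset residual of 0.1 * V_th per spike cannot reach V_th
        # within T <= 10 steps, so the copy stays bit-exact while leaving
        # a 10% margin against weight updates during early training.
        margin = 1.1
        k = self.stem.kernel // 2
        for c in range(C):
            self.stem.weight.data[c] = 0.0
            self.stem.weight.data[c, c, k, k] = margin * spec.body_neuron.v_threshold
        last_fuse = self.fuses[-1]  # its skip input is the stem output
        k = last_fuse.kernel // 2
        for c in range(C):
            last_fuse.weight.data[c] = 0.0
            # concat order is (upsampled branch, skip): skip channel c = c0 + c
            last_fuse.weight.data[c, c0 + c, k, k] = margin * spec.body_neuron.v_threshold
        self.head.weight.data[:] = 0.0
        for c in range(C):
            self.head.weight.data[c, c, 0, 0] = margin * spec.head_neuron.v_threshold

    # -- parameters ------------------------------------------------------

    def parameters(self) -> list[ad.Tensor]:
        return [l.weight for l in self.layers]

    @property
    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    @property
    def bias_parameter_count(self) -> int:
        """Always 0: the architecture has no bias terms anywhere."""
        return 0

    def state_dict(self) -> dict[str, np.ndarray]:
        return {l.name: l.weight.data.copy() for l in self.layers}

    def load_state_dict(self, weights: dict) -> None:
        for l in self.layers:
            w = np.asarray(weights[l.name])
            if w.shape != l.weight.data.shape:
                raise ValueError(f"weight shape mismatch for layer {l.name}: "
                                 f"{w.shape} vs {l.weight.data.shape}")
            l.weight.data = w.astype(np.float64)

    # -- forward ---------------------------------------------------------

    def init_states(self) -> list:
        return [None] * len(self.layers)

    def step(self, x: ad.Tensor, states: list, detach_time: bool = False,
             record: bool = False):
        """One time step: spike plane(s) in, spike plane(s) out.

        ``states`` is the per-layer membrane-state list from the previous
        step (or :meth:`init_states`). With ``detach_time`` the returned
        states carry values only, no gradient edges.
        """
        d = self.spec.depth
        new_states = []
        si = iter(range(len(self.layers)))

        def run(layer, inp):
            i = next(si)
            spikes, u = layer.step(inp, states[i])
            if detach_time:
                u = ad.detach(u)
            new_states.append(u)
            if record:
                tr = self.last_trace.setdefault(
                    layer.name, {"spikes": 0, "slots": 0})
                tr["spikes"] += int(spikes.data.sum())
                tr["slots"] += int(spikes.data.size)
            return spikes

        h = run(self.stem, x)
        skips = [h]
        for i in range(d):
            h = run(self.downs[i], h)
            h = run(self.refines[i], h)
            skips.append(h)
        for j, i in enumerate(range(d, 0, -1)):
            h = run(self.ups[j], h)
            h = run(self.fuses[j], ad.concat([h, skips[i - 1]], axis=3))
        out = run(self.head, h)
        return out, new_states

    def forward_tensor(self, planes, detach_time: bool = False,
                       record: bool = False) -> list[ad.Tensor]:
        """Run T steps on (T, N, H, W, C) input; returns per-step outputs."""
        if record:
            self.last_trace = {}
        states = self.init_states()
        outputs = []
        for t in range(len(planes)):
            x = planes[t] if isinstance(planes[t], ad.Tensor) else ad.Tensor(planes[t])
            self._check_spatial(x.data.shape[1:3])
            out, states = self.step(x, states, detach_time=detach_time, record=record)
            outputs.append(out)
        return outputs

    def forward(self, stack: SpikePlaneStack | np.ndarray, detach_time: bool = False,
                record: bool = False) -> SpikePlaneStack:
        """Denoise one spike stack: T x H x W binary in, T x H x W binary out."""
        planes = stack.planes if isinstance(stack, SpikePlaneStack) else np.asarray(stack)
        if planes.ndim != 3:
            raise ValueError(f"expected T x H x W spike stack, got {planes.shape}")
        if not np.all(np.isin(np.unique(planes), (0, 1))):
            raise ValueError("network input must be strictly binary: the "
                             "forward path is fully spiking")
        if planes.shape[0] != self.spec.in_planes:
            raise ValueError(f"stack has {planes.shape[0]} planes, "
                             f"spec expects {self.spec.in_planes}")
        T, C = self.spec.time_steps, self.spec.in_channels
        # (T, N=1, H, W, C) for the batched channels-last step loop
        x = planes.reshape(T, C, *planes.shape[1:])[:, None].transpose(
            0, 1, 3, 4, 2).astype(np.float64)
        outs = self.forward_tensor(x, detach_time=detach_time, record=record)
        out_planes = np.stack([o.data[0].transpose(2, 0, 1) for o in outs]
                              ).reshape(T * C, *planes.shape[1:])
        weights = 2 ** np.arange(T - 1, -1, -1) if C == 1 else None
        return SpikePlaneStack(out_planes.astype(np.uint8), plane_weights=weights,
                               order_convention="msb_first")

    def _check_spatial(self, hw) -> None:
        h, w = hw
        f = 2 ** self.spec.depth
        if h % f or w % f:
            raise ValueError(
                f"spatial size {h}x{w} not divisible by 2**depth = {f}; "
                f"pad the image to a multiple of {f} first")

    # -- persistence -----------------------------------------------------

    def save(self, path) -> None:
        """Portable checkpoint: npz of weights + embedded spec JSON."""
        arrays = {f"weight__{k}": v for k, v in self.state_dict().items()}
        arrays["spec_json"] = np.frombuffer(
            json.dumps(self.spec.to_dict()).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "SpikingModel":
        with np.load(path) as z:
            spec = NetworkSpec.from_dict(
                json.loads(bytes(z["spec_json"].tobytes()).decode()))
            model = build_uvtsnn(spec, seed=0)
            model.load_state_dict(
                {k[len("weight__"):]: z[k] for k in z.files if k.startswith("weight__")})
        return model


def build_uvtsnn(spec: NetworkSpec | None = None, seed: int = 0,
                 init: str = "identity") -> SpikingModel:
    """Construct a U-VTSNN (He-scaled weights plus, by default, the exact
    identity copy path through the full-resolution branch).

    The default spec (depth 2, base 16 channels) carries ~0.115 M
    weights, calibrated near the reference 0.12 M parameter budget.
    """
    if spec is None:
        spec = NetworkSpec()
    return SpikingModel(spec, np.random.default_rng(seed), init=init)


def forward(model: SpikingModel, stack, detach_time: bool = False,
            record: bool = False) -> SpikePlaneStack:
    """Functional alias for :meth:`SpikingModel.forward`."""
    return model.forward(stack, detach_time=detach_time, record=record)
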