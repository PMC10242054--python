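"""Discrete-time integrate-and-fire neuron dynamics.

Each step charges the membrane potential u with the synaptic input x,
fires where u reaches the threshold (Heaviside with h(0) = 1), and soft-
resets by subtracting V_th from firing units so residual charge is kept:

    IF :  u <- u + x
    LIF:  u <- u + (x - u) / tau        (first-order leak, tau > 1)
    o  =  h(u - V_th)
    u  <- u - V_th * o

Training uses a surrogate derivative for the firing rule,
1 / (1 + (scale * (u - V_th))^2), evaluated at the firing boundary.

The functions here are dual-use: plain ndarrays give a numpy simulation,
:class:`~vtsnn._autodiff.Tensor` inputs build the gradient tape used by
the network and training modules, with identical forward values.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from . import _autodiff as ad

__all__ = [
    "NeuronKind",
    "NeuronConfig",
    "NeuronState",
    "surrogate_grad",
    "neuron_step",
    "run_sequence",
]


class NeuronKind(str, Enum):
    IF = "IF"
    LIF = "LIF"


@dataclass
class NeuronConfig:
    """Parameters of a population of spiking neurons.

    v_threshold is in membrane-potential units (1.0 for the network body,
    0.077 for the final 1x1 readout layer). tau is the LIF time constant
    (> 1; 1.1 by convention here). reset is soft subtraction — the only
    rule supported, matching V_reset = None. surrogate_scale is the
    sharpness of the surrogate derivative (pi by default).
    literal_gate opts into the literal multiplicative leak u * g(o) with
    g = tau (IF) or tau * exp(-1/tau) (LIF); it amplifies the potential
    for tau > 1 and exists for study only.
    """

    kind: NeuronKind = NeuronKind.IF
    v_threshold: float = 1.0
    tau: float = 1.1
    reset: str = "soft_subtract"
    surrogate_scale: float = float(np.pi)
    literal_gate: bool = False

    def __post_init__(self):
        self.kind = NeuronKind(self.kind)
        if self.v_threshold <= 0:
            raise ValueError("v_threshold must be positive")
        if self.kind is NeuronKind.LIF and self.tau <= 1:
            raise ValueError("LIF requires tau > 1")
        if self.reset != "soft_subtract":
            raise ValueError("only soft-subtract reset is supported")

    def to_dict(self) -> dict:
        return {"kind": self.kind.value, "v_threshold": self.v_threshold,
                "tau": self.tau, "surrogate_scale": self.surrogate_scale}

    @classmethod
    def from_dict(cls, d: dict) -> "NeuronConfig":
        return cls(**d)


@dataclass
class NeuronState:
    """Membrane potentials u (one per unit) and the current time index."""

    u: np.ndarray | ad.Tensor
    t: int = 0

    @classmethod
    def zeros(cls, shape, tensor: bool = False) -> "NeuronState":
        z = np.zeros(shape)
        return cls(u=ad.Tensor(z) if tensor else z, t=0)


def surrogate_grad(v, scale: float = float(np.pi)):
    """Surrogate derivative 1 / (1 + (scale*v)^2) at v = u - V_th.

    Symmetric, maximal (= 1) at the firing boundary v = 0, in (0, 1].
    """
    v = np.asarray(v, dtype=np.float64)
    s = scale * v
    out = 1.0 / (1.0 + s * s)
    return out if out.ndim else float(out)


def _charge(u: ad.Tensor, x: ad.Tensor, config: NeuronConfig) -> ad.Tensor:
    if config.literal_gate:
        g = config.tau if config.kind is NeuronKind.IF \
            else config.tau * float(np.exp(-1.0 / config.tau))
        return ad.add(ad.scale(u, g), x)
    if config.kind is NeuronKind.IF:
        return ad.add(u, x)
    # LIF: u + (x - u)/tau
    return ad.add(u, ad.scale(ad.sub(x, u), 1.0 / config.tau))


def _step_tensor(u: ad.Tensor, x: ad.Tensor, config: NeuronConfig):
    u_charged = _charge(u, x, config)
    spikes = ad.spike(u_charged, config.v_threshold, config.surrogate_scale)
    u_next = ad.sub(u_charged, ad.scale(spikes, config.v_threshold))
    return spikes, u_next


def neuron_step(state: NeuronState, input_current, config: NeuronConfig):
    """Advance one time step; returns (binary spikes, new state)."""
    tensor_mode = isinstance(state.u, ad.Tensor) or isinstance(input_current, ad.Tensor)
    u = state.u if isinstance(state.u, ad.Tensor) else ad.Tensor(state.u)
    x = input_current if isinstance(input_current, ad.Tensor) else ad.Tensor(input_current)
    if u.data.shape != x.data.shape:
        raise ValueError(f"shape mismatch: state {u.data.shape} vs input {x.data.shape}")
    if np.any(np.isnan(x.data)):
        raise ValueError("NaN in input current")
    spikes, u_next = _step_tensor(u, x, config)
    if tensor_mode:
        return spikes, NeuronState(u=u_next, t=state.t + 1)
    return spikes.data, NeuronState(u=u_next.data, t=state.t + 1)


def run_sequence(inputs, config: NeuronConfig, detach_time: bool = False):
    """Apply :func:`neuron_step` over a T-step input sequence.

    inputs: sequence of T arrays/tensors (or a single array whose first
    axis is time). With ``detach_time`` the carried membrane state is
    severed from the gradient graph between steps — forward values are
    identical, only gradient paths differ (spatial-only credit
    assignment).
    Returns (list of per-step spike outputs, final state).
    """
    if isinstance(inputs, np.ndarray):
        inputs = list(inputs)
    if len(inputs) == 0:
        raise ValueError("empty input sequence")
    tensor_mode = isinstance(inputs[0], ad.Tensor)
    first = inputs[0].data if tensor_mode else np.asarray(inputs[0])
    state = NeuronState.zeros(first.shape, tensor=tensor_mode)
    outputs = []
    for x in inputs:
        spikes, state = neuron_step(state, x, config)
        if detach_time and isinstance(state.u, ad.Tensor):
            state = NeuronState(u=ad.detach(state.u), t=state.t)
        outputs.append(spikes)
    return outputs, state
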