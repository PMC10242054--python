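"""Reconstruction metrics and the spike-counting energy model.

The energy estimate follows the event-driven accounting convention for
45 nm CMOS: a conventional (ANN) activation operation costs 4.6 pJ, a
spike costs 0.9 pJ, and in the absence of a spike a spiking layer is
assumed to consume nothing. Convolution MACs are excluded on both sides;
what is compared is

    E_ANN = #OP_ANN * 4.6 pJ
    E_SNN = #OP_SNN * spike_rate * 0.9 pJ

where #OP_SNN counts neuron-step *slots* (units x time steps) of the
spiking layers and spike_rate is the fraction of slots that actually
carried a spike. Energies are reported in units of 1e-7 J; the ANN/SNN
ratio is formed from the two-decimal-rounded energies, matching how such
tables are conventionally printed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .codec import GrayImage

__all__ = [
    "MetricReport",
    "EnergyReport",
    "psnr",
    "count_spikes",
    "energy_report",
    "E_PER_OP_PJ",
    "E_PER_SPIKE_PJ",
]

E_PER_OP_PJ = 4.6     # pJ per ANN activation operation (45 nm CMOS)
E_PER_SPIKE_PJ = 0.9  # pJ per spike

_PSNR_CAP = float("inf")


@dataclass
class MetricReport:
    """MSE and PSNR (dB, peak 2^n - 1) for one reconstruction."""

    mse: float
    psnr: float
    peak: int = 255

    @property
    def capped(self) -> bool:
        return math.isinf(self.psnr)


@dataclass
class EnergyReport:
    """Operation/spike counts and the derived pJ-based energies."""

    op_ann: float
    op_snn: float
    spike_rate: float
    e_per_op: float = E_PER_OP_PJ * 1e-12    # joules
    e_per_spike: float = E_PER_SPIKE_PJ * 1e-12
    energy_ann: float = 0.0   # joules, filled by energy_report
    energy_snn: float = 0.0
    ratio: float = float("nan")

    @property
    def energy_ann_1e7(self) -> float:
        """ANN energy in units of 1e-7 J, rounded to two decimals."""
        return round(self.energy_ann / 1e-7, 2)

    @property
    def energy_snn_1e7(self) -> float:
        """SNN energy in units of 1e-7 J, rounded to two decimals."""
        return round(self.energy_snn / 1e-7, 2)


def psnr(a, b, peak: int = 255) -> MetricReport:
    """Peak signal-to-noise ratio, 10*log10(peak^2 / MSE), in dB.

    Identical images have MSE 0 and are reported with an infinite
    (capped) PSNR.
    """
    pa = a.pixels if isinstance(a, GrayImage) else np.asarray(a)
    pb = b.pixels if isinstance(b, GrayImage) else np.asarray(b)
    if pa.shape != pb.shape:
        raise ValueError(f"shape mismatch: {pa.shape} vs {pb.shape}")
    mse = float(np.mean((pa.astype(np.float64) - pb.astype(np.float64)) ** 2))
    if mse == 0.0:
        return MetricReport(mse=0.0, psnr=_PSNR_CAP, peak=peak)
    return MetricReport(mse=mse, psnr=10.0 * math.log10(peak * peak / mse), peak=peak)


def count_spikes(traces) -> tuple[int, float]:
    """Total spikes and spike rate from forward-pass traces.

    ``traces`` is one trace dict (``model.last_trace``) or an iterable of
    them; each maps layer name -> {"spikes": int, "slots": int}. The rate
    is total spikes over total neuron-step slots.
    """
    if traces is None:
        raise ValueError("no traces: run the forward pass with record=True")
    if isinstance(traces, dict):
        traces = [traces]
    traces = list(traces)
    if not traces:
        raise ValueError("no traces: run the forward pass with record=True")
    spikes = sum(t["spikes"] for tr in traces for t in tr.values())
    slots = sum(t["slots"] for tr in traces for t in tr.values())
    if slots == 0:
        raise ValueError("traces contain no neuron-step slots")
    return int(spikes), spikes / slots


def energy_report(op_ann: float, op_snn: float, spike_rate: float,
                  e_per_op_pj: float = E_PER_OP_PJ,
                  e_per_spike_pj: float = E_PER_SPIKE_PJ) -> EnergyReport:
    """Event-driven energy comparison from operation counts.

    op_ann: ANN activation operations; op_snn: spiking neuron-step
    slots; spike_rate in [0, 1]. The ratio uses the energies after
    rounding to two decimals in 1e-7 J units; if the SNN energy rounds
    to zero the ratio is NaN (undefined).
    """
    if op_ann < 0 or op_snn < 0:
        raise ValueError("operation counts must be nonnegative")
    if not (0.0 <= spike_rate <= 1.0):
        raise ValueError("spike_rate must lie in [0, 1]")
    rep = EnergyReport(op_ann=op_ann, op_snn=op_snn, spike_rate=spike_rate,
                       e_per_op=e_per_op_pj * 1e-12,
                       e_per_spike=e_per_spike_pj * 1e-12)
    rep.energy_ann = op_ann * rep.e_per_op
    rep.energy_snn = op_snn * spike_rate * rep.e_per_spike
    snn_r = rep.energy_snn_1e7
    rep.ratio = float("nan") if snn_r == 0 else round(rep.energy_ann_1e7 / snn_r, 2)
    return rep
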