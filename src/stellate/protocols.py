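"""Simulation protocols composed from the cable solver.

These reproduce the in-silico experiments used to characterize electrotonic
filtering and sublinear integration in stellate cells: quantal-EPSC distance
sweeps under somatic voltage clamp, paired-pulse conductance injections,
subthreshold input-output curves under current clamp, the
dendritic-sublinearity index, and synthesis of a mean miniature EPSC as the
synapse-distance-weighted average of quantal EPSCs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .cable import (
    CompartmentalModel,
    SynapseSpec,
    Trace,
    simulate_current_clamp,
    simulate_voltage_clamp,
)
from .events import EventStats, waveform_stats

__all__ = [
    "DistanceSweepResult",
    "SynapseDistanceWeights",
    "qepsc_distance_sweep",
    "simulate_ppr",
    "quantal_io_curve",
    "dendritic_sublinearity",
    "synthesize_mean_mepsc",
]


@dataclass
class DistanceSweepResult:
    """Per-distance quantal EPSC measurements from a somatic-clamp sweep.

    Amplitudes in pA, kinetics in ms, local peak depolarization (voltage
    excursion at the synaptic site) in mV.  ``traces`` holds the
    baseline-subtracted clamp-current trace per distance.
    """

    distances: np.ndarray
    amplitude: np.ndarray
    rise_10_90: np.ndarray
    half_width: np.ndarray
    local_peak_depolarization: np.ndarray
    traces: list[Trace]

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if np.any(self.distances < 0) or np.any(np.diff(self.distances) <= 0):
            raise ValueError("distances must be nonnegative, strictly increasing")


@dataclass
class SynapseDistanceWeights:
    """Relative synapse frequency per 10 µm distance bin (soma bin first).

    ``bin_edges`` has one more entry than ``relative_frequency``; weights
    must be nonnegative and sum to 1.
    """

    bin_edges: np.ndarray
    relative_frequency: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.relative_frequency = np.asarray(self.relative_frequency, dtype=float)
        if self.bin_edges.size != self.relative_frequency.size + 1:
            raise ValueError("need len(bin_edges) == len(weights) + 1")
        if np.any(self.relative_frequency < 0):
            raise ValueError("weights must be nonnegative")
        if abs(self.relative_frequency.sum() - 1.0) > 1e-6:
            raise ValueError("weights must sum to 1")

    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def _sweep_single(
    model: CompartmentalModel,
    g: SynapseSpec,
    distance: float,
    hold: float,
    dt: float,
    duration: float,
) -> tuple[Trace, EventStats, float]:
    loc = model.compartment_at(distance) if distance > 0 else 0
    syn = replace(g, location=loc, onset=1.0)
    res = simulate_voltage_clamp(model, [syn], hold=hold, dt=dt, duration=duration)
    i_trace = res["clamp_current"]
    baseline = float(i_trace.samples[0])
    sub = Trace(dt=dt, samples=i_trace.samples - baseline, unit="pA")
    stats = waveform_stats(sub, baseline=0.0)
    v_local = res["voltages"][:, loc]
    local_depol = float(np.max(v_local) - v_local[0])
    return sub, stats, local_depol


def qepsc_distance_sweep(
    model: CompartmentalModel,
    g: SynapseSpec,
    distances,
    hold: float = -70.0,
    dt: float = 0.005,
    duration: float = 10.0,
) -> DistanceSweepResult:
    """Quantal EPSC vs synapse distance under ideal somatic voltage clamp.

    One simulation per distance (distance 0 = somatic synapse); the synapse
    is placed at the dendritic compartment whose center is nearest the
    requested path distance from the soma/dendrite junction, ties going
    distal.  Kinetics are measured on the baseline-subtracted clamp current.
    """
    distances = np.asarray(list(distances), dtype=float)
    traces, amps, rises, hws, depols = [], [], [], [], []
    for d in distances:
        tr, st, dep = _sweep_single(model, g, float(d), hold, dt, duration)
        traces.append(tr)
        amps.append(st.amplitude)
        rises.append(st.rise_10_90)
        hws.append(st.half_width)
        depols.append(dep)
    return DistanceSweepResult(
        distances=distances,
        amplitude=np.asarray(amps),
        rise_10_90=np.asarray(rises),
        half_width=np.asarray(hws),
        local_peak_depolarization=np.asarray(depols),
        traces=traces,
    )


def simulate_ppr(
    model: CompartmentalModel,
    g1: SynapseSpec,
    conductance_ratio: float = 2.25,
    interval: float = 20.0,
    distance: float = 0.0,
    hold: float = -70.0,
    dt: float = 0.005,
    pre_window: float = 1.0,
    post_window: float = 10.0,
) -> dict:
    """Paired-pulse protocol: two conductances at one site, the second
    scaled by ``conductance_ratio``, separated by ``interval`` ms.

    PPR = amplitude2/amplitude1 of the clamp-current deflections; the second
    amplitude is measured from the decayed tail of the first response (the
    trace value just before the second onset).  Under ideal somatic clamp
    with a somatic synapse, PPR equals the conductance ratio exactly.
    """
    if interval <= 0:
        raise ValueError("interval must be positive")
    if post_window >= interval:
        raise ValueError(
            "measurement window overlaps the second pulse; shorten post_window"
        )
    loc = model.compartment_at(distance) if distance > 0 else 0
    on1 = pre_window
    on2 = pre_window + interval
    s1 = replace(g1, location=loc, onset=on1)
    s2 = replace(
        g1, location=loc, onset=on2, gmax=g1.gmax * conductance_ratio
    )
    duration = on2 + post_window
    res = simulate_voltage_clamp(model, [s1, s2], hold=hold, dt=dt,
                                 duration=duration)
    i = res["clamp_current"].samples
    t = res["clamp_current"].times
    base1 = float(i[0])
    i1_win = (t >= on1) & (t < on1 + post_window)
    amp1 = float(np.max(np.abs(i[i1_win] - base1)))
    i_on2 = int(round(on2 / dt))
    base2 = float(i[i_on2 - 1])
    i2_win = t >= on2
    amp2 = float(np.max(np.abs(i[i2_win] - base2)))
    return {
        "ppr": amp2 / amp1,
        "amplitude1": amp1,
        "amplitude2": amp2,
        "trace": res["clamp_current"],
    }


def _epsp_peak(
    model: CompartmentalModel,
    g: SynapseSpec,
    dt: float,
    duration: float,
    record: int = 0,
) -> float:
    res = simulate_current_clamp(model, [g], dt=dt, duration=duration)
    v = res["voltages"][:, record]
    return float(np.max(v) - v[0])


def quantal_io_curve(
    model: CompartmentalModel,
    g_unit: SynapseSpec,
    quanta,
    distance: float = 0.0,
    reference_quanta: float = 0.1,
    dt: float = 0.01,
    duration: float = 30.0,
) -> dict:
    """Subthreshold input-output curve under current clamp.

    The unit conductance is scaled by each entry of ``quanta``; the somatic
    EPSP peak is recorded.  ``linear_sum`` extrapolates the response to
    ``reference_quanta`` (a conductance small enough that voltage is linear
    in it) proportionally: linear_sum(q) = q * peak(reference)/reference.
    """
    quanta = np.asarray(list(quanta), dtype=float)
    if np.any(quanta <= 0):
        raise ValueError("quanta must be positive")
    loc = model.compartment_at(distance) if distance > 0 else 0
    base = replace(g_unit, location=loc, onset=1.0)
    ref_peak = _epsp_peak(
        model, replace(base, gmax=g_unit.gmax * reference_quanta), dt, duration
    )
    peaks = np.asarray([
        _epsp_peak(model, replace(base, gmax=g_unit.gmax * q), dt, duration)
        for q in quanta
    ])
    linear = quanta * ref_peak / reference_quanta
    return {
        "quanta": quanta,
        "peak_epsp": peaks,
        "linear_sum": linear,
        "reference_peak": ref_peak,
        "reference_quanta": reference_quanta,
    }


def dendritic_sublinearity(io_soma: dict, io_dendrite: dict) -> np.ndarray:
    """Dendritic sublinearity per quanta: 1 - (normalized dendritic EPSP /
    normalized somatic EPSP).

    Each site's EPSP is first normalized to its own small-conductance
    (reference) response expressed per quantum, removing the site's local
    gain; the index then isolates the extra saturation incurred at the
    dendrite.  0 means the dendrite is as linear as the soma.
    """
    qs = io_soma["quanta"]
    qd = io_dendrite["quanta"]
    if qs.shape != qd.shape or not np.allclose(qs, qd):
        raise ValueError("input-output curves measured on different quanta grids")

    def normalized(io):
        per_quantum_ref = io["reference_peak"] / io["reference_quanta"]
        return io["peak_epsp"] / (io["quanta"] * per_quantum_ref)

    return 1.0 - normalized(io_dendrite) / normalized(io_soma)


def synthesize_mean_mepsc(
    sweep: DistanceSweepResult,
    weights: SynapseDistanceWeights,
) -> dict:
    """Mean miniature EPSC as the synapse-distance-weighted average of
    quantal EPSC traces.

    ``sweep`` must contain one trace per weight bin, simulated at the bin's
    representative distance (bin center; the soma bin uses the somatic
    qEPSC).  Traces are aligned on their common time base and averaged
    pointwise with the relative synapse frequencies as weights; kinetics of
    the synthesized trace are then measured like any simulated EPSC.
    """
    w = weights.relative_frequency
    if len(sweep.traces) != w.size:
        raise ValueError(
            f"need one trace per weight bin ({w.size}), got {len(sweep.traces)}"
        )
    n = min(tr.samples.size for tr in sweep.traces)
    dt = sweep.traces[0].dt
    if any(abs(tr.dt - dt) > 1e-12 for tr in sweep.traces):
        raise ValueError("traces must share a sampling interval")
    stack = np.stack([tr.samples[:n] for tr in sweep.traces])
    mean = w @ stack
    trace = Trace(dt=dt, samples=mean, unit=sweep.traces[0].unit)
    stats = waveform_stats(trace, baseline=0.0)
    return {"trace": trace, "stats": stats}
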