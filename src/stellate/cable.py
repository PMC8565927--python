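"""Passive cable theory: analytic constants and a compartmental tree solver.

Analytic layer
--------------
Infinite-cable space constants.  The steady-state constant is

    lambda_DC = sqrt(d * Rm / (4 * Ri))

and the frequency-dependent constant is

    lambda_AC = lambda_DC * sqrt(2 / (1 + sqrt(1 + (2*pi*f*tau_m)**2)))

with the high-frequency simplification sqrt(d / (4*pi*f*Ri*Cm)) valid above
roughly 100 Hz.  ``d`` is the dendritic diameter.

Numerical layer
---------------
The morphology is discretized into isopotential compartments (a spherical
soma of area pi*d^2 plus dendritic cylinders) coupled by axial conductances.
Membrane voltage obeys

    C_i dV_i/dt = -g_leak_i (V_i - E_leak) - g_syn(t) (V_i - E_rev)
                  + sum_j g_ij (V_j - V_i) + I_inj_i(t)

integrated with a Crank-Nicolson scheme and an O(n) tree (Hines-ordered)
direct solve per step; the first step is backward-Euler damped.  Internal
units: µm, ms, mV, µS, nF, nA; boundary units Ω·cm², Ω·cm, µF/cm² are
converted explicitly.  Synaptic conductances are unnormalized differences of
two exponentials (NEURON Exp2-style with explicit scale, not peak-normalized).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq

from .morphology import Morphology, ROOT_PARENT

__all__ = [
    "PassiveProperties",
    "CompartmentalModel",
    "SynapseSpec",
    "IMMATURE_QUANTAL",
    "ADULT_QUANTAL",
    "Trace",
    "lambda_dc",
    "lambda_ac",
    "membrane_time_constant",
    "compartmentalize",
    "biexp_conductance",
    "biexp_peak_time",
    "biexp_peak",
    "biexp_half_width",
    "simulate_voltage_clamp",
    "simulate_current_clamp",
    "input_resistance",
]

UM_PER_CM = 1.0e4


# ---------------------------------------------------------------------------
# Analytic cable constants
# ---------------------------------------------------------------------------

def lambda_dc(d: float, Rm: float, Ri: float) -> float:
    """Steady-state space constant of an infinite cable, in µm.

    d: diameter (µm); Rm: specific membrane resistance (Ω·cm²);
    Ri: internal resistivity (Ω·cm).
    """
    if d <= 0 or Rm <= 0 or Ri <= 0:
        raise ValueError("d, Rm and Ri must be positive")
    d_cm = d / UM_PER_CM
    return math.sqrt(d_cm * Rm / (4.0 * Ri)) * UM_PER_CM


def membrane_time_constant(Rm: float, Cm: float) -> float:
    """Membrane time constant Rm*Cm in ms (Rm Ω·cm², Cm µF/cm²)."""
    if Rm <= 0 or Cm <= 0:
        raise ValueError("Rm and Cm must be positive")
    return Rm * Cm * 1.0e-3  # Ω·cm² * µF/cm² = µs·1e3 -> ms


def lambda_ac(
    d: float,
    Rm: float,
    Ri: float,
    Cm: float,
    f: float,
    simplified: bool = False,
) -> float:
    """Frequency-dependent space constant of an infinite cable, in µm.

    The full form scales lambda_DC by sqrt(2/(1+sqrt(1+(2*pi*f*tau_m)^2))).
    With ``simplified=True`` the high-frequency approximation
    sqrt(d/(4*pi*f*Ri*Cm)) is used (valid for f >~ 100 Hz); Rm then drops
    out of the expression.
    """
    if d <= 0 or Ri <= 0 or Cm <= 0 or f <= 0:
        raise ValueError("d, Ri, Cm and f must be positive")
    if simplified:
        d_cm = d / UM_PER_CM
        cm_f = Cm * 1.0e-6  # F/cm²
        return math.sqrt(d_cm / (4.0 * math.pi * f * Ri * cm_f)) * UM_PER_CM
    if Rm <= 0:
        raise ValueError("Rm must be positive for the full form")
    tau_m_s = membrane_time_constant(Rm, Cm) * 1.0e-3
    omega_tau = 2.0 * math.pi * f * tau_m_s
    factor = math.sqrt(2.0 / (1.0 + math.sqrt(1.0 + omega_tau**2)))
    return lambda_dc(d, Rm, Ri) * factor


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PassiveProperties:
    """Uniform passive membrane parameters.

    Cm µF/cm², Rm Ω·cm², Ri Ω·cm, E_leak mV.  Defaults are the stellate-cell
    values: Cm 0.9, Rm 20000 (tau_m 18 ms), Ri 150, leak reversal at the
    −70 mV holding potential so the cell rests at the clamp level.
    """

    Cm: float = 0.9
    Rm: float = 20000.0
    Ri: float = 150.0
    E_leak: float = -70.0

    def __post_init__(self) -> None:
        if self.Cm <= 0 or self.Rm <= 0 or self.Ri <= 0:
            raise ValueError("Cm, Rm, Ri must be positive")

    @property
    def tau_m(self) -> float:
        """Membrane time constant in ms."""
        return membrane_time_constant(self.Rm, self.Cm)


@dataclass(frozen=True)
class SynapseSpec:
    """Biexponential synaptic conductance at one compartment.

    g(t) = gmax * (exp(-(t-onset)/tau1) - exp(-(t-onset)/tau0)) for t>=onset,
    unnormalized (the realized peak is below gmax).  tau0 rise, tau1 decay,
    ms; gmax µS; E_rev mV; location is a compartment index.
    """

    tau0: float
    tau1: float
    gmax: float
    E_rev: float = 0.0
    onset: float = 0.0
    location: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.tau0 < self.tau1:
            raise ValueError("require 0 < tau0 < tau1")
        if self.gmax <= 0:
            raise ValueError("gmax must be positive")

    def conductance(self, t: np.ndarray | float) -> np.ndarray | float:
        return biexp_conductance(t, self)


IMMATURE_QUANTAL = SynapseSpec(tau0=0.073, tau1=0.26, gmax=0.004)
ADULT_QUANTAL = SynapseSpec(tau0=0.072, tau1=0.24, gmax=0.0032)


@dataclass
class Trace:
    """A uniformly sampled signal: dt/t0 in ms, samples with a unit tag."""

    dt: float
    samples: np.ndarray
    t0: float = 0.0
    unit: str = "mV"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.samples.size)

    def to_text(self, dest) -> None:
        """Write as two-column delimited text (time_ms, value)."""
        if isinstance(dest, str):
            with open(dest, "w") as fh:
                self.to_text(fh)
            return
        dest.write(f"# time_ms\tvalue_{self.unit}\n")
        for t, v in zip(self.times, self.samples):
            dest.write(f"{t:.9g}\t{v:.9g}\n")

    @classmethod
    def from_text(cls, source, unit: str = "mV") -> "Trace":
        if isinstance(source, str):
            with open(source) as fh:
                return cls.from_text(fh, unit=unit)
        rows = []
        header_unit = unit
        for line in source:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "value_" in line:
                    header_unit = line.rsplit("value_", 1)[1].strip()
                continue
            t, v = line.split()
            rows.append((float(t), float(v)))
        if len(rows) < 2:
            raise ValueError("trace file needs at least two samples")
        arr = np.asarray(rows)
        dt = float(np.median(np.diff(arr[:, 0])))
        return cls(dt=dt, samples=arr[:, 1], t0=float(arr[0, 0]), unit=header_unit)


# ---------------------------------------------------------------------------
# Biexponential conductance analytics
# ---------------------------------------------------------------------------

def biexp_conductance(t, s: SynapseSpec):
    """Conductance (µS) of a biexponential synapse at time(s) t (ms)."""
    t = np.asarray(t, dtype=float)
    rel = t - s.onset
    g = np.where(
        rel > 0,
        s.gmax * (np.exp(-np.clip(rel, 0, None) / s.tau1)
                  - np.exp(-np.clip(rel, 0, None) / s.tau0)),
        0.0,
    )
    return float(g) if g.ndim == 0 else g


def biexp_peak_time(s: SynapseSpec) -> float:
    """Time to peak after onset: (tau1*tau0/(tau1-tau0)) * ln(tau1/tau0)."""
    return s.tau1 * s.tau0 / (s.tau1 - s.tau0) * math.log(s.tau1 / s.tau0)


def biexp_peak(s: SynapseSpec) -> float:
    """Peak conductance in µS (closed form at the analytic peak time)."""
    tp = biexp_peak_time(s)
    return s.gmax * (math.exp(-tp / s.tau1) - math.exp(-tp / s.tau0))


def biexp_half_width(s: SynapseSpec) -> float:
    """Full width at half maximum (ms) of the conductance time course,
    found by root bracketing on the continuous waveform."""
    tp = biexp_peak_time(s)
    half = biexp_peak(s) / 2.0

    def f(t):
        return s.gmax * (math.exp(-t / s.tau1) - math.exp(-t / s.tau0)) - half

    t_rise = brentq(f, 1e-12, tp)
    # decay side: bracket out to where the waveform has surely fallen below half
    t_hi = tp
    while f(t_hi) > 0:
        t_hi += s.tau1
    t_fall = brentq(f, tp, t_hi)
    return t_fall - t_rise


# ---------------------------------------------------------------------------
# Compartmentalization
# ---------------------------------------------------------------------------

@dataclass
class CompartmentalModel:
    """Discretized electrical tree.

    Arrays are indexed by compartment, ordered root-first so that
    ``parent[i] < i`` for i > 0 (the soma is compartment 0).  ``g_axial[i]``
    couples compartment i to its parent (µS); areas in cm²; path distances
    are measured to compartment centers from the soma center, and
    ``junction_distance`` from the soma surface (dendrite attachment).
    """

    parent: np.ndarray
    area: np.ndarray
    g_axial: np.ndarray
    path_distance: np.ndarray
    junction_distance: np.ndarray
    properties: PassiveProperties
    morphology: Morphology | None = None

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=int)
        self.area = np.asarray(self.area, dtype=float)
        self.g_axial = np.asarray(self.g_axial, dtype=float)
        if np.any(self.area <= 0):
            raise ValueError("compartment areas must be positive")
        if np.any(self.parent[1:] >= np.arange(1, self.n)):
            raise ValueError("compartments must be ordered root-first")

    @property
    def n(self) -> int:
        return self.parent.size

    @property
    def c_membrane(self) -> np.ndarray:
        """Membrane capacitance per compartment, nF."""
        return self.properties.Cm * self.area * 1.0e3

    @property
    def g_leak(self) -> np.ndarray:
        """Leak conductance per compartment, µS."""
        return self.area / self.properties.Rm * 1.0e6

    def compartment_at(self, distance: float, origin: str = "junction") -> int:
        """Index of the dendritic compartment whose center is nearest to
        ``distance`` (µm); ties go to the more distal compartment.  ``origin``
        is 'junction' (soma/dendrite attachment) or 'soma_center'.  Distance 0
        maps to the soma compartment.
        """
        if distance <= 0:
            return 0
        ref = self.junction_distance if origin == "junction" else self.path_distance
        cand = np.arange(1, self.n)
        if cand.size == 0:
            raise ValueError("model has no dendritic compartments")
        centers = ref[cand]
        spacing = float(np.min(np.diff(np.unique(centers)))) if cand.size > 1 else 1.0
        if distance > centers.max() + spacing / 2 + 1e-9:
            raise ValueError(
                f"distance {distance} µm beyond the most distal compartment "
                f"center ({centers.max():.2f} µm)"
            )
        err = np.abs(centers - distance)
        ties = cand[np.isclose(err, err.min())]
        return int(ties[np.argmax(ref[ties])])


def compartmentalize(
    m: Morphology,
    p: PassiveProperties,
    max_compartment_length: float = 1.0,
) -> CompartmentalModel:
    """Discretize a morphology into a :class:`CompartmentalModel`.

    The soma becomes one spherical compartment of area pi*d²; each dendritic
    edge is split into cylinders no longer than ``max_compartment_length``.
    Axial resistance between compartment centers composes the half-cylinder
    resistances 2*Ri*dx/(pi*d²) on each side (the isopotential soma
    contributes none).
    """
    if max_compartment_length <= 0:
        raise ValueError("max_compartment_length must be positive")
    d_soma_cm = 2.0 * m.soma_radius / UM_PER_CM
    soma_area = math.pi * d_soma_cm**2

    parent = [ROOT_PARENT]
    area = [soma_area]
    g_ax = [0.0]
    pathd = [0.0]
    juncd = [0.0]
    # per-compartment half axial resistance (Ω) toward each end
    half_res = [0.0]

    # map morphology node id -> compartment index carrying that node's end
    comp_of_node: dict[int, int] = {m.root.id: 0}
    # also remember the half-resistance at the distal face of that compartment
    distal_half: dict[int, float] = {m.root.id: 0.0}
    node_pathd: dict[int, float] = {m.root.id: 0.0}
    node_juncd: dict[int, float] = {m.root.id: 0.0}

    # walk nodes in stored (topological) order
    for node in m.nodes:
        if node.parent_id == ROOT_PARENT or node.kind != "dendrite":
            continue
        pnode = m.node(node.parent_id)
        edge_len = math.dist(pnode.position, node.position)
        if pnode.kind == "soma":
            # attachment edge: inside the soma sphere, no cable
            comp_of_node[node.id] = 0
            distal_half[node.id] = 0.0
            node_pathd[node.id] = edge_len
            node_juncd[node.id] = 0.0
            continue
        diam_um = pnode.radius + node.radius  # mean diameter of the frustum
        d_cm = diam_um / UM_PER_CM
        n_seg = max(1, math.ceil(edge_len / max_compartment_length - 1e-9))
        seg_len = edge_len / n_seg
        seg_len_cm = seg_len / UM_PER_CM
        seg_area = math.pi * d_cm * seg_len_cm
        # full cylinder axial resistance Ri*L/(pi r^2) = 4*Ri*L/(pi d^2); half per face
        r_half = p.Ri * seg_len_cm / (math.pi * (d_cm / 2.0) ** 2) / 2.0
        up_comp = comp_of_node[node.parent_id]
        up_half = distal_half[node.parent_id]
        base_pathd = node_pathd[node.parent_id]
        base_juncd = node_juncd[node.parent_id]
        for k in range(n_seg):
            idx = len(parent)
            parent.append(up_comp)
            area.append(seg_area)
            # axial conductance between this compartment center and parent's
            r_total = r_half + up_half
            g_ax.append(1.0e6 / r_total if r_total > 0 else math.inf)
            center = (k + 0.5) * seg_len
            pathd.append(base_pathd + center)
            juncd.append(base_juncd + center)
            half_res.append(r_half)
            up_comp = idx
            up_half = r_half
        comp_of_node[node.id] = up_comp
        distal_half[node.id] = up_half
        node_pathd[node.id] = base_pathd + edge_len
        node_juncd[node.id] = base_juncd + edge_len

    return CompartmentalModel(
        parent=np.asarray(parent),
        area=np.asarray(area),
        g_axial=np.asarray(g_ax),
        path_distance=np.asarray(pathd),
        junction_distance=np.asarray(juncd),
        properties=p,
        morphology=m,
    )


# ---------------------------------------------------------------------------
# Time stepping
# ---------------------------------------------------------------------------

class IntegrationError(RuntimeError):
    """Unstable or divergent integration; retry with a smaller dt."""


def _hines_solve(parent: np.ndarray, diag: np.ndarray, g_ax: np.ndarray,
                 rhs: np.ndarray, free: np.ndarray) -> np.ndarray:
    """Solve (D - offdiag) V = rhs on the tree for the free compartments.

    ``free`` is a boolean mask; non-free compartments hold Dirichlet values
    already accounted for in ``rhs``.  diag and rhs are modified in place.
    """
    n = parent.size
    order = np.arange(n)
    # eliminate leaf-to-root
    for i in range(n - 1, 0, -1):
        if not free[i]:
            continue
        pa = parent[i]
        if pa < 0 or not free[pa]:
            continue
        factor = g_ax[i] / diag[i]
        diag[pa] -= g_ax[i] * factor
        rhs[pa] += rhs[i] * factor
    v = np.zeros(n)
    for i in order:
        if not free[i]:
            continue
        pa = parent[i]
        if pa >= 0 and free[pa]:
            v[i] = (rhs[i] + g_ax[i] * v[pa]) / diag[i]
        else:
            v[i] = rhs[i] / diag[i]
    return v


def _conductance_apply(parent, g_ax, g_total, v):
    """y = A v where A has g_total on the diagonal and -g_ax off-diagonal."""
    y = g_total * v
    idx = np.arange(parent.size)[1:]
    pa = parent[1:]
    y[idx] -= g_ax[1:] * v[pa]
    np.subtract.at(y, pa, g_ax[1:] * v[idx])
    return y


def _simulate(
    model: CompartmentalModel,
    synapses: Sequence[SynapseSpec],
    dt: float,
    duration: float,
    clamp: float | None,
    series_resistance: float,
    injected: tuple[int, Callable[[np.ndarray], np.ndarray]] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Core Crank-Nicolson integration.

    Returns (times, V) with V of shape (n_steps+1, n_compartments).  With
    ``clamp`` set and zero series resistance, compartment 0 is a Dirichlet
    node; with series resistance Rs > 0 the pipette is a conductance 1/Rs µS
    from the soma to the command potential.
    """
    if dt <= 0 or duration <= 0:
        raise ValueError("dt and duration must be positive")
    p = model.properties
    n = model.n
    n_steps = int(round(duration / dt))
    times = dt * np.arange(n_steps + 1)

    c_over = model.c_membrane / dt
    g_leak = model.g_leak
    g_ax = model.g_axial.copy()
    # static total conductance per compartment (leak + axial incidences)
    g_static = g_leak.copy()
    for i in range(1, n):
        g_static[i] += g_ax[i]
        g_static[model.parent[i]] += g_ax[i]

    g_pip = 0.0
    ideal_clamp = clamp is not None and series_resistance == 0
    if clamp is not None and series_resistance > 0:
        g_pip = 1.0 / series_resistance  # MΩ -> µS

    syn_loc = np.asarray([s.location for s in synapses], dtype=int)
    syn_erev = np.asarray([s.E_rev for s in synapses], dtype=float)

    def syn_g(t: float) -> np.ndarray:
        return np.asarray([biexp_conductance(t, s) for s in synapses], dtype=float)

    inj_loc, inj_fun = (None, None)
    if injected is not None:
        inj_loc, inj_fun = injected

    free = np.ones(n, dtype=bool)
    if ideal_clamp:
        free[0] = False

    v = np.full(n, p.E_leak, dtype=float)
    if clamp is not None:
        v[0] = clamp
    V = np.empty((n_steps + 1, n))
    V[0] = v

    def assemble(t: float):
        """diag and b for the conductance matrix at time t."""
        g_tot = g_static.copy()
        b = g_leak * p.E_leak
        gs = syn_g(t)
        np.add.at(g_tot, syn_loc, gs)
        np.add.at(b, syn_loc, gs * syn_erev)
        if g_pip:
            g_tot[0] += g_pip
            b[0] += g_pip * clamp
        if inj_fun is not None:
            b[inj_loc] += float(inj_fun(t))
        return g_tot, b

    for step in range(n_steps):
        t0 = times[step]
        t1 = times[step + 1]
        theta = 1.0 if step == 0 else 0.5  # backward-Euler damped first step
        g0, b0 = assemble(t0)
        g1, b1 = assemble(t1)
        # (C/dt + theta*A1) v1 = (C/dt - (1-theta)*A0) v0 + (1-theta)*b0 + theta*b1
        rhs = c_over * v + (1.0 - theta) * (b0 - _conductance_apply(
            model.parent, g_ax, g0, v)) + theta * b1
        diag = c_over + theta * g1
        # Dirichlet soma: move coupling terms to RHS of its children
        if ideal_clamp:
            kids = np.where(model.parent == 0)[0]
            rhs[kids] += theta * g_ax[kids] * clamp
            # children's diag already includes g_ax via g_static
        g_ax_eff = theta * g_ax
        v_new = _hines_solve(model.parent, diag, g_ax_eff, rhs, free)
        if ideal_clamp:
            v_new[0] = clamp
        if not np.all(np.isfinite(v_new)) or np.max(np.abs(v_new)) > 1e4:
            raise IntegrationError(
                f"integration diverged at t={t1:.3f} ms; reduce dt"
            )
        v = v_new
        V[step + 1] = v
    return times, V


def _clamp_current(model, synapses, clamp, V, times) -> np.ndarray:
    """Current (nA) the ideal clamp injects at the soma at each time."""
    p = model.properties
    g_leak0 = model.g_leak[0]
    kids = np.where(model.parent == 0)[0]
    i = g_leak0 * (clamp - p.E_leak) * np.ones(times.size)
    for s in synapses:
        if s.location == 0:
            i += biexp_conductance(times, s) * (clamp - s.E_rev)
    for k in kids:
        i += model.g_axial[k] * (clamp - V[:, k])
    return i


def simulate_voltage_clamp(
    model: CompartmentalModel,
    synapses: Sequence[SynapseSpec],
    hold: float = -70.0,
    dt: float = 0.005,
    duration: float = 10.0,
    series_resistance: float = 0.0,
) -> dict:
    """Somatic voltage clamp: hold the soma at ``hold`` (mV) and record the
    clamp current.

    With ``series_resistance`` 0 the soma is an ideal Dirichlet node; a
    positive value (MΩ) inserts a pipette conductance so the soma voltage can
    escape.  Returns a dict with ``clamp_current`` (a pA :class:`Trace`,
    positive = injected outward; an inward synaptic current appears as a
    negative deflection), ``voltages`` (array, steps x compartments) and
    ``times``.
    """
    times, V = _simulate(model, synapses, dt, duration, hold, series_resistance)
    if series_resistance > 0:
        i_nA = (hold - V[:, 0]) / series_resistance  # µS form: (mV)/MΩ = nA
    else:
        i_nA = _clamp_current(model, synapses, hold, V, times)
    trace = Trace(dt=dt, samples=i_nA * 1.0e3, unit="pA")
    return {"clamp_current": trace, "voltages": V, "times": times}


def simulate_current_clamp(
    model: CompartmentalModel,
    synapses: Sequence[SynapseSpec],
    injected: tuple[int, Callable] | None = None,
    dt: float = 0.005,
    duration: float = 50.0,
) -> dict:
    """Free-membrane simulation (current clamp).

    ``injected`` optionally supplies (compartment, waveform) with the
    waveform a callable t(ms) -> nA.  Synaptic currents use the instantaneous
    local driving force, the mechanism of sublinear integration.  Returns
    ``voltages`` (steps x compartments) and ``times``; the somatic voltage is
    also wrapped as a :class:`Trace` under ``soma_voltage``.
    """
    times, V = _simulate(model, synapses, dt, duration, None, 0.0,
                         injected=injected)
    return {
        "soma_voltage": Trace(dt=dt, samples=V[:, 0], unit="mV"),
        "voltages": V,
        "times": times,
    }


def input_resistance(model: CompartmentalModel, at: int = 0,
                     delta_i: float = 1.0e-3) -> float:
    """Steady-state input resistance (MΩ) at a compartment, from the linear
    steady-state solution for a small injected current."""
    n = model.n
    g_leak = model.g_leak
    g_ax = model.g_axial
    g_static = g_leak.copy()
    for i in range(1, n):
        g_static[i] += g_ax[i]
        g_static[model.parent[i]] += g_ax[i]
    rhs = np.zeros(n)
    rhs[at] = delta_i  # nA
    diag = g_static.copy()
    free = np.ones(n, dtype=bool)
    dv = _hines_solve(model.parent, diag, g_ax.copy(), rhs, free)
    return float(dv[at] / delta_i)  # mV/nA = MΩ
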