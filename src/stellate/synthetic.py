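"""Synthetic-data generators with known ground truth.

Every pipeline stage has a matching generator here, so recovery of the
generating parameters by the analysis code can be tested end to end:
stochastic dendritic trees with immature-like or adult-like branch
statistics, spatially uniform synaptic puncta along a skeleton (plus
sub-threshold decoys to exercise the filters), miniature-EPSC recordings
with Gaussian noise, and Gaussian fluorescence line profiles for diameter
estimation.

The two presets encode the published group statistics of cerebellar
stellate cells: equal primary-dendrite counts at both ages, more branch
points and longer maximal path length in the adult, dendritic diameters
near 0.47 µm (immature) vs 0.41 µm (adult), miniature-event amplitudes
near 48 vs 24 pA at rates near 1.37 vs 1.14 Hz, and a distance-uniform
puncta density shared by both ages.  All generators are deterministic
functions of their configuration, seed included.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cable import SynapseSpec, Trace, biexp_conductance, biexp_peak
from .mapping import PunctaRecord, Skeleton, resample_skeleton
from .morphology import MorphNode, Morphology, ROOT_PARENT

__all__ = [
    "GeneratorConfig",
    "IMMATURE",
    "ADULT",
    "generate_morphology",
    "generate_puncta",
    "generate_recording",
    "generate_line_profile",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic generators (one age preset).

    Morphology: ``n_primary`` dendrites grow outward from an
    ``soma_diameter`` µm soma with ``node_spacing`` µm steps, bifurcating
    with probability ``branch_prob_per_um`` per µm until the path length
    from the soma reaches ``max_path_length`` µm (jittered per dendrite by
    ``path_length_jitter``); node diameters are drawn from a truncated
    normal around ``diameter_mean``/``diameter_sd``.

    Puncta: homogeneous linear density ``puncta_density`` per µm of
    skeleton, with a ``decoy_fraction`` of sub-threshold spots.

    Events: Poisson rate ``event_rate`` Hz, amplitudes (pA) truncated-normal
    ``amplitude_mean``/``amplitude_sd``, biexponential kinetics
    ``event_tau0``/``event_tau1`` ms, recording noise ``noise_sd`` pA at
    sampling interval ``dt`` ms for ``duration`` s.
    """

    seed: int = 0
    stage: str = "immature"
    # morphology
    n_primary: int = 5
    soma_diameter: float = 8.0
    branch_prob_per_um: float = 0.025
    max_path_length: float = 60.0
    path_length_jitter: float = 10.0
    node_spacing: float = 1.0
    diameter_mean: float = 0.47
    diameter_sd: float = 0.08
    max_branch_order: int = 4
    # puncta
    puncta_density: float = 0.46
    decoy_fraction: float = 0.2
    # events
    event_rate: float = 1.37
    amplitude_mean: float = 48.0
    amplitude_sd: float = 7.0
    event_tau0: float = 0.177
    event_tau1: float = 0.503
    noise_sd: float = 4.8
    dt: float = 0.01
    duration: float = 10.0

    def __post_init__(self) -> None:
        if self.puncta_density < 0 or self.event_rate < 0 or self.duration < 0:
            raise ValueError("densities, rates and durations must be nonnegative")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))


IMMATURE = GeneratorConfig(stage="immature")
ADULT = GeneratorConfig(
    stage="adult",
    branch_prob_per_um=0.02,
    max_path_length=90.0,
    diameter_mean=0.41,
    event_rate=1.14,
    amplitude_mean=24.0,
    amplitude_sd=4.0,
    event_tau0=0.217,
    event_tau1=1.093,
    noise_sd=2.4,
)


# ---------------------------------------------------------------------------
# Morphology
# ---------------------------------------------------------------------------

def _draw_diameter(rng: np.random.Generator, cfg: GeneratorConfig) -> float:
    for _ in range(100):
        d = rng.normal(cfg.diameter_mean, cfg.diameter_sd)
        if d > 0.15:
            return float(d)
    return cfg.diameter_mean


def generate_morphology(cfg: GeneratorConfig) -> Morphology:
    """Grow a stochastic dendritic tree from the configured preset.

    Each primary dendrite starts at the soma surface pointing outward and
    advances in ``node_spacing`` steps with a small random directional
    wander; at each step it bifurcates with the configured probability (up
    to ``max_branch_order`` levels) and terminates when its path length
    reaches a per-dendrite jittered maximum.  Fixed seeds give bit-identical
    trees.
    """
    rng = cfg.rng(salt=1)
    r_soma = cfg.soma_diameter / 2.0
    nodes = [MorphNode(1, ROOT_PARENT, (0.0, 0.0, 0.0), r_soma, "soma")]
    next_id = 2

    def unit(v: np.ndarray) -> np.ndarray:
        return v / np.linalg.norm(v)

    def grow(parent_id: int, pos: np.ndarray, direction: np.ndarray,
             path_len: float, max_len: float, order: int) -> None:
        nonlocal next_id
        radius = _draw_diameter(rng, cfg) / 2.0
        while path_len < max_len:
            direction = unit(direction + 0.15 * rng.normal(size=3))
            pos = pos + direction * cfg.node_spacing
            path_len += cfg.node_spacing
            nodes.append(
                MorphNode(next_id, parent_id, tuple(pos), radius, "dendrite")
            )
            parent_id = next_id
            next_id += 1
            branch_here = (
                order < cfg.max_branch_order
                and rng.random() < cfg.branch_prob_per_um * cfg.node_spacing
            )
            if branch_here:
                for sign in (+1.0, -1.0):
                    perp = unit(np.cross(direction, rng.normal(size=3)))
                    child_dir = unit(direction + 0.6 * sign * perp)
                    grow(parent_id, pos.copy(), child_dir, path_len,
                         max_len, order + 1)
                return

    for k in range(cfg.n_primary):
        theta = 2.0 * math.pi * k / max(cfg.n_primary, 1)
        u = np.array([math.cos(theta), math.sin(theta), 0.0])
        start = u * r_soma
        nodes.append(
            MorphNode(next_id, 1, tuple(start),
                      _draw_diameter(rng, cfg) / 2.0, "dendrite")
        )
        attach_id = next_id
        next_id += 1
        max_len = max(
            cfg.node_spacing,
            cfg.max_path_length + rng.normal(0.0, cfg.path_length_jitter),
        )
        grow(attach_id, start.copy(), u, 0.0, max_len, order=1)
    return Morphology(nodes)


# ---------------------------------------------------------------------------
# Puncta
# ---------------------------------------------------------------------------

def generate_puncta(
    skeleton: Skeleton,
    density: float = 0.46,
    jitter: float = 0.1,
    seed: int = 0,
    decoy_fraction: float = 0.2,
    psf_xyz: tuple[float, float, float] = (0.3, 0.3, 1.1),
    background_mean: float = 100.0,
    background_sd: float = 10.0,
    resample_step: float = 0.1,
) -> tuple[list[PunctaRecord], pd.DataFrame]:
    """Homogeneous synaptic puncta along a skeleton, plus decoys.

    True puncta follow a Poisson point process of the given linear density
    along arclength, displaced radially by at most (local radius + jitter)
    so assignment within the standard search radius is guaranteed; their
    diameters and intensities exceed the filter thresholds.  A
    ``decoy_fraction`` of additional spots violates the size or intensity
    criterion.  Returns the spot list and a ground-truth table (is_decoy,
    true path distance).
    """
    rng = np.random.default_rng((seed, 2))
    samples = resample_skeleton(skeleton, step=resample_step)
    total_len = skeleton.total_length()
    n_true = rng.poisson(density * total_len) if density > 0 else 0
    records: list[PunctaRecord] = []
    truth_rows = []
    if samples.positions.shape[0] and n_true:
        idx = rng.integers(0, samples.positions.shape[0], size=n_true)
        for i in idx:
            base = samples.positions[i]
            radial = rng.normal(size=3)
            radial /= np.linalg.norm(radial)
            offset = rng.uniform(0.0, samples.radii[i] + jitter)
            pos = base + radial * offset
            diam = (
                psf_xyz[0] + rng.uniform(0.05, 0.3),
                psf_xyz[1] + rng.uniform(0.05, 0.3),
                psf_xyz[2] + rng.uniform(0.05, 0.3),
            )
            intensity = background_mean + background_sd * rng.uniform(4.0, 10.0)
            records.append(
                PunctaRecord(tuple(pos), diam, float(intensity),
                             soma_channel_intensity=0.0)
            )
            truth_rows.append(
                {"is_decoy": False,
                 "true_path_distance": float(samples.path_distance[i])}
            )
    n_decoy = rng.poisson(decoy_fraction * max(n_true, 1)) if decoy_fraction > 0 else 0
    for _ in range(n_decoy):
        if samples.positions.shape[0]:
            i = int(rng.integers(0, samples.positions.shape[0]))
            base = samples.positions[i]
        else:
            base = skeleton.soma_center
        pos = base + rng.normal(0.0, 0.5, size=3)
        if rng.random() < 0.5:
            # unresolved: at or below the PSF on at least one axis
            diam = (psf_xyz[0] * rng.uniform(0.5, 1.0), psf_xyz[1] * 1.2,
                    psf_xyz[2] * 1.2)
            intensity = background_mean + background_sd * rng.uniform(4.0, 10.0)
        else:
            # dim: below the mean + 3 SD intensity threshold
            diam = (psf_xyz[0] + 0.1, psf_xyz[1] + 0.1, psf_xyz[2] + 0.1)
            intensity = background_mean + background_sd * rng.uniform(0.0, 2.5)
        records.append(
            PunctaRecord(tuple(pos), diam, float(intensity),
                         soma_channel_intensity=0.0)
        )
        truth_rows.append({"is_decoy": True, "true_path_distance": np.nan})
    truth = pd.DataFrame(truth_rows, columns=["is_decoy", "true_path_distance"])
    return records, truth


# ---------------------------------------------------------------------------
# Recordings
# ---------------------------------------------------------------------------

def generate_recording(cfg: GeneratorConfig) -> tuple[Trace, pd.DataFrame]:
    """Miniature-EPSC recording: a Poisson train of inward biexponential
    currents plus white Gaussian noise.

    Returns the current trace (pA) and the ground-truth event table
    (onset_ms, amplitude_pA, tau0_ms, tau1_ms).
    """
    if cfg.duration <= 0:
        raise ValueError("duration must be positive")
    rng = cfg.rng(salt=3)
    duration_ms = cfg.duration * 1000.0
    n_samples = int(round(duration_ms / cfg.dt)) + 1
    x = (
        rng.normal(0.0, cfg.noise_sd, size=n_samples)
        if cfg.noise_sd > 0
        else np.zeros(n_samples)
    )
    window_margin = min(20.0, cfg.event_tau1 * 12.0)
    hi = duration_ms - window_margin
    n_events = rng.poisson(cfg.event_rate * cfg.duration) if hi > 0 else 0
    onsets = np.sort(rng.uniform(0.0, hi, size=n_events))
    amps = np.clip(
        rng.normal(cfg.amplitude_mean, cfg.amplitude_sd, size=n_events),
        cfg.amplitude_mean * 0.2,
        None,
    )
    shape = SynapseSpec(tau0=cfg.event_tau0, tau1=cfg.event_tau1, gmax=1.0)
    peak_per_gmax = biexp_peak(shape)
    window_ms = cfg.event_tau1 * 12.0
    n_win = int(round(window_ms / cfg.dt))
    t_win = cfg.dt * np.arange(n_win)
    kernel = biexp_conductance(t_win, shape) / peak_per_gmax  # unit peak
    for onset, amp in zip(onsets, amps):
        i0 = int(round(onset / cfg.dt))
        i1 = min(n_samples, i0 + n_win)
        x[i0:i1] -= amp * kernel[: i1 - i0]  # inward = negative
    truth = pd.DataFrame({
        "onset_ms": onsets,
        "amplitude_pA": amps,
        "tau0_ms": cfg.event_tau0,
        "tau1_ms": cfg.event_tau1,
    })
    return Trace(dt=cfg.dt, samples=x, unit="pA"), truth


# ---------------------------------------------------------------------------
# Line profiles
# ---------------------------------------------------------------------------

_FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


def generate_line_profile(
    diameter: float,
    noise_sd: float = 0.0,
    sample_spacing: float = 0.05,
    seed: int = 0,
    center: float = 0.0,
    amplitude: float = 1.0,
    baseline: float = 0.0,
    half_span: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian fluorescence line profile whose FWHM equals ``diameter``.

    ``noise_sd`` is additive Gaussian noise expressed as a fraction of the
    peak amplitude.  Returns (positions, intensities).
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    sigma = diameter / _FWHM_PER_SIGMA
    if half_span is None:
        half_span = 4.0 * sigma
    x = np.arange(center - half_span, center + half_span + sample_spacing / 2,
                  sample_spacing)
    y = baseline + amplitude * np.exp(-0.5 * ((x - center) / sigma) ** 2)
    if noise_sd > 0:
        rng = np.random.default_rng((seed, 4))
        y = y + rng.normal(0.0, noise_sd * amplitude, size=x.size)
    return x, y
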