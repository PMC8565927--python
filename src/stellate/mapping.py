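"""Mapping fluorescent synaptic puncta onto dendritic skeletons.

The pipeline consumes candidate-spot tables exported from image analysis
software (position, per-axis diameter, peak intensity, optional
soma-channel intensity) and a skeleton (centerline polylines with local
radii).  Spots are filtered against the imaging point-spread function and
background noise, assigned to the nearest skeleton sample within a search
radius of (local dendritic radius + alpha), and summarized as distance
histograms (10 µm bins), linear densities and cumulative distributions
(1 µm sampling), with a Kolmogorov-Smirnov two-sample comparison utility
and Pearson's median skewness as a shape summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import ks_2samp

from .morphology import Morphology

__all__ = [
    "PunctaRecord",
    "FilterCriteria",
    "Branch",
    "Skeleton",
    "SkeletonSamples",
    "skeleton_from_morphology",
    "filter_puncta",
    "select_somatic_puncta",
    "resample_skeleton",
    "assign_puncta",
    "distance_histogram",
    "DistanceHistogram",
    "cumulative_distribution",
    "compare_distributions",
    "pearson_median_skewness",
    "puncta_table",
    "puncta_from_table",
]

PUNCTA_COLUMNS = [
    "x", "y", "z",
    "diameter_x", "diameter_y", "diameter_z",
    "peak_intensity", "soma_channel_intensity",
]


@dataclass(frozen=True)
class PunctaRecord:
    """One candidate fluorescent spot (µm, arbitrary intensity units)."""

    position: tuple[float, float, float]
    diameter_xyz: tuple[float, float, float]
    peak_intensity: float
    soma_channel_intensity: float | None = None

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.diameter_xyz):
            raise ValueError("diameters must be positive")
        if self.peak_intensity < 0:
            raise ValueError("intensity must be nonnegative")


@dataclass(frozen=True)
class FilterCriteria:
    """Spot acceptance thresholds.

    psf_xyz: imaging point-spread function FWHM per axis (µm); spots no
    larger than the PSF on any axis are rejected as unresolved.
    background_mean/sd: background-intensity statistics; accepted spots must
    exceed mean + 3*SD.
    """

    psf_xyz: tuple[float, float, float] = (0.3, 0.3, 1.1)
    background_mean: float = 0.0
    background_sd: float = 0.0

    def __post_init__(self) -> None:
        if any(p <= 0 for p in self.psf_xyz):
            raise ValueError("PSF must be positive")
        if self.background_sd < 0:
            raise ValueError("background SD must be nonnegative")


def _passes_size_intensity(p: PunctaRecord, c: FilterCriteria) -> bool:
    size_ok = all(d > psf for d, psf in zip(p.diameter_xyz, c.psf_xyz))
    intensity_ok = (
        p.peak_intensity > c.background_mean + 3.0 * c.background_sd
    )
    return size_ok and intensity_ok


def filter_puncta(
    puncta: list[PunctaRecord], c: FilterCriteria
) -> list[PunctaRecord]:
    """Keep spots strictly larger than the PSF on all three axes and with
    peak intensity strictly above background mean + 3*SD."""
    return [p for p in puncta if _passes_size_intensity(p, c)]


def select_somatic_puncta(
    puncta: list[PunctaRecord],
    stack_max_soma_channel: float,
    c: FilterCriteria,
) -> list[PunctaRecord]:
    """Spots on the soma: soma-channel intensity above half the stack
    maximum, in addition to the size/intensity criteria."""
    for p in puncta:
        if p.soma_channel_intensity is None:
            raise ValueError("puncta lack soma-channel intensities")
    return [
        p
        for p in puncta
        if p.soma_channel_intensity > 0.5 * stack_max_soma_channel
        and _passes_size_intensity(p, c)
    ]


# ---------------------------------------------------------------------------
# Skeletons
# ---------------------------------------------------------------------------

@dataclass
class Branch:
    """A dendritic centerline polyline with per-point local radii.

    ``parent`` indexes the parent branch (-1 for primary branches attached
    at the soma); ``attach_arclength`` is the arclength along the parent at
    which this branch starts (its first point must coincide with the parent
    centerline there).
    """

    points: np.ndarray
    radii: np.ndarray
    parent: int = -1
    attach_arclength: float = 0.0

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.radii = np.asarray(self.radii, dtype=float)
        if self.points.shape[0] != self.radii.size:
            raise ValueError("one radius per point required")
        if np.any(self.radii <= 0):
            raise ValueError("radii must be positive")

    def arclength(self) -> np.ndarray:
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(steps)])


@dataclass
class Skeleton:
    """Dendritic tree as branches plus the soma sphere."""

    branches: list[Branch]
    soma_center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    soma_radius: float = 4.0

    def __post_init__(self) -> None:
        self.soma_center = np.asarray(self.soma_center, dtype=float)
        for bi, b in enumerate(self.branches):
            if b.parent >= bi:
                raise ValueError("parent branches must precede children")
            if b.parent >= 0:
                pb = self.branches[b.parent]
                s = pb.arclength()
                attach = _interp_along(pb.points, s, b.attach_arclength)
                if np.linalg.norm(attach - b.points[0]) > 1e-6:
                    raise ValueError(
                        f"branch {bi} start does not coincide with its "
                        "parent attachment point"
                    )

    def total_length(self) -> float:
        return float(sum(b.arclength()[-1] for b in self.branches))


def _interp_along(points: np.ndarray, s: np.ndarray, target: float) -> np.ndarray:
    target = min(max(target, s[0]), s[-1])
    return np.array([
        np.interp(target, s, points[:, k]) for k in range(points.shape[1])
    ])


def skeleton_from_morphology(m: Morphology) -> Skeleton:
    """Convert a morphology tree into branch polylines.

    Branches are maximal unbranched dendritic paths; primary branches start
    at the soma surface (path-distance origin).
    """
    branches: list[Branch] = []

    def walk(start_id: int, parent_branch: int, attach_arc: float,
             prefix: tuple | None = None) -> None:
        # prefix carries the branch-point sample so every child polyline
        # starts exactly at its parent attachment point
        pts = [prefix[0]] if prefix else []
        rads = [prefix[1]] if prefix else []
        nid = start_id
        while True:
            node = m.node(nid)
            pts.append(node.position)
            rads.append(node.radius)
            kids = [k for k in m.children(nid) if m.node(k).kind == "dendrite"]
            if len(kids) != 1:
                break
            nid = kids[0]
        b = Branch(
            points=np.asarray(pts),
            radii=np.asarray(rads),
            parent=parent_branch,
            attach_arclength=attach_arc,
        )
        branches.append(b)
        bi = len(branches) - 1
        end = m.node(nid)
        end_arc = float(b.arclength()[-1])
        for k in [k for k in m.children(nid) if m.node(k).kind == "dendrite"]:
            walk(k, bi, end_arc, prefix=(end.position, end.radius))

    for child in m.children(m.root.id):
        if m.node(child).kind == "dendrite":
            walk(child, -1, 0.0)
    return Skeleton(
        branches=branches,
        soma_center=m.soma_center(),
        soma_radius=m.soma_radius,
    )


@dataclass
class SkeletonSamples:
    """Output of :func:`resample_skeleton`: positions (N,3), local radii,
    path distances from the soma surface, and branch ids, all aligned."""

    positions: np.ndarray
    radii: np.ndarray
    path_distance: np.ndarray
    branch_id: np.ndarray


def resample_skeleton(s: Skeleton, step: float = 0.1) -> SkeletonSamples:
    """Resample every branch at fixed arclength intervals (default 100 nm).

    Samples sit at multiples of ``step`` from each branch start, always
    including arclength 0 and the branch terminus if it is not a multiple.
    Radii are interpolated linearly; each sample's path distance is the
    branch-start distance plus within-branch arclength, with primary
    branches starting at distance 0 (the soma surface).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    origin: list[float] = []
    pos_all, rad_all, dist_all, bid_all = [], [], [], []
    for bi, b in enumerate(s.branches):
        arc = b.arclength()
        length = float(arc[-1])
        if b.parent < 0:
            start_dist = 0.0
        else:
            start_dist = origin[b.parent] + b.attach_arclength
        origin.append(start_dist)
        n_full = int(np.floor(length / step + 1e-9))
        ticks = list(np.arange(n_full + 1) * step)
        if length - ticks[-1] > 1e-9:
            ticks.append(length)
        ticks = np.asarray(ticks)
        pts = np.column_stack([
            np.interp(ticks, arc, b.points[:, k]) for k in range(3)
        ])
        rads = np.interp(ticks, arc, b.radii)
        pos_all.append(pts)
        rad_all.append(rads)
        dist_all.append(start_dist + ticks)
        bid_all.append(np.full(ticks.size, bi, dtype=int))
    if not pos_all:
        return SkeletonSamples(
            np.empty((0, 3)), np.empty(0), np.empty(0), np.empty(0, dtype=int)
        )
    return SkeletonSamples(
        positions=np.vstack(pos_all),
        radii=np.concatenate(rad_all),
        path_distance=np.concatenate(dist_all),
        branch_id=np.concatenate(bid_all),
    )


# ---------------------------------------------------------------------------
# Assignment and distance statistics
# ---------------------------------------------------------------------------

def assign_puncta(
    puncta: list[PunctaRecord],
    samples: SkeletonSamples,
    alpha: float = 0.2,
) -> pd.DataFrame:
    """Assign each punctum to the nearest qualifying skeleton sample.

    A sample qualifies if the Euclidean distance from the punctum center is
    at most (sample local radius + alpha).  Assigned puncta inherit the
    sample's path distance.  Returns a table with one row per punctum:
    columns assigned (bool), sample_index, distance_to_sample,
    path_distance, branch_id.
    """
    n = len(puncta)
    out = {
        "assigned": np.zeros(n, dtype=bool),
        "sample_index": np.full(n, -1, dtype=int),
        "distance_to_sample": np.full(n, np.nan),
        "path_distance": np.full(n, np.nan),
        "branch_id": np.full(n, -1, dtype=int),
    }
    if n and samples.positions.shape[0]:
        tree = cKDTree(samples.positions)
        r_max = float(samples.radii.max()) + alpha
        pts = np.asarray([p.position for p in puncta], dtype=float)
        neighbor_lists = tree.query_ball_point(pts, r_max)
        for i, neighbors in enumerate(neighbor_lists):
            if not neighbors:
                continue
            idx = np.asarray(neighbors, dtype=int)
            d = np.linalg.norm(samples.positions[idx] - pts[i], axis=1)
            ok = d <= samples.radii[idx] + alpha
            if not np.any(ok):
                continue
            idx, d = idx[ok], d[ok]
            j = int(np.argmin(d))
            out["assigned"][i] = True
            out["sample_index"][i] = idx[j]
            out["distance_to_sample"][i] = d[j]
            out["path_distance"][i] = samples.path_distance[idx[j]]
            out["branch_id"][i] = samples.branch_id[idx[j]]
    return pd.DataFrame(out)


@dataclass
class DistanceHistogram:
    """Binned distance distribution of assigned puncta.

    ``segment_counts`` counts resampled skeleton samples per bin; density is
    puncta per µm of dendrite, computed as counts/(segments * step).
    """

    bin_edges: np.ndarray
    puncta_counts: np.ndarray
    segment_counts: np.ndarray
    density_per_um: np.ndarray
    density_per_segment: np.ndarray


def distance_histogram(
    assignments: pd.DataFrame,
    samples: SkeletonSamples,
    bin_width: float = 10.0,
    step: float = 0.1,
) -> DistanceHistogram:
    """Histogram of assigned-puncta path distances in half-open bins
    [lo, hi) of ``bin_width`` µm, with per-bin linear densities."""
    d = assignments.loc[assignments["assigned"], "path_distance"].to_numpy()
    max_d = max(
        float(samples.path_distance.max(initial=0.0)),
        float(d.max(initial=0.0)),
    )
    n_bins = max(1, int(np.ceil((max_d + 1e-9) / bin_width)))
    edges = bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(d, bins=edges)
    seg_counts, _ = np.histogram(samples.path_distance, bins=edges)
    with np.errstate(divide="ignore", invalid="ignore"):
        dens_um = np.where(seg_counts > 0, counts / (seg_counts * step), np.nan)
        dens_seg = np.where(seg_counts > 0, counts / seg_counts, np.nan)
    return DistanceHistogram(
        bin_edges=edges,
        puncta_counts=counts,
        segment_counts=seg_counts,
        density_per_um=dens_um,
        density_per_segment=dens_seg,
    )


def cumulative_distribution(
    assignments: pd.DataFrame, step: float = 1.0
) -> pd.DataFrame:
    """Empirical CDF of assigned-puncta path distances on a ``step`` µm grid
    (columns distance_um, cumulative_fraction)."""
    d = np.sort(assignments.loc[assignments["assigned"], "path_distance"].to_numpy())
    if d.size == 0:
        raise ValueError("no assigned puncta")
    grid = step * np.arange(int(np.ceil(d.max() / step)) + 1)
    frac = np.searchsorted(d, grid, side="right") / d.size
    return pd.DataFrame({"distance_um": grid, "cumulative_fraction": frac})


def compare_distributions(distances_a, distances_b) -> dict:
    """Two-sample Kolmogorov-Smirnov test on raw path distances."""
    a = np.asarray(list(distances_a), dtype=float)
    b = np.asarray(list(distances_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = ks_2samp(a, b)
    return {"statistic": float(res.statistic), "pvalue": float(res.pvalue)}


def pearson_median_skewness(values) -> float:
    """Pearson's second skewness coefficient: 3*(mean - median)/SD
    (sample SD, n-1)."""
    x = np.asarray(list(values), dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise ValueError("zero dispersion")
    return 3.0 * (float(np.mean(x)) - float(np.median(x))) / sd


# ---------------------------------------------------------------------------
# Delimited-text I/O for spot tables
# ---------------------------------------------------------------------------

def puncta_table(puncta: list[PunctaRecord]) -> pd.DataFrame:
    """Spot list as a DataFrame with the documented column names."""
    rows = []
    for p in puncta:
        rows.append(
            (*p.position, *p.diameter_xyz, p.peak_intensity,
             np.nan if p.soma_channel_intensity is None
             else p.soma_channel_intensity)
        )
    return pd.DataFrame(rows, columns=PUNCTA_COLUMNS)


def puncta_from_table(df: pd.DataFrame) -> list[PunctaRecord]:
    """Inverse of :func:`puncta_table`."""
    out = []
    for row in df.itertuples(index=False):
        soma = getattr(row, "soma_channel_intensity", None)
        if soma is not None and np.isnan(soma):
            soma = None
        out.append(
            PunctaRecord(
                position=(row.x, row.y, row.z),
                diameter_xyz=(row.diameter_x, row.diameter_y, row.diameter_z),
                peak_intensity=row.peak_intensity,
                soma_channel_intensity=soma,
            )
        )
    return out
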