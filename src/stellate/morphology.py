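"""Neuronal morphology data model, SWC I/O and morphometrics.

A morphology is a rooted tree of 3D points with radii, in µm.  The root is a
single soma node treated electrically as an isopotential sphere; dendrites
attach at the soma surface.  Morphometrics implemented here are the ones used
to characterise stellate-cell dendritic trees: path distances, Sholl
intersection counts, branch-point statistics and dendritic-diameter
estimation from fluorescence line profiles (Gaussian FWHM).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, TextIO

import warnings

import networkx as nx
import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

__all__ = [
    "MorphNode",
    "Morphology",
    "MorphologyError",
    "read_swc",
    "write_swc",
    "build_idealized_sc",
    "path_distance",
    "sholl_analysis",
    "branch_statistics",
    "estimate_diameter_fwhm",
]

# SWC structure-type codes
_SWC_KIND = {"soma": 1, "axon": 2, "dendrite": 3}
_KIND_FROM_SWC = {1: "soma", 2: "axon", 3: "dendrite", 4: "dendrite"}

ROOT_PARENT = -1


class MorphologyError(ValueError):
    """Raised for malformed morphologies (cycles, orphans, bad radii)."""


@dataclass(frozen=True)
class MorphNode:
    """One sample point of a morphology.

    position is (x, y, z) in µm, radius in µm; kind is one of
    ``soma`` / ``dendrite`` / ``axon``.
    """

    id: int
    parent_id: int
    position: tuple[float, float, float]
    radius: float
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in _SWC_KIND:
            raise MorphologyError(f"node {self.id}: unknown kind {self.kind!r}")
        if not self.radius > 0:
            raise MorphologyError(f"node {self.id}: nonpositive radius {self.radius}")


@dataclass
class Morphology:
    """A validated rooted tree of :class:`MorphNode`.

    ``soma_surface_offset`` is subtracted from path distances measured with
    the ``soma_surface`` origin (defaults to the root radius).
    """

    nodes: list[MorphNode] = field(default_factory=list)
    soma_surface_offset: float | None = None

    def __post_init__(self) -> None:
        self._index: dict[int, MorphNode] = {}
        self._children: dict[int, list[int]] = {}
        self._validate()

    # -- structure ---------------------------------------------------------
    def _validate(self) -> None:
        if not self.nodes:
            raise MorphologyError("empty morphology")
        self._index = {}
        for n in self.nodes:
            if n.id in self._index:
                raise MorphologyError(f"duplicate node id {n.id}")
            self._index[n.id] = n
        roots = [n for n in self.nodes if n.parent_id == ROOT_PARENT]
        if len(roots) != 1:
            raise MorphologyError(f"expected exactly one root, found {len(roots)}")
        self._root = roots[0]
        if self._root.kind != "soma":
            raise MorphologyError(f"root node {self._root.id} must be soma")
        g = nx.DiGraph()
        for n in self.nodes:
            g.add_node(n.id)
        self._children = {n.id: [] for n in self.nodes}
        for n in self.nodes:
            if n.parent_id == ROOT_PARENT:
                continue
            if n.parent_id not in self._index:
                raise MorphologyError(f"node {n.id}: undefined parent {n.parent_id}")
            g.add_edge(n.parent_id, n.id)
            self._children[n.parent_id].append(n.id)
        if not nx.is_arborescence(g):
            raise MorphologyError("morphology graph is not a rooted tree")
        if self.soma_surface_offset is None:
            self.soma_surface_offset = self._root.radius

    @property
    def root(self) -> MorphNode:
        return self._root

    def node(self, node_id: int) -> MorphNode:
        try:
            return self._index[node_id]
        except KeyError:
            raise MorphologyError(f"unknown node id {node_id}") from None

    def children(self, node_id: int) -> list[int]:
        return self._children[node_id]

    def soma_center(self) -> np.ndarray:
        return np.asarray(self._root.position, dtype=float)

    @property
    def soma_radius(self) -> float:
        return self._root.radius

    def dendrite_nodes(self) -> list[MorphNode]:
        return [n for n in self.nodes if n.kind == "dendrite"]

    def edges(self, kind: str | None = None) -> list[tuple[MorphNode, MorphNode]]:
        """(parent, child) node pairs; optionally restricted to a child kind."""
        out = []
        for n in self.nodes:
            if n.parent_id == ROOT_PARENT:
                continue
            if kind is not None and n.kind != kind:
                continue
            out.append((self._index[n.parent_id], n))
        return out

    def tips(self, kind: str = "dendrite") -> list[MorphNode]:
        return [
            n for n in self.nodes if n.kind == kind and not self._children[n.id]
        ]

    def total_length(self, kind: str = "dendrite") -> float:
        """Total cable length of a neurite kind.

        Edges from the soma to a neurite attachment node lie inside the soma
        sphere and carry no cable, so only edges whose two endpoints are both
        of the requested kind contribute.
        """
        return float(
            sum(
                _dist(p.position, c.position)
                for p, c in self.edges(kind)
                if p.kind == kind
            )
        )

    def node_table(self) -> list[tuple]:
        """Node rows as (id, kind, x, y, z, radius, parent_id)."""
        return [
            (n.id, n.kind, *n.position, n.radius, n.parent_id) for n in self.nodes
        ]


def _dist(a: Iterable[float], b: Iterable[float]) -> float:
    return math.dist(tuple(a), tuple(b))


# ---------------------------------------------------------------------------
# SWC I/O (7-column dialect: id type x y z radius parent; µm; parent -1 = root)
# ---------------------------------------------------------------------------

def read_swc(source: TextIO | str) -> Morphology:
    """Read a 7-column SWC stream or file path into a :class:`Morphology`."""
    if isinstance(source, str):
        with open(source) as fh:
            return read_swc(fh)
    nodes: list[MorphNode] = []
    for lineno, line in enumerate(source, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise MorphologyError(f"SWC line {lineno}: expected 7 columns, got {len(parts)}")
        try:
            nid, kind_code = int(parts[0]), int(parts[1])
            x, y, z, radius = (float(v) for v in parts[2:6])
            parent = int(parts[6])
        except ValueError as exc:
            raise MorphologyError(f"SWC line {lineno}: {exc}") from None
        kind = _KIND_FROM_SWC.get(kind_code, "dendrite")
        nodes.append(MorphNode(nid, parent, (x, y, z), radius, kind))
    return Morphology(nodes)


def write_swc(m: Morphology, dest: TextIO | str) -> None:
    """Write a morphology as 7-column SWC."""
    if isinstance(dest, str):
        with open(dest, "w") as fh:
            write_swc(m, fh)
        return
    dest.write("# id type x y z radius parent\n")
    for n in m.nodes:
        x, y, z = n.position
        dest.write(
            f"{n.id} {_SWC_KIND[n.kind]} {x:.6g} {y:.6g} {z:.6g} "
            f"{n.radius:.6g} {n.parent_id}\n"
        )


# ---------------------------------------------------------------------------
# Idealized stellate-cell morphology
# ---------------------------------------------------------------------------

def build_idealized_sc(
    soma_diameter: float = 8.0,
    n_dendrites: int = 1,
    dendrite_length: float = 90.0,
    dendrite_diameter: float = 0.47,
    branches_per_dendrite: int = 1,
    node_spacing: float = 1.0,
) -> Morphology:
    """Build the idealized stellate-cell model: a spherical soma with
    straight, uniform-diameter dendrites attached at the soma surface.

    ``branches_per_dendrite`` of 1 gives unbranched dendrites; 3 or 5 split
    each dendrite into daughter branches at equal fractions of its length
    (1 split point for 3 terminal branches would be ambiguous, so the
    convention here is: the mother bifurcates at L/k fractions so the tree
    has the requested number of terminal branches, daughters sharing the
    mother diameter).  Total path length per dendrite equals
    ``dendrite_length`` along any root-to-tip path.
    """
    if soma_diameter <= 0:
        raise MorphologyError("soma_diameter must be positive")
    if n_dendrites > 0:
        if dendrite_length <= 0 or dendrite_diameter <= 0:
            raise MorphologyError("dendrite dimensions must be positive")
        if node_spacing <= 0:
            raise MorphologyError("node_spacing must be positive")
        if branches_per_dendrite not in (1, 3, 5):
            raise MorphologyError("branches_per_dendrite must be 1, 3 or 5")

    r_soma = soma_diameter / 2.0
    r_dend = dendrite_diameter / 2.0
    nodes = [MorphNode(1, ROOT_PARENT, (0.0, 0.0, 0.0), r_soma, "soma")]
    next_id = 2

    def add_segment(parent_id: int, start: np.ndarray, direction: np.ndarray,
                    length: float) -> int:
        """Append a straight run of nodes every node_spacing; return last id."""
        nonlocal next_id
        n_steps = max(1, int(round(length / node_spacing)))
        step = length / n_steps
        pos = start.copy()
        pid = parent_id
        for _ in range(n_steps):
            pos = pos + direction * step
            nodes.append(
                MorphNode(next_id, pid, tuple(pos), r_dend, "dendrite")
            )
            pid = next_id
            next_id += 1
        return pid

    # n_splits successive bifurcations yield n_splits+1 terminal branches:
    # 1 -> unbranched, 3 -> 2 splits, 5 -> 4 splits.
    n_splits = branches_per_dendrite - 1 if branches_per_dendrite > 1 else 0
    for k in range(n_dendrites):
        theta = 2.0 * math.pi * k / max(n_dendrites, 1)
        u = np.array([math.cos(theta), math.sin(theta), 0.0])
        start = u * r_soma
        # attachment node on the soma surface; the soma->attachment edge lies
        # inside the soma sphere and carries no dendritic cable
        nodes.append(MorphNode(next_id, 1, tuple(start), r_dend, "dendrite"))
        attach_id = next_id
        next_id += 1
        if n_splits == 0:
            add_segment(attach_id, start, u, dendrite_length)
            continue
        # mother trunk then splits at equal length fractions; one daughter of
        # each split continues along the trunk axis, the other runs parallel
        # after a small lateral offset, so every tip is dendrite_length from
        # the soma surface along its path.
        frac = dendrite_length / (n_splits + 1)
        pid = attach_id
        pos = start.copy()
        for s in range(n_splits):
            pid = add_segment(pid, pos, u, frac)
            pos = pos + u * frac
            # lateral daughter: runs at a fixed angle covering the remaining length
            lateral = np.array([-u[1], u[0], 0.0])
            remaining = dendrite_length - (s + 1) * frac
            v = (u + 0.35 * (s + 1) * lateral)
            v = v / np.linalg.norm(v)
            add_segment(pid, pos, v, remaining)
        add_segment(pid, pos, u, dendrite_length - n_splits * frac)
    return Morphology(nodes)


# ---------------------------------------------------------------------------
# Morphometrics
# ---------------------------------------------------------------------------

def path_distance(m: Morphology, node_id: int, origin: str = "soma_center") -> float:
    """Path distance (µm) from the soma to a node, along the tree.

    ``origin='soma_center'`` sums Euclidean inter-node steps from the root;
    ``origin='soma_surface'`` subtracts the soma radius along the first step,
    floored at zero.
    """
    if origin not in ("soma_center", "soma_surface"):
        raise ValueError(f"unknown origin {origin!r}")
    node = m.node(node_id)
    total = 0.0
    while node.parent_id != ROOT_PARENT:
        parent = m.node(node.parent_id)
        total += _dist(parent.position, node.position)
        node = parent
    if origin == "soma_surface":
        total = max(0.0, total - m.soma_surface_offset)
    return total


def sholl_analysis(m: Morphology, radii: Iterable[float]) -> np.ndarray:
    """Number of dendritic segments intersecting concentric spheres centred
    at the soma center, one count per radius."""
    radii = np.asarray(list(radii), dtype=float)
    if radii.size and np.any(np.diff(radii) <= 0):
        raise ValueError("radii must be strictly increasing")
    c = m.soma_center()
    counts = np.zeros(radii.size, dtype=int)
    for parent, child in m.edges(kind="dendrite"):
        p = np.asarray(parent.position) - c
        q = np.asarray(child.position) - c
        lo, hi = _segment_radial_range(p, q)
        # half-open in the radial range so a sphere through a shared node
        # counts one segment, not both
        counts += (lo < radii) & (radii <= hi)
    return counts


def _segment_radial_range(p: np.ndarray, q: np.ndarray) -> tuple[float, float]:
    """Min and max distance from the origin over the segment p->q."""
    d = q - p
    dd = float(d @ d)
    rp, rq = float(np.linalg.norm(p)), float(np.linalg.norm(q))
    hi = max(rp, rq)
    if dd == 0.0:
        return rp, hi
    t = -float(p @ d) / dd
    if 0.0 < t < 1.0:
        lo = float(np.linalg.norm(p + t * d))
    else:
        lo = min(rp, rq)
    return lo, hi


def _subtree_max_path(m: Morphology, node_id: int) -> float:
    """Longest path length (µm) from node_id down to any descendant tip."""
    best = 0.0
    stack = [(node_id, 0.0)]
    while stack:
        nid, acc = stack.pop()
        kids = m.children(nid)
        if not kids:
            best = max(best, acc)
        for k in kids:
            step = _dist(m.node(nid).position, m.node(k).position)
            stack.append((k, acc + step))
    return best


def branch_statistics(m: Morphology, min_branch_length: float = 10.0) -> dict:
    """Branch-point statistics of the dendritic tree.

    Primary dendrites are dendrite nodes whose parent is the soma.  A branch
    point is counted only if at least two daughter subtrees each extend more
    than ``min_branch_length`` µm (short twigs do not define a branch).
    ``max_dendritic_length`` is the greatest tip-to-soma path distance,
    measured from the soma center.
    """
    primaries = [
        n for n in m.dendrite_nodes() if m.node(n.parent_id).kind == "soma"
    ] if len(m.nodes) > 1 else []
    n_primary = len(primaries)
    n_branch_points = 0
    for n in m.dendrite_nodes():
        kids = [k for k in m.children(n.id) if m.node(k).kind == "dendrite"]
        if len(kids) < 2:
            continue
        long_daughters = sum(
            1
            for k in kids
            if _dist(n.position, m.node(k).position) + _subtree_max_path(m, k)
            > min_branch_length
        )
        if long_daughters >= 2:
            n_branch_points += 1
    tips = m.tips("dendrite")
    max_len = max(
        (path_distance(m, t.id, "soma_center") for t in tips), default=0.0
    )
    return {
        "n_primary": n_primary,
        "branch_points_per_primary": (
            n_branch_points / n_primary if n_primary else 0.0
        ),
        "n_branch_points": n_branch_points,
        "max_dendritic_length": max_len,
    }


# ---------------------------------------------------------------------------
# Diameter estimation from fluorescence line profiles
# ---------------------------------------------------------------------------

_FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.3548...


def estimate_diameter_fwhm(
    positions: Iterable[float], intensities: Iterable[float]
) -> float:
    """Dendritic diameter (µm) as the FWHM of a Gaussian least-squares fit
    (amplitude, center, sigma, baseline) to an intensity line profile taken
    perpendicular to the dendrite.
    """
    x = np.asarray(list(positions), dtype=float)
    y = np.asarray(list(intensities), dtype=float)
    if x.size < 7:
        raise ValueError("need at least 7 samples spanning the peak")

    def gauss(x, amp, mu, sigma, base):
        return base + amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)

    base0 = float(np.min(y))
    amp0 = float(np.max(y) - base0)
    mu0 = float(x[np.argmax(y)])
    span = float(x.max() - x.min())
    sigma0 = max(span / 6.0, 1e-3)
    try:
        with warnings.catch_warnings():
            # noiseless profiles fit exactly; the singular covariance is fine
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(
                gauss, x, y, p0=[amp0, mu0, sigma0, base0], maxfev=10000
            )
    except RuntimeError as exc:
        raise ValueError(f"Gaussian fit failed: {exc}") from None
    amp, mu, sigma, base = popt
    sigma = abs(float(sigma))
    if amp <= 0 or sigma > span or not (x.min() <= mu <= x.max()):
        raise ValueError(
            "profile is not peaked: fitted "
            f"amplitude={amp:.3g}, center={mu:.3g}, sigma={sigma:.3g}"
        )
    return _FWHM_PER_SIGMA * sigma
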