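"""Neuronal morphologies: SWC I/O, Sholl analysis, branch metrics, synthesis.

A morphology is a rooted tree of 3D points with radii, stored in the standard
7-column SWC dialect (id, type, x, y, z, radius, parent; type codes 1=soma,
2=axon, 3=dendrite).  All lengths are micrometres.  The module provides the
morphometric quantities used to characterize medium spiny neuron dendritic
arbors — Sholl intersection profiles and their geometric centroid, maximum
dendritic radius, neuropil coverage area, and the branch decomposition — plus
a stochastic generator of MSN-like trees with wild-type and knockout presets
(the knockout preset encodes the experimentally observed direction of effect:
roughly twofold larger total dendritic length, more branches and branching
points, larger maximal Sholl radius).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "NodeKind",
    "MorphNode",
    "Morphology",
    "ShollProfile",
    "MorphoSummary",
    "MorphogenParams",
    "MorphologyError",
    "SWCParseError",
    "StructureError",
    "GenerationError",
    "read_swc",
    "write_swc",
    "sholl",
    "centroid",
    "max_radius",
    "coverage_area",
    "branch_metrics",
    "estimate_spine_number",
    "synthesize_morphology",
    "morphogen_preset",
    "total_dendritic_length",
]


class MorphologyError(ValueError):
    """Base class for morphology errors."""


class SWCParseError(MorphologyError):
    """Malformed SWC content (carries the 1-based line number)."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line else message)


class StructureError(MorphologyError):
    """Tree-structure violation (orphan parent, multiple roots, ...)."""


class GenerationError(MorphologyError):
    """Synthetic generator could not satisfy its target constraints."""


class NodeKind(Enum):
    soma = 1
    axon = 2
    dendrite = 3

    @classmethod
    def from_swc_code(cls, code: int) -> "NodeKind":
        mapping = {1: cls.soma, 2: cls.axon, 3: cls.dendrite}
        if code in mapping:
            return mapping[code]
        warnings.warn(
            f"unknown SWC type code {code}; treating as dendrite", stacklevel=3
        )
        return cls.dendrite


@dataclass(frozen=True)
class MorphNode:
    """One SWC point: position, radius and parent link (-1 for the root)."""

    id: int
    parent_id: int
    kind: NodeKind
    x: float
    y: float
    z: float
    radius: float

    def __post_init__(self):
        if self.id <= 0:
            raise StructureError(f"node id must be positive, got {self.id}")
        if self.radius <= 0:
            raise StructureError(f"node {self.id}: radius must be > 0")

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class Morphology:
    """An ordered, connected tree of :class:`MorphNode` with a label."""

    nodes: list[MorphNode]
    label: str = ""
    provenance: str = "reconstructed"  # or "synthetic"

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not self.nodes:
            raise StructureError("morphology has no nodes")
        seen: set[int] = set()
        n_roots = 0
        for node in self.nodes:
            if node.id in seen:
                raise StructureError(f"duplicate node id {node.id}")
            if node.parent_id == -1:
                n_roots += 1
            elif node.parent_id not in seen:
                raise StructureError(
                    f"node {node.id} references undefined parent {node.parent_id}"
                )
            seen.add(node.id)
        if n_roots != 1:
            raise StructureError(f"expected exactly one root, found {n_roots}")
        if not any(n.kind is NodeKind.soma for n in self.nodes):
            raise StructureError("morphology contains no soma node")

    # -- convenience accessors -------------------------------------------------

    def node_by_id(self, node_id: int) -> MorphNode:
        return self._index()[node_id]

    def _index(self) -> dict[int, MorphNode]:
        return {n.id: n for n in self.nodes}

    def soma_center(self) -> np.ndarray:
        """Centroid of the soma nodes (the Sholl origin)."""
        pts = np.array([n.xyz for n in self.nodes if n.kind is NodeKind.soma])
        return pts.mean(axis=0)

    def segments(self, dendrite_only: bool = True) -> Iterator[tuple[MorphNode, MorphNode]]:
        """Yield (parent, child) cable segments.

        With ``dendrite_only`` a segment counts as dendritic cable when the
        child is a dendrite node and the parent is not axonal; this includes
        the stem segments that attach primary dendrites to the soma.
        """
        index = self._index()
        for child in self.nodes:
            if child.parent_id == -1:
                continue
            parent = index[child.parent_id]
            if dendrite_only:
                if child.kind is not NodeKind.dendrite or parent.kind is NodeKind.axon:
                    continue
            yield parent, child

    def __eq__(self, other) -> bool:
        if not isinstance(other, Morphology):
            return NotImplemented
        return self.nodes == other.nodes and self.label == other.label


def total_dendritic_length(morphology: Morphology) -> float:
    """Summed Euclidean length of all dendritic cable segments (µm)."""
    return float(
        sum(
            np.linalg.norm(c.xyz - p.xyz)
            for p, c in morphology.segments(dendrite_only=True)
        )
    )


# -- SWC I/O ------------------------------------------------------------------


def read_swc(path: str | Path) -> Morphology:
    """Parse a 7-column SWC file into a :class:`Morphology`.

    Lines starting with ``#`` are comments.  Raises :class:`SWCParseError`
    with the offending line number on malformed content and
    :class:`StructureError` on orphan parents or multiple roots.
    """
    path = Path(path)
    nodes: list[MorphNode] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 7:
                raise SWCParseError(
                    f"expected 7 columns, got {len(fields)}", line=lineno
                )
            try:
                nid = int(fields[0])
                code = int(fields[1])
                x, y, z, radius = (float(v) for v in fields[2:6])
                parent = int(fields[6])
            except ValueError as exc:
                raise SWCParseError(str(exc), line=lineno) from None
            nodes.append(
                MorphNode(
                    id=nid,
                    parent_id=parent,
                    kind=NodeKind.from_swc_code(code),
                    x=x,
                    y=y,
                    z=z,
                    radius=radius,
                )
            )
    return Morphology(nodes=nodes, label=path.stem)


def write_swc(morphology: Morphology, path: str | Path) -> None:
    """Write standard SWC text; round-trips through :func:`read_swc`."""
    path = Path(path)
    lines = ["# SWC export (id type x y z radius parent)"]
    for n in morphology.nodes:
        lines.append(
            f"{n.id} {n.kind.value} {n.x:.6f} {n.y:.6f} {n.z:.6f} "
            f"{n.radius:.6f} {n.parent_id}"
        )
    path.write_text("\n".join(lines) + "\n")


# -- Sholl analysis -----------------------------------------------------------


@dataclass(frozen=True)
class ShollProfile:
    """Intersection counts on concentric spheres around the soma centre."""

    radii: np.ndarray  # µm, strictly increasing
    counts: np.ndarray  # intersections per shell
    step: float  # µm

    def __post_init__(self):
        if len(self.radii) != len(self.counts):
            raise MorphologyError("radii and counts length mismatch")
        if np.any(np.diff(self.radii) <= 0):
            raise MorphologyError("radii must be strictly increasing")


def _segment_crossings(
    p0: np.ndarray, p1: np.ndarray, center: np.ndarray, r: float
) -> int:
    """Number of transversal crossings of sphere |x-c|=r by segment p0->p1.

    Roots of the quadratic |p0 + t (p1-p0) - c|^2 = r^2 counted on t in (0, 1];
    tangency (double root) does not count.  The squared distance is convex in
    t, so there are at most two crossings per segment.
    """
    d = p1 - p0
    f = p0 - center
    a = float(d @ d)
    if a == 0.0:
        return 0
    b = 2.0 * float(f @ d)
    c = float(f @ f) - r * r
    disc = b * b - 4.0 * a * c
    if disc <= 0.0:  # no intersection, or tangent
        return 0
    sq = math.sqrt(disc)
    count = 0
    for t in ((-b - sq) / (2 * a), (-b + sq) / (2 * a)):
        if 0.0 < t <= 1.0:
            count += 1
    return count


def sholl(
    morphology: Morphology, step_um: float, projection: str = "3d"
) -> ShollProfile:
    """Sholl profile: dendritic crossings of spheres centred on the soma.

    ``projection='xy'`` measures distances in the xy-plane (matching analyses
    done on 2D maximum-intensity projections); the default is true 3D
    distance.  A segment that crosses a shell twice counts twice; a segment
    ending exactly on a shell counts as crossing it.
    """
    if step_um <= 0:
        raise MorphologyError("step_um must be > 0")
    if projection not in ("3d", "xy"):
        raise MorphologyError(f"unknown projection {projection!r}")
    center = morphology.soma_center()
    segs = []
    for parent, child in morphology.segments(dendrite_only=True):
        p0, p1 = parent.xyz.astype(float), child.xyz.astype(float)
        if projection == "xy":
            p0, p1 = p0.copy(), p1.copy()
            p0[2] = p1[2] = 0.0
        segs.append((p0, p1))
    if projection == "xy":
        center = center.copy()
        center[2] = 0.0
    if not segs:
        raise MorphologyError("morphology has no dendritic segments")
    max_dist = max(
        max(np.linalg.norm(p0 - center), np.linalg.norm(p1 - center))
        for p0, p1 in segs
    )
    n_shells = max(1, math.ceil(max_dist / step_um - 1e-9))
    radii = step_um * np.arange(1, n_shells + 1, dtype=float)
    counts = np.zeros(n_shells, dtype=int)
    for i, r in enumerate(radii):
        counts[i] = sum(_segment_crossings(p0, p1, center, r) for p0, p1 in segs)
    return ShollProfile(radii=radii, counts=counts, step=step_um)


def centroid(profile: ShollProfile) -> float:
    """Count-weighted mean radius of the Sholl profile (µm), the geometric
    centroid ⟨t⟩ of the dendritic arbor."""
    total = profile.counts.sum()
    if total == 0:
        raise MorphologyError("all-zero Sholl profile has no centroid")
    return float((profile.radii * profile.counts).sum() / total)


def max_radius(profile: ShollProfile) -> float:
    """Largest shell radius with at least one dendritic crossing (µm)."""
    nonzero = np.nonzero(profile.counts)[0]
    if nonzero.size == 0:
        raise MorphologyError("all-zero Sholl profile has no maximum radius")
    return float(profile.radii[nonzero[-1]])


# -- coverage and branch metrics ---------------------------------------------


def coverage_area(morphology: Morphology) -> float:
    """Neuropil coverage: convex-hull area of the dendritic nodes projected
    onto the xy-plane (µm²).  Degenerate (collinear) arbors return 0 with a
    warning."""
    pts = np.array(
        [[n.x, n.y] for n in morphology.nodes if n.kind is NodeKind.dendrite]
    )
    if len(pts) < 3:
        warnings.warn("fewer than 3 dendritic nodes; coverage area is 0")
        return 0.0
    try:
        hull = ConvexHull(pts)
    except QhullError:
        warnings.warn("degenerate (collinear) dendritic arbor; coverage area is 0")
        return 0.0
    return float(hull.volume)  # 2D: 'volume' is the area


@dataclass(frozen=True)
class MorphoSummary:
    """Scalar morphometry of one cell's dendritic arbor."""

    total_dendritic_length: float  # µm
    n_branches: int
    n_branching_points: int
    mean_branch_length: float  # µm
    max_radius: float  # µm
    centroid: float  # µm
    coverage_area: float  # µm²

    def as_dict(self) -> dict[str, float]:
        return {
            "total_dendritic_length": self.total_dendritic_length,
            "n_branches": self.n_branches,
            "n_branching_points": self.n_branching_points,
            "mean_branch_length": self.mean_branch_length,
            "max_radius": self.max_radius,
            "centroid": self.centroid,
            "coverage_area": self.coverage_area,
        }


def _dendritic_children(morphology: Morphology) -> dict[int, list[MorphNode]]:
    children: dict[int, list[MorphNode]] = {}
    for n in morphology.nodes:
        if n.kind is NodeKind.dendrite and n.parent_id != -1:
            children.setdefault(n.parent_id, []).append(n)
    return children


def branch_decomposition(morphology: Morphology) -> list[list[MorphNode]]:
    """Maximal unbranched dendritic paths.

    Branches are delimited by the soma, by branching points (dendritic nodes
    with ≥2 dendritic children) and by terminal tips.  Each returned path
    lists the nodes from (but excluding) its proximal delimiter to its distal
    end; the cable segment connecting the delimiter to the first listed node
    belongs to the path, so branch lengths sum exactly to the total dendritic
    length.
    """
    index = morphology._index()
    children = _dendritic_children(morphology)
    starts = [
        n
        for n in morphology.nodes
        if n.kind is NodeKind.dendrite
        and n.parent_id != -1
        and (
            index[n.parent_id].kind is NodeKind.soma
            or (
                index[n.parent_id].kind is NodeKind.dendrite
                and len(children.get(n.parent_id, [])) >= 2
            )
        )
    ]
    branches = []
    for start in starts:
        path = [start]
        node = start
        while len(children.get(node.id, [])) == 1:
            node = children[node.id][0]
            path.append(node)
        branches.append(path)
    return branches


def branch_metrics(morphology: Morphology, sholl_step_um: float = 10.0) -> MorphoSummary:
    """Full scalar morphometry: branch decomposition totals plus the Sholl
    maximum radius, centroid and coverage area at the stated shell step."""
    index = morphology._index()
    children = _dendritic_children(morphology)
    branches = branch_decomposition(morphology)
    branch_lengths = []
    for path in branches:
        length = 0.0
        for node in path:
            parent = index[node.parent_id]
            length += float(np.linalg.norm(node.xyz - parent.xyz))
        branch_lengths.append(length)
    n_branching_points = sum(
        1
        for n in morphology.nodes
        if n.kind is NodeKind.dendrite and len(children.get(n.id, [])) >= 2
    )
    total = float(sum(branch_lengths))
    n_branches = len(branches)
    profile = sholl(morphology, sholl_step_um)
    return MorphoSummary(
        total_dendritic_length=total,
        n_branches=n_branches,
        n_branching_points=n_branching_points,
        mean_branch_length=total / n_branches if n_branches else 0.0,
        max_radius=max_radius(profile),
        centroid=centroid(profile),
        coverage_area=coverage_area(morphology),
    )


def estimate_spine_number(
    spine_density_per_um: float, total_dendritic_length_um: float
) -> float:
    """Spine number = spine density × dendritic length (returned unrounded)."""
    if spine_density_per_um < 0 or total_dendritic_length_um < 0:
        raise MorphologyError("spine density and length must be non-negative")
    return spine_density_per_um * total_dendritic_length_um


# -- synthetic generator ------------------------------------------------------


@dataclass(frozen=True)
class MorphogenParams:
    """Targets and stochastic rules for the synthetic dendritic-tree grower.

    A tree is grown as ``n_primary`` dendrites from a spherical soma; each
    branch is a chain of ~``node_step_um`` segments of total length drawn
    from N(mean_branch_length_um, branch_length_sd_um), and terminates or
    bifurcates with probability ``branching_prob`` until ``max_depth``.
    Realizations are rejected until the total dendritic length falls within
    ``target_total_length_um`` ± ``target_tolerance`` (fractional).
    """

    n_primary: int = 4
    mean_branch_length_um: float = 60.0
    branch_length_sd_um: float = 15.0
    branching_prob: float = 0.65
    max_depth: int = 3
    target_total_length_um: float = 1500.0
    target_tolerance: float = 0.15
    soma_radius_um: float = 7.0
    node_step_um: float = 10.0
    dendrite_radius_um: float = 0.6
    max_attempts: int = 200
    label: str = "synthetic"


_PRESETS = {
    # Wild-type-like D1-MSN arbor.
    "wt": MorphogenParams(
        n_primary=4,
        branching_prob=0.65,
        max_depth=3,
        target_total_length_um=1500.0,
        label="wt",
    ),
    # Knockout-like arbor: ~twofold total length, more branches/branching
    # points, larger maximal extent (direction of the genotype effect).
    "ko": MorphogenParams(
        n_primary=5,
        branching_prob=0.72,
        max_depth=4,
        target_total_length_um=3000.0,
        label="ko",
    ),
}


def morphogen_preset(genotype: str) -> MorphogenParams:
    """Generator parameters for ``'wt'`` or ``'ko'`` arbors."""
    try:
        return _PRESETS[genotype]
    except KeyError:
        raise MorphologyError(f"unknown genotype preset {genotype!r}") from None


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _rotate_towards(direction: np.ndarray, angle: float, rng: np.random.Generator) -> np.ndarray:
    """Rotate `direction` by `angle` about a random axis orthogonal to it."""
    # random orthogonal axis
    helper = rng.standard_normal(3)
    axis = np.cross(direction, helper)
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        helper = np.array([1.0, 0.0, 0.0])
        axis = np.cross(direction, helper)
        norm = np.linalg.norm(axis)
    axis = axis / norm
    # Rodrigues rotation
    return (
        direction * math.cos(angle)
        + np.cross(axis, direction) * math.sin(angle)
        + axis * float(axis @ direction) * (1 - math.cos(angle))
    )


def synthesize_morphology(params: MorphogenParams, seed: int) -> Morphology:
    """Grow a random MSN-like dendritic tree meeting the length target.

    Deterministic for a given ``(params, seed)``.  Raises
    :class:`GenerationError` if no realization lands within the target
    tolerance in ``params.max_attempts`` attempts.
    """
    rng = np.random.default_rng(seed)
    lo = params.target_total_length_um * (1 - params.target_tolerance)
    hi = params.target_total_length_um * (1 + params.target_tolerance)
    for _ in range(params.max_attempts):
        nodes = _grow_tree(params, rng)
        morph = Morphology(nodes=nodes, label=params.label, provenance="synthetic")
        realized = total_dendritic_length(morph)
        if lo <= realized <= hi:
            return morph
    raise GenerationError(
        f"could not reach total length {params.target_total_length_um} "
        f"±{params.target_tolerance:.0%} in {params.max_attempts} attempts"
    )


def _grow_tree(params: MorphogenParams, rng: np.random.Generator) -> list[MorphNode]:
    nodes = [
        MorphNode(
            id=1,
            parent_id=-1,
            kind=NodeKind.soma,
            x=0.0,
            y=0.0,
            z=0.0,
            radius=params.soma_radius_um,
        )
    ]

    def next_id() -> int:
        return len(nodes) + 1

    def grow_branch(parent_id: int, origin: np.ndarray, direction: np.ndarray, depth: int):
        length = max(
            params.node_step_um,
            rng.normal(params.mean_branch_length_um, params.branch_length_sd_um),
        )
        n_steps = max(1, round(length / params.node_step_um))
        pos = origin.copy()
        d = direction.copy()
        # taper towards the tip, slightly thicker at proximal branches
        r0 = params.dendrite_radius_um * (1.25 - 0.15 * depth)
        r0 = max(r0, 0.3)
        pid = parent_id
        for _ in range(n_steps):
            d = _unit(d + 0.25 * rng.standard_normal(3))
            pos = pos + d * (length / n_steps)
            nid = next_id()
            nodes.append(
                MorphNode(
                    id=nid,
                    parent_id=pid,
                    kind=NodeKind.dendrite,
                    x=float(pos[0]),
                    y=float(pos[1]),
                    z=float(pos[2]),
                    radius=r0,
                )
            )
            pid = nid
        if depth < params.max_depth and rng.random() < params.branching_prob:
            for sign in (+1, -1):
                angle = sign * rng.uniform(0.4, 0.9)  # ~23-52 degrees
                grow_branch(pid, pos, _unit(_rotate_towards(d, angle, rng)), depth + 1)

    for _ in range(params.n_primary):
        direction = _unit(rng.standard_normal(3))
        origin = direction * params.soma_radius_um
        grow_branch(1, origin, direction, depth=0)
    return nodes
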