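"""Reading, validating, writing and soma-normalizing SWC morphologies.

The SWC format stores one reconstruction point (node) per line with seven
whitespace-delimited columns::

    node_id  type_code  x  y  z  radius  parent_id

``type_code`` follows the usual convention: 1 soma, 2 axon, 3 basal
dendrite, 4 apical dendrite; other codes are passed through and treated as
generic dendrite-like processes.  Radii are stored as read; everything
user-facing works in diameters (2 x radius).  Coordinates and radii are in
micrometres throughout (NeuroMorpho convention); no unit conversion is done.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

__all__ = [
    "MorphNode",
    "Morphology",
    "SWCError",
    "SWCParseError",
    "SWCStructureError",
    "SWCValidationError",
    "read_swc",
    "write_swc",
    "normalize_soma",
]

SOMA = 1
AXON = 2
BASAL = 3
APICAL = 4

#: SWC type codes participating in dendritic analysis (soma and axon excluded).
DENDRITE_CODES_EXCLUDED = (SOMA, AXON)


class SWCError(Exception):
    """Base class for SWC I/O and structure problems."""


class SWCParseError(SWCError):
    """A malformed SWC line; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class SWCStructureError(SWCError):
    """Topology violation: dangling parent, cycle, multiple roots, ..."""


class SWCValidationError(SWCError):
    """A Morphology that cannot be used (e.g. empty node list)."""


@dataclass(frozen=True)
class MorphNode:
    """One SWC reconstruction point."""

    node_id: int
    type_code: int
    x: float
    y: float
    z: float
    radius: float
    parent_id: int  # -1 for the root

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius

    def distance_to(self, other: "MorphNode") -> float:
        return math.dist((self.x, self.y, self.z), (other.x, other.y, other.z))


@dataclass
class Morphology:
    """A neuron reconstruction: an ordered node list forming a rooted tree.

    ``metadata`` carries free-form source tags (archive, cell type, NMO id).
    ``warnings`` collects non-fatal validation findings (nonpositive radii,
    large z-steps) so callers can decide on exclusion themselves.
    """

    nodes: list[MorphNode]
    metadata: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._reindex()

    def _reindex(self) -> None:
        self._by_id: dict[int, MorphNode] = {}
        for n in self.nodes:
            if n.node_id in self._by_id:
                raise SWCStructureError(f"duplicate node id {n.node_id}")
            self._by_id[n.node_id] = n
        self._children: dict[int, list[int]] = {n.node_id: [] for n in self.nodes}
        for n in self.nodes:
            if n.parent_id != -1:
                if n.parent_id not in self._by_id:
                    raise SWCStructureError(
                        f"node {n.node_id} references missing parent {n.parent_id}"
                    )
                self._children[n.parent_id].append(n.node_id)
        self._check_tree()

    def _check_tree(self) -> None:
        roots = [n for n in self.nodes if n.parent_id == -1]
        if not self.nodes:
            return
        if len(roots) != 1:
            raise SWCStructureError(
                f"expected exactly one root, found {len(roots)}"
            )
        # cycle/connectivity check: every node must reach the root
        seen = {roots[0].node_id}
        stack = [roots[0].node_id]
        while stack:
            nid = stack.pop()
            for c in self._children[nid]:
                if c in seen:
                    raise SWCStructureError(f"cycle involving node {c}")
                seen.add(c)
                stack.append(c)
        if len(seen) != len(self.nodes):
            missing = sorted(set(self._by_id) - seen)
            raise SWCStructureError(
                f"nodes not connected to root: {missing[:5]}"
            )
        # dendritic nodes must never have soma descendants
        for n in self.nodes:
            if n.parent_id != -1 and n.type_code == SOMA:
                parent = self._by_id[n.parent_id]
                if parent.type_code != SOMA:
                    raise SWCStructureError(
                        f"soma node {n.node_id} attached to non-soma parent"
                    )

    # -- accessors ---------------------------------------------------------

    def node(self, node_id: int) -> MorphNode:
        return self._by_id[node_id]

    def __contains__(self, node_id: int) -> bool:
        return node_id in self._by_id

    def __len__(self) -> int:
        return len(self.nodes)

    def children(self, node_id: int) -> list[MorphNode]:
        return [self._by_id[c] for c in self._children[node_id]]

    def parent(self, node: MorphNode) -> MorphNode | None:
        return None if node.parent_id == -1 else self._by_id[node.parent_id]

    @property
    def root(self) -> MorphNode:
        (r,) = [n for n in self.nodes if n.parent_id == -1]
        return r

    @property
    def soma_nodes(self) -> list[MorphNode]:
        return [n for n in self.nodes if n.type_code == SOMA]

    @property
    def soma_root(self) -> MorphNode:
        root = self.root
        if root.type_code != SOMA:
            raise SWCStructureError("morphology root is not a soma node")
        return root

    @property
    def soma_diameter(self) -> float:
        """Diameter of the root soma node (after normalize_soma for contours)."""
        return self.soma_root.diameter

    def dendritic_nodes(self) -> list[MorphNode]:
        """All nodes participating in dendritic analysis (not soma, not axon)."""
        return [n for n in self.nodes if n.type_code not in DENDRITE_CODES_EXCLUDED]

    def is_dendritic(self, node: MorphNode) -> bool:
        return node.type_code not in DENDRITE_CODES_EXCLUDED

    def dendritic_children(self, node_id: int) -> list[MorphNode]:
        return [c for c in self.children(node_id) if self.is_dendritic(c)]

    def with_nodes(self, nodes: Iterable[MorphNode]) -> "Morphology":
        return Morphology(list(nodes), dict(self.metadata), list(self.warnings))

    def max_z_step(self) -> float:
        """Largest |dz| between connected nodes; reported, never auto-excluded."""
        best = 0.0
        for n in self.nodes:
            p = self.parent(n)
            if p is not None:
                best = max(best, abs(n.z - p.z))
        return best


def _soma_surface_area(m: Morphology) -> float:
    """Soma membrane area in um^2.

    Single point: sphere of that radius.  Multi-point: sum of frustum lateral
    areas along soma-to-soma parent links (a cylinder for the common 3-point
    soma); falls back to the root sphere if the links have zero extent.
    """
    soma = m.soma_nodes
    if not soma:
        raise SWCStructureError("morphology has no soma node")
    if len(soma) == 1:
        return 4.0 * math.pi * soma[0].radius ** 2
    area = 0.0
    for n in soma:
        p = m.parent(n)
        if p is not None and p.type_code == SOMA:
            length = n.distance_to(p)
            slant = math.hypot(length, n.radius - p.radius)
            area += math.pi * (n.radius + p.radius) * slant
    if area == 0.0:
        return 4.0 * math.pi * m.soma_root.radius ** 2
    return area


def _is_three_point_soma(m: Morphology) -> bool:
    soma = m.soma_nodes
    if len(soma) != 3:
        return False
    root = m.root
    if root.type_code != SOMA:
        return False
    flanks = [n for n in soma if n.node_id != root.node_id]
    if any(f.parent_id != root.node_id for f in flanks):
        return False
    r = root.radius
    for f in flanks:
        if not math.isclose(f.radius, r, rel_tol=1e-9):
            return False
        if not math.isclose(f.distance_to(root), r, rel_tol=1e-6):
            return False
    return True


def normalize_soma(m: Morphology, mode: str = "three_point") -> Morphology:
    """Rewrite the soma as a 3-point soma or a single sphere-equivalent point.

    The replacement preserves the soma surface area: the equivalent radius is
    ``sqrt(area / 4 pi)``, and a 3-point soma (cylinder of length 2r and
    diameter 2r) has exactly the sphere's lateral area.  All non-soma nodes
    previously attached to any soma point are re-parented to the centre.
    Idempotent: an already-3-point soma is returned unchanged.
    """
    if mode not in ("three_point", "single_point"):
        raise ValueError(f"unknown soma mode {mode!r}")
    if not m.soma_nodes:
        raise SWCStructureError("morphology has no soma node")
    if mode == "three_point" and _is_three_point_soma(m):
        return m.with_nodes(m.nodes)

    area = _soma_surface_area(m)
    r_eq = math.sqrt(area / (4.0 * math.pi))
    root = m.soma_root
    soma_ids = {n.node_id for n in m.soma_nodes}
    center = MorphNode(root.node_id, SOMA, root.x, root.y, root.z, r_eq, -1)

    new_nodes: list[MorphNode] = [center]
    if mode == "three_point":
        next_id = max(n.node_id for n in m.nodes) + 1
        new_nodes.append(
            MorphNode(next_id, SOMA, root.x, root.y - r_eq, root.z, r_eq, center.node_id)
        )
        new_nodes.append(
            MorphNode(next_id + 1, SOMA, root.x, root.y + r_eq, root.z, r_eq, center.node_id)
        )
    for n in m.nodes:
        if n.node_id in soma_ids:
            continue
        if n.parent_id in soma_ids:
            n = replace(n, parent_id=center.node_id)
        new_nodes.append(n)
    out = m.with_nodes(new_nodes)
    out.metadata["soma_mode"] = mode
    return out


def read_swc(path, metadata: dict | None = None) -> Morphology:
    """Read and validate a 7-column SWC file.

    Node order is preserved and parents are resolved after the whole file is
    read, so unsorted ids are accepted.  Nonpositive radii are collected as
    warnings, not errors; structural violations raise :class:`SWCStructureError`
    and malformed lines raise :class:`SWCParseError` with the line number.
    """
    nodes: list[MorphNode] = []
    warnings: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SWCParseError(
                    f"expected 7 columns, got {len(parts)}", lineno
                )
            try:
                nid = int(parts[0])
                tcode = int(parts[1])
                x, y, z, radius = (float(p) for p in parts[2:6])
                pid = int(parts[6])
            except ValueError as exc:
                raise SWCParseError(str(exc), lineno) from None
            if radius <= 0:
                warnings.append(
                    f"node {nid}: nonpositive radius {radius}"
                )
            nodes.append(MorphNode(nid, tcode, x, y, z, radius, pid))
    if not nodes:
        raise SWCValidationError(f"{path}: no nodes")
    m = Morphology(nodes, metadata=dict(metadata or {}), warnings=warnings)
    m.metadata.setdefault("source", str(path))
    m.metadata["max_z_step"] = m.max_z_step()
    return m


def write_swc(m: Morphology, path, precision: int = 4,
              header: Iterable[str] = ()) -> None:
    """Write a Morphology as standard SWC.

    Coordinates and radii are rounded to ``precision`` decimals; a read-back
    reproduces all fields at that precision.  ``header`` lines are emitted as
    '#'-prefixed comments (provenance, model set used, ...).
    """
    if not m.nodes:
        raise SWCValidationError("refusing to write an empty morphology")
    fmt = f"{{:.{precision}f}}"
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        for n in m.nodes:
            fh.write(
                f"{n.node_id} {n.type_code} "
                f"{fmt.format(n.x)} {fmt.format(n.y)} {fmt.format(n.z)} "
                f"{fmt.format(n.radius)} {n.parent_id}\n"
            )


def iter_swc_dir(directory) -> Iterator[Morphology]:
    """Yield morphologies for every ``*.swc`` file in a directory (sorted)."""
    import os

    for name in sorted(os.listdir(directory)):
        if name.lower().endswith(".swc"):
            yield read_swc(os.path.join(directory, name))
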