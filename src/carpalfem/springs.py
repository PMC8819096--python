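"""Ligament spring network.

Every extrinsic/intrinsic ligament except the SLIL is a 1D linear spring
attached to a single mesh node on each bone, with stiffness k (N/mm) from
the published table.  Rest length is the as-built node distance, i.e. the
springs are unstressed in the reference configuration (no pre-tension is
published).  A ``tension_only`` flag is available because real ligaments go
slack in compression, but the published model says "linear spring", so it
defaults to False.

Single-node attachment reproduces a known artifact of the source model:
forces concentrate at the attachment nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tables import LIGAMENT_ROWS


@dataclass
class SpringElement:
    name: str
    part_a: str
    node_a: int
    part_b: str
    node_b: int
    k: float                    # N/mm
    rest_length: float          # mm
    tension_only: bool = False

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("spring stiffness must be positive")
        if self.rest_length < 0:
            raise ValueError("rest length must be non-negative")
        if self.node_a == self.node_b:
            raise ValueError("spring endpoints must be distinct nodes")


@dataclass
class SpringSet:
    elements: list[SpringElement]
    #: element name -> ligament table row it came from
    provenance: dict[str, str] = field(default_factory=dict)

    def __len__(self):
        return len(self.elements)

    def stiffnesses(self) -> list[float]:
        return [e.k for e in self.elements]

    def to_text(self) -> str:
        lines = ["name\tpartA\tnodeA\tpartB\tnodeB\tk_N_per_mm\tL0_mm"]
        for e in self.elements:
            lines.append(f"{e.name}\t{e.part_a}\t{e.node_a}\t{e.part_b}\t"
                         f"{e.node_b}\t{e.k:.9g}\t{e.rest_length:.9g}")
        return "\n".join(lines) + "\n"


#: landmark part names -> volume-mesh part names (the radius body is meshed
#: as one part with cortical/cancellous regions)
DEFAULT_PART_ALIAS = {
    "radius_cortical": "radius",
    "radius_cancellous": "radius",
}


def build_spring_set(landmarks, mesh, stiffness_table=None,
                     part_alias: dict | None = None,
                     tolerance: float = 3.0,
                     tension_only: bool = False) -> SpringSet:
    """Resolve each ligament landmark pair to nearest boundary nodes.

    Parameters
    ----------
    landmarks : LandmarkSet with one entry per spring.
    mesh : VolumeMesh containing (aliased) parts for every landmark.
    stiffness_table : rows (ligament, conn1, conn2, k); defaults to the
        published table.  Stiffness is matched by ligament name.
    tolerance : max snap distance (mm) from landmark to its part's nearest
        boundary node.
    """
    rows = stiffness_table if stiffness_table is not None else LIGAMENT_ROWS
    k_by_name = {r[0]: r[3] for r in rows}
    alias = dict(DEFAULT_PART_ALIAS)
    if part_alias:
        alias.update(part_alias)

    bnode_cache: dict[str, np.ndarray] = {}

    def nearest_boundary_node(part: str, point: np.ndarray) -> int:
        part = alias.get(part, part)
        if part not in mesh.part_names:
            raise KeyError(f"mesh has no part {part!r} (have "
                           f"{mesh.part_names})")
        if part not in bnode_cache:
            bnode_cache[part] = mesh.boundary_node_indices(part)
        idx = bnode_cache[part]
        d = np.linalg.norm(mesh.nodes[idx] - point, axis=1)
        j = int(np.argmin(d))
        if d[j] > tolerance:
            raise ValueError(
                f"landmark {point} is {d[j]:.3g} mm from the nearest "
                f"boundary node of part {part!r} (tolerance {tolerance:g})")
        return int(idx[j])

    elements: list[SpringElement] = []
    provenance: dict[str, str] = {}
    seen: set[str] = set()
    for e in landmarks.entries:
        if e.ligament not in k_by_name:
            raise KeyError(f"no stiffness for ligament {e.ligament!r}")
        na = nearest_boundary_node(e.part_a, e.point_a)
        nb = nearest_boundary_node(e.part_b, e.point_b)
        name = e.ligament
        if name in seen:                      # expanded combined rows
            name = f"{e.ligament} -> {e.part_b}"
        seen.add(name)
        rest = float(np.linalg.norm(mesh.nodes[nb] - mesh.nodes[na]))
        elements.append(SpringElement(
            name=name, part_a=alias.get(e.part_a, e.part_a), node_a=na,
            part_b=alias.get(e.part_b, e.part_b), node_b=nb,
            k=k_by_name[e.ligament], rest_length=rest,
            tension_only=tension_only))
        provenance[name] = e.ligament
    return SpringSet(elements, provenance)


def spring_force(spring: SpringElement, xa: np.ndarray, xb: np.ndarray):
    """Equal-and-opposite axial forces (N) at the two endpoints.

    Returns (f_a, f_b) with f_a the force applied to endpoint a; a
    stretched spring pulls the endpoints together.
    """
    xa = np.asarray(xa, dtype=float)
    xb = np.asarray(xb, dtype=float)
    dx = xb - xa
    L = float(np.linalg.norm(dx))
    if L == 0.0:
        raise ValueError(f"spring {spring.name!r}: endpoints coincide")
    n = dx / L
    stretch = L - spring.rest_length
    if spring.tension_only and stretch < 0:
        return np.zeros(3), np.zeros(3)
    f = spring.k * stretch * n
    return f, -f


def spring_energy(spring: SpringElement, xa, xb) -> float:
    L = float(np.linalg.norm(np.asarray(xb, float) - np.asarray(xa, float)))
    stretch = L - spring.rest_length
    if spring.tension_only and stretch < 0:
        return 0.0
    return 0.5 * spring.k * stretch ** 2


def spring_tangent(spring: SpringElement, xa, xb) -> np.ndarray:
    """Consistent 6x6 stiffness (Hessian of the spring energy).

    Rows/cols ordered (a_x, a_y, a_z, b_x, b_y, b_z); symmetric, with both
    the material (k n n^T) and geometric (force/length) parts.
    """
    xa = np.asarray(xa, dtype=float)
    xb = np.asarray(xb, dtype=float)
    dx = xb - xa
    L = float(np.linalg.norm(dx))
    if L == 0.0:
        raise ValueError(f"spring {spring.name!r}: endpoints coincide")
    n = dx / L
    stretch = L - spring.rest_length
    if spring.tension_only and stretch < 0:
        return np.zeros((6, 6))
    nn = np.outer(n, n)
    h = spring.k * nn + spring.k * stretch / L * (np.eye(3) - nn)
    out = np.zeros((6, 6))
    out[:3, :3] = h
    out[3:, 3:] = h
    out[:3, 3:] = -h
    out[3:, :3] = -h
    return out
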