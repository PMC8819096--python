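"""Wrist motion to prescribed displacements.

Wrist motions are published as joint rotations (range-of-motion table) but
applied to the capitate as cartesian displacements.  The conversion used
here rotates a point at lever-arm distance r from the rotation centre:

    tangential = r sin(theta)        (y for flexion/extension, x for
                                      radial/ulnar deviation)
    axial      = -r (1 - cos(theta)) (z, always proximal)

with the sign convention extension -> -y, flexion -> +y, radial -> -x,
ulnar -> +x in the model frame.  With theta at the midpoint of each
published motion range and r = 19.40 mm this reproduces the published
displacement table entries to better than 0.02 mm; r was reconstructed by
least squares over those entries and is exposed as a parameter.

Pronation/supination does not involve the scapholunate joint and is never
converted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tables import ROM_DEGREES

SIMULATED_MOTIONS = ("flexion", "extension", "radial", "ulnar")

#: lever arm r (mm) reconstructed from the published displacement table
DEFAULT_LEVER_ARM_MM = 19.40

# (tangential axis index, tangential sign)
_MOTION_AXIS = {
    "extension": (1, -1.0),
    "flexion": (1, +1.0),
    "radial": (0, -1.0),
    "ulnar": (0, +1.0),
}


@dataclass
class RomTable:
    """Range of motion per wrist movement, degrees (lower, upper)."""

    ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(ROM_DEGREES))

    def __post_init__(self):
        for name, (lo, hi) in self.ranges.items():
            if not (0 < lo < hi):
                raise ValueError(f"ROM for {name!r} must satisfy "
                                 f"0 < lower < upper, got ({lo}, {hi})")

    def __getitem__(self, motion: str) -> tuple[float, float]:
        return self.ranges[motion]


def motion_angle(motion: str, rom: RomTable | None = None,
                 policy: str = "midpoint",
                 explicit_deg: float | None = None) -> float:
    """Pick the simulated angle (degrees) for a motion from its ROM range."""
    rom = rom or RomTable()
    if motion not in SIMULATED_MOTIONS:
        raise ValueError(f"unknown motion {motion!r}; simulated motions are "
                         f"{SIMULATED_MOTIONS}")
    lo, hi = rom[motion]
    if policy == "midpoint":
        return 0.5 * (lo + hi)
    if policy == "lower":
        return lo
    if policy == "upper":
        return hi
    if policy == "explicit":
        if explicit_deg is None:
            raise ValueError("policy 'explicit' needs explicit_deg")
        return float(explicit_deg)
    raise ValueError(f"unknown angle policy {policy!r}")


def rotation_to_displacement(angle_deg: float, r_mm: float,
                             motion: str) -> np.ndarray:
    """Cartesian displacement (mm) of the capitate drive point."""
    if motion not in _MOTION_AXIS:
        raise ValueError(f"unknown motion {motion!r}")
    if not 0.0 <= angle_deg < 180.0:
        raise ValueError("angle must lie in [0, 180) degrees")
    if r_mm <= 0:
        raise ValueError("lever arm r must be positive")
    th = np.deg2rad(angle_deg)
    out = np.zeros(3)
    axis, sign = _MOTION_AXIS[motion]
    out[axis] = sign * r_mm * np.sin(th)
    out[2] = -r_mm * (1.0 - np.cos(th))
    return out


def fit_lever_arm(entries: dict[str, tuple[float, float]],
                  rom: RomTable | None = None,
                  policy: str = "midpoint") -> float:
    """Least-squares lever arm r from (tangential, axial) displacement pairs.

    ``entries`` maps motion name to the published (tangential, axial) mm
    pair; with the published table this recovers r = 19.40 mm.
    """
    rom = rom or RomTable()
    num = den = 0.0
    for motion, (tang, axial) in entries.items():
        th = np.deg2rad(motion_angle(motion, rom, policy))
        _, sign = _MOTION_AXIS[motion]
        # model: tang = sign * r sin th ; axial = -r (1 - cos th)
        num += sign * tang * np.sin(th) + (-axial) * (1 - np.cos(th))
        den += np.sin(th) ** 2 + (1 - np.cos(th)) ** 2
    if den == 0:
        raise ValueError("no entries given")
    return num / den


@dataclass
class BcSet:
    """Fixed and prescribed node sets for one simulation case."""

    fixed_nodes: np.ndarray               # all six dofs zero
    prescribed_nodes: np.ndarray
    target_displacement: np.ndarray       # (3,) mm, reached at ramp end
    ramp: np.ndarray                      # monotone fractions ending at 1

    def __post_init__(self):
        self.fixed_nodes = np.asarray(self.fixed_nodes, dtype=int)
        self.prescribed_nodes = np.asarray(self.prescribed_nodes, dtype=int)
        self.target_displacement = np.asarray(self.target_displacement,
                                              dtype=float)
        self.ramp = np.asarray(self.ramp, dtype=float)
        if np.intersect1d(self.fixed_nodes, self.prescribed_nodes).size:
            raise ValueError("fixed and prescribed node sets must be disjoint")
        if len(self.ramp) and not np.isclose(self.ramp[-1], 1.0):
            raise ValueError("ramp must end at 1")

    @property
    def n_steps(self) -> int:
        return len(self.ramp)


def build_bc_set(mesh, motion: str, steps: int = 10,
                 rom: RomTable | None = None, policy: str = "midpoint",
                 explicit_deg: float | None = None,
                 r_mm: float = DEFAULT_LEVER_ARM_MM,
                 radius_part: str = "radius",
                 capitate_parts: tuple[str, ...] = ("capitate",),
                 proximal_tol: float = 1.0) -> BcSet:
    """Fix the proximal radius face and prescribe the capitate displacement.

    The fixed set is every radius node within ``proximal_tol`` mm of the
    proximal (minimum z) extreme; the prescribed set is every node of the
    capitate part(s), translated uniformly (the distal row is taken to move
    as a rigid solid with the capitate) with a linear ramp over ``steps``.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    rnodes = mesh.part_nodes(radius_part)
    if not len(rnodes):
        raise ValueError(f"no nodes in radius part {radius_part!r}")
    z = mesh.nodes[rnodes, 2]
    fixed = rnodes[z <= z.min() + proximal_tol]
    prescribed = np.unique(np.concatenate(
        [mesh.part_nodes(p) for p in capitate_parts]))
    if not len(fixed) or not len(prescribed):
        raise ValueError("empty fixed or prescribed node selection")
    angle = motion_angle(motion, rom, policy, explicit_deg)
    target = rotation_to_displacement(angle, r_mm, motion)
    ramp = np.arange(1, steps + 1) / steps
    return BcSet(fixed, prescribed, target, ramp)
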