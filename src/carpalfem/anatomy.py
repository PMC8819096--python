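"""Parametric surrogate anatomy for the reduced wrist model.

The published model segments a CT scan of one wrist; those scans are not
part of this package, so a parametric stand-in is generated instead: each
part (distal radius with cortical shell and cancellous core, scaphoid,
lunate, capitate, their articular cartilage layers, and a 3D block for the
scapholunate interosseous ligament) is a superellipsoid-like star-shaped
solid with a small smooth "organic" perturbation.  All downstream field
magnitudes are therefore geometry-specific: the pipeline reproduces the
published *procedure* and qualitative patterns, not its pressure numbers.

Model frame (mm):
    x: radial (-) to ulnar (+)
    y: dorsal (-) to volar (+)
    z: proximal (-) to distal (+)

The scaphoid sits on the radial side, the lunate on the ulnar side, the
SLIL block bridges the gap between their facing surfaces, and the capitate
sits distally; articular cartilage layers are separate thin parts placed
between the bones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import trimesh

from .mesh import SurfaceMesh
from .tables import LIGAMENT_ROWS

PART_NAMES = [
    "radius_cortical", "radius_cancellous", "radius_cartilage",
    "scaphoid", "lunate", "capitate",
    "scaphoid_cartilage", "lunate_cartilage", "capitate_cartilage",
    "slil",
]

FRAME = {
    "x": "radial(-)/ulnar(+)",
    "y": "dorsal(-)/volar(+)",
    "z": "proximal(-)/distal(+)",
    "units": "mm",
}


@dataclass(frozen=True)
class ShapeConfig:
    """Characteristic dimensions of the surrogate wrist (mm).

    ``scale`` multiplies every length, so geometry is homogeneous in it.
    """

    scale: float = 1.0
    slil_gap: float = 2.0                 # scaphoid-lunate facing distance
    joint_gap: float = 0.3                # articular (contact) clearances
    bump_amplitude: float = 0.015         # relative organic perturbation

    radius_semi: tuple[float, float, float] = (13.0, 11.0, 14.0)
    cancellous_scale: float = 0.72
    radius_cartilage_semi: tuple[float, float, float] = (11.0, 9.5, 1.0)

    scaphoid_semi: tuple[float, float, float] = (5.5, 6.5, 5.0)
    lunate_semi: tuple[float, float, float] = (5.0, 6.0, 4.8)
    capitate_semi: tuple[float, float, float] = (5.5, 6.0, 5.0)
    carpal_cartilage_half_thickness: float = 0.6
    slil_semi_yz: tuple[float, float] = (3.5, 3.0)
    slil_clearance: float = 0.05

    subdiv_large: int = 3                 # icosphere subdivisions, radius
    subdiv_small: int = 2                 # icosphere subdivisions, others

    lever_arm_r: float = 19.40            # rotation->displacement lever (mm)

    def scaled(self) -> "ShapeConfig":
        """Return a copy with scale folded into every length."""
        s = self.scale
        if s == 1.0:
            return self
        return replace(
            self, scale=1.0,
            slil_gap=self.slil_gap * s, joint_gap=self.joint_gap * s,
            radius_semi=tuple(v * s for v in self.radius_semi),
            radius_cartilage_semi=tuple(v * s for v in self.radius_cartilage_semi),
            scaphoid_semi=tuple(v * s for v in self.scaphoid_semi),
            lunate_semi=tuple(v * s for v in self.lunate_semi),
            capitate_semi=tuple(v * s for v in self.capitate_semi),
            carpal_cartilage_half_thickness=self.carpal_cartilage_half_thickness * s,
            slil_semi_yz=tuple(v * s for v in self.slil_semi_yz),
            slil_clearance=self.slil_clearance * s,
        )

    def validate(self) -> None:
        lengths = [self.scale, self.slil_gap, self.joint_gap,
                   self.carpal_cartilage_half_thickness, self.lever_arm_r,
                   *self.radius_semi, *self.radius_cartilage_semi,
                   *self.scaphoid_semi, *self.lunate_semi,
                   *self.capitate_semi, *self.slil_semi_yz]
        if any(v <= 0 for v in lengths):
            raise ValueError("all characteristic dimensions must be positive")
        min_bone = min(min(self.scaphoid_semi), min(self.lunate_semi),
                       min(self.capitate_semi))
        if 2 * self.carpal_cartilage_half_thickness >= min_bone:
            raise ValueError("cartilage thickness must be smaller than the "
                             "smallest bone radius")
        if not 0 <= self.bump_amplitude < 0.2:
            raise ValueError("bump_amplitude must be small and non-negative")


@dataclass
class LigamentAttachment:
    ligament: str
    part_a: str
    point_a: np.ndarray
    part_b: str
    point_b: np.ndarray


@dataclass
class LandmarkSet:
    """One attachment pair per ligament spring (Scaphoid+Lunate expanded)."""

    entries: list[LigamentAttachment]

    def __len__(self):
        return len(self.entries)

    def to_text(self) -> str:
        lines = ["ligament\tpartA\txA\tyA\tzA\tpartB\txB\tyB\tzB"]
        for e in self.entries:
            a = "\t".join(f"{v:.9g}" for v in e.point_a)
            b = "\t".join(f"{v:.9g}" for v in e.point_b)
            lines.append(f"{e.ligament}\t{e.part_a}\t{a}\t{e.part_b}\t{b}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "LandmarkSet":
        entries = []
        for line in text.strip().splitlines()[1:]:
            f = line.split("\t")
            entries.append(LigamentAttachment(
                f[0], f[1], np.array(f[2:5], dtype=float),
                f[5], np.array(f[6:9], dtype=float)))
        return cls(entries)


@dataclass
class AnatomyModel:
    parts: dict[str, SurfaceMesh]
    landmarks: LandmarkSet | None
    frame: dict
    lever_arm_r: float
    config: ShapeConfig = field(default_factory=ShapeConfig)

    def validate(self) -> None:
        """Assert the geometric invariants of the surrogate model."""
        if self.lever_arm_r <= 0:
            raise ValueError("lever_arm_r must be positive")
        for name in PART_NAMES:
            if name not in self.parts:
                raise ValueError(f"missing part {name!r}")
            if not self.parts[name].is_watertight:
                raise ValueError(f"part {name!r} is not watertight")
        cort = self.parts["radius_cortical"]
        canc = self.parts["radius_cancellous"]
        if not cort.contains(canc.vertices).all():
            raise ValueError("cancellous surface not strictly inside cortical")
        slil = self.parts["slil"]
        for name in ("scaphoid", "lunate"):
            d = self.parts[name].distance_to(slil.vertices).min()
            if d > 1.0 * self.config.scaled().joint_gap / 0.3:
                raise ValueError(f"slil does not bridge to {name} (min "
                                 f"distance {d:.3g} mm)")
        for name, part in self.parts.items():
            if name == "slil":
                continue
            if part.contains(slil.vertices).any() or \
                    slil.contains(part.vertices).any():
                raise ValueError(f"slil intersects part {name!r}")


# --------------------------------------------------------------------------
# solid generation
# --------------------------------------------------------------------------

def _superellipsoid(center, semi, power, subdiv, rng, bump_amp) -> SurfaceMesh:
    """Star-shaped solid: icosphere directions radially mapped onto a
    superellipsoid of exponent ``power``, with a smooth random perturbation."""
    ico = trimesh.creation.icosphere(subdivisions=subdiv)
    d = ico.vertices / np.linalg.norm(ico.vertices, axis=1, keepdims=True)
    semi = np.asarray(semi, dtype=float)
    rho = (np.abs(d / semi) ** power).sum(axis=1) ** (-1.0 / power)
    if bump_amp > 0:
        # smooth even perturbation: quadratic forms in random directions
        g = rng.standard_normal((6, 3))
        g /= np.linalg.norm(g, axis=1, keepdims=True)
        c = rng.standard_normal(6) / np.sqrt(6)
        f = ((d @ g.T) ** 2 * c).sum(axis=1)
        rho = rho * np.clip(1.0 + bump_amp * f, 1.0 - 2 * bump_amp,
                            1.0 + 2 * bump_amp)
    verts = center + rho[:, None] * d
    return SurfaceMesh(verts, ico.faces.copy())


def generate_reduced_wrist(shape_config: ShapeConfig | None = None,
                           seed: int = 0) -> AnatomyModel:
    """Generate the ten-part surrogate wrist.

    Deterministic: identical (seed, shape_config) give bit-identical vertex
    arrays.  Raises ValueError on non-positive dimensions or a cartilage
    thickness that reaches the bone radius.
    """
    cfg_in = shape_config or ShapeConfig()
    cfg_in.validate()
    cfg = cfg_in.scaled()

    t_cart = cfg.carpal_cartilage_half_thickness
    g = cfg.joint_gap
    radius_top = 0.0
    rad_cart_c = radius_top + cfg.radius_cartilage_semi[2]
    rad_cart_top = radius_top + 2 * cfg.radius_cartilage_semi[2]
    carpal_cart_c = rad_cart_top + g + t_cart
    carpal_bottom = rad_cart_top + g + 2 * t_cart
    sca_c = np.array([-(cfg.scaphoid_semi[0] + cfg.slil_gap / 2), 0.0,
                      carpal_bottom + cfg.scaphoid_semi[2]])
    lun_c = np.array([+(cfg.lunate_semi[0] + cfg.slil_gap / 2), 0.0,
                      carpal_bottom + cfg.lunate_semi[2]])
    carpal_top = max(sca_c[2] + cfg.scaphoid_semi[2],
                     lun_c[2] + cfg.lunate_semi[2])
    cap_cart_c = carpal_top + g + t_cart
    cap_c = np.array([0.0, 0.0, carpal_top + g + 2 * t_cart
                      + cfg.capitate_semi[2]])

    def part_rng(idx):
        return np.random.default_rng([int(seed) & 0x7FFFFFFF, idx])

    parts: dict[str, SurfaceMesh] = {}
    amp = cfg.bump_amplitude
    parts["radius_cortical"] = _superellipsoid(
        (0.0, 0.0, -cfg.radius_semi[2]), cfg.radius_semi, 2.5,
        cfg.subdiv_large, part_rng(0), amp)
    parts["radius_cancellous"] = _superellipsoid(
        (0.0, 0.0, -cfg.radius_semi[2]),
        tuple(v * cfg.cancellous_scale for v in cfg.radius_semi), 2.5,
        cfg.subdiv_small, part_rng(1), amp)
    parts["radius_cartilage"] = _superellipsoid(
        (0.0, 0.0, rad_cart_c), cfg.radius_cartilage_semi, 2.5,
        cfg.subdiv_large, part_rng(2), 0.004)
    parts["scaphoid"] = _superellipsoid(
        sca_c, cfg.scaphoid_semi, 2.2, cfg.subdiv_small, part_rng(3), amp)
    parts["lunate"] = _superellipsoid(
        lun_c, cfg.lunate_semi, 2.2, cfg.subdiv_small, part_rng(4), amp)
    parts["capitate"] = _superellipsoid(
        cap_c, cfg.capitate_semi, 2.2, cfg.subdiv_small, part_rng(5), amp)
    parts["scaphoid_cartilage"] = _superellipsoid(
        (sca_c[0], 0.0, carpal_cart_c),
        (0.8 * cfg.scaphoid_semi[0], 0.8 * cfg.scaphoid_semi[1], t_cart),
        2.5, cfg.subdiv_small, part_rng(6), 0.004)
    parts["lunate_cartilage"] = _superellipsoid(
        (lun_c[0], 0.0, carpal_cart_c),
        (0.8 * cfg.lunate_semi[0], 0.8 * cfg.lunate_semi[1], t_cart),
        2.5, cfg.subdiv_small, part_rng(7), 0.004)
    parts["capitate_cartilage"] = _superellipsoid(
        (0.0, 0.0, cap_cart_c),
        (0.8 * cfg.capitate_semi[0], 0.8 * cfg.capitate_semi[1], t_cart),
        2.5, cfg.subdiv_small, part_rng(8), 0.004)
    parts["slil"] = _superellipsoid(
        (0.0, 0.0, 0.5 * (sca_c[2] + lun_c[2])),
        (cfg.slil_gap / 2 - cfg.slil_clearance, *cfg.slil_semi_yz),
        3.0, cfg.subdiv_small, part_rng(9), 0.004)

    model = AnatomyModel(parts=parts, landmarks=None, frame=dict(FRAME),
                         lever_arm_r=cfg_in.lever_arm_r, config=cfg_in)
    model.landmarks = place_ligament_landmarks(model)
    return model


# --------------------------------------------------------------------------
# ligament landmarks
# --------------------------------------------------------------------------

# table connection name -> surrogate part carrying the attachment surface
CONNECTION_PART = {
    "Radius": "radius_cortical",
    "Scaphoid": "scaphoid",
    "Lunate": "lunate",
    "Capitate": "capitate",
}

# anatomical placement directions in the model frame, keyed by
# (ligament, connection).  y<0 dorsal, y>0 volar, x<0 radial.
_DIRS: dict[tuple[str, str], tuple[float, float, float]] = {
    ("Dorsal intercarpal (lunate)", "Capitate"): (0.4, -1.0, -0.6),
    ("Dorsal intercarpal (lunate)", "Lunate"): (0.0, -1.0, 0.5),
    ("Dorsal intercarpal (scaphoid)", "Capitate"): (-0.4, -1.0, -0.6),
    ("Dorsal intercarpal (scaphoid)", "Scaphoid"): (0.0, -1.0, 0.5),
    ("Dorsal scapholunate", "Scaphoid"): (1.0, -0.7, 0.2),
    ("Dorsal scapholunate", "Lunate"): (-1.0, -0.7, 0.2),
    ("Long radiolunate", "Lunate"): (0.0, 1.0, -0.5),
    ("Long radiolunate", "Radius"): (0.4, 1.0, 0.9),
    ("Radial arcuate", "Capitate"): (-0.6, 1.0, -0.6),
    ("Radial arcuate", "Scaphoid"): (0.0, 1.0, 0.6),
    ("Radial collateral carpal", "Radius"): (-1.0, 0.1, 0.9),
    ("Radial collateral carpal", "Scaphoid"): (-1.0, 0.1, -0.2),
    ("Radioscaphocapitate", "Radius"): (-0.6, 1.0, 0.9),
    ("Radioscaphocapitate", "Capitate"): (-0.3, 1.0, -0.9),
    ("Short radiolunate", "Radius"): (0.0, 1.0, 1.0),
    ("Short radiolunate", "Scaphoid"): (-0.2, 1.0, -0.6),
    ("Volar Radioscapholunate", "Radius"): (0.0, 1.0, 1.2),
    ("Volar Radioscapholunate", "Scaphoid"): (0.6, 1.0, -0.5),
    ("Volar Radioscapholunate", "Lunate"): (-0.6, 1.0, -0.5),
}


def _attach_point(part: SurfaceMesh, ligament: str, connection: str
                  ) -> np.ndarray:
    """Surface point of ``part`` in the ligament's anatomical direction."""
    d = np.array(_DIRS[(ligament, connection)], dtype=float)
    d /= np.linalg.norm(d)
    center = 0.5 * (part.vertices.min(0) + part.vertices.max(0))
    reach = part.bbox_diagonal
    return part.snap((center + reach * d)[None])[0]


def place_ligament_landmarks(model: AnatomyModel,
                             rows=None) -> LandmarkSet:
    """One landmark pair per ligament table row; the combined
    Scaphoid+Lunate row expands into two entries sharing the radius point."""
    rows = rows if rows is not None else LIGAMENT_ROWS
    entries: list[LigamentAttachment] = []
    for (lig, con_a, con_b, _k) in rows:
        targets = con_b.split("+")
        for con in [con_a] + targets:
            if con not in CONNECTION_PART:
                raise KeyError(f"unknown connection name {con!r} in ligament "
                               f"table row {lig!r}")
            if CONNECTION_PART[con] not in model.parts:
                raise KeyError(f"model has no part for connection {con!r} "
                               f"(ligament {lig!r})")
        part_a = CONNECTION_PART[con_a]
        pa = _attach_point(model.parts[part_a], lig, con_a)
        for con in targets:
            part_b = CONNECTION_PART[con]
            pb = _attach_point(model.parts[part_b], lig, con)
            entries.append(LigamentAttachment(lig, part_a, pa, part_b, pb))
    return LandmarkSet(entries)


#: meshable bodies: the parts merged into one conforming tet mesh each
BODY_PARTS = {
    "radius": ["radius_cortical", "radius_cartilage"],
    "scaphoid": ["scaphoid", "scaphoid_cartilage"],
    "lunate": ["lunate", "lunate_cartilage"],
    "capitate": ["capitate", "capitate_cartilage"],
    "slil": ["slil"],
}


def body_envelope(model: AnatomyModel, body: str,
                  subdivisions: int = 3) -> SurfaceMesh:
    """Watertight outer surface of a bone together with its cartilage layer.

    Bone and cartilage are each star-shaped about the bone centre and
    tangent to each other, so their union is star-shaped too: for every
    icosphere direction, the envelope radius is the farthest exit point
    through either part's surface (ray casting).  The envelope is meshed
    once and its tets are region-tagged by centroid containment, giving a
    conforming bone-cartilage interface with shared nodes.
    """
    from ._geometry import ray_exit_distances
    if body not in BODY_PARTS:
        raise KeyError(f"unknown body {body!r}; have {list(BODY_PARTS)}")
    names = BODY_PARTS[body]
    primary = model.parts[names[0]]
    center = 0.5 * (primary.vertices.min(0) + primary.vertices.max(0))
    ico = trimesh.creation.icosphere(subdivisions=subdivisions)
    d = ico.vertices / np.linalg.norm(ico.vertices, axis=1, keepdims=True)
    rho = np.zeros(len(d))
    for name in names:
        part = model.parts[name]
        tri = part.vertices[part.faces]
        rho = np.maximum(rho, ray_exit_distances(center, d, tri))
    if np.any(rho <= 0):
        raise RuntimeError(f"envelope of {body!r} is not star-shaped about "
                           "the bone centre")
    return SurfaceMesh(center + rho[:, None] * d, ico.faces.copy())


def write_parts(model: AnatomyModel, out_dir, fmt: str = "ply") -> list[str]:
    """Export every part surface (ASCII PLY or STL) plus the landmark table."""
    import os
    os.makedirs(out_dir, exist_ok=True)
    written = []
    for name, part in model.parts.items():
        path = os.path.join(out_dir, f"{name}.{fmt}")
        t = part.as_trimesh()
        if fmt == "ply":
            data = t.export(file_type="ply", encoding="ascii")
        elif fmt == "stl":
            data = t.export(file_type="stl_ascii")
        else:
            raise ValueError(f"unsupported surface format {fmt!r}")
        mode = "wb" if isinstance(data, bytes) else "w"
        with open(path, mode) as fh:
            fh.write(data)
        written.append(path)
    lm_path = os.path.join(out_dir, "landmarks.tsv")
    with open(lm_path, "w") as fh:
        fh.write(model.landmarks.to_text())
    written.append(lm_path)
    return written
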