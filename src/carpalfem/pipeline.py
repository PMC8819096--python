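"""Assembly of the full reduced-wrist simulation case.

Glues the stages together: surrogate anatomy -> per-part tet meshes ->
merged model with tied interfaces, articular contacts, ligament springs and
motion boundary conditions -> SimulationCase ready for the solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anatomy import AnatomyModel, ShapeConfig, generate_reduced_wrist
from .fem import (ContactPair, SimulationCase, SolverSettings, TieConstraint,
                  build_part_ties)
from .kinematics import build_bc_set
from .materials import MaterialParams, default_library
from .mesh import SurfaceMesh, VolumeMesh, tetrahedralize
from .springs import SpringSet, build_spring_set

#: default target edge length (mm) per meshed body; coarse desk-scale meshes
DEFAULT_TARGET_EDGES = {
    "radius": 2.8,
    "scaphoid": 1.8,
    "lunate": 1.8,
    "capitate": 2.0,
    "slil": 0.9,
}

#: tied (bonded) interfaces: the SLIL block to both bones.  Cartilage needs
#: no ties: each bone+cartilage body is meshed conformingly (shared nodes).
TIE_TOPOLOGY = [
    ("slil", "scaphoid"),
    ("slil", "lunate"),
]

#: articulating surface pairs (frictionless)
CONTACT_TOPOLOGY = [
    ("scaphoid_cartilage", "radius_cartilage"),
    ("lunate_cartilage", "radius_cartilage"),
    ("capitate_cartilage", "scaphoid"),
    ("capitate_cartilage", "lunate"),
]

#: mesh region -> material library entry (carpal bones are modelled as a
#: single cortical piece, the conclusion of the cancellous-influence study)
REGION_MATERIAL = {
    "radius_cortical": "cortical",
    "radius_cancellous": "cancellous",
    "radius_cartilage": "cartilage",
    "scaphoid": "cortical",
    "lunate": "cortical",
    "capitate": "cortical",
    "scaphoid_cartilage": "cartilage",
    "lunate_cartilage": "cartilage",
    "capitate_cartilage": "cartilage",
    "slil": "slil",
}


def mesh_model(model: AnatomyModel,
               target_edges: dict[str, float] | None = None,
               include_slil: bool = True) -> VolumeMesh:
    """Tet-mesh every body and merge into one labelled volume mesh.

    Each bone is meshed together with its cartilage layer as a single
    conforming body (the union envelope is triangulated once and the tets
    region-tagged by centroid containment), so bone-cartilage interfaces
    share nodes; the radius additionally carries its cancellous region.
    The SLIL block is its own body, later tied to scaphoid and lunate.
    """
    from .anatomy import body_envelope
    edges = dict(DEFAULT_TARGET_EDGES)
    if target_edges:
        edges.update(target_edges)
    pieces = [tetrahedralize(
        body_envelope(model, "radius"), edges["radius"], part="radius",
        base_region="radius_cortical",
        region_surfaces=[
            ("radius_cancellous", model.parts["radius_cancellous"]),
            ("radius_cartilage", model.parts["radius_cartilage"]),
        ])]
    for bone in ("scaphoid", "lunate", "capitate"):
        pieces.append(tetrahedralize(
            body_envelope(model, bone), edges[bone], part=bone,
            base_region=bone,
            region_surfaces=[(f"{bone}_cartilage",
                              model.parts[f"{bone}_cartilage"])]))
    if include_slil:
        pieces.append(tetrahedralize(model.parts["slil"], edges["slil"],
                                     part="slil"))
    return VolumeMesh.merge(pieces)


@dataclass
class WristCaseConfig:
    """Everything needed to assemble the full-wrist simulation."""

    shape: ShapeConfig = field(default_factory=ShapeConfig)
    seed: int = 1
    motion: str = "extension"
    angle_policy: str = "midpoint"
    explicit_angle_deg: float | None = None
    steps: int = 10
    no_slil: bool = False
    target_edges: dict[str, float] = field(default_factory=dict)
    tie_stiffness: float = 1e3            # N/mm per node pair
    tie_search_radius: float = 1.5        # mm
    contact_mode: str = "gap_spring"
    contact_penalty: float = 150.0        # N/mm
    contact_search_radius: float = 2.5    # mm
    spring_tension_only: bool = False
    material_overrides: dict[str, MaterialParams] = field(default_factory=dict)
    settings: SolverSettings = field(default_factory=SolverSettings)


def build_wrist_case(config: WristCaseConfig | None = None,
                     model: AnatomyModel | None = None
                     ) -> tuple[SimulationCase, AnatomyModel]:
    """Build the assembled SimulationCase (and return the anatomy used)."""
    cfg = config or WristCaseConfig()
    if model is None:
        model = generate_reduced_wrist(cfg.shape, seed=cfg.seed)
    mesh = mesh_model(model, cfg.target_edges,
                      include_slil=not cfg.no_slil)

    ties: list[TieConstraint] = []
    for a, b in TIE_TOPOLOGY:
        if cfg.no_slil and "slil" in (a, b):
            continue
        ties.append(build_part_ties(mesh, a, b, cfg.tie_stiffness,
                                    cfg.tie_search_radius))

    contacts = [ContactPair(a, b, cfg.contact_penalty, cfg.contact_mode,
                            cfg.contact_search_radius)
                for a, b in CONTACT_TOPOLOGY]

    springs: SpringSet = build_spring_set(
        model.landmarks, mesh, tension_only=cfg.spring_tension_only)

    bcs = build_bc_set(mesh, cfg.motion, steps=cfg.steps,
                       policy=cfg.angle_policy,
                       explicit_deg=cfg.explicit_angle_deg,
                       r_mm=model.lever_arm_r,
                       capitate_parts=("capitate",))

    lib = default_library(cfg.material_overrides or None)
    materials = {region: lib[kind] for region, kind in REGION_MATERIAL.items()
                 if region in mesh.region_names}

    case = SimulationCase(mesh, materials, bcs, springs=springs, ties=ties,
                          contacts=contacts, settings=cfg.settings)
    case.validate()
    return case, model
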