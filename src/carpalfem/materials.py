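"""Constitutive models for the carpal model (mm-N-MPa unit system).

Bone (cortical and cancellous) is linear elastic isotropic.  Cartilage and
the scapholunate interosseous ligament (SLIL) block are compressible
two-parameter Mooney-Rivlin solids with strain energy

    W = C1 (I1bar - 3) + C2 (I2bar - 3) + (K/2) (J - 1)^2

where J = det F, I1bar = J^(-2/3) tr(C), I2bar = J^(-4/3) I2(C) are the
deviatoric invariants of C = F^T F, and the volumetric coefficient D1 is
taken as K/2 so the small-strain bulk response equals the bulk modulus K.

The default library stores the literature parameter set used throughout the
model: cortical bone E = 18 MPa, nu = 0.2 and cancellous E = 100 MPa,
nu = 0.25 (as printed in the source literature; cortical bone is usually
quoted in GPa, so an override hook is provided); cartilage C1 = 4.1,
C2 = 0.41, K = 19.3 MPa; SLIL C1 = 832.4e-6, C2 = 11.05e-6, K = 9.19802 MPa.

All stress evaluators accept complex-valued inputs so that derivatives can
be obtained by complex-step differentiation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class LinearElasticParams:
    """Isotropic Hooke material: Young's modulus E (MPa), Poisson ratio nu."""

    E: float
    nu: float

    def __post_init__(self):
        if self.E <= 0:
            raise ValueError("E must be positive")
        if not -1.0 < self.nu < 0.5:
            raise ValueError("nu must lie in (-1, 0.5)")

    @property
    def lame(self) -> tuple[float, float]:
        lam = self.E * self.nu / ((1 + self.nu) * (1 - 2 * self.nu))
        mu = self.E / (2 * (1 + self.nu))
        return lam, mu


@dataclass(frozen=True)
class MooneyRivlinParams:
    """Compressible Mooney-Rivlin: C1=C10, C2=C01 (MPa), bulk modulus K (MPa)."""

    C1: float
    C2: float
    K: float

    def __post_init__(self):
        if self.C1 + self.C2 <= 0:
            raise ValueError("C1 + C2 must be positive")
        if self.K <= 0:
            raise ValueError("K must be positive")

    @property
    def D1(self) -> float:
        return 0.5 * self.K


MaterialParams = LinearElasticParams | MooneyRivlinParams


def bulk_modulus(E: float, nu: float) -> float:
    """K = E / (3 (1 - 2 nu)).  E.g. cartilage E=11.6, nu=0.4 -> 19.33 MPa."""
    if E <= 0:
        raise ValueError("E must be positive")
    if nu >= 0.5:
        raise ValueError("nu >= 0.5 (incompressible limit) has no finite K")
    return E / (3.0 * (1.0 - 2.0 * nu))


def poisson_from_bulk(E: float, K: float) -> float:
    """Invert K = E/(3(1-2nu)): nu = (1 - E/(3K)) / 2."""
    if E <= 0:
        raise ValueError("E must be positive")
    if E >= 3.0 * K:
        raise ValueError("requires E < 3K for a positive Poisson ratio")
    return 0.5 * (1.0 - E / (3.0 * K))


def ligament_bulk_as_printed() -> float:
    """The SLIL bulk modulus as used in the model: 9.19802 MPa.

    The source quotes a bulk/shear ratio of 1000 for ligament together with
    the Weiss constants C1 = 832.4e-6 and C2 = 11.05e-6 MPa, and prints
    K = 9.19802 MPa.  The printed value is reproduced (only) by the chain
    1000 * (832.4e-6 * 11.05e-6) * 1e6, whose unit bookkeeping is ambiguous;
    the constant is therefore stored as printed rather than derived.
    """
    return 9.19802


# --------------------------------------------------------------------------
# Mooney-Rivlin energy / stress
# --------------------------------------------------------------------------

def _invariants(F: np.ndarray):
    C = F.swapaxes(-1, -2) @ F
    I1 = np.trace(C, axis1=-2, axis2=-1)
    I2 = 0.5 * (I1 ** 2 - np.trace(C @ C, axis1=-2, axis2=-1))
    J = np.linalg.det(F)
    return I1, I2, J


def mr_energy(F: np.ndarray, p: MooneyRivlinParams):
    """Strain-energy density W(F) in MPa (= mJ/mm^3).

    Accepts a single 3x3 deformation gradient or a batch (..., 3, 3);
    complex input is allowed for complex-step differentiation.
    """
    F = np.asarray(F)
    I1, I2, J = _invariants(F)
    if not np.iscomplexobj(F) and np.any(J.real <= 0):
        raise ValueError("element inversion: det(F) <= 0")
    I1b = J ** (-2.0 / 3.0) * I1
    I2b = J ** (-4.0 / 3.0) * I2
    return p.C1 * (I1b - 3.0) + p.C2 * (I2b - 3.0) + p.D1 * (J - 1.0) ** 2


def mr_first_piola(F: np.ndarray, p: MooneyRivlinParams) -> np.ndarray:
    """First Piola-Kirchhoff stress P = dW/dF (analytic), batched."""
    F = np.asarray(F)
    single = F.ndim == 2
    if single:
        F = F[None]
    I1, I2, J = _invariants(F)
    if not np.iscomplexobj(F) and np.any(J.real <= 0):
        raise ValueError("element inversion: det(F) <= 0")
    Fit = np.linalg.inv(F).swapaxes(-1, -2)       # F^{-T}
    C = F.swapaxes(-1, -2) @ F
    FC = F @ C
    Jm23 = J ** (-2.0 / 3.0)
    Jm43 = J ** (-4.0 / 3.0)
    b1 = I1[..., None, None]
    b2 = I2[..., None, None]
    bJ = J[..., None, None]
    dI1b = Jm23[..., None, None] * (2.0 * F - (2.0 / 3.0) * b1 * Fit)
    dI2b = Jm43[..., None, None] * (2.0 * b1 * F - 2.0 * FC
                                    - (4.0 / 3.0) * b2 * Fit)
    dvol = 2.0 * p.D1 * (bJ - 1.0) * bJ * Fit
    P = p.C1 * dI1b + p.C2 * dI2b + dvol
    return P[0] if single else P


def mr_stress(F: np.ndarray, p: MooneyRivlinParams) -> np.ndarray:
    """Cauchy stress sigma = J^{-1} P F^T (MPa); symmetric by construction."""
    F = np.asarray(F, dtype=float)
    single = F.ndim == 2
    if single:
        F = F[None]
    P = mr_first_piola(F, p)
    J = np.linalg.det(F)
    sig = P @ F.swapaxes(-1, -2) / J[..., None, None]
    sig = 0.5 * (sig + sig.swapaxes(-1, -2))   # kill roundoff asymmetry
    return sig[0] if single else sig


def linear_stress(strain: np.ndarray, p: LinearElasticParams) -> np.ndarray:
    """Hooke's law sigma = lambda tr(eps) I + 2 mu eps, batched."""
    eps = np.asarray(strain)
    lam, mu = p.lame
    tr = np.trace(eps, axis1=-2, axis2=-1)
    eye = np.eye(3, dtype=eps.dtype)
    return lam * tr[..., None, None] * eye + 2.0 * mu * eps


# --------------------------------------------------------------------------
# default library
# --------------------------------------------------------------------------

def default_library(overrides: dict[str, MaterialParams] | None = None
                    ) -> dict[str, MaterialParams]:
    """Named default materials; ``overrides`` replaces entries wholesale."""
    lib: dict[str, MaterialParams] = {
        "cortical": LinearElasticParams(E=18.0, nu=0.2),
        "cancellous": LinearElasticParams(E=100.0, nu=0.25),
        "cartilage": MooneyRivlinParams(C1=4.1, C2=0.41, K=19.3),
        "slil": MooneyRivlinParams(C1=832.4e-6, C2=11.05e-6,
                                   K=ligament_bulk_as_printed()),
    }
    if overrides:
        lib.update(overrides)
    return lib


def library_to_config(lib: dict[str, MaterialParams]) -> dict:
    """Serializable description (names, model kind, parameters, units)."""
    out = {}
    for name, p in lib.items():
        if isinstance(p, LinearElasticParams):
            out[name] = {"model": "linear_elastic", "E_MPa": p.E, "nu": p.nu}
        else:
            out[name] = {"model": "mooney_rivlin", "C1_MPa": p.C1,
                         "C2_MPa": p.C2, "K_MPa": p.K}
    return out


def library_from_config(cfg: dict) -> dict[str, MaterialParams]:
    lib: dict[str, MaterialParams] = {}
    for name, d in cfg.items():
        if d["model"] == "linear_elastic":
            lib[name] = LinearElasticParams(E=d["E_MPa"], nu=d["nu"])
        elif d["model"] == "mooney_rivlin":
            lib[name] = MooneyRivlinParams(C1=d["C1_MPa"], C2=d["C2_MPa"],
                                           K=d["K_MPa"])
        else:
            raise ValueError(f"unknown material model {d['model']!r}")
    return lib
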