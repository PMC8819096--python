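"""Pressure observables extracted from solved fields.

"Pressure" here is the hydrostatic part of the Cauchy stress,

    p = -(sigma_11 + sigma_22 + sigma_33) / 3,

with the sign convention that compression is positive (so the published
"max compression"/"max traction" pair maps to the maximum of p and of -p).
The opposite sign convention is equally common; mind the sign when
comparing against other tools.  Internally stresses are MPa; reported
pressures are converted to Pa exactly once, here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MPA_TO_PA = 1.0e6


def element_pressure(stress: np.ndarray) -> np.ndarray | float:
    """Hydrostatic pressure, compression positive (input units preserved)."""
    s = np.asarray(stress, dtype=float)
    tr = np.trace(s, axis1=-2, axis2=-1)
    p = -tr / 3.0
    return float(p) if p.ndim == 0 else p


@dataclass
class PressureCurveSet:
    """Per-step envelope (min/max over region elements) and average."""

    region: str
    steps: np.ndarray          # ramp fractions
    p_min: np.ndarray          # Pa
    p_max: np.ndarray
    p_mean: np.ndarray         # volume-weighted
    units: str = "Pa"

    def __post_init__(self):
        if not (len(self.steps) == len(self.p_min) == len(self.p_max)
                == len(self.p_mean)):
            raise ValueError("curve arrays must share a length")
        if np.any(self.p_min > self.p_mean + 1e-9) or \
                np.any(self.p_mean > self.p_max + 1e-9):
            raise ValueError("envelope must satisfy min <= mean <= max")

    def to_text(self) -> str:
        lines = ["step_fraction\tp_min_Pa\tp_max_Pa\tp_mean_Pa"]
        for t, a, b, m in zip(self.steps, self.p_min, self.p_max,
                              self.p_mean):
            lines.append(f"{t:.6g}\t{a:.9e}\t{b:.9e}\t{m:.9e}")
        return "\n".join(lines) + "\n"


def _region_pressures(result, region: str):
    mask = result.mesh.part_mask(region)
    if not mask.any():
        raise ValueError(f"region {region!r} has no elements")
    if result.n_steps == 0:
        raise ValueError("result holds no converged steps")
    p = element_pressure(result.stresses[:, mask]) * MPA_TO_PA
    vol = np.abs(result.mesh.signed_volumes())[mask]
    return p, vol


def region_envelope(result, region: str) -> PressureCurveSet:
    """Min/max/volume-weighted-mean pressure per step over a region."""
    p, vol = _region_pressures(result, region)
    return PressureCurveSet(
        region=region,
        steps=result.ramp.copy(),
        p_min=p.min(axis=1),
        p_max=p.max(axis=1),
        p_mean=(p * vol).sum(axis=1) / vol.sum(),
    )


def max_compression_traction(result, region: str) -> tuple[float, float]:
    """(max compression, max traction) in Pa over all steps and elements.

    Both values are reported as non-negative magnitudes; an all-compressive
    field has zero traction.
    """
    p, _ = _region_pressures(result, region)
    return float(max(p.max(), 0.0)), float(max(-p.min(), 0.0))


def plot_envelope(curves: PressureCurveSet, path) -> None:
    """Envelope-and-average plot for one region (PNG/PDF by extension)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.fill_between(curves.steps, curves.p_min, curves.p_max,
                    alpha=0.3, label="envelope")
    ax.plot(curves.steps, curves.p_mean, "-o", ms=3, label="average")
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("ramp fraction")
    ax.set_ylabel("pressure [Pa] (compression > 0)")
    ax.set_title(curves.region)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
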