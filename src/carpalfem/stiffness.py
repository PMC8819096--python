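"""SLIL stiffness estimation from uniaxial load-displacement curves.

Cadaveric scapholunate-ligament samples pulled in a tensile machine give a
force-displacement record with a compliant "toe" region followed by an
approximately linear branch; the linear stiffness k (N/mm) is the
least-squares slope over a window of that branch.  Summary statistics over
samples use the sample (n-1) standard deviation, which is what reproduces
the published 71.50/39.00 N/mm from the six published samples.  A synthetic
curve generator stands in for the testing machine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .tables import (EXPERIMENTAL_SLIL_STIFFNESS, LITERATURE_SLIL_STIFFNESS,
                     LITERATURE_SUMMARY_PRINTED)


@dataclass
class LoadDisplacementCurve:
    displacement_mm: np.ndarray
    force_n: np.ndarray
    sample_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.displacement_mm = np.asarray(self.displacement_mm, dtype=float)
        self.force_n = np.asarray(self.force_n, dtype=float)
        if self.displacement_mm.shape != self.force_n.shape:
            raise ValueError("displacement and force must have equal length")
        if np.any(np.diff(self.displacement_mm) <= 0):
            raise ValueError("displacement must be strictly increasing")

    def to_text(self) -> str:
        lines = ["displacement_mm\tforce_N"]
        lines += [f"{d:.9g}\t{f:.9g}" for d, f in
                  zip(self.displacement_mm, self.force_n)]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str, sample_id: str = "") -> "LoadDisplacementCurve":
        rows = [ln.split("\t") for ln in text.strip().splitlines()[1:]]
        arr = np.array(rows, dtype=float)
        return cls(arr[:, 0], arr[:, 1], sample_id=sample_id)


@dataclass
class StiffnessSummary:
    values: list[float]               # per-sample k, N/mm
    mean: float
    std: float                       # sample (n-1) standard deviation

    def rounded(self, ndigits: int = 2) -> tuple[float, float]:
        """Reported (mean, std) rounded in decimal.

        Values are first snapped to 6 decimals so binary representation
        noise (e.g. 71.505000...007) does not flip the final rounding.
        """
        from decimal import ROUND_HALF_EVEN, Decimal

        def _round(v: float) -> float:
            q = Decimal(1).scaleb(-ndigits)
            return float(Decimal(str(round(v, 6))).quantize(
                q, rounding=ROUND_HALF_EVEN))

        return _round(self.mean), _round(self.std)


#: default fit window: the upper fraction of the displacement range
DEFAULT_WINDOW_FRACTION = 0.6


def fit_linear_stiffness(curve: LoadDisplacementCurve,
                         window: tuple[float, float] | None = None) -> float:
    """Ordinary least-squares slope of force vs displacement (N/mm).

    ``window`` is a (lower, upper) displacement interval; by default the
    upper 60% of the displacement range is used, skipping the toe region.
    Needs at least 3 samples in the window.
    """
    d, f = curve.displacement_mm, curve.force_n
    if window is None:
        lo = d.min() + (1.0 - DEFAULT_WINDOW_FRACTION) * (d.max() - d.min())
        window = (lo, d.max())
    sel = (d >= window[0]) & (d <= window[1])
    if sel.sum() < 3:
        raise ValueError(f"fit window {window} selects {int(sel.sum())} "
                         "samples; need >= 3")
    res = stats.linregress(d[sel], f[sel])
    return float(res.slope)


def summarize_stiffness(values) -> StiffnessSummary:
    """Mean and sample (n-1) standard deviation of per-sample stiffness."""
    vals = [float(v) for v in values]
    if len(vals) < 2:
        raise ValueError("need at least 2 stiffness values")
    arr = np.asarray(vals)
    return StiffnessSummary(values=vals, mean=float(arr.mean()),
                            std=float(arr.std(ddof=1)))


def experimental_summary() -> StiffnessSummary:
    """Summary of the six published cadaveric SLIL samples."""
    return summarize_stiffness(EXPERIMENTAL_SLIL_STIFFNESS)


def compare_to_literature(summary: StiffnessSummary,
                          literature: dict | None = None) -> dict:
    """Is the experimental mean inside each published range?

    Point literature values count as a closed single-point interval.  The
    published pooled literature summary is attached as a reference constant
    (its printed derivation is ambiguous, see ``tables``).
    """
    lit = literature if literature is not None else LITERATURE_SLIL_STIFFNESS
    rows = {}
    for name, entry in lit.items():
        lo, hi = (entry, entry) if np.isscalar(entry) else entry
        rows[name] = {
            "range_n_per_mm": (float(lo), float(hi)),
            "mean_inside": bool(lo <= summary.mean <= hi),
        }
    return {
        "experimental_mean": summary.mean,
        "experimental_std": summary.std,
        "literature": rows,
        "literature_pooled_printed": LITERATURE_SUMMARY_PRINTED,
    }


def report_text(comparison: dict) -> str:
    mean, std = StiffnessSummary([], comparison["experimental_mean"],
                                 comparison["experimental_std"]).rounded()
    lines = [
        "SLIL linear stiffness summary",
        f"  experimental mean/std: {mean:.2f}/{std:.2f} N/mm",
        f"  literature pooled (printed): "
        f"{comparison['literature_pooled_printed'][0]:.2f}"
        f"/{comparison['literature_pooled_printed'][1]:.2f} N/mm",
    ]
    for name, row in comparison["literature"].items():
        lo, hi = row["range_n_per_mm"]
        verdict = "inside" if row["mean_inside"] else "outside"
        rng = f"{lo:g}" if lo == hi else f"{lo:g}-{hi:g}"
        lines.append(f"  vs {name}: {rng} N/mm -> mean {verdict}")
    return "\n".join(lines) + "\n"


def synthesize_curve(k_true: float, noise_sd: float = 1.0,
                     toe_extent: float = 0.3, n: int = 50,
                     seed: int = 0,
                     max_displacement: float = 2.0) -> LoadDisplacementCurve:
    """Synthetic tensile test: cubic toe region then a linear branch.

    The toe ramps force as a cubic reaching slope ``k_true`` continuously at
    ``toe_extent`` (mm); beyond it the response is exactly linear with slope
    k_true.  Gaussian force noise of sd ``noise_sd`` (N) is added.
    Deterministic for a fixed seed.
    """
    if k_true <= 0:
        raise ValueError("k_true must be positive")
    if n < 10:
        raise ValueError("need n >= 10 samples")
    if noise_sd < 0 or toe_extent < 0 or max_displacement <= toe_extent:
        raise ValueError("invalid noise/toe/extent parameters")
    rng = np.random.default_rng(seed)
    d = np.linspace(0.0, max_displacement, n)
    if toe_extent > 0:
        # toe cubic with f(0)=f'(0)=0, meeting the linear branch with value
        # (2/3) k t and slope k at d = t (C1-continuous)
        t = toe_extent
        f_toe = k_true * (d ** 2 / t - d ** 3 / (3 * t ** 2))
        f_lin = (2.0 / 3.0) * k_true * t + k_true * (d - t)
        f = np.where(d < t, f_toe, f_lin)
    else:
        f = k_true * d
    f = f + rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else f
    return LoadDisplacementCurve(d, f, sample_id=f"synthetic-k{k_true:g}",
                                 metadata={"k_true": k_true, "seed": seed,
                                           "noise_sd": noise_sd,
                                           "toe_extent": toe_extent})
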