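"""Droplet solute-concentration estimation from fluorescence.

Residual microdroplets on a drying surface are far more concentrated than
the starting medium.  With a fluorescent dye added as a concentration
reporter, droplet concentration is estimated by (1) building a monotone
piecewise-linear calibration curve from intensity measurements of standards
of known concentration, (2) measuring each droplet's mean dye intensity —
excluding a ~1 µm-wide rim and any bead pixels — and (3) inverting the
curve.  Concentrations are expressed in multiples of the reference medium.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "CalibrationCurve",
    "ConcentrationEstimate",
    "build_calibration",
    "droplet_mean_intensity",
    "estimate_concentration",
    "concentration_summary",
    "DILUTION_FACTORS",
]

#: the standard dilution series used to span a calibration curve
DILUTION_FACTORS = (1.11, 1.25, 1.43, 1.6, 2, 2.5, 3.33, 5, 10, 20)


@dataclass(frozen=True)
class CalibrationCurve:
    """Monotone piecewise-linear intensity↔concentration mapping.

    ``concentrations`` are in multiples of the reference medium,
    ``intensities`` in camera units; both strictly increasing.
    """

    concentrations: np.ndarray
    intensities: np.ndarray
    solute: str = ""
    acquisition: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        i = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "intensities", i)
        if len(c) < 2 or len(c) != len(i):
            raise ValueError("need >= 2 (concentration, intensity) knots")
        if not np.all(np.diff(c) > 0):
            bad = np.where(np.diff(c) <= 0)[0]
            raise ValueError(f"concentrations not strictly increasing at knots {bad.tolist()}")
        if not np.all(np.diff(i) > 0):
            bad = np.where(np.diff(i) <= 0)[0]
            raise ValueError(f"intensities not strictly increasing at knots {bad.tolist()}")

    def intensity_at(self, concentration: float) -> float:
        """Forward lookup (linear interpolation; linear extrapolation from
        the terminal segments outside the knot range)."""
        return float(_interp_extrap(concentration, self.concentrations, self.intensities))

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "concentration": self.concentrations, "intensity": self.intensities,
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, **meta) -> "CalibrationCurve":
        df = pd.read_csv(path)
        return build_calibration(list(zip(df["concentration"], df["intensity"])), **meta)


@dataclass(frozen=True)
class ConcentrationEstimate:
    droplet_id: int
    mean_intensity: float
    concentration: float
    extrapolated: bool


def build_calibration(
    pairs: Sequence[tuple[float, float]], solute: str = "", acquisition: str = ""
) -> CalibrationCurve:
    """Build the calibration curve from (concentration, intensity) pairs.

    Pairs are sorted by concentration; non-monotone intensities are rejected
    with the offending knots named.
    """
    if len(pairs) < 2:
        raise ValueError(f"need >= 2 pairs, got {len(pairs)}")
    arr = sorted((float(c), float(i)) for c, i in pairs)
    c = np.array([p[0] for p in arr])
    i = np.array([p[1] for p in arr])
    return CalibrationCurve(c, i, solute=solute, acquisition=acquisition)


def _interp_extrap(x: float, xp: np.ndarray, yp: np.ndarray) -> float:
    """np.interp with linear extrapolation from the terminal segments."""
    if x < xp[0]:
        s = (yp[1] - yp[0]) / (xp[1] - xp[0])
        return yp[0] + s * (x - xp[0])
    if x > xp[-1]:
        s = (yp[-1] - yp[-2]) / (xp[-1] - xp[-2])
        return yp[-1] + s * (x - xp[-1])
    return float(np.interp(x, xp, yp))


def droplet_mean_intensity(
    image: np.ndarray,
    droplet_mask: np.ndarray,
    bead_mask: Optional[np.ndarray] = None,
    boundary_width_um: float = 1.0,
    pixel_size_um: float = 0.1625,
) -> float:
    """Mean dye intensity over a droplet's interior.

    The ~``boundary_width_um``-wide rim is dropped by eroding the droplet
    mask with a Euclidean disk: a pixel is kept only if its distance to the
    nearest background pixel exceeds the rim width plus half a pixel (the
    half pixel bridges pixel centers and the actual mask edge).  Bead pixels
    (from a bright-field threshold) are excluded as well.  Raises if nothing
    remains — the droplet is too small to measure.
    """
    droplet_mask = np.asarray(droplet_mask, dtype=bool)
    if not droplet_mask.any():
        raise ValueError("droplet mask is empty")
    interior = droplet_mask
    if boundary_width_um > 0:
        r = boundary_width_um / pixel_size_um + 0.5
        # pad so the image border counts as background
        padded = np.pad(droplet_mask, 1)
        edt = ndimage.distance_transform_edt(padded)[1:-1, 1:-1]
        interior = edt > r
    if bead_mask is not None:
        interior = interior & ~np.asarray(bead_mask, dtype=bool)
    if not interior.any():
        raise ValueError(
            "no pixels remain after rim and bead exclusion; droplet too small to measure"
        )
    return float(np.asarray(image, dtype=float)[interior].mean())


def estimate_concentration(
    intensity: float, curve: CalibrationCurve, droplet_id: int = 0
) -> ConcentrationEstimate:
    """Inverse piecewise-linear lookup of concentration from intensity.

    Intensities outside the knot range are linearly extrapolated from the
    terminal segment and flagged ``extrapolated=True``.
    """
    extrapolated = not (curve.intensities[0] <= intensity <= curve.intensities[-1])
    conc = _interp_extrap(float(intensity), curve.intensities, curve.concentrations)
    return ConcentrationEstimate(droplet_id, float(intensity), conc, extrapolated)


def concentration_summary(
    estimates: Sequence[ConcentrationEstimate], reference_dilution: float = 1.0
) -> dict[str, float]:
    """Mean ± SD (sample SD) of concentration factors.

    Returns the factor relative to the reference medium and, additionally,
    relative to the starting dilution (e.g. a 0.5× start doubles the
    factor).
    """
    if len(estimates) == 0:
        raise ValueError("no estimates")
    if reference_dilution <= 0:
        raise ValueError("reference_dilution must be > 0")
    vals = np.array([e.concentration for e in estimates], dtype=float)
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return {
        "mean_factor": mean,
        "sd_factor": sd,
        "n": len(vals),
        "mean_factor_vs_start": mean / reference_dilution,
    }


def osmolarity(factor: float, base_osmolarity_osm_per_l: float) -> float:
    """Scale a user-supplied base osmolarity by a concentration factor.

    No default base value is provided: the base osmolarity of the medium
    must be computed or measured by the user.
    """
    if base_osmolarity_osm_per_l <= 0:
        raise ValueError("base osmolarity must be > 0")
    return factor * base_osmolarity_osm_per_l


def estimates_to_csv(estimates: Sequence[ConcentrationEstimate], path) -> None:
    pd.DataFrame([
        {
            "droplet_id": e.droplet_id, "mean_intensity": e.mean_intensity,
            "concentration": e.concentration, "extrapolated": e.extrapolated,
        }
        for e in estimates
    ]).to_csv(path, index=False)
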