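"""Three-dimensional morphology from cell thickness maps.

Because a red cell's interior refractive index is approximately uniform, the
measured phase is proportional to local thickness, phi = 2 pi dn T / lambda.
Inverting that relation turns a phase map into a height field T(x, y), from
which six 3-D descriptors are computed: volume V, surface-to-volume ratio S/V,
sphericity index SI = pi^(1/3) (6V)^(2/3) / S, average thickness Tavg, central
thickness T0, and the doughnut indicator Delta75 = Tbar(0.75) - T0 (the
azimuthally averaged thickness at three-quarters of the normalised radius
minus the central thickness; positive for dimpled, doughnut-like cells).

The surface model treats the cell as mirror-symmetric about its midplane: the
upper surface is the graph of T/2 and S = 2 * sum sqrt(1 + |grad(T/2)|^2) dA.
There is no separate rim term; the phantom family's thickness goes to zero at
the support edge, so the rim contribution vanishes in the continuum limit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .errors import ParameterError, ValidationError
from .holography import PhaseMap

logger = logging.getLogger(__name__)

_TWO_PI = 2.0 * np.pi

#: minimum mask size (pixels) for radial-profile features
MIN_PROFILE_PIXELS = 50
#: number of angular bins for azimuthal averaging
N_ANGULAR_BINS = 64

FEATURE3D_COLUMNS = [
    "volume_um3",
    "surface_um2",
    "sv_ratio_per_um",
    "sphericity",
    "t_avg_um",
    "t_0_um",
    "delta_75_um",
]


@dataclass
class ThicknessMap:
    """Cell thickness in micrometres on a pixel grid; zero outside the cell."""

    thickness: np.ndarray
    pixel_size: float
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.thickness = np.asarray(self.thickness, dtype=float)
        if self.thickness.ndim != 2:
            raise ValidationError("thickness must be a 2-D array")
        if not np.all(np.isfinite(self.thickness)):
            raise ValidationError("thickness contains non-finite values")
        if np.any(self.thickness < 0):
            raise ValidationError("thickness must be non-negative")
        if self.pixel_size <= 0:
            raise ValidationError("pixel_size must be positive")
        if self.mask is None:
            self.mask = self.thickness > 0
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.thickness.shape:
                raise ValidationError("mask shape does not match thickness")
            if np.any(self.thickness[~self.mask] > 0):
                raise ValidationError("thickness must be zero outside the mask")


def thickness_from_phase(
    p: PhaseMap,
    mask: np.ndarray,
    delta_n: float,
    wavelength: float,
) -> ThicknessMap:
    """Invert phi = 2 pi dn T / lambda inside the mask (clipped at zero)."""
    if delta_n <= 0:
        raise ParameterError("delta_n must be positive")
    if wavelength <= 0:
        raise ParameterError("wavelength must be positive")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != p.phase.shape:
        raise ValidationError("mask shape does not match phase")
    t = np.zeros_like(p.phase)
    t[mask] = np.clip(wavelength * p.phase[mask] / (_TWO_PI * delta_n), 0.0, None)
    return ThicknessMap(t, pixel_size=p.pixel_size, mask=mask)


def volume_and_surface(t: ThicknessMap) -> tuple[float, float]:
    """Volume and mirror-symmetric surface area of a thickness field.

    V = sum T dA; S = 2 sum sqrt(1 + |grad(T/2)|^2) dA over the mask, with
    central-difference gradients.
    """
    if not t.mask.any():
        raise ValidationError("mask is empty")
    dA = t.pixel_size ** 2
    volume = float(t.thickness.sum() * dA)
    gy, gx = np.gradient(t.thickness / 2.0, t.pixel_size)
    integrand = np.sqrt(1.0 + gy ** 2 + gx ** 2)
    surface = float(2.0 * integrand[t.mask].sum() * dA)
    return volume, surface


def sphericity(volume: float, surface_area: float) -> float:
    """Sphericity index SI = pi^(1/3) (6 V)^(2/3) / S; 1 for a sphere."""
    if volume <= 0 or surface_area <= 0:
        raise ParameterError("volume and surface_area must be positive")
    return float(np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / surface_area)


def thickness_profile_features(t: ThicknessMap) -> tuple[float, float, float]:
    """Average thickness, central thickness, and the doughnut indicator Delta75.

    Tavg = V / projected area.  The radial coordinate is normalised by the
    equivalent-disc radius R_eq = sqrt(area / pi) about the mask centroid.
    T0 is the mean thickness within rho <= 0.1 (a small central average, for
    noise robustness); Tbar(0.75) is the thickness azimuthally averaged over
    64 angular bins at rho = 0.75 with bilinear sampling.  Delta75 =
    Tbar(0.75) - T0, positive for doughnut-shaped cells.

    Masks below 50 px are flagged and the profile features returned as NaN.
    """
    mask = t.mask
    npx = int(mask.sum())
    if npx == 0:
        raise ValidationError("mask is empty")
    dA = t.pixel_size ** 2
    t_avg = float(t.thickness.sum() * dA / (npx * dA))
    if npx < MIN_PROFILE_PIXELS:
        logger.warning(
            "thickness profile: mask has %d px < %d; profile features set to NaN",
            npx,
            MIN_PROFILE_PIXELS,
        )
        return t_avg, float("nan"), float("nan")

    cy, cx = ndi.center_of_mass(mask)
    r_eq = np.sqrt(npx / np.pi)  # pixels
    yy, xx = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
    rho = np.hypot(yy - cy, xx - cx) / r_eq
    central = mask & (rho <= 0.1)
    if central.any():
        t_0 = float(t.thickness[central].mean())
    else:
        t_0 = float(
            ndi.map_coordinates(t.thickness, [[cy], [cx]], order=1)[0]
        )

    theta = np.linspace(0.0, 2.0 * np.pi, N_ANGULAR_BINS, endpoint=False)
    ry = cy + 0.75 * r_eq * np.sin(theta)
    rx = cx + 0.75 * r_eq * np.cos(theta)
    t75 = float(ndi.map_coordinates(t.thickness, [ry, rx], order=1).mean())
    return t_avg, t_0, t75 - t_0


def cell_features3d(t: ThicknessMap) -> dict[str, float]:
    """All six 3-D features of one cell as a column-named dict."""
    volume, surface = volume_and_surface(t)
    t_avg, t_0, d75 = thickness_profile_features(t)
    return {
        "volume_um3": volume,
        "surface_um2": surface,
        "sv_ratio_per_um": surface / volume,
        "sphericity": sphericity(volume, surface),
        "t_avg_um": t_avg,
        "t_0_um": t_0,
        "delta_75_um": d75,
    }


def extract_features3d(
    p: PhaseMap,
    labels,
    delta_n: float,
    wavelength: float,
) -> pd.DataFrame:
    """Per-instance 3-D features from a phase map via the constant-RI inversion.

    ``labels`` is a LabelMap; each instance's thickness is recovered with
    ``thickness_from_phase`` and summarised by ``cell_features3d``.
    """
    rows = []
    lab = labels.labels
    for i in range(1, int(lab.max()) + 1):
        mask = lab == i
        t = thickness_from_phase(p, mask, delta_n, wavelength)
        row = {"cell_id": i}
        row.update(cell_features3d(t))
        rows.append(row)
    return pd.DataFrame(rows, columns=["cell_id"] + FEATURE3D_COLUMNS)
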