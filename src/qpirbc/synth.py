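"""Parametric red-blood-cell phantoms and forward models.

Healthy red cells are biconcave discocytes; thalassemia-minor cells are
hypochromic (lower haemoglobin, hence lower refractive-index contrast) and
flatter, trending toward a doughnut shape with a deeper central dimple.  Both
regimes are realised with the Evans-Fung thickness parameterisation

    T(rho) = sqrt(1 - rho^2) * (c0 + c2 rho^2 + c4 rho^4),   rho = r / R,

which has closed-form volume and profile values, so every downstream
measurement can be checked against analytic ground truth.  The forward optics
are the thin-object phase model phi = 2 pi dn T / lambda and an off-axis
two-beam interference pattern with additive Gaussian camera noise and 16-bit
quantisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError, SpecRejectionError, ValidationError
from .holography import Interferogram, PhaseMap
from .morphology3d import ThicknessMap
from .segmentation import LabelMap

logger = logging.getLogger(__name__)

_TWO_PI = 2.0 * np.pi

#: per-class sampling distributions (mean, sd) for the phantom parameters.
#: Thalassemic cells: smaller radius, much smaller central thickness c0 (deeper
#: dimple relative to the rim), larger rim coefficients, and a lower
#: refractive-index contrast (hypochromia).  These defaults realise the
#: population contrasts expected of the two classes: lower optical volume and
#: mean phase but higher phase SD and a more doughnut-like profile for the
#: thalassemic class.
DEFAULT_CLASS_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "healthy": {
        "radius": (3.85, 0.35),
        "c0": (0.75, 0.20),
        "c2": (7.8, 0.7),
        "c4": (-4.4, 0.45),
        "delta_n": (0.0630, 0.0035),
    },
    "thal": {
        "radius": (3.55, 0.35),
        "c0": (0.15, 0.06),
        "c2": (10.6, 0.7),
        "c4": (-6.6, 0.5),
        "delta_n": (0.0540, 0.0035),
    },
}

DEFAULT_WAVELENGTH = 0.532  # um, 532-nm continuous-wave laser


@dataclass
class PhantomSpec:
    """Analytic description of one cell phantom."""

    cell_class: str  # healthy | thal
    radius: float  # um
    shape_coeffs: tuple[float, float, float]  # (c0, c2, c4) um
    delta_n: float
    wavelength: float = DEFAULT_WAVELENGTH
    center: tuple[float, float] = (0.0, 0.0)  # (x, y) um
    rotation: float = 0.0  # degrees; no-op for the axisymmetric family

    def __post_init__(self) -> None:
        if self.cell_class not in ("healthy", "thal"):
            raise ValidationError(f"unknown cell class {self.cell_class!r}")
        if self.radius <= 0:
            raise ValidationError("radius must be positive")
        if self.delta_n <= 0 or self.wavelength <= 0:
            raise ValidationError("delta_n and wavelength must be positive")
        # check the polynomial factor itself: near rho = 1 the sqrt envelope
        # suppresses a sign change below any pointwise thickness tolerance
        c0, c2, c4 = self.shape_coeffs
        u = np.linspace(0.0, 1.0, 1000)
        if np.any(c0 + c2 * u + c4 * u * u < -1e-12):
            raise SpecRejectionError(
                f"negative thickness for coefficients {self.shape_coeffs}"
            )

    # -- closed forms ------------------------------------------------------
    def thickness_profile(self, rho: np.ndarray) -> np.ndarray:
        """Evans-Fung thickness at normalised radius rho (0 outside)."""
        rho = np.asarray(rho, dtype=float)
        c0, c2, c4 = self.shape_coeffs
        inside = rho < 1.0
        r2 = np.where(inside, rho * rho, 1.0)
        t = np.sqrt(np.clip(1.0 - r2, 0.0, None)) * (c0 + c2 * r2 + c4 * r2 * r2)
        return np.where(inside, t, 0.0)

    @property
    def analytic_volume(self) -> float:
        """Closed-form radial integral: V = 2 pi R^2 (c0/3 + 2 c2/15 + 8 c4/105)."""
        c0, c2, c4 = self.shape_coeffs
        return float(_TWO_PI * self.radius ** 2 * (c0 / 3 + 2 * c2 / 15 + 8 * c4 / 105))

    @property
    def analytic_t0(self) -> float:
        """Central thickness measured as the mean over the disc rho <= 0.1,
        matching the measurement convention (area-weighted quadrature)."""
        rho = np.linspace(0.0, 0.1, 201)
        t = self.thickness_profile(rho)
        return float(np.trapezoid(t * rho, rho) * 2.0 / 0.1 ** 2)

    @property
    def analytic_center_thickness(self) -> float:
        """Point thickness at the cell center, T(0) = c0."""
        return float(self.shape_coeffs[0])

    @property
    def analytic_delta_75(self) -> float:
        return float(self.thickness_profile(np.array(0.75)) - self.analytic_t0)

    @property
    def analytic_ov(self) -> float:
        """Optical volume (2 pi dn / lambda) * V in rad um^2."""
        return float(_TWO_PI * self.delta_n / self.wavelength * self.analytic_volume)


@dataclass
class SceneTruth:
    """A composed multi-cell scene together with its ground truth."""

    phase: PhaseMap
    labels: LabelMap
    thickness: dict[int, ThicknessMap]
    features_true: pd.DataFrame
    specs: list[PhantomSpec] = field(default_factory=list)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def discocyte_thickness(
    spec: PhantomSpec,
    shape: tuple[int, int],
    pixel_size: float,
    center_px: tuple[float, float] | None = None,
) -> ThicknessMap:
    """Sample the phantom thickness on a pixel grid.

    ``center_px`` overrides the spec's physical center with explicit (row, col)
    pixel coordinates; by default the spec center (x, y in um) is mapped onto
    the grid with the grid middle as origin.
    """
    ny, nx = shape
    if 2 * spec.radius / pixel_size < 20:
        raise ValidationError(
            "grid does not resolve the cell: need >= 20 px across the diameter"
        )
    if center_px is None:
        cx, cy = spec.center
        center_px = (ny / 2 + cy / pixel_size, nx / 2 + cx / pixel_size)
    yy, xx = np.mgrid[0:ny, 0:nx]
    r = np.hypot(yy - center_px[0], xx - center_px[1]) * pixel_size
    t = spec.thickness_profile(r / spec.radius)
    return ThicknessMap(t, pixel_size=pixel_size)


def phase_forward(
    t: ThicknessMap, delta_n: float, wavelength: float = DEFAULT_WAVELENGTH
) -> PhaseMap:
    """Thin-object forward model phi = 2 pi dn T / lambda (0 outside the cell)."""
    if delta_n <= 0 or wavelength <= 0:
        raise ParameterError("delta_n and wavelength must be positive")
    phase = _TWO_PI * delta_n / wavelength * t.thickness
    return PhaseMap(
        phase, pixel_size=t.pixel_size, provenance="synthetic", wavelength=wavelength
    )


def hologram_forward(
    p: PhaseMap,
    carrier: tuple[float, float] = (0.25, 0.25),
    fringe_contrast: float = 0.9,
    noise_sd: float = 0.0,
    rng_seed: int = 0,
    base_intensity: float = 8000.0,
    wavelength: float | None = None,
) -> Interferogram:
    """Synthesise an off-axis hologram of a phase object.

    I = I0 |1 + m exp(i(phi + 2 pi f.r))|^2 + N(0, noise_sd), clipped at 0 and
    quantised to 16 bits.  ``carrier`` is (f_row, f_col) in cycles/pixel and
    must keep the sideband separable from DC and from its conjugate.
    """
    cmag = float(np.hypot(*carrier))
    if not 0.05 < cmag < 0.45:
        raise ParameterError(
            f"|carrier| = {cmag:.3f} cycles/px outside (0.05, 0.45); the sideband "
            "must be separable from the DC term"
        )
    if not 0 < fringe_contrast <= 1:
        raise ParameterError("fringe_contrast must be in (0, 1]")
    ny, nx = p.phase.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    m = fringe_contrast
    total = p.phase + _TWO_PI * (carrier[0] * yy + carrier[1] * xx)
    intensity = base_intensity * (1.0 + m * m + 2.0 * m * np.cos(total))
    if noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        intensity = intensity + rng.normal(0.0, noise_sd, size=intensity.shape)
    intensity = np.clip(intensity, 0.0, 65535.0)
    intensity = np.round(intensity).astype(np.uint16)
    return Interferogram(
        intensity,
        pixel_size=p.pixel_size,
        wavelength=wavelength if wavelength is not None else (p.wavelength or DEFAULT_WAVELENGTH),
        carrier_hint=carrier,
    )


def sample_population(
    n_per_class: int | tuple[int, int],
    class_params: dict | None = None,
    rng_seed: int = 0,
    wavelength: float = DEFAULT_WAVELENGTH,
) -> list[PhantomSpec]:
    """Draw phantom specs for the two classes from Gaussian parameter priors.

    Specs whose thickness polynomial would go negative (or degenerate radii /
    contrasts) are rejected and resampled.  Returns healthy specs first.
    """
    if isinstance(n_per_class, int):
        counts = {"healthy": n_per_class, "thal": n_per_class}
    else:
        counts = {"healthy": n_per_class[0], "thal": n_per_class[1]}
    params = class_params or DEFAULT_CLASS_PARAMS
    rng = np.random.default_rng(rng_seed)
    specs: list[PhantomSpec] = []
    for cls in ("healthy", "thal"):
        pr = params[cls]
        made = 0
        while made < counts[cls]:
            draw = {k: rng.normal(*pr[k]) for k in ("radius", "c0", "c2", "c4", "delta_n")}
            if draw["radius"] < 1.0 or draw["c0"] < 0.02 or draw["delta_n"] < 0.02:
                continue
            try:
                spec = PhantomSpec(
                    cell_class=cls,
                    radius=draw["radius"],
                    shape_coeffs=(draw["c0"], draw["c2"], draw["c4"]),
                    delta_n=draw["delta_n"],
                    wavelength=wavelength,
                )
            except SpecRejectionError:
                continue
            specs.append(spec)
            made += 1
    return specs


def apply_imaging_effects(
    phase: np.ndarray,
    rng: np.random.Generator,
    speckle_amp_range: tuple[float, float] = (0.02, 0.09),
    speckle_corr_px: float = 1.2,
    defocus_range_px: tuple[float, float] = (0.2, 0.9),
) -> np.ndarray:
    """Add acquisition realism to an ideal phase map.

    Two effects dominate residual structure in reconstructed single-cell
    phase images: coherent (speckle-like) phase noise, modelled as an
    additive Gaussian random field with correlation length
    ``speckle_corr_px`` and a per-acquisition amplitude drawn uniformly from
    ``speckle_amp_range`` (radians); and focus jitter, modelled as a Gaussian
    blur with a per-acquisition sigma from ``defocus_range_px``.  Both vary
    between acquisitions far more than between cell classes, which is what
    makes texture descriptors unreliable on real data.
    """
    from scipy import ndimage as ndi

    blur = rng.uniform(*defocus_range_px)
    amp = rng.uniform(*speckle_amp_range)
    field = ndi.gaussian_filter(rng.normal(size=phase.shape), speckle_corr_px)
    field /= field.std()
    return ndi.gaussian_filter(phase, blur) + amp * field


def render_cell(
    spec: PhantomSpec,
    pixel_size: float = 0.1,
    margin_px: int = 8,
) -> tuple[ThicknessMap, PhaseMap, np.ndarray]:
    """Render a single cell on its own minimal grid, centered.

    Returns (thickness, phase, support mask).
    """
    diam_px = int(np.ceil(2 * spec.radius / pixel_size))
    n = diam_px + 2 * margin_px
    t = discocyte_thickness(spec, (n, n), pixel_size, center_px=(n / 2, n / 2))
    p = phase_forward(t, spec.delta_n, spec.wavelength)
    return t, p, t.mask


def compose_scene(
    specs: list[PhantomSpec],
    shape: tuple[int, int],
    pixel_size: float,
    min_gap_px: float = 5.0,
    rng_seed: int = 0,
    max_tries: int = 1000,
) -> SceneTruth:
    """Place phantoms on a canvas without overlap (rejection sampling).

    Phases superpose (thin-object approximation); labels come from the
    per-cell supports, later cells winning ties by larger local thickness.
    A negative ``min_gap_px`` permits controlled overlap.
    """
    ny, nx = shape
    rng = np.random.default_rng(rng_seed)
    centers: list[tuple[float, float]] = []
    radii_px = [s.radius / pixel_size for s in specs]
    for i, rpx in enumerate(radii_px):
        placed = False
        for _ in range(max_tries):
            cy = rng.uniform(rpx + 2, ny - rpx - 2)
            cx = rng.uniform(rpx + 2, nx - rpx - 2)
            ok = True
            for (oy, ox), orpx in zip(centers, radii_px[: len(centers)]):
                if np.hypot(cy - oy, cx - ox) < rpx + orpx + min_gap_px:
                    ok = False
                    break
            if ok:
                centers.append((cy, cx))
                placed = True
                break
        if not placed:
            raise ValidationError(
                f"could not place cell {i} after {max_tries} tries; use a larger canvas"
            )

    phase = np.zeros(shape)
    labels = np.zeros(shape, dtype=np.int32)
    best_t = np.zeros(shape)
    thickness: dict[int, ThicknessMap] = {}
    rows = []
    wavelength = specs[0].wavelength if specs else DEFAULT_WAVELENGTH
    for i, (spec, c) in enumerate(zip(specs, centers), start=1):
        t = discocyte_thickness(spec, shape, pixel_size, center_px=c)
        p = phase_forward(t, spec.delta_n, spec.wavelength)
        phase += p.phase
        sup = t.mask
        claim = sup & (t.thickness > best_t)
        labels[claim] = i
        best_t = np.maximum(best_t, t.thickness)
        thickness[i] = t
        rows.append(
            {
                "cell_id": i,
                "class": spec.cell_class,
                "ov_true_rad_um2": spec.analytic_ov,
                "volume_true_um3": spec.analytic_volume,
                "t_0_true_um": spec.analytic_t0,
                "delta_75_true_um": spec.analytic_delta_75,
            }
        )
    features_true = pd.DataFrame(
        rows,
        columns=[
            "cell_id",
            "class",
            "ov_true_rad_um2",
            "volume_true_um3",
            "t_0_true_um",
            "delta_75_true_um",
        ],
    )
    return SceneTruth(
        phase=PhaseMap(phase, pixel_size=pixel_size, provenance="synthetic", wavelength=wavelength),
        labels=LabelMap(labels, pixel_size=pixel_size, validate_connectivity=False),
        thickness=thickness,
        features_true=features_true,
        specs=list(specs),
    )
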