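"""Off-axis hologram reconstruction.

An off-axis digital holographic microscope records the interference between
the object beam and a tilted reference beam.  The tilt puts the object
information on a spatial-frequency carrier, so a single camera frame contains
the full complex field: isolating the shifted spectral lobe (the sideband),
re-centering it at DC and inverse transforming yields ``exp(i*phi)`` up to a
constant.  The phase is then known modulo 2*pi and is unwrapped with the
unweighted least-squares method of Ghiglia and Romero, which solves a discrete
Poisson equation under Neumann boundary conditions via the type-II cosine
transform.  A final plane fit over background pixels removes residual tilt
from imperfect carrier centering and reference curvature.

All transforms operate at the native image size; no zero-padding is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import fft as spfft

from .errors import CarrierDetectionError, ParameterError, ValidationError

logger = logging.getLogger(__name__)

_TWO_PI = 2.0 * np.pi

#: radius (in frequency bins) of the disc around DC excluded from carrier search
DC_EXCLUSION_BINS = 4.0
#: minimum ratio of carrier-peak magnitude to median off-DC magnitude
MIN_SPECTRAL_SNR = 3.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Interferogram:
    """Raw off-axis intensity image with optical metadata.

    Parameters
    ----------
    intensity : 2-D array
        Non-negative camera counts; both dimensions must be >= 64.
    pixel_size : float
        Object-space sampling in micrometres per pixel.
    wavelength : float
        Illumination wavelength in micrometres (e.g. 0.532 for a 532-nm laser).
    carrier_hint : (float, float), optional
        Known carrier frequency ``(f_row, f_col)`` in cycles/pixel.
    """

    intensity: np.ndarray
    pixel_size: float
    wavelength: float
    carrier_hint: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValidationError("interferogram must be a 2-D array")
        if min(self.intensity.shape) < 64:
            raise ValidationError(
                f"interferogram dimensions must be >= 64, got {self.intensity.shape}"
            )
        if not np.all(np.isfinite(self.intensity)):
            raise ValidationError("interferogram contains non-finite values")
        if np.any(self.intensity < 0):
            raise ValidationError("interferogram contains negative intensities")
        if self.pixel_size <= 0:
            raise ValidationError("pixel_size must be positive")
        if self.wavelength <= 0:
            raise ValidationError("wavelength must be positive")


@dataclass
class PhaseMap:
    """Unwrapped phase shift in radians on a regular pixel grid."""

    phase: np.ndarray
    pixel_size: float
    provenance: str = "reconstructed"  # reconstructed | synthetic | loaded
    wavelength: float | None = None

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        if self.phase.ndim != 2:
            raise ValidationError("phase must be a 2-D array")
        if not np.all(np.isfinite(self.phase)):
            raise ValidationError("phase contains non-finite values")
        if self.pixel_size <= 0:
            raise ValidationError("pixel_size must be positive")
        if self.provenance not in ("reconstructed", "synthetic", "loaded"):
            raise ValidationError(f"unknown provenance {self.provenance!r}")

    @property
    def pixel_area(self) -> float:
        return self.pixel_size ** 2


@dataclass
class WrappedPhase:
    """Phase known only modulo 2*pi, constrained to the branch (-pi, pi]."""

    phase: np.ndarray
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        if self.phase.ndim != 2:
            raise ValidationError("wrapped phase must be a 2-D array")
        if not np.all(np.isfinite(self.phase)):
            raise ValidationError("wrapped phase contains non-finite values")
        if np.any(self.phase <= -np.pi) or np.any(self.phase > np.pi):
            raise ValidationError("wrapped phase must lie in (-pi, pi]")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap to the principal branch (-pi, pi]."""
    out = np.mod(a + np.pi, _TWO_PI) - np.pi
    # np.mod maps exact multiples to -pi; move them onto the closed end
    out[out <= -np.pi] += _TWO_PI
    return out


def _signed_bin_grids(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    ny, nx = shape
    ky = np.fft.fftfreq(ny) * ny
    kx = np.fft.fftfreq(nx) * nx
    return np.meshgrid(ky, kx, indexing="ij")


def _wrapped_bin_distance(shape, ky0, kx0):
    """Distance in bins on the periodic frequency grid from bin (ky0, kx0)."""
    ny, nx = shape
    iy = np.arange(ny)
    ix = np.arange(nx)
    dy = (iy - ky0 + ny / 2) % ny - ny / 2
    dx = (ix - kx0 + nx / 2) % nx - nx / 2
    return np.hypot(dy[:, None], dx[None, :])


def detect_carrier(holo: Interferogram) -> tuple[float, float]:
    """Locate the off-axis carrier frequency from the hologram spectrum.

    Searches for the dominant spectral peak outside a DC-exclusion disc,
    restricted to the half-plane of positive column frequency (the conjugate
    lobe carries the negated phase).  Returns ``(f_row, f_col)`` in
    cycles/pixel.
    """
    F = np.fft.fft2(holo.intensity)
    mag = np.abs(F)
    ny, nx = mag.shape
    KY, KX = _signed_bin_grids(mag.shape)
    rbin = np.hypot(KY, KX)
    off_dc = rbin > DC_EXCLUSION_BINS
    # positive-fx half-plane; on the fx = 0 line require fy > 0
    half = (KX > 0) | ((KX == 0) & (KY > 0))
    cand = off_dc & half
    med = np.median(mag[off_dc])
    idx = np.argmax(np.where(cand, mag, -1.0))
    iy, ix = np.unravel_index(idx, mag.shape)
    snr = float(mag[iy, ix] / med) if med > 0 else np.inf
    dc_mag = mag[0, 0]
    if snr < MIN_SPECTRAL_SNR or mag[iy, ix] <= 1e-9 * dc_mag:
        raise CarrierDetectionError(
            f"no off-DC carrier peak: spectral SNR {snr:.2f} "
            f"(threshold {MIN_SPECTRAL_SNR}; peak/DC = {mag[iy, ix] / dc_mag:.2e})"
        )
    return (float(KY[iy, ix]) / ny, float(KX[iy, ix]) / nx)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def extract_sideband(
    holo: Interferogram,
    carrier_hint: tuple[float, float] | None = None,
    radius_fraction: float = 0.5,
) -> np.ndarray:
    """Demodulate the off-axis sideband to a complex field at native size.

    The spectral lobe nearest the carrier is selected with a circular bandpass
    of radius ``radius_fraction`` times the carrier distance, shifted to DC
    (integer-bin roll) and inverse transformed.

    Parameters
    ----------
    carrier_hint : (f_row, f_col) in cycles/pixel, optional
        Overrides the hint stored on the hologram; when both are absent the
        carrier is auto-detected from the spectrum.
    radius_fraction : float in (0, 0.5]
        Bandpass radius as a fraction of the carrier distance.
    """
    if not 0 < radius_fraction <= 0.5:
        raise ParameterError(
            f"radius_fraction must be in (0, 0.5], got {radius_fraction}"
        )
    hint = carrier_hint if carrier_hint is not None else holo.carrier_hint
    ny, nx = holo.intensity.shape
    if hint is None:
        fy, fx = detect_carrier(holo)
    else:
        fy, fx = float(hint[0]), float(hint[1])
    # nearest integer bin, then refine to the local spectral maximum
    F = np.fft.fft2(holo.intensity)
    mag = np.abs(F)
    ky0 = int(round(fy * ny)) % ny
    kx0 = int(round(fx * nx)) % nx
    best = (ky0, kx0)
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            cand = ((ky0 + dy) % ny, (kx0 + dx) % nx)
            if mag[cand] > mag[best]:
                best = cand
    ky0, kx0 = best
    # signed bin coordinates for the carrier distance
    sy = ky0 - ny if ky0 > ny // 2 else ky0
    sx = kx0 - nx if kx0 > nx // 2 else kx0
    cdist = float(np.hypot(sy, sx))
    if cdist <= DC_EXCLUSION_BINS:
        raise CarrierDetectionError(
            f"carrier at {cdist:.1f} bins lies inside the DC exclusion disc"
        )
    bandpass = _wrapped_bin_distance(mag.shape, ky0, kx0) <= radius_fraction * cdist
    field = np.fft.ifft2(np.roll(F * bandpass, (-ky0, -kx0), axis=(0, 1)))
    return field


def wrapped_phase(field: np.ndarray, pixel_size: float | None = None) -> WrappedPhase:
    """Argument of the demodulated field, on the principal branch (-pi, pi]."""
    field = np.asarray(field)
    if not np.all(np.isfinite(field)):
        raise ValidationError("field contains non-finite values")
    if not np.any(field):
        raise ValidationError("field is identically zero")
    zero = field == 0
    nzero = int(zero.sum())
    if nzero:
        logger.warning("wrapped_phase: %d zero-magnitude pixels set to 0", nzero)
    phase = np.angle(field)
    phase[zero] = 0.0
    phase[phase <= -np.pi] += _TWO_PI
    return WrappedPhase(phase, pixel_size=pixel_size)


def unwrap_dct(w: WrappedPhase, pixel_size: float | None = None) -> PhaseMap:
    """Unweighted least-squares phase unwrapping (Ghiglia-Romero scheme).

    Wrapped first differences are assembled into a discrete Laplacian and the
    Poisson equation is solved under Neumann boundary conditions with the
    type-II discrete cosine transform.  The solution is defined up to an
    additive constant, fixed here so the minimum over the frame border is 0.
    The result is exact (up to that constant) whenever the true phase is
    residue-free, i.e. its per-pixel gradient magnitude stays below pi.
    """
    psi = np.asarray(w.phase, dtype=float)
    if not np.all(np.isfinite(psi)):
        raise ValidationError("wrapped phase contains non-finite values")
    ny, nx = psi.shape
    if ny < 4 or nx < 4:
        raise ValidationError("both dimensions must be >= 4 for unwrapping")

    dy = wrap_angle(np.diff(psi, axis=0))
    dx = wrap_angle(np.diff(psi, axis=1))
    rho = np.zeros_like(psi)
    rho[:-1, :] += dy
    rho[1:, :] -= dy
    rho[:, :-1] += dx
    rho[:, 1:] -= dx
    # rho is the divergence of the wrapped gradient field = Neumann Laplacian RHS

    D = spfft.dctn(rho, type=2, norm="ortho")
    denom = 2.0 * (
        np.cos(np.pi * np.arange(ny) / ny)[:, None]
        + np.cos(np.pi * np.arange(nx) / nx)[None, :]
        - 2.0
    )
    denom[0, 0] = 1.0
    D = D / denom
    D[0, 0] = 0.0
    phi = spfft.idctn(D, type=2, norm="ortho")

    border = np.concatenate([phi[0, :], phi[-1, :], phi[:, 0], phi[:, -1]])
    phi = phi - border.min()
    ps = pixel_size if pixel_size is not None else (w.pixel_size or 1.0)
    return PhaseMap(phi, pixel_size=ps, provenance="reconstructed")


def flatten_background(
    p: PhaseMap, cell_mask: np.ndarray | None = None
) -> PhaseMap:
    """Remove residual tilt by subtracting a plane fitted to background pixels.

    Background is the complement of ``cell_mask`` when given, otherwise the
    25% lowest-phase pixels.  After the plane subtraction, the background
    median is shifted to exactly zero.
    """
    phase = p.phase
    if cell_mask is not None:
        cell_mask = np.asarray(cell_mask, dtype=bool)
        if cell_mask.shape != phase.shape:
            raise ValidationError("cell_mask shape does not match phase")
        bg = ~cell_mask
        if bg.sum() < 0.1 * phase.size:
            raise ValidationError(
                "fewer than 10% background pixels; pass a tighter cell mask"
            )
    else:
        bg = phase <= np.quantile(phase, 0.25)
    if not bg.any():
        raise ValidationError(
            "background region is empty; pass an explicit cell mask"
        )

    yy, xx = np.mgrid[0 : phase.shape[0], 0 : phase.shape[1]]
    A = np.column_stack(
        [np.ones(int(bg.sum())), xx[bg].astype(float), yy[bg].astype(float)]
    )
    coef, *_ = np.linalg.lstsq(A, phase[bg], rcond=None)
    plane = coef[0] + coef[1] * xx + coef[2] * yy
    out = phase - plane
    out = out - np.median(out[bg])
    return PhaseMap(
        out, pixel_size=p.pixel_size, provenance=p.provenance, wavelength=p.wavelength
    )


def reconstruct_phase(
    holo: Interferogram,
    carrier_hint: tuple[float, float] | None = None,
    radius_fraction: float = 0.5,
    cell_mask: np.ndarray | None = None,
) -> PhaseMap:
    """Full reconstruction chain: sideband -> wrap -> unwrap -> flatten."""
    field = extract_sideband(holo, carrier_hint=carrier_hint, radius_fraction=radius_fraction)
    w = wrapped_phase(field, pixel_size=holo.pixel_size)
    p = unwrap_dct(w)
    p.wavelength = holo.wavelength
    return flatten_background(p, cell_mask=cell_mask)
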