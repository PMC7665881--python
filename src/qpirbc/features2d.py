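"""The 15 single-cell features used by the classifier.

Three groups of five, computed per segmented cell on the phase map:

* phase-shift statistics — optical volume (the phase integral over the cell,
  in rad um^2), mean, 5th and 95th percentile, and population SD of the
  in-mask phase;
* 2-D morphology — projected area, perimeter (marching-squares contour
  length), major/minor axis of the moment-matched ellipse, eccentricity;
* texture — gray-level co-occurrence matrix (GLCM) contrast, dissimilarity,
  homogeneity, energy and angular second moment, averaged over the four
  standard offsets, with the co-occurrence counted only for pixel pairs that
  both fall inside the cell mask.

Optical volume carries the pixel area so it is invariant to magnification;
divide by ``pixel_size**2`` to recover the plain phase sum.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import find_contours, label as sk_label, regionprops

from .errors import ValidationError
from .holography import PhaseMap

logger = logging.getLogger(__name__)

#: the 15 feature columns, in canonical CSV order
FEATURE_COLUMNS = [
    "ov_rad_um2",
    "phase_mean_rad",
    "phase_p5_rad",
    "phase_p95_rad",
    "phase_sd_rad",
    "area_um2",
    "perimeter_um",
    "major_axis_um",
    "minor_axis_um",
    "eccentricity",
    "glcm_contrast",
    "glcm_dissimilarity",
    "glcm_homogeneity",
    "glcm_energy",
    "glcm_asm",
]

PHASE_FEATURES = FEATURE_COLUMNS[:5]
MORPHOLOGY_FEATURES = FEATURE_COLUMNS[5:10]
TEXTURE_FEATURES = FEATURE_COLUMNS[10:]

#: masks below this pixel count are flagged degenerate
DEGENERATE_MASK_PIXELS = 20

#: GLCM pixel offsets (row, col) for angles 0, 45, 90, 135 degrees at unit distance
_GLCM_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def phase_statistics(
    p: PhaseMap, mask: np.ndarray
) -> tuple[float, float, float, float, float]:
    """(optical volume, mean, p5, p95, SD) of the in-mask phase.

    Optical volume is the in-mask phase sum times the pixel area (rad um^2);
    percentiles use linear interpolation between order statistics; the SD is
    the population SD (a per-cell descriptor, not an estimator).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != p.phase.shape:
        raise ValidationError("mask shape does not match phase")
    if not mask.any():
        raise ValidationError("mask is empty")
    if mask.sum() < DEGENERATE_MASK_PIXELS:
        logger.warning("phase_statistics: degenerate mask of %d px", int(mask.sum()))
    vals = p.phase[mask]
    ov = float(vals.sum() * p.pixel_area)
    p5, p95 = np.percentile(vals, [5.0, 95.0])
    return ov, float(vals.mean()), float(p5), float(p95), float(vals.std())


def morphology2d(
    mask: np.ndarray, pixel_size: float
) -> tuple[float, float, float, float, float]:
    """(area, perimeter, major axis, minor axis, eccentricity) of a mask.

    Area is the pixel count times the pixel area.  Perimeter is the
    marching-squares contour length (all contours, so an annular mask counts
    its inner rim).  Axis lengths come from the ellipse with identical
    normalised second central moments (4 * sqrt(eigenvalue)); eccentricity is
    sqrt(1 - (minor/major)^2).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValidationError("mask is empty")
    lab = sk_label(mask, connectivity=2)
    ncomp = int(lab.max())
    if ncomp != 1:
        raise ValidationError(f"mask has {ncomp} connected components, expected 1")
    npx = int(mask.sum())
    if npx < DEGENERATE_MASK_PIXELS:
        logger.warning("morphology2d: degenerate mask of %d px", npx)
    area = npx * pixel_size ** 2

    # marching-squares contour length; a light Gaussian pre-smooth (sigma = 1 px)
    # removes the digitisation bias of contouring a hard binary edge
    padded = ndi.gaussian_filter(np.pad(mask.astype(float), 2), 1.0)
    perimeter = 0.0
    for contour in find_contours(padded, 0.5):
        perimeter += float(np.sum(np.hypot(*np.diff(contour, axis=0).T)))
    perimeter *= pixel_size

    props = regionprops(mask.astype(np.uint8))[0]
    major = float(props.axis_major_length) * pixel_size
    minor = float(props.axis_minor_length) * pixel_size
    if major > 0:
        ecc = float(np.sqrt(max(0.0, 1.0 - (minor / major) ** 2)))
    else:
        ecc = 0.0
    return area, perimeter, major, minor, ecc


def glcm_features(
    p: PhaseMap,
    mask: np.ndarray,
    levels: int = 32,
    distance_px: int = 1,
    angles: tuple[int, ...] = (0, 45, 90, 135),
) -> tuple[float, float, float, float, float]:
    """(contrast, dissimilarity, homogeneity, energy, ASM) from the masked GLCM.

    The in-mask phase is linearly quantised to ``levels`` gray levels between
    the in-mask min and max.  Co-occurrences are counted only for pixel pairs
    both inside the mask, symmetrised and normalised per angle; the five
    Haralick statistics are averaged over the angle set.  A constant in-mask
    phase yields (0, 0, 1, 1, 1).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 2:
        raise ValidationError("mask must contain at least 2 pixels")
    if levels < 2:
        raise ValidationError("levels must be >= 2")
    vals = p.phase[mask]
    vmin, vmax = float(vals.min()), float(vals.max())
    if vmax == vmin:
        logger.warning("glcm_features: constant in-mask phase; returning degenerate texture")
        return 0.0, 0.0, 1.0, 1.0, 1.0
    quant = np.zeros(p.phase.shape, dtype=np.int64)
    q = np.floor((p.phase[mask] - vmin) / (vmax - vmin) * levels).astype(np.int64)
    quant[mask] = np.clip(q, 0, levels - 1)

    feats = np.zeros(5)
    n_used = 0
    lv = np.arange(levels)
    di = lv[:, None] - lv[None, :]
    for ang in angles:
        if ang % 180 not in _GLCM_OFFSETS:
            raise ValidationError(f"unsupported GLCM angle {ang}")
        dr, dc = (v * distance_px for v in _GLCM_OFFSETS[ang % 180])
        # pair (r, c) -> (r + dr, c + dc); both must be in frame and in mask
        r0, c0 = max(0, -dr), max(0, -dc)
        r1 = mask.shape[0] - max(0, dr)
        c1 = mask.shape[1] - max(0, dc)
        a = mask[r0:r1, c0:c1]
        b = mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        valid = a & b
        if not valid.any():
            continue
        qi = quant[r0:r1, c0:c1][valid]
        qj = quant[r0 + dr : r1 + dr, c0 + dc : c1 + dc][valid]
        counts = np.bincount(qi * levels + qj, minlength=levels * levels).reshape(
            levels, levels
        ).astype(float)
        counts = counts + counts.T  # symmetrise
        pmat = counts / counts.sum()
        contrast = float((pmat * di ** 2).sum())
        dissim = float((pmat * np.abs(di)).sum())
        homog = float((pmat / (1.0 + di ** 2)).sum())
        asm = float((pmat ** 2).sum())
        feats += np.array([contrast, dissim, homog, 0.0, asm])
        n_used += 1
    if n_used == 0:
        raise ValidationError("no valid co-occurring pixel pairs for any angle")
    feats /= n_used
    feats[3] = np.sqrt(feats[4])  # energy = sqrt(angle-averaged ASM), exactly
    return tuple(float(v) for v in feats)


def single_cell_features(
    p: PhaseMap,
    mask: np.ndarray,
    glcm_levels: int = 32,
) -> dict[str, float]:
    """All 15 features of one cell as a column-named dict."""
    ov, mean, p5, p95, sd = phase_statistics(p, mask)
    area, perim, major, minor, ecc = morphology2d(mask, p.pixel_size)
    contrast, dissim, homog, energy, asm = glcm_features(p, mask, levels=glcm_levels)
    return {
        "ov_rad_um2": ov,
        "phase_mean_rad": mean,
        "phase_p5_rad": p5,
        "phase_p95_rad": p95,
        "phase_sd_rad": sd,
        "area_um2": area,
        "perimeter_um": perim,
        "major_axis_um": major,
        "minor_axis_um": minor,
        "eccentricity": ecc,
        "glcm_contrast": contrast,
        "glcm_dissimilarity": dissim,
        "glcm_homogeneity": homog,
        "glcm_energy": energy,
        "glcm_asm": asm,
    }


def extract_features(
    p: PhaseMap,
    labels,
    cell_classes: dict[int, str] | None = None,
    glcm_levels: int = 32,
    exclude_border: bool = True,
) -> pd.DataFrame:
    """One row of 15 features per instance in a label map.

    Border-touching cells are excluded (their features would be truncated);
    the excluded count is logged.  ``cell_classes`` maps instance label to a
    class string for the ``class`` column (empty string when unknown).
    """
    lab = labels.labels
    if lab.shape != p.phase.shape:
        raise ValidationError("labels shape does not match phase")
    border = np.zeros(lab.shape, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    rows = []
    excluded = 0
    for i in range(1, int(lab.max()) + 1):
        mask = lab == i
        if not mask.any():
            continue
        if exclude_border and np.any(mask & border):
            excluded += 1
            continue
        row: dict[str, object] = {
            "cell_id": i,
            "class": cell_classes.get(i, "") if cell_classes else "",
        }
        row.update(single_cell_features(p, mask, glcm_levels=glcm_levels))
        rows.append(row)
    if excluded:
        logger.info("extract_features: excluded %d border-touching cells", excluded)
    return pd.DataFrame(rows, columns=["cell_id", "class"] + FEATURE_COLUMNS)
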