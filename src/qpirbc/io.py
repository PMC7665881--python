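"""TIFF input/output with optical metadata.

Single-channel TIFFs only.  Interferograms are 8/16-bit integer,
reconstructed phase and thickness maps 32-bit float, label maps 16-bit
unsigned, boolean masks 8-bit (0/255).  Pixel size and wavelength travel in
the ImageDescription tag as a small JSON object.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .errors import ValidationError
from .holography import Interferogram, PhaseMap
from .morphology3d import ThicknessMap
from .segmentation import LabelMap


def _metadata(path: str | Path) -> dict:
    with tifffile.TiffFile(path) as tf:
        desc = tf.pages[0].description or ""
    try:
        meta = json.loads(desc)
    except (json.JSONDecodeError, TypeError):
        meta = {}
    return meta if isinstance(meta, dict) else {}


def write_interferogram(path: str | Path, holo: Interferogram) -> None:
    meta = {
        "pixel_size_um": holo.pixel_size,
        "wavelength_um": holo.wavelength,
        "kind": "interferogram",
    }
    if holo.carrier_hint is not None:
        meta["carrier_cycles_per_px"] = list(holo.carrier_hint)
    data = holo.intensity
    if data.max() > 65535:
        raise ValidationError("interferogram counts exceed 16-bit range")
    tifffile.imwrite(path, data.astype(np.uint16), description=json.dumps(meta))


def read_interferogram(
    path: str | Path,
    pixel_size: float | None = None,
    wavelength: float | None = None,
) -> Interferogram:
    meta = _metadata(path)
    data = tifffile.imread(path)
    ps = pixel_size if pixel_size is not None else meta.get("pixel_size_um")
    wl = wavelength if wavelength is not None else meta.get("wavelength_um")
    if ps is None or wl is None:
        raise ValidationError(
            f"{path}: pixel size / wavelength neither in metadata nor given"
        )
    hint = meta.get("carrier_cycles_per_px")
    return Interferogram(
        data, pixel_size=float(ps), wavelength=float(wl),
        carrier_hint=tuple(hint) if hint else None,
    )


def write_phase(path: str | Path, p: PhaseMap) -> None:
    meta = {
        "pixel_size_um": p.pixel_size,
        "kind": "phase",
        "provenance": p.provenance,
    }
    if p.wavelength is not None:
        meta["wavelength_um"] = p.wavelength
    tifffile.imwrite(path, p.phase.astype(np.float32), description=json.dumps(meta))


def read_phase(path: str | Path, pixel_size: float | None = None) -> PhaseMap:
    meta = _metadata(path)
    data = tifffile.imread(path).astype(float)
    ps = pixel_size if pixel_size is not None else meta.get("pixel_size_um")
    if ps is None:
        raise ValidationError(f"{path}: pixel size neither in metadata nor given")
    wl = meta.get("wavelength_um")
    return PhaseMap(
        data, pixel_size=float(ps), provenance="loaded",
        wavelength=float(wl) if wl is not None else None,
    )


def write_labels(path: str | Path, labels: LabelMap) -> None:
    if labels.labels.max() > 65535:
        raise ValidationError("too many instances for a 16-bit label TIFF")
    meta = {"pixel_size_um": labels.pixel_size, "kind": "labels"}
    tifffile.imwrite(
        path, labels.labels.astype(np.uint16), description=json.dumps(meta)
    )


def read_labels(path: str | Path, pixel_size: float | None = None) -> LabelMap:
    meta = _metadata(path)
    data = tifffile.imread(path).astype(np.int32)
    ps = pixel_size if pixel_size is not None else meta.get("pixel_size_um")
    if ps is None:
        raise ValidationError(f"{path}: pixel size neither in metadata nor given")
    return LabelMap(data, pixel_size=float(ps), validate_connectivity=False)


def write_thickness(path: str | Path, t: ThicknessMap) -> None:
    meta = {"pixel_size_um": t.pixel_size, "kind": "thickness"}
    tifffile.imwrite(path, t.thickness.astype(np.float32), description=json.dumps(meta))


def read_thickness(path: str | Path, pixel_size: float | None = None) -> ThicknessMap:
    meta = _metadata(path)
    data = tifffile.imread(path).astype(float)
    ps = pixel_size if pixel_size is not None else meta.get("pixel_size_um")
    if ps is None:
        raise ValidationError(f"{path}: pixel size neither in metadata nor given")
    return ThicknessMap(np.clip(data, 0.0, None), pixel_size=float(ps))


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    tifffile.imwrite(path, (np.asarray(mask, bool) * 255).astype(np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(path) > 0
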