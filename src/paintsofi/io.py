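"""File formats: multipage-TIFF movies with plain-text metadata sidecars,
cumulant/reconstruction TIFFs, localization CSVs and JSON-ish QC reports.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import tifffile

from .blink_sim import MovieStack, OpticsCamera
from .cumulants import CumulantImage

__all__ = [
    "write_movie",
    "read_movie",
    "sidecar_path",
    "write_cumulant_image",
    "read_cumulant_image",
    "write_report",
    "read_report",
]

_SIDECAR_FIELDS = {
    "pixel_size_nm": ("pixel_size", float),
    "psf_fwhm_nm": ("psf_fwhm", float),
    "frame_time_s": ("frame_time", float),
    "n_frames": ("n_frames", int),
    "photons_per_bound_imager_per_s": ("photons_per_bound_imager_per_s", float),
    "background_photons_per_pixel_per_frame": ("background_photons_per_pixel_per_frame", float),
    "illumination_mode": ("illumination_mode", str),
    "camera_gain": ("camera_gain", float),
    "camera_offset": ("camera_offset", float),
    "read_noise_sd": ("read_noise_sd", float),
    "seed": ("seed", int),
}


def sidecar_path(path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".meta.txt")


def write_movie(stack: MovieStack, path) -> Path:
    """Write a movie as 16-bit unsigned multipage TIFF + key-value sidecar."""
    path = Path(path)
    frames = np.asarray(stack.frames)
    if frames.max() > 65535:
        warnings.warn("counts exceed 16-bit range; clipping for TIFF output")
    data = np.clip(np.rint(frames), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")
    with open(sidecar_path(path), "w") as fh:
        for key, (attr, _typ) in _SIDECAR_FIELDS.items():
            fh.write(f"{key} = {getattr(stack.meta, attr)}\n")
    return path


def read_movie(path) -> MovieStack:
    """Read a multipage TIFF movie; the sidecar restores acquisition metadata.

    A missing sidecar yields default metadata with a warning.  Malformed
    pages raise with the page index.
    """
    path = Path(path)
    try:
        frames = tifffile.imread(path)
    except Exception as exc:
        raise ValueError(f"malformed TIFF {path}: {exc}") from exc
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise ValueError(f"malformed TIFF {path}: expected T x H x W, got {frames.shape}")

    meta_kwargs: dict = {}
    sp = sidecar_path(path)
    if sp.exists():
        for lineno, line in enumerate(sp.read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"malformed sidecar {sp} line {lineno}: {line!r}")
            key, _, val = line.partition("=")
            key = key.strip()
            if key in _SIDECAR_FIELDS:
                attr, typ = _SIDECAR_FIELDS[key]
                meta_kwargs[attr] = typ(val.strip())
    else:
        warnings.warn(f"no metadata sidecar next to {path}; using defaults")
    meta_kwargs["n_frames"] = frames.shape[0]
    meta = OpticsCamera(**meta_kwargs)
    return MovieStack(frames.astype(float), meta=meta)


def write_cumulant_image(cimg: CumulantImage, path) -> Path:
    """32-bit float TIFF + sidecar (order, oversampling, lattice convention)."""
    path = Path(path)
    tifffile.imwrite(path, cimg.values.astype(np.float32), photometric="minisblack")
    side = {
        "order": cimg.order,
        "oversampling": cimg.oversampling,
        "pixel_size_nm": cimg.pixel_size_nm,
        "flattened": cimg.flattened,
        "lattice_origin": "fine-lattice point (0,0) coincides with camera pixel center (0,0)",
        "provenance": cimg.provenance,
    }
    with open(sidecar_path(path), "w") as fh:
        json.dump(side, fh, indent=2, default=str)
    return path


def read_cumulant_image(path) -> CumulantImage:
    path = Path(path)
    values = tifffile.imread(path).astype(float)
    side = json.loads(sidecar_path(path).read_text())
    return CumulantImage(
        order=int(side["order"]),
        values=values,
        oversampling=int(side["oversampling"]),
        pixel_size_nm=side.get("pixel_size_nm"),
        flattened=bool(side.get("flattened", False)),
        provenance=side.get("provenance", {}),
    )


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_report(results: dict, path) -> Path:
    """Write a QC report as JSON plus a human-readable text rendering."""
    path = Path(path)
    payload = _to_jsonable(results)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
    txt = path.with_suffix(".txt")
    with open(txt, "w") as fh:
        fh.write("paintsofi QC report\n===================\n")

        def emit(d, indent=0):
            for k, v in d.items():
                if isinstance(v, dict):
                    fh.write("  " * indent + f"{k}:\n")
                    emit(v, indent + 1)
                else:
                    fh.write("  " * indent + f"{k}: {v}\n")

        emit(payload)
    return path


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())
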