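"""File readers and writers plus strip reconstruction.

Accepted inputs are single-frame DICOM secondary captures (any vendor) and
plain PNG/TIFF grayscale strips; everything is normalized to an 8-bit
grayscale matrix with row 0 at the top.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import TdiError

# ITU-R BT.601 luma weights; they sum to 1 so pure grays are preserved.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class DopplerStrip:
    """A 2-D grayscale Doppler strip: rows = velocity axis, columns = time."""

    pixels: np.ndarray              # uint8
    source: str = "synthetic"       # "dicom" | "png_strip" | "synthetic"
    meta: dict = field(default_factory=dict)

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]


def _to_uint8_gray(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[..., :3]
        arr = np.rint(arr.astype(float) @ _LUMA)
    if arr.dtype != np.uint8:
        arr = arr.astype(float)
        lo, hi = arr.min(), arr.max()
        arr = np.zeros_like(arr) if hi == lo else (arr - lo) / (hi - lo) * 255.0
        arr = np.rint(arr)
    return np.clip(arr, 0, 255).astype(np.uint8)


def _read_dicom(path: Path) -> DopplerStrip:
    import pydicom

    ds = pydicom.dcmread(path)
    arr = ds.pixel_array
    photometric = str(getattr(ds, "PhotometricInterpretation", "MONOCHROME2"))
    if arr.ndim == 3 and arr.shape[-1] == 3:
        arr = np.rint(arr.astype(float) @ _LUMA)
    arr = _to_uint8_gray(arr)
    if photometric == "MONOCHROME1":           # white-is-zero convention
        arr = (255 - arr).astype(np.uint8)
    meta = {"photometric": photometric,
            "modality": str(getattr(ds, "Modality", "")),
            "path": str(path)}
    return DopplerStrip(pixels=arr, source="dicom", meta=meta)


def read_image(path: str | Path, format_hint: str | None = None) -> DopplerStrip:
    """Read a frame or strip as 8-bit grayscale.

    DICOM MONOCHROME1/2 and RGB photometric interpretations are handled
    (RGB via BT.601 luma; MONOCHROME1 inverted); non-8-bit pixel data is
    min-max scaled. PNG/TIFF are read as-is (RGB collapsed to luma).
    """
    path = Path(path)
    if not path.exists():
        raise TdiError(f"no such file: {path}")
    kind = (format_hint or path.suffix.lstrip(".")).lower()
    try:
        if kind in ("dcm", "dicom"):
            return _read_dicom(path)
        arr = iio.imread(path)
    except TdiError:
        raise
    except Exception as exc:
        raise TdiError(f"cannot read {path}: {exc}") from exc
    return DopplerStrip(pixels=_to_uint8_gray(arr), source="png_strip",
                        meta={"path": str(path)})


def write_image(pixels: np.ndarray, path: str | Path) -> None:
    iio.imwrite(Path(path), np.asarray(pixels, dtype=np.uint8))


def reconstruct_strip(frames: list[DopplerStrip | np.ndarray],
                      overlap_px: int | list[int] = 0) -> DopplerStrip:
    """Concatenate time-ordered frames into one long strip.

    ``overlap_px`` gives the known overlap between each consecutive pair
    (a scalar applies to every pair); overlapping columns are dropped from
    the trailing frame. Overlaps are supplied, not estimated.
    """
    if not frames:
        raise TdiError("no frames to reconstruct")
    arrays = [f.pixels if isinstance(f, DopplerStrip) else np.asarray(f) for f in frames]
    heights = {a.shape[0] for a in arrays}
    if len(heights) != 1:
        raise TdiError("frames have mismatched heights")
    n_pairs = len(arrays) - 1
    overlaps = [overlap_px] * n_pairs if np.isscalar(overlap_px) else list(overlap_px)
    if len(overlaps) != n_pairs:
        raise TdiError("need one overlap per consecutive frame pair")
    parts = [arrays[0]]
    for arr, ov in zip(arrays[1:], overlaps):
        if ov < 0 or ov >= arr.shape[1]:
            raise TdiError("overlap out of range")
        parts.append(arr[:, ov:])
    return DopplerStrip(pixels=np.concatenate(parts, axis=1),
                        source="png_strip", meta={"reconstructed_from": len(arrays)})
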