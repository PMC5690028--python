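"""Image readers and writers.

Supported formats, chosen by extension (or an explicit ``fmt`` hint):

- NIfTI ``.nii`` / ``.nii.gz`` (nibabel) — float data round-trips losslessly
- TIFF ``.tif`` / ``.tiff`` (tifffile) — float32, or 8/16-bit integer
- PNG ``.png`` (imageio) — 8/16-bit; float data is quantized to 16-bit with
  an affine transform recorded in a JSON sidecar
- raw float ``.raw`` with a JSON sidecar giving ``shape`` and ``dtype``
- DICOM ``.dcm`` (read-only; requires the optional ``pydicom`` dependency);
  rescale slope/intercept are applied

3-D volumes are handled slice-by-slice via :func:`read_slices`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from emmcup.core import ImageGrid, auto_mask
from emmcup.errors import FormatError

__all__ = ["read_image", "read_slices", "write_image", "resolve_mask"]

_NIFTI = (".nii", ".nii.gz")
_TIFF = (".tif", ".tiff")


def _format_of(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    name = path.name.lower()
    if name.endswith(_NIFTI):
        return "nifti"
    if name.endswith(_TIFF):
        return "tiff"
    if name.endswith(".png"):
        return "png"
    if name.endswith(".dcm"):
        return "dicom"
    if name.endswith(".raw"):
        return "raw"
    raise FormatError(f"cannot infer image format of {path}")


def _load_array(path: Path, fmt: str) -> np.ndarray:
    if fmt == "nifti":
        import nibabel as nib

        img = nib.load(str(path))
        return np.asarray(img.dataobj, dtype=np.float64)
    if fmt == "tiff":
        import tifffile

        return np.asarray(tifffile.imread(str(path)), dtype=np.float64)
    if fmt == "png":
        import imageio.v3 as iio

        data = np.asarray(iio.imread(str(path)), dtype=np.float64)
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            if "slope" in meta:
                data = data * meta["slope"] + meta.get("intercept", 0.0)
        return data
    if fmt == "dicom":
        try:
            import pydicom
        except ImportError as exc:  # pragma: no cover - env dependent
            raise FormatError(
                f"{path}: DICOM support needs the optional pydicom dependency "
                "(pip install emmcup[dicom])"
            ) from exc
        ds = pydicom.dcmread(str(path))
        data = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        return data * slope + intercept
    if fmt == "raw":
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise FormatError(f"{path}: raw format needs a {sidecar.name} sidecar")
        meta = json.loads(sidecar.read_text())
        data = np.fromfile(str(path), dtype=np.dtype(meta["dtype"]))
        return data.reshape(meta["shape"]).astype(np.float64)
    raise FormatError(f"unknown format {fmt!r}")


def read_image(path, fmt: str | None = None) -> ImageGrid:
    """Read a single 2-D slice as an :class:`ImageGrid` with a full mask.

    Apply :func:`resolve_mask` afterwards to restrict to the object support.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"input file not found: {path}")
    fmt = _format_of(path, fmt)
    try:
        data = _load_array(path, fmt)
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"{path}: failed to read as {fmt}: {exc}") from exc
    data = np.squeeze(data)
    if data.ndim != 2:
        raise FormatError(
            f"{path}: expected a 2-D slice, got shape {data.shape}; "
            "use read_slices for volumes"
        )
    return ImageGrid.from_array(data)


def read_slices(path, fmt: str | None = None):
    """Yield ``(index, 2-D array)`` for a 2-D image or a 3-D stack.

    NIfTI volumes are iterated along the last axis; TIFF stacks along the
    first (page) axis.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"input file not found: {path}")
    fmt = _format_of(path, fmt)
    data = _load_array(path, fmt)
    data = np.squeeze(data)
    if data.ndim == 2:
        yield 0, data
    elif data.ndim == 3:
        axis = 2 if fmt == "nifti" else 0
        for k in range(data.shape[axis]):
            yield k, np.take(data, k, axis=axis)
    else:
        raise FormatError(f"{path}: unsupported dimensionality {data.ndim}")


def write_image(field: np.ndarray, path, fmt: str | None = None) -> None:
    """Write a 2-D (or 3-D) float field.

    NIfTI, float TIFF, and raw are lossless for float data.  PNG output is
    quantized to 16-bit; slope/intercept for de-quantization are stored in a
    JSON sidecar next to the file.
    """
    path = Path(path)
    fmt = _format_of(path, fmt)
    field = np.asarray(field, dtype=np.float64)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "nifti":
        import nibabel as nib

        img = nib.Nifti1Image(field, affine=np.eye(4))
        nib.save(img, str(path))
    elif fmt == "tiff":
        import tifffile

        tifffile.imwrite(str(path), field.astype(np.float64))
    elif fmt == "png":
        import imageio.v3 as iio

        lo, hi = float(field.min()), float(field.max())
        span = hi - lo if hi > lo else 1.0
        quantized = np.round((field - lo) / span * 65535.0).astype(np.uint16)
        iio.imwrite(str(path), quantized)
        path.with_suffix(".json").write_text(
            json.dumps({"slope": span / 65535.0, "intercept": lo}, indent=2)
        )
    elif fmt == "raw":
        field.tofile(str(path))
        path.with_suffix(".json").write_text(
            json.dumps({"shape": list(field.shape), "dtype": "float64"}, indent=2)
        )
    elif fmt == "dicom":
        raise FormatError("DICOM writing is not supported")
    else:
        raise FormatError(f"unknown format {fmt!r}")


def resolve_mask(grid: ImageGrid, mask_option: str) -> ImageGrid:
    """Apply a mask policy: ``auto`` (Otsu), ``none``, or a mask file path."""
    if mask_option == "none":
        return grid
    if mask_option == "auto":
        mask = auto_mask(grid.intensities)
    else:
        mask_grid = read_image(mask_option)
        if mask_grid.shape != grid.shape:
            raise FormatError(
                f"mask shape {mask_grid.shape} differs from image {grid.shape}"
            )
        mask = mask_grid.intensities > 0
    return ImageGrid.from_array(grid.intensities, mask=mask)
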