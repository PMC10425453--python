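"""Reading and writing volumes, images and quality reports.

Volumes are stored as multi-page TIFF stacks — one 2-D frame per time
sample, row = y and column = x within a frame — beside a JSON sidecar
holding ``nx, ny, nt, dt, scale, provenance``.  Storage is 32-bit float, the
working precision of a :class:`~samdenoise.volume.Volume`, so a round trip
is lossless.  Reports are plain CSV.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, ParameterError
from .volume import Volume

__all__ = [
    "write_volume",
    "read_volume",
    "write_image",
    "write_report",
    "read_report",
    "sidecar_path",
]

log = logging.getLogger(__name__)

_SIDE_SUFFIX = ".json"


def sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix(_SIDE_SUFFIX)


def write_volume(v: Volume, path: str | Path) -> Path:
    """Write a volume as a multi-page float32 TIFF plus a JSON sidecar.

    Page ``t`` holds frame ``(y, x)`` of time sample ``t``.
    """
    path = Path(path)
    pages = np.ascontiguousarray(v.data.transpose(2, 1, 0))  # (t, y, x)
    tifffile.imwrite(path, pages, photometric="minisblack")
    meta = {
        "nx": v.nx,
        "ny": v.ny,
        "nt": v.nt,
        "dt": v.dt,
        "scale": 1.0,
        "provenance": v.provenance,
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return path


def read_volume(path: str | Path) -> Volume:
    """Read a volume written by :func:`write_volume`, validating the sidecar."""
    path = Path(path)
    side = sidecar_path(path)
    if not side.exists():
        raise FormatError(f"missing sidecar metadata file {side}")
    try:
        meta = json.loads(side.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"unreadable sidecar {side}: {exc}") from exc
    for key in ("nx", "ny", "nt"):
        if key not in meta:
            raise FormatError(f"sidecar {side} lacks required key {key!r}")
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None, ...]
    if pages.ndim != 3:
        raise FormatError(f"{path} is not a stack of 2-D frames")
    nt, ny, nx = pages.shape
    if nt != meta["nt"]:
        raise FormatError(
            f"{path} has {nt} pages but sidecar declares nt={meta['nt']}"
        )
    if (nx, ny) != (meta["nx"], meta["ny"]):
        raise FormatError(
            f"{path} frames are {nx}x{ny} but sidecar declares "
            f"{meta['nx']}x{meta['ny']}"
        )
    data = np.ascontiguousarray(pages.transpose(2, 1, 0))
    return Volume(
        data,
        dt=float(meta.get("dt", 1.0)),
        provenance=str(meta.get("provenance", str(path))),
        meta={k: v for k, v in meta.items()
              if k not in ("nx", "ny", "nt", "dt", "provenance")},
    )


def write_image(img: np.ndarray, path: str | Path, bitdepth: str = "float") -> Path:
    """Write a 2-D grayscale image as TIFF or PNG.

    ``float`` stores the raw float32 values (TIFF only).  Integer modes
    (``"8"``/``"16"``) min-max scale to the full range and record the scaling
    constants in a JSON sidecar; a constant image is written as mid-gray
    with a logged warning.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ParameterError("write_image expects a 2-D array")
    if not np.all(np.isfinite(img)):
        raise ParameterError("image contains non-finite values")
    path = Path(path)
    bitdepth = str(bitdepth)
    if bitdepth == "float":
        if path.suffix.lower() not in (".tif", ".tiff"):
            raise ParameterError("float images must be written as TIFF")
        tifffile.imwrite(path, img.T.astype(np.float32),
                         photometric="minisblack")
        meta = {"bitdepth": "float", "scale_min": None, "scale_max": None}
    elif bitdepth in ("8", "16"):
        maxval = 255 if bitdepth == "8" else 65535
        lo, hi = float(img.min()), float(img.max())
        if hi == lo:
            log.warning("constant image written as mid-gray: %s", path)
            scaled = np.full(img.shape, (maxval + 1) // 2, dtype=np.float64)
        else:
            scaled = np.round((img - lo) / (hi - lo) * maxval)
        arr = scaled.T.astype(np.uint8 if bitdepth == "8" else np.uint16)
        if path.suffix.lower() in (".tif", ".tiff"):
            tifffile.imwrite(path, arr, photometric="minisblack")
        else:
            import imageio.v3 as iio

            iio.imwrite(path, arr)
        meta = {"bitdepth": bitdepth, "scale_min": lo, "scale_max": hi}
    else:
        raise ParameterError(f"bitdepth must be '8', '16' or 'float', got {bitdepth!r}")
    sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return path


def write_report(report, path: str | Path) -> Path:
    """Write a QualityReport as CSV with columns filter, psnr_db, ssim."""
    df = report.to_frame() if hasattr(report, "to_frame") else pd.DataFrame(report)
    if df.empty:
        raise ParameterError("refusing to write an empty report")
    if df["filter"].duplicated().any():
        dup = df["filter"][df["filter"].duplicated()].iloc[0]
        raise ParameterError(f"duplicate filter name in report: {dup!r}")
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.6f")
    return path


def read_report(path: str | Path) -> pd.DataFrame:
    """Read a CSV quality report back into a DataFrame."""
    df = pd.read_csv(path)
    expected = {"filter", "psnr_db", "ssim"}
    if not expected.issubset(df.columns):
        raise FormatError(f"report {path} lacks columns {expected}")
    return df
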