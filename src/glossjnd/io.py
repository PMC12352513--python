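"""File formats: PNG (8-bit sRGB), PFM (linear HDR), trial CSV, JSON reports.

PNG goes through imageio and is assumed sRGB-encoded; PFM stores float32
linear radiance (little-endian, bottom-up rows per the format convention).
CSV schemas are validated on read with errors naming the missing column.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "write_png", "read_png", "write_pfm", "read_pfm",
    "write_mask_png", "read_mask_png",
    "read_trials_csv", "write_trials_csv", "write_json", "read_json",
]


def write_png(path, srgb_u8: np.ndarray) -> None:
    """Write an 8-bit sRGB image (H,W) or (H,W,3)."""
    arr = np.asarray(srgb_u8)
    if arr.dtype != np.uint8:
        raise ValueError("write_png expects uint8 sRGB codes")
    iio.imwrite(Path(path), arr)


def read_png(path) -> np.ndarray:
    """Read a PNG as uint8 sRGB codes (alpha dropped)."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[..., :3]
    return arr.astype(np.uint8)


def write_mask_png(path, mask: np.ndarray) -> None:
    write_png(path, (np.asarray(mask, bool) * np.uint8(255)))


def read_mask_png(path) -> np.ndarray:
    arr = read_png(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 127


def write_pfm(path, image: np.ndarray) -> None:
    """Write a float32 PFM (Pf greyscale or PF colour), scale -1 = little-endian."""
    img = np.asarray(image, dtype=np.float32)
    if img.ndim == 2:
        header, data = b"Pf", img
    elif img.ndim == 3 and img.shape[2] == 3:
        header, data = b"PF", img
    else:
        raise ValueError("PFM supports (H,W) or (H,W,3) images")
    h, w = img.shape[:2]
    with open(path, "wb") as f:
        f.write(header + b"\n%d %d\n-1.0\n" % (w, h))
        f.write(np.flipud(data).astype("<f4").tobytes())


def read_pfm(path) -> np.ndarray:
    with open(path, "rb") as f:
        header = f.readline().strip()
        if header not in (b"Pf", b"PF"):
            raise ValueError(f"not a PFM file: header {header!r}")
        w, h = map(int, f.readline().split())
        scale = float(f.readline())
        count = w * h * (3 if header == b"PF" else 1)
        data = np.frombuffer(f.read(count * 4),
                             dtype="<f4" if scale < 0 else ">f4", count=count)
    shape = (h, w, 3) if header == b"PF" else (h, w)
    return np.flipud(data.reshape(shape)).astype(np.float64)


def read_trials_csv(path, required: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    for i, row in df.iterrows():
        if row.isna().any():
            raise ValueError(f"{path}: malformed row at line {i + 2} "
                             f"(1-based, incl. header): {row.to_dict()}")
    return df


def write_trials_csv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=default))


def read_json(path):
    return json.loads(Path(path).read_text())
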