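"""Reading image stacks and writing analysis artifacts.

Coordinate convention used throughout the package: origin at the top-left
pixel, ``x`` is the column index increasing rightward, ``y`` the row index
increasing downward, both 0-based.  ``u`` is the x-displacement and ``v``
the y-displacement, in pixels; conversion to micrometres multiplies by
``pixel_size_um``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "DEFAULT_PIXEL_SIZE_UM",
    "AcquisitionMeta",
    "ImageStack",
    "read_stack",
    "write_stack",
    "write_fields",
    "read_fields",
    "write_manifest",
]

#: Effective micrometres per pixel of the reference acquisition setup
#: (10X objective), recovered from the 532.6 um^2 normalisation area of a
#: 24 px vector block: sqrt(532.6) / 24.
DEFAULT_PIXEL_SIZE_UM = 0.9616

_FLOAT_FMT = "%.6f"


@dataclass
class AcquisitionMeta:
    """Acquisition metadata attached to an image stack."""

    fps: float
    pixel_size_um: float
    objective: str = ""
    source_path: str = ""

    def __post_init__(self) -> None:
        if not self.fps > 0:
            raise ValueError("fps must be > 0")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")


@dataclass
class ImageStack:
    """Ordered grayscale frames with frame-rate and pixel-size metadata.

    ``frames`` has shape ``(n_frames, rows, cols)`` with float values in
    ``[0, 1]``.
    """

    frames: np.ndarray
    fps: float
    pixel_size_um: float
    source: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, rows, cols) array")
        if self.frames.shape[0] < 2:
            raise ValueError("need a time series: stack must hold >= 2 frames")
        if not self.fps > 0:
            raise ValueError("fps must be > 0")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def frame_shape(self) -> tuple[int, int]:
        return tuple(self.frames.shape[1:])  # type: ignore[return-value]

    @property
    def times_s(self) -> np.ndarray:
        """Acquisition time of each frame in seconds (frame 0 at t = 0)."""
        return np.arange(self.n_frames) / self.fps

    def __len__(self) -> int:
        return self.n_frames


def _to_gray(frames: np.ndarray) -> np.ndarray:
    """Collapse an RGB(A) axis to luminance (ITU-R 601 weights)."""
    if frames.ndim == 4 and frames.shape[-1] in (3, 4):
        rgb = frames[..., :3].astype(np.float64)
        return rgb @ np.array([0.299, 0.587, 0.114])
    if frames.ndim == 3:
        return frames.astype(np.float64)
    raise ValueError(f"cannot interpret frame array of shape {frames.shape}")


def _normalize(frames: np.ndarray, dtype: np.dtype) -> np.ndarray:
    if np.issubdtype(dtype, np.integer):
        return frames / float(np.iinfo(dtype).max)
    peak = float(np.nanmax(frames)) if frames.size else 1.0
    if peak > 1.0:  # float file stored on an unnormalised scale
        return frames / peak
    return frames


def _tiff_fps(path: Path) -> float | None:
    try:
        with tifffile.TiffFile(path) as tf:
            meta = tf.imagej_metadata or {}
            if "fps" in meta:
                return float(meta["fps"])
            if meta.get("finterval"):
                return 1.0 / float(meta["finterval"])
    except Exception:
        return None
    return None


def read_stack(
    path: str | Path,
    fps: float | None = None,
    pixel_size_um: float | None = None,
) -> ImageStack:
    """Read a multi-page TIFF or video container as a grayscale stack.

    Explicit ``fps`` / ``pixel_size_um`` arguments override anything found
    in file metadata.  A frame rate must come from one of the two sources;
    there is deliberately no silent default.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        raw = tifffile.imread(path)
        dtype = raw.dtype
        if raw.ndim == 2:
            raw = raw[None]
        file_fps = _tiff_fps(path)
    else:
        import imageio.v2 as iio

        reader = iio.get_reader(path)
        frames = [np.asarray(f) for f in reader]
        file_fps = None
        try:
            file_fps = float(reader.get_meta_data().get("fps"))
        except Exception:
            pass
        reader.close()
        if not frames:
            raise IOError(f"no frames readable from {path}")
        raw = np.stack(frames)
        dtype = raw.dtype

    frames = _normalize(_to_gray(raw), dtype)
    if frames.shape[0] < 2:
        raise ValueError("need a time series: file holds a single frame")

    fps = fps if fps is not None else file_fps
    if fps is None:
        raise ValueError(
            "frame rate unknown: pass fps explicitly or store it in the file"
        )
    if pixel_size_um is None:
        raise ValueError("pixel_size_um must be provided")
    return ImageStack(frames, fps=fps, pixel_size_um=pixel_size_um, source=str(path))


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as a 16-bit multi-page ImageJ TIFF with fps metadata."""
    path = Path(path)
    data = np.clip(stack.frames, 0.0, 1.0)
    data16 = np.round(data * np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(
        path,
        data16,
        imagej=True,
        metadata={"fps": stack.fps, "finterval": 1.0 / stack.fps},
    )


# ---------------------------------------------------------------------------
# displacement-field tables

_FIELD_COLUMNS = [
    "frame",
    "reference",
    "grid_x",
    "grid_y",
    "u_px",
    "v_px",
    "quality",
    "valid",
]


def write_fields(fields, path: str | Path) -> None:
    """Write displacement fields as one long-format CSV.

    Byte-stable for identical inputs: fixed column order and float format.
    An empty field list produces a header-only file.
    """
    rows = []
    for f in fields:
        gx, gy = np.meshgrid(f.grid_x, f.grid_y)
        rows.append(
            pd.DataFrame(
                {
                    "frame": f.frame_index,
                    "reference": f.reference_index,
                    "grid_x": gx.ravel(),
                    "grid_y": gy.ravel(),
                    "u_px": f.u.ravel(),
                    "v_px": f.v.ravel(),
                    "quality": f.quality.ravel(),
                    "valid": f.valid.ravel().astype(int),
                }
            )
        )
    if rows:
        table = pd.concat(rows, ignore_index=True)
    else:
        table = pd.DataFrame(columns=_FIELD_COLUMNS)
    table.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_fields(path: str | Path):
    """Read displacement fields written by :func:`write_fields`.

    A NaN displacement cell is loaded as an invalid vector, never as a
    silent zero.
    """
    from .piv import DisplacementField

    table = pd.read_csv(path)
    fields = []
    for (frame, ref), sub in table.groupby(["frame", "reference"], sort=True):
        gx = np.unique(sub["grid_x"].to_numpy())
        gy = np.unique(sub["grid_y"].to_numpy())
        shape = (len(gy), len(gx))
        ix = np.searchsorted(gx, sub["grid_x"].to_numpy())
        iy = np.searchsorted(gy, sub["grid_y"].to_numpy())
        u = np.full(shape, np.nan)
        v = np.full(shape, np.nan)
        q = np.zeros(shape)
        ok = np.zeros(shape, dtype=bool)
        u[iy, ix] = sub["u_px"].to_numpy()
        v[iy, ix] = sub["v_px"].to_numpy()
        q[iy, ix] = sub["quality"].to_numpy()
        ok[iy, ix] = sub["valid"].to_numpy().astype(bool)
        ok &= np.isfinite(u) & np.isfinite(v)
        fields.append(
            DisplacementField(
                grid_x=gx,
                grid_y=gy,
                u=u,
                v=v,
                quality=q,
                valid=ok,
                frame_index=int(frame),
                reference_index=int(ref),
            )
        )
    fields.sort(key=lambda f: f.frame_index)
    return fields


def write_manifest(manifest: dict, path: str | Path) -> None:
    """Write the JSON run manifest (sorted keys, stable formatting)."""
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
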