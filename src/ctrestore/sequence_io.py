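"""Image-sequence I/O and the stack/unstack bridge to the decomposition matrix.

A CT study arrives as an ordered stack of same-sized grayscale frames
(PNG/TIFF files or a DICOM series).  The decomposition solvers operate on
the (H*W) x n "data matrix" whose column i is frame i flattened in
row-major order; this module owns the two containers and the lossless
conversions between them.

Intensities are kept as float64 on the 8-bit [0, 255] convention
throughout, since the quality metrics assume 256 gray levels.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "BT601_WEIGHTS",
    "ImageSequence",
    "DataMatrix",
    "load_sequence",
    "save_sequence",
    "stack_sequence",
    "unstack_matrix",
]

#: ITU-R BT.601 luminance weights used for RGB -> gray conversion.
BT601_WEIGHTS = (0.299, 0.587, 0.114)

_IMAGE_EXTENSIONS = {".png", ".tif", ".tiff"}
_DICOM_EXTENSIONS = {".dcm", ".dicom", ".ima"}


class DimensionMismatchError(ValueError):
    """Frames in a sequence do not share a common height/width."""


@dataclass
class ImageSequence:
    """Ordered stack of same-sized 2-D grayscale frames.

    Parameters
    ----------
    frames
        List of 2-D float arrays on the [0, 255] intensity scale.
    source_ids
        Per-frame provenance labels (filenames, DICOM instance numbers, or
        synthetic tags).  Defaults to stringified indices.
    """

    frames: list[np.ndarray]
    source_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValueError("an ImageSequence needs at least one frame")
        self.frames = [np.asarray(f, dtype=np.float64) for f in self.frames]
        shapes = {f.shape for f in self.frames}
        if len(shapes) != 1:
            raise DimensionMismatchError(
                f"frames have unequal dimensions: {sorted(shapes)}"
            )
        (shape,) = shapes
        if len(shape) != 2:
            raise ValueError(f"frames must be 2-D, got shape {shape}")
        for i, f in enumerate(self.frames):
            if not np.all(np.isfinite(f)):
                raise ValueError(f"frame {i} contains non-finite values")
        if not self.source_ids:
            self.source_ids = [str(i) for i in range(len(self.frames))]
        if len(self.source_ids) != len(self.frames):
            raise ValueError("source_ids length must match frame count")

    @property
    def height(self) -> int:
        return self.frames[0].shape[0]

    @property
    def width(self) -> int:
        return self.frames[0].shape[1]

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def __len__(self) -> int:
        return self.n_frames

    def __iter__(self):
        return iter(self.frames)


@dataclass
class DataMatrix:
    """(H*W) x n matrix whose column i is frame i flattened row-major."""

    values: np.ndarray
    height: int
    width: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("DataMatrix values must be 2-D")
        if self.values.shape[0] != self.height * self.width:
            raise ValueError(
                f"row count {self.values.shape[0]} != height*width "
                f"{self.height}*{self.width}"
            )

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


def _to_gray(arr: np.ndarray, weights: Sequence[float]) -> np.ndarray:
    """Collapse an RGB(A) array to luminance; pass 2-D arrays through."""
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        w = np.asarray(weights, dtype=np.float64)
        return arr[:, :, :3] @ (w / w.sum())
    raise ValueError(f"unsupported image shape {arr.shape}")


def _scale_to_255(arr: np.ndarray, dtype) -> np.ndarray:
    """Map integer sample values onto the float [0, 255] scale."""
    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        if info.max > 255:
            return arr * (255.0 / info.max)
    return arr


def _read_dicom_frame(path: Path, window: tuple[float, float] | None):
    import pydicom

    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array.astype(np.float64)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    arr = arr * slope + intercept
    if window is None:
        lo, hi = float(arr.min()), float(arr.max())
    else:
        lo, hi = window
    if hi <= lo:
        arr = np.zeros_like(arr)
    else:
        arr = np.clip((arr - lo) / (hi - lo), 0.0, 1.0) * 255.0
    order = getattr(ds, "InstanceNumber", None)
    return arr, order


def load_sequence(
    source: str | os.PathLike | Sequence[str | os.PathLike],
    luminance_weights: Sequence[float] = BT601_WEIGHTS,
    dicom_window: tuple[float, float] | None = None,
) -> ImageSequence:
    """Load an image sequence from a directory or an explicit file list.

    Frames are ordered lexicographically by filename; DICOM series are
    reordered by InstanceNumber when every file carries one.  RGB frames
    are converted to gray with the given luminance weights; 8-bit and
    16-bit integer samples are mapped to float on [0, 255].  DICOM pixel
    data has rescale slope/intercept applied and is then windowed linearly
    to [0, 255] (full data range by default).

    Raises
    ------
    DimensionMismatchError
        If decoded frames disagree in height/width.
    IOError
        Naming the offending file, if one cannot be read.
    """
    if isinstance(source, (str, os.PathLike)):
        root = Path(source)
        if root.is_dir():
            paths = sorted(
                p for p in root.iterdir()
                if p.suffix.lower() in _IMAGE_EXTENSIONS | _DICOM_EXTENSIONS
            )
        else:
            paths = [root]
    else:
        paths = [Path(p) for p in source]
    if not paths:
        raise IOError(f"no image files found in {source!r}")

    frames: list[np.ndarray] = []
    ids: list[str] = []
    dicom_orders: list[int | None] = []
    for path in paths:
        try:
            if path.suffix.lower() in _DICOM_EXTENSIONS:
                arr, order = _read_dicom_frame(path, dicom_window)
                dicom_orders.append(order)
            elif path.suffix.lower() in {".tif", ".tiff"}:
                import tifffile

                raw = tifffile.imread(str(path))
                if raw.ndim == 3 and raw.shape[2] not in (3, 4):
                    # multi-page stack: append every page
                    for k in range(raw.shape[0]):
                        page = _scale_to_255(
                            _to_gray(raw[k], luminance_weights), raw.dtype
                        )
                        frames.append(page)
                        ids.append(f"{path.name}[{k}]")
                        dicom_orders.append(None)
                    continue
                arr = _scale_to_255(_to_gray(raw, luminance_weights), raw.dtype)
                dicom_orders.append(None)
            else:
                import imageio.v3 as iio

                raw = iio.imread(str(path))
                arr = _scale_to_255(_to_gray(raw, luminance_weights), raw.dtype)
                dicom_orders.append(None)
        except IOError:
            raise
        except Exception as exc:  # decoder backends raise assorted types
            raise IOError(f"cannot read image file {path}: {exc}") from exc
        frames.append(arr)
        ids.append(path.name)

    if dicom_orders and all(o is not None for o in dicom_orders):
        order = np.argsort(np.asarray(dicom_orders, dtype=int), kind="stable")
        frames = [frames[i] for i in order]
        ids = [ids[i] for i in order]

    return ImageSequence(frames=frames, source_ids=ids)


def save_sequence(
    seq: ImageSequence,
    directory: str | os.PathLike,
    prefix: str = "frame",
    fmt: str = "png",
    clip: bool = True,
) -> list[Path]:
    """Write frames as lossless 8-bit PNG or float32 TIFF files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fmt = fmt.lower().lstrip(".")
    if fmt not in {"png", "tif", "tiff"}:
        raise ValueError(f"lossless formats only (png/tiff), got {fmt!r}")
    paths = []
    for i, frame in enumerate(seq.frames):
        path = directory / f"{prefix}_{i:04d}.{fmt}"
        if fmt == "png":
            import imageio.v3 as iio

            data = np.clip(frame, 0, 255) if clip else frame
            iio.imwrite(str(path), np.round(data).astype(np.uint8))
        else:
            import tifffile

            tifffile.imwrite(str(path), frame.astype(np.float32))
        paths.append(path)
    return paths


def stack_sequence(seq: ImageSequence) -> DataMatrix:
    """Stack frames into the (H*W) x n data matrix (row-major scan order)."""
    cols = [f.reshape(-1) for f in seq.frames]
    return DataMatrix(
        values=np.column_stack(cols), height=seq.height, width=seq.width
    )


def unstack_matrix(matrix: DataMatrix) -> ImageSequence:
    """Inverse of :func:`stack_sequence`."""
    frames = [
        matrix.values[:, i].reshape(matrix.height, matrix.width)
        for i in range(matrix.n_frames)
    ]
    return ImageSequence(frames=frames)
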