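"""Read confocal z-stacks and write result artifacts.

Supported inputs: multi-page TIFF, uncompressed 24-bit AVI (the classic
confocal export container), and directories of numbered single-frame
PNG/TIFF images.  Color frames are reduced to a single channel (red, green,
blue, or luminance = rounded mean of R,G,B) on read.

Outputs: 16-bit multi-page label TIFF (pixel value = 3-D cell id, 0 =
background), a per-cell CSV table, and a JSON flag report.

Coordinates everywhere are 0-based (row, col), row = y downward, col = x
rightward, z ascending with frame order.
"""

from __future__ import annotations

import json
import re
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import imageio.v3 as iio

__all__ = [
    "IntensityStack",
    "CHANNELS",
    "read_stack",
    "write_label_stack",
    "read_label_stack",
    "write_cell_table",
    "write_flag_report",
]

CHANNELS = ("red", "green", "blue", "luminance")
_CHANNEL_INDEX = {"red": 0, "green": 1, "blue": 2}


class StackInputError(ValueError):
    """Unreadable or inconsistent stack input."""


@dataclass
class IntensityStack:
    """An ordered sequence of 2-D grayscale frames (one channel).

    ``frames`` is a (z, height, width) array; ``bit_depth`` 8 or 16;
    ``pixel_size_xy`` and ``z_step`` carry optional physical metadata in μm
    (plane-to-plane separations of 5-20 μm are typical for the confocal
    acquisitions this tool targets).
    """

    frames: np.ndarray
    bit_depth: int = 8
    pixel_size_xy: Optional[float] = None
    z_step: Optional[float] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise StackInputError("frames must form a (z, height, width) array")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.frames.size and self.frames.max() > 2**self.bit_depth - 1:
            raise ValueError("intensities exceed the stated bit depth")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self):
        return self.frames.shape


def _extract_channel(frames: np.ndarray, channel: str, source: str) -> np.ndarray:
    if channel not in CHANNELS:
        raise ValueError(f"channel must be one of {CHANNELS}")
    if frames.ndim == 3:  # already single-channel
        if channel != "luminance":
            raise StackInputError(
                f"{source}: grayscale input has no {channel!r} channel; use 'luminance'"
            )
        return frames
    if frames.ndim == 4 and frames.shape[-1] >= 3:
        rgb = frames[..., :3]
        if channel == "luminance":
            return np.rint(rgb.astype(np.float64).mean(axis=-1)).astype(rgb.dtype)
        return rgb[..., _CHANNEL_INDEX[channel]]
    raise StackInputError(f"{source}: unsupported frame layout {frames.shape}")


_NUM_RE = re.compile(r"(\d+)")


def _natural_key(name: str):
    return [int(t) if t.isdigit() else t for t in _NUM_RE.split(name)]


def _read_directory(path: Path) -> np.ndarray:
    files = sorted(
        (p for p in path.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")),
        key=lambda p: _natural_key(p.name),
    )
    if not files:
        raise StackInputError(f"{path}: no PNG/TIFF frames found")
    frames = []
    for i, f in enumerate(files):
        try:
            img = iio.imread(f)
        except Exception as exc:  # noqa: BLE001 - report the frame index
            raise StackInputError(f"{path}: frame {i} ({f.name}) unreadable: {exc}") from exc
        frames.append(img)
    shapes = {fr.shape for fr in frames}
    if len(shapes) > 1:
        raise StackInputError(f"{path}: mixed frame dimensions {sorted(shapes)}")
    return np.stack(frames)


def _read_avi_uncompressed(path: Path) -> np.ndarray:
    """Minimal RIFF reader for uncompressed 24-bit DIB AVI streams.

    Frames are stored bottom-up in BGR order with rows padded to 4 bytes;
    they are returned top-down as (z, h, w, 3) RGB uint8.
    """
    data = path.read_bytes()
    if data[:4] != b"RIFF" or data[8:12] != b"AVI ":
        raise StackInputError(f"{path}: not a RIFF/AVI file")
    # main AVI header gives frame geometry
    pos = data.find(b"avih")
    if pos < 0:
        raise StackInputError(f"{path}: missing AVI header")
    avih = data[pos + 8 :]
    width = struct.unpack_from("<I", avih, 32)[0]
    height = struct.unpack_from("<I", avih, 36)[0]
    movi = data.find(b"movi")
    if movi < 0:
        raise StackInputError(f"{path}: missing movi list")
    row_bytes = (width * 3 + 3) & ~3
    frames: List[np.ndarray] = []
    pos = movi + 4
    while pos + 8 <= len(data):
        ckid = data[pos : pos + 4]
        (size,) = struct.unpack_from("<I", data, pos + 4)
        body = data[pos + 8 : pos + 8 + size]
        if ckid[2:4] in (b"db", b"dc"):
            if len(body) < row_bytes * height:
                raise StackInputError(
                    f"{path}: frame {len(frames)} truncated or compressed "
                    "(only uncompressed 24-bit AVI is supported)"
                )
            rows = np.frombuffer(body[: row_bytes * height], dtype=np.uint8)
            rows = rows.reshape(height, row_bytes)[:, : width * 3].reshape(height, width, 3)
            frames.append(rows[::-1, :, ::-1])  # bottom-up BGR -> top-down RGB
        pos += 8 + size + (size & 1)
    if not frames:
        raise StackInputError(f"{path}: no video frames found")
    return np.stack(frames)


def read_stack(path, channel: str = "luminance") -> IntensityStack:
    """Read a z-stack and reduce it to one intensity channel.

    ``path`` may be a multi-page TIFF, an uncompressed 24-bit AVI, or a
    directory of numbered PNG/TIFF frames (natural filename order).  Frames
    are returned in ascending z order.
    """
    path = Path(path)
    if not path.exists():
        raise StackInputError(f"{path}: no such file or directory")
    if path.is_dir():
        raw = _read_directory(path)
    elif path.suffix.lower() in (".tif", ".tiff"):
        try:
            raw = tifffile.imread(path)
        except Exception as exc:  # noqa: BLE001
            raise StackInputError(f"{path}: unreadable TIFF: {exc}") from exc
        if raw.ndim == 2:
            raw = raw[None]
    elif path.suffix.lower() == ".avi":
        raw = _read_avi_uncompressed(path)
    else:
        raise StackInputError(f"{path}: unsupported container {path.suffix!r}")
    frames = _extract_channel(raw, channel, str(path))
    bit_depth = 16 if frames.dtype.itemsize > 1 else 8
    return IntensityStack(frames=frames, bit_depth=bit_depth)


def write_label_stack(labels, path) -> None:
    """Write per-frame label grids as a multi-page 16-bit TIFF.

    Pixel value is the 3-D cell id, 0 the background; the round trip through
    :func:`read_label_stack` is lossless.  More than 65535 cells exceed the
    16-bit capacity and raise.
    """
    vol = np.asarray(labels)
    if vol.size == 0 or vol.ndim != 3:
        raise ValueError("labels must be a non-empty (z, h, w) volume")
    if vol.min() < 0:
        raise ValueError("labels must be non-negative")
    if vol.max() > 0xFFFF:
        raise ValueError("more than 65535 cells exceed 16-bit label capacity")
    tifffile.imwrite(path, vol.astype(np.uint16))


def read_label_stack(path) -> np.ndarray:
    vol = tifffile.imread(path)
    if vol.ndim == 2:
        vol = vol[None]
    return vol.astype(np.int32)


def write_cell_table(db, path, flag_path=None) -> None:
    """Write the per-cell statistics table as CSV (and optionally the flag
    report as JSON next to it).

    Columns: cell_id, z_start, z_end, n_slices, total_pixels, centroid_x,
    centroid_y, centroid_z, equiv_diameter_mean, flagged.
    """
    rows = []
    for cell in db.cells:
        s = db.cell_stats(cell.cell_id)
        rows.append(
            {
                "cell_id": cell.cell_id,
                "z_start": cell.z_start,
                "z_end": cell.z_end,
                "n_slices": cell.n_slices,
                "total_pixels": cell.total_pixels,
                "centroid_x": round(s["centroid"][0], 4),
                "centroid_y": round(s["centroid"][1], 4),
                "centroid_z": round(s["centroid"][2], 4),
                "equiv_diameter_mean": round(s["equiv_diameter_mean"], 4),
                "flagged": cell.flagged,
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "cell_id",
            "z_start",
            "z_end",
            "n_slices",
            "total_pixels",
            "centroid_x",
            "centroid_y",
            "centroid_z",
            "equiv_diameter_mean",
            "flagged",
        ],
    )
    frame.to_csv(path, index=False)
    if flag_path is not None:
        write_flag_report(db, flag_path)


def write_flag_report(db, path) -> None:
    """JSON report of every flag raised during 3-D merging.

    Each entry names the frame, the offending 2-D object, the reason
    (``forward_multi`` or ``reverse_multi``) and the 3-D cell containing the
    object, if any.
    """
    obj_to_cell = {}
    for cell in db.cells:
        for m in cell.members:
            obj_to_cell[(m.frame_index, m.id)] = cell.cell_id
    entries = [
        {
            "frame_index": f.frame_index,
            "object_id": f.object_id,
            "cell_id": obj_to_cell.get((f.frame_index, f.object_id)),
            "reason": f.reason,
        }
        for f in db.state.flags
    ]
    Path(path).write_text(json.dumps({"flags": entries}, indent=2))
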