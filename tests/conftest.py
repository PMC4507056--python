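"""Shared fixtures and brute-force oracles for the test suite."""

from __future__ import annotations

import math
import struct

import numpy as np
import pytest

from somaseg.segment2d import Object2D


def make_object(oid, frame, pixels):
    """Build an Object2D from an iterable of (row, col) pixels."""
    pts = frozenset((int(r), int(c)) for (r, c) in pixels)
    rows = [r for (r, _) in pts]
    cols = [c for (_, c) in pts]
    return Object2D(
        id=oid,
        frame_index=frame,
        pixels=pts,
        centroid=(sum(rows) / len(rows), sum(cols) / len(cols)),
    )


def rect(oid, frame, r0, c0, h, w):
    return make_object(oid, frame, [(r, c) for r in range(r0, r0 + h) for c in range(c0, c0 + w)])


def disc(oid, frame, rc, cc, radius):
    pts = [
        (r, c)
        for r in range(int(rc - radius), int(rc + radius) + 1)
        for c in range(int(cc - radius), int(cc + radius) + 1)
        if (r - rc) ** 2 + (c - cc) ** 2 <= radius**2
    ]
    return make_object(oid, frame, pts)


def brute_force_distance(mask: np.ndarray, metric: str) -> np.ndarray:
    """O(n^2 m) scan over all background pixels, including the implicit
    one-pixel background border around the frame."""
    mask = np.asarray(mask, dtype=bool)
    padded = np.pad(mask, 1, constant_values=False)
    bg = np.argwhere(~padded)
    out = np.zeros(mask.shape, dtype=float)
    for (r, c) in np.argwhere(mask):
        pr, pc = r + 1, c + 1
        dr = bg[:, 0] - pr
        dc = bg[:, 1] - pc
        if metric == "euclidean":
            d = np.sqrt(dr**2 + dc**2)
        else:
            d = np.maximum(np.abs(dr), np.abs(dc))
        out[r, c] = d.min()
    return out


def write_uncompressed_avi(path, frames_rgb: np.ndarray) -> None:
    """Emit a minimal uncompressed 24-bit DIB AVI (test fixture writer)."""
    nz, h, w, _ = frames_rgb.shape
    row_bytes = (w * 3 + 3) & ~3

    def chunk(ckid, payload):
        pad = b"\x00" if len(payload) % 2 else b""
        return ckid + struct.pack("<I", len(payload)) + payload + pad

    avih = struct.pack("<14I", 40_000, row_bytes * h, 0, 0, nz, 0, 1, row_bytes * h, w, h, 0, 0, 0, 0)
    strh = b"vids" + b"DIB " + struct.pack("<11I", 0, 0, 0, 1, 25, 0, nz, row_bytes * h, 0, 0, 0)
    strf = struct.pack("<IiiHHIIiiII", 40, w, h, 1, 24, 0, row_bytes * h, 0, 0, 0, 0)
    strl = b"LIST" + struct.pack("<I", 0) + b"strl" + chunk(b"strh", strh) + chunk(b"strf", strf)
    strl = b"LIST" + struct.pack("<I", len(strl) - 8) + strl[12:]
    hdrl_body = b"hdrl" + chunk(b"avih", avih) + strl
    hdrl = b"LIST" + struct.pack("<I", len(hdrl_body)) + hdrl_body
    movi_body = b"movi"
    for f in frames_rgb:
        dib = np.zeros((h, row_bytes), dtype=np.uint8)
        dib[:, : w * 3] = f[::-1, :, ::-1].reshape(h, w * 3)  # bottom-up BGR
        movi_body += chunk(b"00db", dib.tobytes())
    movi = b"LIST" + struct.pack("<I", len(movi_body)) + movi_body
    body = b"AVI " + hdrl + movi
    with open(path, "wb") as fh:
        fh.write(b"RIFF" + struct.pack("<I", len(body)) + body)


@pytest.fixture(scope="session")
def level1_phantom():
    """Small well-separated level-1 stack with ground truth."""
    from somaseg.synthgen import make_spec, generate_stack

    spec = make_spec(1, n_somata=8, seed=7, volume=(10, 128, 128))
    return generate_stack(spec)


@pytest.fixture(scope="session")
def level2_phantom():
    from somaseg.synthgen import make_spec, generate_stack

    spec = make_spec(2, n_somata=15, seed=11, volume=(12, 256, 256))
    return generate_stack(spec)
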