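"""Depth-frame container and file dialects.

Two on-disk dialects are supported:

* **Text matrix** — one line per pixel row (top row first), whitespace
  separated integer depths in mm, 0 = invalid.  A 640x480 frame is 480
  lines of 640 fields.
* **16-bit PGM** — magic ``P2`` (ASCII) or ``P5`` (binary, big-endian
  sample order), maxval 65535, one grey level per mm.

Both round-trip integer frames losslessly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

__all__ = [
    "DepthFrame",
    "write_text_frame",
    "read_text_frame",
    "write_pgm",
    "read_pgm",
    "depth_window",
]

PathLike = Union[str, Path]


@dataclass
class DepthFrame:
    """An n-row by m-column grid of per-pixel depth in mm; 0 = invalid."""

    values: np.ndarray
    sensor_tag: Optional[str] = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("depth frame must be a 2-D grid")
        if np.any(self.values < 0):
            raise ValueError("depth values must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return self.values > 0

    @property
    def n_valid(self) -> int:
        return int(np.count_nonzero(self.values))

    def copy(self) -> "DepthFrame":
        return DepthFrame(self.values.copy(), self.sensor_tag)


def write_text_frame(frame: DepthFrame, sink: PathLike) -> None:
    """Write the frame as whitespace-separated integer mm, one line per row."""
    vals = np.rint(frame.values).astype(np.int64)
    with open(sink, "w") as fh:
        for row in vals:
            fh.write(" ".join(map(str, row.tolist())))
            fh.write("\n")


def read_text_frame(source: PathLike) -> DepthFrame:
    """Read a text-dialect depth frame; rejects ragged or negative input."""
    rows: list[np.ndarray] = []
    width = None
    with open(source) as fh:
        for lineno, line in enumerate(fh):
            tokens = line.split()
            if not tokens:
                continue
            try:
                row = np.array([float(t) for t in tokens])
            except ValueError:
                raise ValueError(f"non-numeric token in row {lineno}")
            if width is None:
                width = row.size
            elif row.size != width:
                raise ValueError(
                    f"ragged row {lineno}: {row.size} fields, expected {width}"
                )
            if np.any(row < 0):
                raise ValueError(f"negative depth in row {lineno}")
            rows.append(row)
    if not rows:
        raise ValueError("empty depth-frame file")
    return DepthFrame(np.vstack(rows))


_PGM_MAXVAL = 65535


def write_pgm(frame: DepthFrame, sink: PathLike, binary: bool = True) -> None:
    """Write a 16-bit PGM (P5 binary by default, P2 ASCII otherwise).

    One grey level equals one mm; values are rounded to integers.
    """
    vals = np.rint(frame.values).astype(np.int64)
    if np.any(vals > _PGM_MAXVAL):
        raise ValueError(f"depth exceeds PGM maxval {_PGM_MAXVAL}")
    h, w = vals.shape
    if binary:
        with open(sink, "wb") as fh:
            fh.write(f"P5\n{w} {h}\n{_PGM_MAXVAL}\n".encode("ascii"))
            fh.write(vals.astype(">u2").tobytes())
    else:
        with open(sink, "w") as fh:
            fh.write(f"P2\n{w} {h}\n{_PGM_MAXVAL}\n")
            for row in vals:
                fh.write(" ".join(map(str, row.tolist())))
                fh.write("\n")


def _pgm_header_tokens(fh: io.BufferedReader, count: int) -> list[int]:
    """Read `count` whitespace/comment-separated integer header tokens."""
    tokens: list[int] = []
    buf = b""
    while len(tokens) < count:
        ch = fh.read(1)
        if not ch:
            raise ValueError("truncated PGM header")
        if ch == b"#":  # comment to end of line
            while ch not in (b"\n", b""):
                ch = fh.read(1)
            continue
        if ch.isspace():
            if buf:
                tokens.append(int(buf))
                buf = b""
            continue
        if not ch.isdigit():
            raise ValueError("malformed PGM header")
        buf += ch
    return tokens


def read_pgm(source: PathLike) -> DepthFrame:
    """Read a 16-bit P2/P5 PGM depth frame (maxval must be 65535)."""
    with open(source, "rb") as fh:
        magic = fh.read(2)
        if magic not in (b"P2", b"P5"):
            raise ValueError(f"not a P2/P5 PGM file (magic {magic!r})")
        w, h, maxval = _pgm_header_tokens(fh, 3)
        if maxval != _PGM_MAXVAL:
            raise ValueError(f"expected maxval {_PGM_MAXVAL}, found {maxval}")
        if magic == b"P5":
            data = fh.read(w * h * 2)
            if len(data) != w * h * 2:
                raise ValueError("truncated P5 pixel data")
            vals = np.frombuffer(data, dtype=">u2").reshape(h, w)
        else:
            text = fh.read().split()
            if len(text) != w * h:
                raise ValueError("wrong P2 sample count")
            vals = np.array([int(t) for t in text]).reshape(h, w)
    return DepthFrame(vals.astype(float))


def depth_window(frame: DepthFrame, d_lo: float = 160.0, d_hi: float = 700.0) -> DepthFrame:
    """Invalidate pixels outside the close-shot window [d_lo, d_hi] mm.

    Idempotent: surviving pixels are untouched.
    """
    if not (0 < d_lo < d_hi):
        raise ValueError("require 0 < d_lo < d_hi")
    vals = frame.values.copy()
    vals[(vals < d_lo) | (vals > d_hi)] = 0.0
    return DepthFrame(vals, frame.sensor_tag)
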