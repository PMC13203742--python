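"""Frame-stack container and multi-page TIFF I/O.

All pipeline stages exchange :class:`FrameSequence` objects: an ordered stack
of 2-D grayscale frames with bit-depth and acquisition metadata. Stacks are
persisted as multi-page TIFF at the sequence's native bit depth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import tifffile

_DTYPES = {8: np.uint8, 16: np.uint16}


@dataclass
class FrameSequence:
    """Ordered stack of 2-D intensity frames.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        Integer intensity frames; dtype must match ``bit_depth``.
    bit_depth : {8, 16}
        Declared dynamic range of the stack.
    frame_rate : float
        Acquisition rate in Hz.
    pixel_size : float
        Pixel pitch in micrometres (metadata only).
    """

    frames: np.ndarray
    bit_depth: int = 8
    frame_rate: float = 40.0
    pixel_size: float = 0.187

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError(
                f"frames must be a (T, H, W) stack with T >= 1, got shape {self.frames.shape}"
            )
        if self.bit_depth not in _DTYPES:
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        want = _DTYPES[self.bit_depth]
        if self.frames.dtype != want:
            if not np.issubdtype(self.frames.dtype, np.integer):
                raise ValueError(
                    f"frames dtype {self.frames.dtype} is not integer; "
                    f"expected {np.dtype(want)} for {self.bit_depth}-bit data"
                )
            info = np.iinfo(want)
            if self.frames.min() < info.min or self.frames.max() > info.max:
                raise ValueError(
                    f"frame values exceed the {self.bit_depth}-bit range"
                )
            self.frames = self.frames.astype(want)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def with_frames(self, frames: np.ndarray, bit_depth: int | None = None) -> "FrameSequence":
        """Copy of this sequence with new pixel data (metadata preserved)."""
        return replace(
            self, frames=frames, bit_depth=self.bit_depth if bit_depth is None else bit_depth
        )


def read_stack(path: str | Path, frame_rate: float = 40.0, pixel_size: float = 0.187) -> FrameSequence:
    """Read a multi-page grayscale TIFF into a :class:`FrameSequence`.

    Only 8- and 16-bit single-channel stacks are accepted; color/RGB files
    are rejected.
    """
    path = Path(path)
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(
            f"{path}: expected a grayscale stack, got array of shape {arr.shape} "
            "(color/multi-channel TIFF is not supported)"
        )
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise ValueError(f"{path}: unsupported dtype {arr.dtype}; only uint8/uint16 grayscale")
    return FrameSequence(arr, bit_depth=depth, frame_rate=frame_rate, pixel_size=pixel_size)


def write_stack(seq: FrameSequence, path: str | Path) -> None:
    """Write a sequence to a multi-page TIFF at its native bit depth."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, seq.frames, photometric="minisblack")
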