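"""Preprocessing: stabilize input statistics before detection.

Order of operations: 8->16-bit promotion, sliding-window frame accumulation,
optional generalized Anscombe transform, static-background subtraction with
sequence-global normalization, and isotropic Gaussian smoothing with mirror
boundary handling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .io import FrameSequence

U16_MAX = 65535


@dataclass
class PreprocessConfig:
    """Preprocessing parameters.

    ``accumulation_window`` (m) is matched to the shortest expected event
    (~333 ms at 40 Hz -> 13 frames); ``gaussian_sigma`` is the spatial
    smoothing width in pixels. ``use_gat`` inserts a generalized Anscombe
    transform between accumulation and background subtraction.
    """

    accumulation_window: int = 13
    accumulation_stride: int = 1
    gaussian_sigma: float = 1.0
    use_gat: bool = False
    gat_gain: float = 1.0
    gat_read_noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.accumulation_window < 1:
            raise ValueError("accumulation_window must be >= 1")
        if self.accumulation_stride < 1:
            raise ValueError("accumulation_stride must be >= 1")
        if self.gaussian_sigma <= 0:
            raise ValueError("gaussian_sigma must be > 0")


def promote_bit_depth(seq: FrameSequence) -> FrameSequence:
    """Promote an 8-bit stack to 16-bit, values unchanged.

    Guarantees an m-frame sum (up to 255*m) stays representable for
    m <= 257. A 16-bit input passes through with a warning.
    """
    if seq.bit_depth == 16:
        warnings.warn("sequence is already 16-bit; promotion is a no-op", stacklevel=2)
        return seq
    return seq.with_frames(seq.frames.astype(np.uint16), bit_depth=16)


def accumulate_frames(seq: FrameSequence, m: int, stride: int = 1) -> FrameSequence:
    """Sliding-window sum of ``m`` consecutive frames.

    Output frame ``j`` is the sum of input frames ``[j*stride, j*stride+m)``;
    output length is ``floor((T-m)/stride) + 1``. Boosts an event that spans
    the window by ~m while i.i.d. noise grows only by sqrt(m).
    """
    T = seq.n_frames
    if T < m:
        raise ValueError(f"need at least m={m} frames to accumulate, got {T}")
    cs = np.cumsum(seq.frames.astype(np.int64), axis=0)
    n_out = (T - m) // stride + 1
    starts = np.arange(n_out) * stride
    ends = starts + m - 1
    sums = cs[ends]
    nonzero = starts > 0
    sums[nonzero] -= cs[starts[nonzero] - 1]
    if sums.max(initial=0) > U16_MAX:
        raise ValueError(
            f"accumulated intensities exceed 16-bit range (max {sums.max()}); "
            "reduce the window length"
        )
    return seq.with_frames(sums.astype(np.uint16), bit_depth=16)


def generalized_anscombe(
    seq: FrameSequence, gain: float, read_noise_sigma: float = 0.0
) -> FrameSequence:
    """Variance-stabilizing transform for Poisson-Gaussian data.

    Per pixel: ``2*sqrt(max(0, x/gain + 3/8 + (sigma/gain)^2))``, then
    rescaled min-max back to the input's own intensity range so the
    downstream scale anchors (window transform, threshold floors) are
    unaffected. Monotone in x, so intensity ordering is preserved.
    """
    if gain <= 0:
        raise ValueError("gain must be > 0")
    x = seq.frames.astype(np.float64)
    t = 2.0 * np.sqrt(np.maximum(0.0, x / gain + 0.375 + (read_noise_sigma / gain) ** 2))
    lo, hi = t.min(), t.max()
    xlo, xhi = x.min(), x.max()
    if hi > lo:
        t = xlo + (t - lo) / (hi - lo) * (xhi - xlo)
    else:
        t = np.zeros_like(t)
    return seq.with_frames(np.floor(t + 0.5).astype(np.uint16), bit_depth=16)


def estimate_static_background(seq: FrameSequence) -> np.ndarray:
    """Static background image: per-pixel temporal mean over all frames."""
    return seq.frames.mean(axis=0)


def subtract_background_normalize(seq: FrameSequence, background: np.ndarray) -> FrameSequence:
    """Remove the static background, keeping the native accumulated scale.

    Residual = max(0, frame - background), rounded back to 16-bit. The
    residual is *not* stretched to the full 16-bit range: downstream both
    the detector's intensity-threshold floor (tau_g >= 2 gray levels) and
    the final 16->8-bit window transform (denominator min(m*255, 65535))
    are anchored to the accumulated-intensity scale of at most m*255, so
    preserving that scale keeps the output remapping linear and saturation
    free. Negatives are clipped to zero (normalization of the residual to a
    nonnegative dynamic-signal image).
    """
    background = np.asarray(background)
    if background.shape != seq.frame_shape:
        raise ValueError(
            f"background shape {background.shape} does not match frames {seq.frame_shape}"
        )
    res = np.maximum(seq.frames.astype(np.float64) - background[None], 0.0)
    return seq.with_frames(np.floor(res + 0.5).astype(np.uint16), bit_depth=16)


def gaussian_smooth(seq: FrameSequence, sigma: float) -> FrameSequence:
    """Isotropic spatial Gaussian smoothing, mirror-padded at the boundary.

    The kernel is truncated at 4 sigma; the temporal axis is untouched.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    out = gaussian_filter(
        seq.frames.astype(np.float32), sigma=(0.0, sigma, sigma), mode="mirror", truncate=4.0
    )
    hi = U16_MAX if seq.bit_depth == 16 else 255
    return seq.with_frames(
        np.clip(np.floor(out + 0.5), 0, hi).astype(seq.frames.dtype)
    )


def preprocess(seq: FrameSequence, config: PreprocessConfig | None = None) -> FrameSequence:
    """Full preprocessing pipeline on an 8-bit input.

    promote -> accumulate -> (optional GAT) -> background subtract/normalize
    -> Gaussian smooth. Emits a 16-bit sequence of length
    ``floor((T - m)/stride) + 1``.
    """
    if config is None:
        config = PreprocessConfig()
    if seq.bit_depth != 8:
        raise ValueError("preprocess expects an 8-bit raw input sequence")
    out = promote_bit_depth(seq)
    out = accumulate_frames(out, config.accumulation_window, config.accumulation_stride)
    if config.use_gat:
        # gat_read_noise_sigma is quoted per raw frame; an m-frame sum has
        # read noise sigma*sqrt(m), while the Poisson gain (photons per
        # intensity unit) is invariant under summation
        sigma_acc = config.gat_read_noise_sigma * math.sqrt(config.accumulation_window)
        out = generalized_anscombe(out, config.gat_gain, sigma_acc)
    bg = estimate_static_background(out)
    out = subtract_background_normalize(out, bg)
    out = gaussian_smooth(out, config.gaussian_sigma)
    return out
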