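"""Adaptive GMM-based detection of weak calcium events.

The detector couples four mechanisms, applied per frame to the preprocessed
16-bit sequence:

1. **Temporal mask** — pixels above a global statistical threshold
   (mean + theta_g * std of the frame) are candidates; a per-pixel
   consecutive-activation counter enforces temporal persistence.
2. **Segment-wise GMM** — periodically, the frame's gray-level distribution
   is decomposed into K in {1,2,3} Gaussian components (EM, k-means init,
   BIC model selection). The highest-mean component is the signal peak; each
   component defines a gray-level segment with intensity and area thresholds
   used to filter 8-connected regions. Retained background regions are
   subtracted from the event mask to suppress dominant static structures.
3. **Adaptive updates** — the global threshold theta_g reacts to the
   stability of bright-pixel prevalence, the local (duration) threshold
   theta_l to inter-frame Jaccard consistency, and the GMM refit period N to
   a mask-based SNR.
4. **Window transform** — detected intensities are remapped to 8-bit with
   background zeroed, compensating the amplitude gain of frame accumulation.

Only three parameters are user-facing: minimum area, minimum duration and
the initialization coefficient theta_g_init.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import FrameSequence

#: 8-connectivity structuring element for component labeling
_STRUCT8 = np.ones((3, 3), dtype=bool)

#: variance floor for degenerate mixture components
_REG_VAR = 1e-6

_SNR_CAP = 1e6


def _round_half_up(x):
    """Round half away from zero for nonnegative values."""
    return np.floor(x + 0.5)


@dataclass
class DetectorConfig:
    """The three user parameters plus fixed framework constants.

    ``min_area`` (pixels), ``min_duration`` (frames) and ``theta_g_init``
    are the user-facing knobs. ``accumulation_window`` echoes the
    preprocessing window m for the final 16->8-bit remapping.
    ``duration_reference`` converts the dimensionless local threshold
    theta_l in [0.2, 0.5] into frames; it defaults to 2*min_duration so the
    initial theta_l = 0.5 maps exactly to min_duration frames.
    """

    min_area: int = 29
    min_duration: int = 5
    theta_g_init: float = 2.0
    accumulation_window: int = 13
    theta_g_bounds: tuple[float, float] = (0.5, 6.0)
    duration_reference: int | None = None

    def __post_init__(self) -> None:
        if self.min_area < 1:
            raise ValueError("min_area must be >= 1")
        if self.min_duration < 1:
            raise ValueError("min_duration must be >= 1")
        if self.theta_g_init <= 0:
            raise ValueError("theta_g_init must be > 0")
        lo, hi = self.theta_g_bounds
        if not lo < hi:
            raise ValueError("theta_g_bounds must satisfy low < high")
        if self.duration_reference is None:
            self.duration_reference = 2 * self.min_duration


@dataclass
class FrameStats:
    mu: float
    sigma: float


@dataclass
class GmmFit:
    """A fitted per-frame intensity mixture, components sorted by mean."""

    K: int
    weights: np.ndarray
    means: np.ndarray
    stds: np.ndarray
    bic_per_K: dict[int, float]


@dataclass
class Segment:
    """Gray-level segment of one mixture component with its thresholds."""

    L: float
    H: float
    tau_g: float
    tau_a: int
    beta: float
    is_signal: bool


@dataclass
class DetectorState:
    """All mutable per-frame quantities of the adaptive core."""

    theta_g: float
    theta_l: float
    count_matrix: np.ndarray
    prev_temporal_mask: np.ndarray
    prev_rho: float
    period: int
    frames_since_fit: int
    event_mask: np.ndarray
    segments: list[Segment] = field(default_factory=list)


# ---------------------------------------------------------------------------
# temporal mask construction
# ---------------------------------------------------------------------------

def frame_stats(frame: np.ndarray) -> FrameStats:
    """Population mean and standard deviation over all pixels of a frame."""
    f = np.asarray(frame, dtype=np.float64)
    return FrameStats(mu=float(f.mean()), sigma=float(f.std()))


def instantaneous_mask(frame: np.ndarray, stats: FrameStats, theta_g: float) -> np.ndarray:
    """Candidate active pixels: intensity strictly above mu + theta_g*sigma."""
    return np.asarray(frame, dtype=np.float64) > stats.mu + theta_g * stats.sigma


def update_count_matrix(C: np.ndarray, inst_mask: np.ndarray) -> np.ndarray:
    """Consecutive-activation counter: +1 where active, reset to 0 elsewhere."""
    if C.shape != inst_mask.shape:
        raise ValueError("count matrix and mask shapes differ")
    return np.where(inst_mask, C + 1, 0)


def effective_duration_threshold(theta_l: float, duration_reference: int) -> int:
    """Convert the dimensionless local threshold to a frame count.

    ``max(1, round(theta_l * D_ref))``; with D_ref = 10, theta_l = 0.5 gives
    the default 5-frame persistence requirement.
    """
    return max(1, int(_round_half_up(theta_l * duration_reference)))


def temporal_mask(C: np.ndarray, duration_threshold: int) -> np.ndarray:
    """Pixels whose activation streak reaches or exceeds the threshold."""
    return C >= duration_threshold


# ---------------------------------------------------------------------------
# segment-wise Gaussian mixture estimation
# ---------------------------------------------------------------------------

def _weighted_kmeans_1d(v: np.ndarray, w: np.ndarray, K: int, n_iter: int = 15) -> np.ndarray:
    """Deterministic weighted Lloyd's algorithm on sorted 1-D values.

    Centers start at weighted quantiles, assignments use midpoint boundaries.
    """
    cw = np.cumsum(w)
    total = cw[-1]
    q = (np.arange(K) + 0.5) / K
    centers = v[np.searchsorted(cw, q * total)]
    for _ in range(n_iter):
        bounds = (centers[:-1] + centers[1:]) / 2.0
        labels = np.searchsorted(bounds, v)
        new = centers.copy()
        for k in range(K):
            sel = labels == k
            wk = w[sel]
            if wk.sum() > 0:
                new[k] = np.average(v[sel], weights=wk)
        if np.allclose(new, centers):
            centers = new
            break
        centers = np.sort(new)
    return centers


def _em_1d(
    v: np.ndarray, w: np.ndarray, K: int, tol: float = 1e-3, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Weighted EM for a K-component 1-D Gaussian mixture.

    ``v`` are the distinct gray levels of the frame and ``w`` their pixel
    counts, so the likelihood is identical to EM on the flattened pixel
    vector. Converges when the mean per-pixel log-likelihood increment
    drops below ``tol``. Returns (weights, means, stds, total log-likelihood).
    """
    n = w.sum()
    centers = _weighted_kmeans_1d(v, w, K)
    bounds = (centers[:-1] + centers[1:]) / 2.0
    labels = np.searchsorted(bounds, v)
    pi = np.empty(K)
    mu = np.empty(K)
    var = np.empty(K)
    for k in range(K):
        sel = labels == k
        wk = w[sel].sum()
        if wk == 0:
            pi[k] = 1.0 / n
            mu[k] = centers[k]
            var[k] = _REG_VAR
        else:
            pi[k] = wk / n
            mu[k] = np.average(v[sel], weights=w[sel])
            var[k] = np.average((v[sel] - mu[k]) ** 2, weights=w[sel]) + _REG_VAR
    pi /= pi.sum()

    prev_mean_ll = -np.inf
    total_ll = -np.inf
    for _ in range(max_iter):
        # E-step in log space
        log_prob = (
            -0.5 * ((v[:, None] - mu[None, :]) ** 2 / var[None, :]
                    + np.log(2 * np.pi * var[None, :]))
            + np.log(pi[None, :])
        )
        m = log_prob.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(log_prob - m).sum(axis=1))
        total_ll = float(np.dot(w, lse))
        resp = np.exp(log_prob - lse[:, None])
        # M-step with pixel-count weights
        wr = resp * w[:, None]
        Nk = wr.sum(axis=0)
        Nk = np.maximum(Nk, 1e-12)
        pi = Nk / n
        mu = (wr * v[:, None]).sum(axis=0) / Nk
        var = (wr * (v[:, None] - mu[None, :]) ** 2).sum(axis=0) / Nk + _REG_VAR
        mean_ll = total_ll / n
        if mean_ll - prev_mean_ll < tol:
            break
        prev_mean_ll = mean_ll
    return pi, mu, np.sqrt(var), total_ll


def fit_gmm(frame: np.ndarray) -> GmmFit:
    """Fit K in {1,2,3} Gaussian mixtures to a frame's gray levels, pick by BIC.

    The frame is flattened; EM runs on the exact value/count representation
    of the integer gray levels (identical likelihood to fitting the raw
    pixel vector). With fewer than 3 distinct gray levels the candidate K is
    capped at the number of distinct values; a constant frame degenerates to
    a single component.
    """
    flat = np.asarray(frame).ravel()
    counts = np.bincount(flat.astype(np.int64))
    v = np.flatnonzero(counts).astype(np.float64)
    w = counts[counts > 0].astype(np.float64)
    n = flat.size
    n_distinct = v.size

    if n_distinct == 1:
        return GmmFit(
            K=1,
            weights=np.array([1.0]),
            means=v.copy(),
            stds=np.array([math.sqrt(_REG_VAR)]),
            bic_per_K={1: float("nan")},
        )

    k_max = min(3, n_distinct)
    best = None
    bics: dict[int, float] = {}
    for K in range(1, k_max + 1):
        pi, mu, sd, ll = _em_1d(v, w, K)
        bic = -2.0 * ll + (3 * K - 1) * math.log(n)
        bics[K] = bic
        if best is None or bic < best[0]:
            best = (bic, K, pi, mu, sd)
    _, K, pi, mu, sd = best
    order = np.argsort(mu)
    return GmmFit(K=K, weights=pi[order], means=mu[order], stds=sd[order], bic_per_K=bics)


def _signal_lower_bound(fit: GmmFit, gmin: float, gmax: float) -> float:
    """Bayes decision boundary between the signal component and its neighbor.

    The first gray level above the neighbor's mean at which the weighted
    signal density overtakes the neighbor's. Keeps the signal segment from
    dipping into intensities the fitted mixture itself attributes to
    background when the components overlap heavily.
    """
    if fit.K < 2:
        return gmin
    xs = np.linspace(gmin, gmax, 2048)

    def logp(k: int) -> np.ndarray:
        return (
            np.log(fit.weights[k])
            - 0.5 * np.log(2 * np.pi * fit.stds[k] ** 2)
            - 0.5 * ((xs - fit.means[k]) / fit.stds[k]) ** 2
        )

    diff = logp(fit.K - 1) - logp(fit.K - 2)
    above = np.flatnonzero((diff >= 0) & (xs > fit.means[fit.K - 2]))
    if above.size == 0:
        return gmax
    return float(xs[above[0]])


def build_segments(
    fit: GmmFit, min_area: int, frame_range: tuple[float, float]
) -> list[Segment]:
    """Derive per-component gray-level segments and thresholds.

    Background components span ``[mu_k - 2*sd_k, mu_k + 2*sd_k]`` truncated
    to the frame's actual gray-level range. The highest-mean component is
    the signal peak; its segment runs from ``max(mu_K - 2*sd_K, Bayes
    boundary with the next component)`` up to the gray-level maximum —
    pixels brighter than the signal peak are a fortiori signal, and the
    lower bound must not include intensities the mixture itself classifies
    as background. Signal: beta = 0.5, area threshold min_area; background:
    beta = 2 and 10*min_area, making background-structure retention
    stricter so dominant non-signal structures can be subtracted from the
    event mask.
    """
    gmin, gmax = frame_range
    segments: list[Segment] = []
    for k in range(fit.K):
        is_signal = k == fit.K - 1
        beta = 0.5 if is_signal else 2.0
        sd = fit.stds[k]
        if is_signal:
            L = max(gmin, fit.means[k] - 2 * sd, _signal_lower_bound(fit, gmin, gmax))
            H = gmax
        else:
            L = max(gmin, fit.means[k] - 2 * sd)
            H = min(gmax, fit.means[k] + 2 * sd)
        segments.append(
            Segment(
                L=float(L),
                H=float(H),
                tau_g=float(max(2.0, beta * sd)),
                tau_a=min_area if is_signal else 10 * min_area,
                beta=beta,
                is_signal=is_signal,
            )
        )
    return segments


def segment_mask(frame: np.ndarray, segment: Segment) -> np.ndarray:
    """Binary mask of pixels inside the segment's gray-level interval."""
    f = np.asarray(frame, dtype=np.float64)
    return (f >= segment.L) & (f <= segment.H)


def filter_components(mask: np.ndarray, segment: Segment, frame: np.ndarray) -> np.ndarray:
    """Area- and intensity-filter the 8-connected components of a mask.

    A region survives iff its pixel count is >= tau_a and its mean intensity
    is >= L + tau_g (elevation above the segment floor). Returns the binary
    mask of retained pixels.
    """
    labels, n = ndimage.label(mask, structure=_STRUCT8)
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    idx = np.arange(1, n + 1)
    areas = ndimage.sum_labels(np.ones_like(labels), labels, idx)
    means = ndimage.mean(np.asarray(frame, dtype=np.float64), labels, idx)
    keep = (areas >= segment.tau_a) & (means >= segment.L + segment.tau_g)
    keep_ids = idx[keep]
    if keep_ids.size == 0:
        return np.zeros_like(mask, dtype=bool)
    return np.isin(labels, keep_ids)


def compose_event_mask(signal_regions: np.ndarray, background_regions: np.ndarray) -> np.ndarray:
    """Union of retained signal regions minus retained background structures."""
    return signal_regions & ~background_regions


# ---------------------------------------------------------------------------
# adaptive threshold updating
# ---------------------------------------------------------------------------

def bright_fraction(mask: np.ndarray) -> float:
    """Fraction of mask-on pixels in the frame."""
    return float(np.count_nonzero(mask)) / mask.size


def update_global_threshold(
    theta_g: float, delta_rho: float, bounds: tuple[float, float]
) -> float:
    """Multiplicative theta_g update driven by prevalence fluctuation.

    A fluctuating bright-pixel prevalence (|delta_rho| >= 0.001) tightens
    the threshold (x1.2) to suppress instability; stable prevalence relaxes
    it (x0.8) to recover weak signal. This negative feedback makes the
    threshold oscillate around the level where mask fluctuations sit at the
    0.001 scale; the clamp to ``bounds`` guards degenerate scenes.
    """
    factor = 1.2 if abs(delta_rho) >= 0.001 else 0.8
    return float(np.clip(theta_g * factor, bounds[0], bounds[1]))


def jaccard(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Inter-frame Jaccard index |A.B| / (|A+B| + 1e-9)."""
    if mask_a.shape != mask_b.shape:
        raise ValueError("mask shapes differ")
    inter = np.count_nonzero(mask_a & mask_b)
    union = np.count_nonzero(mask_a | mask_b)
    return inter / (union + 1e-9)


def update_local_threshold(theta_l: float, J: float) -> float:
    """Jaccard-driven local-threshold update, clamped to [0.2, 0.5].

    High inter-frame consistency (J > 0.7) raises the persistence demand
    (x1.3, capped at 0.5); otherwise it relaxes (x0.9, floored at 0.2).
    """
    if J > 0.7:
        return min(1.3 * theta_l, 0.5)
    return max(0.9 * theta_l, 0.2)


def mask_snr(frame: np.ndarray, mask: np.ndarray) -> float:
    """Mean intensity inside the mask over std outside it.

    Degenerate conventions: an empty mask returns the neutral value 1
    (shortest refit period); a constant outside region caps the ratio at a
    large finite value.
    """
    f = np.asarray(frame, dtype=np.float64)
    inside = f[mask]
    if inside.size == 0:
        return 1.0
    outside = f[~mask]
    if outside.size == 0:
        return _SNR_CAP
    sd = outside.std()
    if sd == 0:
        return _SNR_CAP
    return float(min(inside.mean() / sd, _SNR_CAP))


def update_estimation_period(snr: float) -> int:
    """GMM refit period from the mask SNR.

    alpha = clip(1 - 1/SNR, 0.85, 0.99); N = max(1, round(1/(1-alpha))),
    hence N in [7, 100]: better-separated frames are refit less often.
    """
    alpha = min(max(1.0 - 1.0 / snr, 0.85), 0.99)
    return max(1, int(_round_half_up(1.0 / (1.0 - alpha))))


# ---------------------------------------------------------------------------
# output mapping
# ---------------------------------------------------------------------------

def window_transform(frame: np.ndarray, mask: np.ndarray, m: int) -> np.ndarray:
    """Remap detected 16-bit intensities to 8-bit; background to zero.

    Inside the mask: ``round(I / min(m*255, 65535) * 255)`` clipped to
    [0, 255], compensating the ~m amplitude gain of frame accumulation while
    preserving intensity ordering.
    """
    denom = min(m * 255, 65535)
    out = np.zeros(frame.shape, dtype=np.uint8)
    vals = np.asarray(frame, dtype=np.float64)[mask] / denom * 255.0
    out[mask] = np.clip(_round_half_up(vals), 0, 255).astype(np.uint8)
    return out


# ---------------------------------------------------------------------------
# the per-frame driver
# ---------------------------------------------------------------------------

def run_detection(
    seq: FrameSequence, config: DetectorConfig | None = None
) -> tuple[FrameSequence, np.ndarray, pd.DataFrame]:
    """Run the adaptive detector over a preprocessed 16-bit sequence.

    Returns the 8-bit output sequence, the boolean detection-mask stack
    (event mask gated by the temporal mask), and a per-frame trace of the
    adaptive state (theta_g, theta_l, duration threshold, rho, Jaccard, SNR,
    refit period, refit flag).
    """
    if config is None:
        config = DetectorConfig()
    if seq.n_frames < 1:
        raise ValueError("empty sequence")
    T = seq.n_frames
    H, W = seq.frame_shape
    state = DetectorState(
        theta_g=config.theta_g_init,
        theta_l=0.5,
        count_matrix=np.zeros((H, W), dtype=np.int32),
        prev_temporal_mask=np.zeros((H, W), dtype=bool),
        prev_rho=0.0,
        period=1,
        frames_since_fit=0,
        event_mask=np.zeros((H, W), dtype=bool),
    )
    out = np.empty((T, H, W), dtype=np.uint8)
    masks = np.empty((T, H, W), dtype=bool)
    rows = []

    for t in range(T):
        frame = seq.frames[t]
        stats = frame_stats(frame)
        inst = instantaneous_mask(frame, stats, state.theta_g)
        state.count_matrix = update_count_matrix(state.count_matrix, inst)
        dur_thr = effective_duration_threshold(state.theta_l, config.duration_reference)
        tcm = temporal_mask(state.count_matrix, dur_thr)

        refit = t == 0 or state.frames_since_fit >= state.period
        if refit:
            # mixture parameters and segment thresholds update at the
            # estimation period; mask construction below runs every frame
            fit = fit_gmm(frame)
            frange = (float(frame.min()), float(frame.max()))
            state.segments = build_segments(fit, config.min_area, frange)
            state.frames_since_fit = 0
        else:
            state.frames_since_fit += 1
        sig = np.zeros((H, W), dtype=bool)
        bg = np.zeros((H, W), dtype=bool)
        for seg in state.segments:
            regions = filter_components(segment_mask(frame, seg), seg, frame)
            if seg.is_signal:
                sig |= regions
            else:
                bg |= regions
        state.event_mask = compose_event_mask(sig, bg)

        rho = bright_fraction(tcm)
        delta_rho = rho - state.prev_rho
        state.theta_g = update_global_threshold(
            state.theta_g, delta_rho, config.theta_g_bounds
        )
        J = jaccard(tcm, state.prev_temporal_mask)
        state.theta_l = update_local_threshold(state.theta_l, J)
        snr = mask_snr(frame, tcm)
        state.period = update_estimation_period(snr)

        support = state.event_mask & tcm
        out[t] = window_transform(frame, support, config.accumulation_window)
        masks[t] = support

        state.prev_rho = rho
        state.prev_temporal_mask = tcm
        rows.append(
            {
                "frame": t,
                "theta_g": state.theta_g,
                "theta_l": state.theta_l,
                "duration_threshold": dur_thr,
                "rho": rho,
                "jaccard": J,
                "snr": snr,
                "period_N": state.period,
                "refit_flag": refit,
            }
        )

    trace = pd.DataFrame(rows)
    out_seq = seq.with_frames(out, bit_depth=8)
    return out_seq, masks, trace
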