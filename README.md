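# astrocal

Adaptive detection of weak astrocytic Ca²⁺ events in low-SNR two-photon
imaging, with a ground-truth simulator and evaluation metrics.

## The problem

Astrocytic calcium transients in two-photon video are weak, transient and
strongly coupled to a bright static background; the recordings mix
photon-limited (Poisson) shot noise with Gaussian read noise. Fixed
thresholds either miss the dim events or drown in background noise, and
heavyweight event-parsing or learned-denoising pipelines bring many tunable
parameters. This package implements a low-parameter front-end detector:
only the minimum event area, the minimum event duration and a global
threshold initialization coefficient are user-facing.

## The method

**Preprocessing** stabilizes input statistics: the 8-bit video is promoted
to 16 bits, summed over a sliding window of m = 13 frames (matched to the
~333 ms minimum event duration at 40 Hz; boosts events ≈ m-fold while
i.i.d. noise grows only √m), the temporal-average static background is
subtracted, and each frame is smoothed with an isotropic Gaussian (σ = 1 px,
mirror padding). An optional generalized Anscombe transform can be inserted
after accumulation to stabilize the Poisson–Gaussian variance.

**Detection** couples four per-frame mechanisms:

1. *Temporal mask* — pixels with intensity > μₜ + θ_g·σₜ (frame-wise mean
   and standard deviation) increment a per-pixel consecutive-activation
   counter Cₜ; pixels with Cₜ ≥ round(θ_l·D_ref) form the temporal mask,
   enforcing persistence.
2. *Segment-wise Gaussian mixture* — periodically, the frame's gray-level
   distribution is decomposed into K ∈ {1,2,3} Gaussian components (EM,
   k-means initialization, tolerance 10⁻³, ≤ 100 iterations; K chosen by
   BIC). The highest-mean component is the signal peak. Each component
   defines a gray-level segment with an intensity threshold
   τ_g = max(2, β·σ_k) and an area threshold τ_a (min_area for the signal
   component, 10·min_area for background components); 8-connected regions
   failing either are discarded, and retained background structures are
   subtracted from the event mask.
3. *Adaptive updates* — θ_g tightens (×1.2) when the bright-pixel
   prevalence ρₜ fluctuates (|Δρ| ≥ 0.001) and relaxes (×0.8) when stable;
   θ_l follows the inter-frame Jaccard similarity (×1.3 above 0.7, ×0.9
   otherwise, clamped to [0.2, 0.5]); the mixture refit period
   N = max(1, round(1/(1−α))) with α = clip(1 − 1/SNRₜ, 0.85, 0.99) follows
   a mask-based SNR, so N ∈ [7, 100].
4. *Window transform* — detected intensities are remapped to 8 bits by
   round(I/min(m·255, 65535)·255) with background zeroed, undoing the
   accumulation gain.

**Evaluation** provides block-statistics noise, wavelet-MAD noise
(σ̂ = MAD/0.6745 of the diagonal detail band), local-statistics SNR, a
ground-truth reference SNR 10·log₁₀(Σ truth²/Σ(truth−est)²), and the Dice
coefficient 2|A∩B|/(|A|+|B|).

**The simulator** builds videos with known ground truth: a procedural
cellular-skeleton background, moving Gaussian spots with rise/decay
envelopes (97 events per minute by default), weighted fusion
(0.2 signal / 0.8 background) and calibrated Poisson–Gaussian noise.

## Worked example

```python
import numpy as np
from astrocal import (SimulationConfig, simulate, preprocess, run_detection)
from astrocal.metrics import align_truth, dice, reference_snr

cfg = SimulationConfig(duration=15.0, n_events=24, seed=1)   # 15 s at 40 Hz
noisy, truth = simulate(cfg)          # 600-frame 8-bit video + ground truth
pre = preprocess(noisy)               # 588-frame 16-bit stabilized stack
out, masks, trace = run_detection(pre)

tr = align_truth(truth.mask, 13, 1, pre.n_frames)
ts = align_truth(truth.clean_signal, 13, 1, pre.n_frames)
print(f"Dice          {dice(tr, out.frames > 0):.3f}")
print(f"output SNR    {reference_snr(ts, out.frames):+.2f} dB")
print(f"input SNR     {reference_snr(ts, pre.frames):+.2f} dB")
```

prints

```
Dice          0.674
output SNR    +4.37 dB
input SNR     -11.05 dB
```

so the adaptive detector lifts this replicate from an unusable −11 dB input
to a +4.4 dB segmented output with Dice 0.67 against ground truth. The
`trace` DataFrame logs θ_g, θ_l, ρ, Jaccard, SNR and the refit period for
every frame.

A command-line interface mirrors the library:
`astrocal simulate|preprocess|detect|evaluate|run-experiment|run-sensitivity`
(see `astrocal --help`).

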