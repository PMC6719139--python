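# Methods

This note records the model assumptions, the numerical choices made where
the design was genuinely open, and what the synthetic-data generator does
and does not emulate.

## Signal model and assumptions

Cardiac ejection produces a quasi-periodic vibration at the sternum. On the
dorsoventral acceleration axis (aZ) each cycle carries an S1 complex — the
aortic-opening (AO) maximum followed by the isovolumetric-contraction (IC)
trough — and a weaker S2 complex (aortic closing AC / mitral opening MO)
roughly 300 ms later. The longitudinal gyration axis carries the same
S1-locked signature with opposite polarity (the beat rides on −gX) and much
weaker S2 crosstalk. The algorithm assumes a stationary, supine subject:
motion artifact beyond respiration is out of scope. The AO point is treated
as a surrogate for the ECG R-peak; in the simulator the two are separated
by a fixed 100 ms pre-ejection delay, far below the 250 ms evaluation
tolerance, so the surrogate assumption never dominates the scoring.

## Rolling-buffer replay

Measurements are emitted at 1 Hz over the most recent 10 s of data; nothing
is emitted before a full buffer has accrued, and recordings shorter than
2 s (the smallest analysis window) are rejected. Non-monotone or duplicate
timestamps — ordinary serial-acquisition artifacts — are dropped with a
warning. Acquisition gaps that leave a buffer empty are warned about and
skipped rather than treated as fatal. Timestamps are absolute seconds from
acquisition start and every downstream beat timestamp shares that clock.

## Preprocessing

Each buffered channel is resampled with shape-preserving (pchip) cubic
interpolation onto the uniform grid of integer multiples of 1/fs
(fs = 200 Hz by default) that falls inside the buffer. Aligning the grid to
absolute multiples of 1/fs means overlapping buffers evaluate the identical
grid points, so a beat found in ten different buffers lands on the same
timestamp and cross-buffer deduplication is exact. The high-pass is an
ideal (brick-wall) projection computed per buffer: FFT, zero all bins below
0.4 Hz, inverse FFT. A projection is idempotent and removes baseline wander
completely; the price is Gibbs ringing near buffer edges, which the beat
stage absorbs with an adaptive amplitude floor (below). Filtering is
per-buffer rather than whole-record to match the real-time architecture.
No anti-alias filter precedes downsampling, so resampling below ~100 Hz is
a documented caveat of the rate-sweep harness.

## VarWin

The enhancement operator has no published closed form, so one was fixed
here and frozen against a naive O(n·w) oracle (bit-exact equality is part
of the acceptance suite):

* **HR variant** (centered, 250 ms span): V[i] = R[i]·G[i], where R is the
  windowed range and G gates on the presence of at least one strict local
  maximum and one strict local minimum strictly inside the window
  (plateaus count once, at their first sample). Constants and monotone
  ramps map to zero; the output is scale-covariant and offset-invariant.
* **Beat variant** (strictly forward-looking): the range is *anchored* at
  the current sample, V[i] = (x[i] − min x[i..i+w−1])·G[i], with the gate
  allowing the current point itself to serve as the maximum. Anchoring is
  the design choice that makes the response peak exactly at the AO sample:
  a plain forward max−min is constant on a ~span-wide plateau ahead of the
  complex, which destroys the 25 ms SCG/GCG coincidence test as soon as
  noise decides the argmax within the plateau.
* **Suppression**: the beat variant is zeroed for one span (250 ms)
  directly after every raw-signal minimum whose prominence reaches 60 % of
  the signal range. This mutes features that follow a deep trough — the
  rapid-ejection peak after IC, and an AC complex of deceptive amplitude —
  while noise troughs (far below the prominence floor) trigger nothing.
  The prominence-gated form keeps the operator usable at realistic SNR;
  suppressing after *every* minimum would blank the whole record once
  noise is present. With a 250 ms suppression span, an S1 trough can mask
  the next AO only above ~170 bpm, outside the 36–140 bpm design range.

## Heart-rate estimation

Per axis and trailing window of n ∈ {2..10} s, the mean-removed enhanced
waveform is autocorrelated (unbiased normalization). Peaks are sought for
lags between 60/200 s and min(60/30, n/2) s — capping at half the window
keeps the unbiased estimate out of its high-variance tail, which silently
removes the 2 s and 3 s windows from play below ~45 bpm. Acceptance rules,
in order:

1. prominence ≥ 0.3 of the zero-lag value (otherwise the window abstains —
   an absent estimate, not an error; white noise abstains ≥ 95 % of runs);
2. amplitude ≥ 0.9 of the strongest candidate. This step realizes the
   AO/AC amplitude filtering: S1–S2 cross-terms produce autocorrelation
   peaks at the S2 offset whose height is at most 2ab/(a²+b²) of the true
   BTB peak (0.8 for the worst case b = a/2 with the offset at half the
   BTB), so they always fall below the 0.9 floor;
3. harmonic support: the shortest surviving lag whose integer multiples
   (±5 %, up to 0.9 of the search cap) all carry autocorrelation peaks
   wins. This resists half-rate errors (a halved lag lacks peaks at its
   odd multiples) and double-rate errors (the true lag is shorter and
   passes). If no candidate passes, the window abstains.

The chosen lag is refined by three-point parabolic interpolation (the
5 ms lag quantization at 200 Hz would otherwise cost ~1.5 bpm at 132 bpm).
Window estimates fuse by weighted mean with weights 1/n; "window size" is
taken in seconds (at fixed fs the normalized weights are identical either
way). Axis consolidation follows the 10 bpm decision table; equidistant
ties and disagreements before any previous measurement exists resolve to
the SCG value, the axis with the more mature analysis path. The
previous-measurement feedback engages only after the first dual agreement,
so an early one-axis outlier cannot seed the feedback loop.

## Beat identification

Beat candidates are the local maxima of the beat-variant output, admitted
greedily in descending amplitude at a minimum spacing of 0.75 × 60/HR
seconds using the buffer's fused HR as prior (buffers without an HR emit no
candidates; neighbouring buffers cover their beats). Two further choices:

* an adaptive floor at 30 % of the window's strongest peak rejects Gibbs
  edge ringing and residual AC echoes — echoes of relative amplitude 0.5
  still pass this floor but are then excluded by the spacing constraint,
  since 0.75 of the BTB exceeds the 0.3 s S2 offset for all rates below
  150 bpm;
* the minimum-spacing rule is treated as the BTB-fit filter; no second
  interval test is applied.

Candidates pooled over all windows and buffers are clustered at 100 ms
(single linkage, cluster centroid) — safely below the shortest plausible
BTB (~0.3 s at 200 bpm) and above grid granularity; because all buffers
share one absolute grid the clusters are in practice single points. SCG
candidates are then vetoed by the gyration axis: nearest-first one-to-one
matching against −gX candidates at 25 ms, SCG timing authoritative. The
gyroscope can only remove beats, never add them. When the gyroscope
channel is missing entirely, a permissive configuration flag passes SCG
candidates unverified (strict discard is the default). A final greedy pass
enforces the global physiological minimum spacing. Instantaneous heart
rate is the inverse BTB, timestamped at the later beat of each pair.

## ECG reference

Pan-Tompkins with the canonical constants: 5–15 Hz band-pass, derivative,
squaring, 150 ms moving-window integration, a 2 s learning phase, dual
adaptive thresholds (SPKI/NPKI with 0.125/0.875 updates) and search-back at
1.66 × the running RR average. The band-pass is a zero-phase Butterworth
cascade rather than the original fixed-point difference equations — the
original's constants are exact only at 200 Hz and introduce a rate-dependent
group delay; the zero-phase form behaves identically across the sweep rates
and detections are anyway snapped to the raw local maximum within ±50 ms.
A 200 ms refractory period is enforced on the final peak list.

## Evaluation

Matching is an optimal one-to-one assignment (maximum matches, then
minimum total offset, via the Hungarian algorithm with an infeasibility
cost) rather than nearest-first greedy: greedy is not cardinality-optimal
(two detections can be forced onto one reference), and TP + FN = n_ref —
the identity the sensitivity definition relies on — holds for any
one-to-one assignment, so the optimal one is the canonical choice and is
verified against exhaustive search. Instantaneous-rate pairs come from
adjacent true-positive runs only; pairs broken by an intervening FP/FN are
dropped. For averaged-rate agreement the ECG reference at each refresh
instant is the mean inverse R-R interval over the trailing 10 s window,
mirroring how the detector's own output summarizes its buffer. Limits of
agreement use the conventional 1.96 multiplier and the sample (n−1)
standard deviation.

## Synthetic data

The generator draws RR intervals as
RR(t) = baseRR(t)·(1 + σ_HRV ε)·(1 + m sin 2π f_resp t) with Gaussian ε,
σ_HRV = 0.03 and 5 % respiratory modulation at 0.25 Hz by default; baseRR
is either constant (rest) or an exponential recovery profile (e.g.
140 → 70 bpm, τ = 60 s). Channels are sums of per-beat templates: Gaussian
PQRST bumps for ECG; for aZ and gX an asymmetric Gabor packet (18 Hz
carrier, 12 ms leading / 50 ms trailing envelope) whose first extremum is
the dominant AO maximum, plus an S2 packet at +300 ms with relative
amplitude 0.5 (aZ) and 0.2 (gX) — the crosstalk asymmetry the fusion logic
exploits. Baseline wander sits strictly below 0.4 Hz; broadband Gaussian
noise is scaled to the cardiac-signal RMS (15 dB SNR default); timestamps
get clipped Gaussian jitter (0.5 ms), bounded below half the sample
spacing so monotonicity is guaranteed. Trailing beats whose AO complex
would spill past the end of the recording are not annotated, keeping the
ground truth consistent with the rendered waveform. Identical seed and
configuration give bit-identical recordings.

What the generator does **not** emulate: motion artifact beyond
respiration-band wander, beat-to-beat morphology variability, sensor
misplacement, amplitude modulation by respiration, or pathological rhythms.
Passing tests therefore demonstrate correctness of the algorithmic chain
under the stated signal model, not clinical performance on real subjects.

## Problem sizes

The test suite and the acceptance script use 60 s recordings (ten seeds by
four rates in the recovery surface; three seeds in stochastic checks) and
120 s recordings for the rest/recovery agreement battery — sizes chosen so
each battery pools on the order of 10²–10³ beats, enough for rate
estimates at the asserted tolerances while keeping a full run in tens of
seconds.

## Known limitations

* The brick-wall filter's edge ringing is handled statistically (adaptive
  floor, cross-buffer redundancy), not removed; a tapered window would
  trade ringing for passband distortion and is deliberately not applied.
* Suppression after prominent minima assumes the AO rise is not preceded
  by a deep trough within 250 ms; above ~170 bpm with a fixed 300 ms S2
  offset this assumption fails.
* In strict mode a recording whose gyroscope is pure noise loses most
  beats to the 25 ms veto (by design — the veto is the noise-rejection
  mechanism); the permissive flag exists only for a *missing* channel.
* The instantaneous-rate r² against the ECG reference is bounded by the
  5 ms timestamp quantization of both beat streams at 200 Hz.
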