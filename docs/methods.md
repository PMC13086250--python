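# Methods

This note documents the models, estimators and design choices behind
`dyadtune`, what the synthetic-data generator does and does not emulate,
and the numerical conventions used throughout.

## Stimuli

Each chord-progression exemplar is a 15 s, 140 BPM, four-track score. The
harmonic skeleton is the ii–V–I–vi progression in seventh chords (m7, dom7,
maj7, m7) played as half notes in close position rooted in octave 3; the
bass doubles the roots an octave below in quarter notes; the melody is half
notes drawn from the key's major pentatonic scale following one of four
fixed contour templates; drums are a ride cymbal on every quarter note and
a kick on every half note. At 140 BPM a 15 s clip holds 17.5 half-note
slots: three full ii–V–I–vi cycles (12 slots), then ii, V, and the tonic
major seventh sustained 3 s to the end, so every exemplar resolves on I.
The four melody templates and the chord voicings are package conventions —
the construct that matters downstream is "grid-locked consonant progression
vs. the same notes shuffled", not any particular tune.

The control condition displaces each tonal (melody/chords/bass) onset by an
independent uniform draw of magnitude 0.25–2 s with random sign, circular
within the clip; drums are untouched. Jitter (rather than onset
permutation, which is available as `mode="permute"`) matches the stated
displacement range directly; either destroys harmonic simultaneity and
metric placement while preserving the per-track multiset of
(pitch, duration) pairs. Rendering uses additive harmonic synthesis with
ADSR envelopes for tonal tracks, a band-passed noise burst (80 ms decay)
for the ride and a 60 Hz decaying sine for the kick; note segments that
would spill past the clip wrap circularly so shuffling conserves per-note
energy exactly. Rendering is bit-deterministic given the patch seed.

## Acoustic features

All features start from a magnitude STFT with 46 ms Hann windows and a
10 ms hop. The fluctuation spectrum groups STFT bins into 40 log-spaced
bands (40 Hz–Nyquist), mean-removes and Hann-tapers each band envelope,
Fourier-transforms along time (4× zero-padding for grid resolution) and
sums magnitudes over bands, keeping the 0.5–10 Hz rhythmic band — the
range of beat-rate periodicities (30–600 BPM). Modulation below 0.5 Hz
(e.g. the 0.29 Hz chord-cycle rate of these stimuli) is phrase-level
structure, not rhythm, and is excluded; without the taper its spectral
skirt would dominate the band edge.

- **Peak magnitude / peak-to-median**: maximum of the fluctuation
  magnitude and its ratio to the median.
- **Entropy**: Shannon entropy of the normalized magnitudes divided by
  log(#bins), scale-free in [0, 1] and invariant to audio gain.
- **Tempo**: the beat-range (0.5–5 Hz) modulation frequency maximizing
  magnitude plus half the magnitude one octave up (harmonic support),
  weighted by a log-Gaussian preference centered at 120 BPM (σ = 1
  octave) — the standard perceptual-tempo prior. On these stimuli the
  grid rate 2.333 Hz = 140 BPM falls exactly on the 1/15 Hz analysis grid.
- **Pulse clarity**: the onset envelope is the summed positive spectral
  flux per frame; its autocorrelation, normalized by lag 0, is weighted by
  a log-Gaussian resonance curve centered at 0.55 s (σ = 1.2 octaves,
  the perceptual tactus preference) and the maximum over lags 0.2–2 s is
  reported.
- **Timbre**: spectral flux is the mean L2 norm of positive differences
  between consecutive L1-normalized frames; RMS is reported in dBFS
  (full scale = 1); the centroid is the per-frame energy-weighted mean
  frequency, averaged over non-silent frames.

**Known limitation.** On re-synthesized stimuli the chord-progression
condition is *strictly* grid-quantized, so it is more periodic than its
shuffled control under any autocorrelation-family estimator, and measured
pulse clarity comes out higher for the progression condition, not lower.
Published comparisons of hardware-synthesized originals can show the
opposite ordering; that ordering depends on the original audio (attack
shapes, mixing, masking of drum transients by sustained chords) and on
toolbox internals, and is not recoverable from note-level re-synthesis.
The direction tests for fluctuation peak, peak-to-median and entropy are
robust to this; the pulse-clarity direction is not, and the corresponding
acceptance check documents the discrepancy rather than hiding it.

## Synthetic dyads

The generator's defaults define the study conditions: 29 abstract channels
per participant, 30 Hz sampling, three wavelengths (780/805/830 nm), eight
2 min runs of four 15 s task blocks (one per condition of the 2×2
face × chord design, order shuffled per run) alternating with 15 s rests —
16 min total.

Per channel, OxyHb is the sum of (i) HRF-convolved condition boxcars scaled
by ground-truth β (defaults: ten "signal" channels with β = 1.0 for
face-chord and 0.5 for the other conditions, zero elsewhere), (ii) a
systemic waveform shared across the participant's channels with mild
per-channel gains (0.8–1.2): cardiac ~1 Hz (amp 0.25), respiratory
~0.25 Hz (0.2), Mayer ~0.1 Hz (0.3) sinusoids plus unit-normalized
random-walk drift (0.2), (iii) the cross-brain coupled component, and
(iv) white noise (SD 0.3). DeOxyHb is −γ times the evoked parts (γ = 1/3)
plus its own, 2.5×-attenuated systemics and half-SD noise — a
physiologically shaped anticorrelation without any claim of fidelity.
Chromophores map to optical densities through a fixed 3×2 extinction
matrix whose shape follows the standard compiled hemoglobin spectra
(HbR dominant below the ~805 nm isosbestic point, HbO above).

The coupled component is a Gaussian process band-limited around a target
period (default 15 s, Gaussian spectral window, 25% relative bandwidth),
built as √r·shared + √(1−r)·own for the two partners so their components
correlate at exactly r (default 0.6), gated to the designated condition's
blocks (default face-chord only) on three designated channel pairs, with
SD 0.4. Amplitudes are in the same arbitrary units as β.

What the generator does **not** emulate: optode geometry and scalp/skull
photon transport, motion artifacts, heteroscedastic or 1/f channel noise,
inter-individual HRF variability, and any anatomical meaning of channel
indices. Passing parameter-recovery tests therefore shows the pipeline is
correct under its own forward model, not that it is robust to everything
real data contains.

## Preprocessing

Beer–Lambert inversion solves od = ε·[ΔHbO, ΔHbR]ᵀ per channel and
timepoint by least squares (unit pathlength, relative units); matrices with
condition number above 10⁶ are rejected. Detrending decomposes each
channel with the orthogonal symlet `sym4` and zeroes the approximation
band; the decomposition level is chosen so the removed band lies beyond
the 128 s cutoff period (level 11 at 30 Hz; the approximation then covers
periods > 137 s, leaving the 120 s condition-cycle untouched). `sym4` is
used because its short support keeps level 11 within the maximum useful
level for 16 min recordings.

The PCA global filter centers the channel × time matrix, takes its SVD and
projects out components whose unit-norm spatial loadings are near-uniform:
|mean loading|·√n ≥ 0.7. Only leading components are examined, up to 80%
of total variance. The 0.7 threshold equals √(k/n) for a component loading
equally on half the channels — a task response confined to the default 10
of 29 channels scores 0.59 and survives, while shared physiology (gains
0.8–1.2 across all channels) scores ≈ 0.99 and is removed. The output is
exactly orthogonal to every removed component.

HbDiff defaults to OxyHb − deOxyHb. Since task-evoked deOxyHb is
negative-going, the difference is the reliability-optimizing combination
(amplitude (1+γ)β); the literature's wording for this construct sometimes
says "sum", so `mode="sum"` is available and recorded in provenance.
Every stage appends its name and parameters to the series' provenance list.

## GLM

The canonical HRF is h(t) = g(t; mode 6 s) − (1/6)·g(t; mode 16 s) with
unit-rate gamma densities, sampled over 32 s and peak-normalized, so the
response peaks at 6 s with a 16 s undershoot at ratio 6:1. Designs contain
one HRF-convolved boxcar per condition plus an intercept; no drift columns
by default, because detrending precedes the GLM. Fitting is plain OLS per
channel. The second level is a one-sample t across participants of a
per-participant contrast of betas, two-sided, df = n−1, uncorrected per
channel (Benjamini–Hochberg available but off by default, matching the
uncorrected-map convention for block-design fNIRS). Ratings enter as a
covariate by regressing participant contrast values on the same contrast
applied to their per-condition mean ratings (nonanswers excluded);
run-level ratings are averaged within condition.

## Cross-brain coherence

Scales are geometric: periods 2.5 s·2^(k/4), k = 0…15 — 4 octaves × 4
voices spanning 0.4 Hz downward, adjacent periods differing by exactly
2^(1/4). The stated 0.025 Hz lower edge is the open endpoint of the last
voice (largest sampled period 33.6 s); both readings of the "2.5 s"
spacing convention are recorded in `ScaleSet.meta`. The CWT kernel is the
order-4 complex Gaussian (`cgau4`), an analytic derivative-of-Gaussian
wavelet; coefficients are computed by FFT convolution.

Signals are first residualized against the full task design so
block-evoked responses cannot masquerade as coupling; the stochastic
coupled process survives this projection because it is block-gated noise,
not a boxcar. Coherence is the Pearson correlation of partner coefficient
*magnitudes* (phase-insensitive; real-part correlation available by
option) over the concatenated samples of one condition's blocks. A
cone-of-influence mask excludes samples within one e-folding time
(period/√2) of the *recording* edges. Block edges are deliberately not
masked: at a 15 s analysis period one e-folding exceeds half a 15 s block,
so block-edge masking would leave no samples at the scales of interest;
the cost is some cross-condition leakage of coupling through the wavelet's
time support, which biases condition contrasts conservatively toward zero.

Band comparisons average coherence over scales with periods in 10–20 s per
(dyad, channel-pair) unit and use a paired t across units; the pairing
unit and df are reported with every comparison. The scrambled-pair null
resamples partner assignments as derangements (partner A of dyad i with
partner B of dyad j ≠ i) and reruns the identical pipeline; wavelet
coefficients depend only on each participant's own data and are cached
across draws.

## Behavior

Ratings of 0 are nonanswers and excluded everywhere. Observations for the
omnibus and post hoc tests are per-participant condition means (five
groups: four conditions plus baseline; retroactive baseline ratings
included by default). Kruskal–Wallis uses tie-corrected ranks with a
chi-square reference (df = groups − 1). Games–Howell uses
q = |Δmean| / √((s₁²/n₁ + s₂²/n₂)/2), Welch–Satterthwaite df, and p-values
from scipy's studentized-range distribution (numerical integration of the
distribution function, no table lookup). Bonferroni pairwise t-tests are
pooled-variance with adjusted p = min(1, p·#pairs). The synthetic ratings
generator draws integer ratings from a latent rater offset (SD 0.5) plus
condition shifts (face-chord 3.4, face-no-chord 2.6, no-face-chord 2.1,
no-face-no-chord 1.7, baseline 2.0) plus noise (SD 0.8), clipped to
[0, 5] — the qualitative ordering of the study with realistic overlap.

## Numerical conventions and problem sizes

All randomness flows from explicit integer seeds; experiment-level seeds
spawn per-dyad seeds via `numpy.random.SeedSequence`, and the pipeline
derives per-stage seeds from one root seed (CRC of the stage label folded
in, kept below 2³¹). Degenerate inputs are flagged rather than silently
dropped: zero-variance groups, empty conditions, all-zero spectra and
silent audio produce explicit flags, sentinels (−∞ dBFS) or rejections.
Validation and recovery tests run at the study's native geometry
(29 channels, 30 Hz, 16 min) with 20 dyads for the power-style checks and
2–3 dyads for smoke tests — sizes at which the whole suite completes in
about a minute of compute.
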