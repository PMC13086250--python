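# dyadtune

Analysis toolkit for dyadic fNIRS hyperscanning experiments on shared music
listening: do consonant chord progressions, heard during live face-to-face
gaze, upregulate social neural systems and cross-brain synchrony?

The package implements the complete computational chain of such a study as a
tested, reusable library:

1. **Stimulus synthesis** (`dyadtune.stimulus`) — procedurally composes
   15 s, 140 BPM exemplars of a ii–V–I–vi chord progression in each of the
   12 major keys (piano melody + chords, bass, ride/kick drums), plus
   note-shuffled controls in which every tonal onset is displaced by a
   random 0.25–2 s offset while the drum grid stays untouched, and renders
   them to WAV/MIDI.
2. **Acoustic features** (`dyadtune.features`) — rhythm and timbre
   descriptors from 46 ms/10 ms STFT analysis: fluctuation-spectrum peak
   magnitude, peak-to-median ratio, normalized entropy, pulse clarity,
   tempo, spectral flux, RMS (dBFS) and spectral centroid, with a pooled
   two-sample *t* comparison between conditions.
3. **Synthetic dyads** (`dyadtune.simulate`) — dyadic three-wavelength
   (780/805/830 nm) optical-density recordings at 30 Hz over 29 channels
   per participant, built from HRF-convolved block responses with known
   per-condition amplitudes β, systemic physiology (cardiac, respiratory,
   Mayer waves, drift), channel noise, and a band-limited cross-brain
   coupled process injected only in chosen conditions and channel pairs at
   a chosen correlation *r* — so every downstream stage can be validated by
   parameter recovery.
4. **Preprocessing** (`dyadtune.preprocess`) — modified Beer–Lambert
   inversion (OD → ΔHbO/ΔHbR), wavelet detrending, a PCA spatial
   global-mean filter for systemic components, and the HbDiff analysis
   signal.
5. **GLM** (`dyadtune.glm`) — block-design GLM with the canonical
   double-gamma HRF, per-channel betas, one-sample group contrasts, and
   connectedness ratings as covariates.
6. **Cross-brain coherence** (`dyadtune.coherence`) — complex-Gaussian CWT
   over 16 scales (4 octaves × 4 voices, 0.4–0.025 Hz, shortest period
   2.5 s), task-regressor removal, per-scale correlation of partner
   coefficient magnitudes over concatenated condition blocks, 10–20 s band
   contrasts, and a scrambled-pair (derangement) null.
7. **Behavior** (`dyadtune.behavior`) — 0–5 connectedness ratings
   (0 = nonanswer): Kruskal–Wallis omnibus, Games–Howell post hoc tests,
   Bonferroni-corrected pairwise *t*.

A `dyadtune` CLI wraps each stage plus an end-to-end orchestrator
(`dyadtune run`) that writes a provenance manifest; one root seed derives
every stage seed, so a whole synthetic experiment reproduces bit-identically.

## The core quantities

Per channel *c* and participant, the first-level model is

    y_c(t) = Σ_k β_{c,k} (boxcar_k ⊗ h)(t) + intercept + ε,

with *h* the double-gamma HRF (peak 6 s, undershoot 16 s, ratio 6:1) and
one boxcar per condition of the 2×2 design (face × chord progression; four
15 s task blocks alternating with 15 s rests per 2 min run, eight runs).
Cross-brain coherence between partners A and B at wavelet scale *s* and
condition *k* is

    C_{AB}(s, k) = corr( |W_A(s, t)|, |W_B(s, t)| ),  t ∈ blocks of k,

computed on residuals after projecting out the task regressors, and
compared between conditions as the mean over scales with periods in
10–20 s, paired across (dyad, channel-pair) units.

## Worked example

```python
from dyadtune import features, stimulus

score = stimulus.compose_chord_progression(key="C", melody_id=1)
clip = stimulus.render_audio(score)          # 15.3 s mono at 22,050 Hz
row = features.extract_features(clip)
print(f"tempo    {row.tempo_bpm:7.1f} BPM")
print(f"clarity  {row.pulse_clarity:7.3f}")
print(f"entropy  {row.fluct_entropy:7.3f}")
print(f"rms      {row.rms_dbfs:7.2f} dBFS")
```

prints

```
tempo      140.2 BPM
clarity      0.603
entropy      0.933
rms        -19.10 dBFS
```

The estimated tempo recovers the composed 140 BPM grid; pulse clarity near
0.6 reflects the fully quantized beat; the fluctuation entropy near 0.93
shows modulation energy concentrated at the metrical rates (the shuffled
control scores higher, ~0.95, because its tonal onsets spread modulation
energy across the rhythmic band).

A two-dyad synthetic experiment end to end:

```bash
dyadtune run --seed 1 --dyads 2 --outdir out/
```

writes the feature comparison table, per-channel contrast table, true-pair
and scrambled-pair coherence spectra, rating statistics and a
`manifest.json` with the config hash and output checksums.

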