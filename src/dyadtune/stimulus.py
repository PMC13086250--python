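"""Procedural chord-progression stimuli.

Composes 15 s musical exemplars built on the ii-V-I-vi progression
(supertonic, dominant, tonic, submediant seventh chords) in each of the 12
major keys, derives note-shuffled controls that destroy the harmonic and
tonal-rhythmic structure while leaving the drum pattern untouched, and
renders scores to mono audio with a small additive synthesizer.

Each chord-progression exemplar has four tracks at 140 BPM:

* ``melody`` — half notes drawn from the key's major pentatonic scale,
  following one of four fixed contour templates;
* ``chords`` — close-position seventh chords (ii7, V7, Imaj7, vi7) as half
  notes, cycling and resolving on the tonic major seventh;
* ``bass`` — quarter notes on the chord roots, one octave below;
* ``drums`` — ride cymbal on every quarter note, kick drum on every half
  note.

The no-chord-progression control jitters every tonal note onset by a random
0.25-2 s offset (circular within the clip) so that the pitch content, note
durations and drum grid are preserved but harmonic simultaneity and metric
placement are not.
"""
from __future__ import annotations

import json
import math
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal as _signal
from scipy.io import wavfile

__all__ = [
    "KEYS",
    "TRACKS",
    "TONAL_TRACKS",
    "MELODY_TEMPLATES",
    "NoteEvent",
    "StimulusScore",
    "SynthPatch",
    "AudioClip",
    "compose_chord_progression",
    "shuffle_tonal_tracks",
    "build_stimulus_sets",
    "default_patch",
    "render_audio",
    "score_to_json",
    "score_from_json",
    "write_midi",
    "write_wav",
    "read_wav",
]

KEYS = ("C", "Db", "D", "Eb", "E", "F", "Gb", "G", "Ab", "A", "Bb", "B")
KEY_PCS = {k: i for i, k in enumerate(KEYS)}

TRACKS = ("melody", "chords", "bass", "drums")
TONAL_TRACKS = ("melody", "chords", "bass")

CONDITION_CP = "chord_progression"
CONDITION_NCP = "no_chord_progression"

# Roman-numeral progression: (label, root interval above tonic, quality).
PROGRESSION = (("ii", 2, "m7"), ("V", 7, "dom7"), ("I", 0, "maj7"), ("vi", 9, "m7"))
_QUALITY_INTERVALS = {"m7": (0, 3, 7, 10), "dom7": (0, 4, 7, 10), "maj7": (0, 4, 7, 11)}

# Major-pentatonic scale degrees -> semitones above the tonic.
_PENTATONIC = {1: 0, 2: 2, 3: 4, 5: 7, 6: 9}

# Four fixed half-note contour templates over pentatonic degrees {1,2,3,5,6};
# each is cycled over the half-note grid of the clip.
MELODY_TEMPLATES = {
    1: (3, 2, 1, 2, 3, 5, 6, 5),
    2: (5, 6, 5, 3, 2, 3, 2, 1),
    3: (1, 2, 3, 5, 6, 5, 3, 2),
    4: (6, 5, 3, 2, 1, 2, 3, 5),
}

# General MIDI percussion codes.
RIDE_PITCH = 51
KICK_PITCH = 36

_CHORD_OCTAVE_ROOT = 48   # C3: chord roots live in octave 3
_BASS_OCTAVE_ROOT = 36    # C2: bass one octave below the chord roots
_MELODY_OCTAVE_ROOT = 72  # C5

_VELOCITY = {"melody": 0.8, "chords": 0.6, "bass": 0.9, "ride": 0.5, "kick": 0.9}


@dataclass(frozen=True)
class NoteEvent:
    """A single timed note on one of the four named tracks."""

    onset: float
    duration: float
    pitch: int
    velocity: float
    track: str

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError(f"onset must be >= 0, got {self.onset}")
        if self.duration < 0:
            raise ValueError(f"duration must be >= 0, got {self.duration}")
        if not 0 <= self.pitch <= 127:
            raise ValueError(f"pitch must be in [0, 127], got {self.pitch}")
        if not 0.0 <= self.velocity <= 1.0:
            raise ValueError(f"velocity must be in [0, 1], got {self.velocity}")
        if self.track not in TRACKS:
            raise ValueError(f"unknown track {self.track!r}")


@dataclass(frozen=True)
class StimulusScore:
    """Timed note events on four named tracks, with key/condition metadata."""

    events: tuple[NoteEvent, ...]
    key: str
    tempo_bpm: float = 140.0
    length_s: float = 15.0
    condition: str = CONDITION_CP
    melody_id: int = 1

    def track_events(self, track: str) -> tuple[NoteEvent, ...]:
        return tuple(e for e in self.events if e.track == track)

    @property
    def beat_s(self) -> float:
        return 60.0 / self.tempo_bpm


@dataclass(frozen=True)
class SynthPatch:
    """Additive-synthesis voice definitions for the four tracks.

    Rendering any score with the same patch and seed is bit-identical: the
    only stochastic element (the ride cymbal's noise burst) is drawn from a
    generator seeded by ``seed`` over events visited in a canonical order.
    """

    harmonics: dict = field(
        default_factory=lambda: {
            "melody": (1.0, 0.4, 0.2, 0.1),
            "chords": (1.0, 0.5, 0.25, 0.12),
            "bass": (1.0, 0.3, 0.1),
        }
    )
    adsr: dict = field(
        default_factory=lambda: {
            "melody": (0.010, 0.050, 0.75, 0.050),
            "chords": (0.010, 0.060, 0.75, 0.060),
            "bass": (0.008, 0.040, 0.80, 0.040),
        }
    )
    ride_decay_s: float = 0.08
    ride_band_hz: tuple = (4000.0, 9000.0)
    kick_freq_hz: float = 60.0
    kick_decay_s: float = 0.15
    master_gain: float = 0.1
    seed: int = 0


@dataclass
class AudioClip:
    """Mono audio samples in [-1, 1] with a condition/key label."""

    samples: np.ndarray
    sample_rate: int
    label: str = ""

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate


def default_patch(seed: int = 0) -> SynthPatch:
    return SynthPatch(seed=seed)


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

def _chord_schedule(length_s: float, half_s: float) -> list[tuple[float, float, int, str]]:
    """(onset, duration, root interval, quality) covering ``length_s``.

    Lead cycles play the full ii-V-I-vi; the final cycle plays ii, V and then
    sustains the tonic major seventh to the end of the clip, so a 15 s clip
    at 140 BPM (17.5 half-note slots) ends resolved on I.
    """
    if length_s <= 0 or half_s <= 0:
        return []
    n_slots = length_s / half_s
    out: list[tuple[float, float, int, str]] = []
    if n_slots >= 3:
        n_lead = int((n_slots - 3) // 4)
        slot = 0
        for _ in range(n_lead):
            for _, interval, quality in PROGRESSION:
                out.append((slot * half_s, half_s, interval, quality))
                slot += 1
        # resolution: ii, V, then I sustained to the end
        for _, interval, quality in PROGRESSION[:2]:
            out.append((slot * half_s, half_s, interval, quality))
            slot += 1
        onset = slot * half_s
        out.append((onset, length_s - onset, 0, "maj7"))
    else:
        # degenerate short clip: walk the progression until the clip ends
        slot = 0
        while slot * half_s < length_s:
            _, interval, quality = PROGRESSION[slot % 4]
            onset = slot * half_s
            out.append((onset, min(half_s, length_s - onset), interval, quality))
            slot += 1
    return out


def compose_chord_progression(
    key: str = "C",
    melody_id: int = 1,
    tempo_bpm: float = 140.0,
    length_s: float = 15.0,
) -> StimulusScore:
    """Compose one chord-progression exemplar.

    Parameters
    ----------
    key
        One of the 12 major keys (``"C"``, ``"Db"``, ... ``"B"``).
    melody_id
        Which of the four pentatonic melody templates to use (1-4).
    tempo_bpm, length_s
        Grid tempo and clip length; defaults 140 BPM and 15 s.
    """
    if key not in KEY_PCS:
        raise ValueError(f"invalid key {key!r}; expected one of {KEYS}")
    if melody_id not in MELODY_TEMPLATES:
        raise ValueError(f"invalid melody_id {melody_id}; expected 1-4")
    if tempo_bpm <= 0:
        raise ValueError("tempo_bpm must be positive")
    if length_s < 0:
        raise ValueError("length_s must be >= 0")

    tonic = KEY_PCS[key]
    beat = 60.0 / tempo_bpm
    half = 2.0 * beat
    events: list[NoteEvent] = []

    schedule = _chord_schedule(length_s, half)

    # chords: close-position sevenths rooted in octave 3
    for onset, dur, interval, quality in schedule:
        root = _CHORD_OCTAVE_ROOT + (tonic + interval) % 12
        for off in _QUALITY_INTERVALS[quality]:
            events.append(
                NoteEvent(onset, dur, root + off, _VELOCITY["chords"], "chords")
            )

    # bass: quarter notes on the sounding chord's root, one octave below
    for onset, dur, interval, _quality in schedule:
        pitch = _BASS_OCTAVE_ROOT + (tonic + interval) % 12
        t = onset
        while t < onset + dur - 1e-9:
            events.append(
                NoteEvent(t, min(beat, onset + dur - t), pitch, _VELOCITY["bass"], "bass")
            )
            t += beat

    # melody: half notes from the key's major pentatonic, cycled template
    template = MELODY_TEMPLATES[melody_id]
    k = 0
    while k * half < length_s - 1e-9:
        onset = k * half
        degree = template[k % len(template)]
        pitch = _MELODY_OCTAVE_ROOT + tonic + _PENTATONIC[degree]
        events.append(
            NoteEvent(onset, min(half, length_s - onset), pitch, _VELOCITY["melody"], "melody")
        )
        k += 1

    # drums: ride on every quarter, kick on every half note
    k = 0
    while k * beat < length_s - 1e-9:
        events.append(
            NoteEvent(k * beat, beat, RIDE_PITCH, _VELOCITY["ride"], "drums")
        )
        k += 1
    k = 0
    while k * half < length_s - 1e-9:
        events.append(
            NoteEvent(k * half, half, KICK_PITCH, _VELOCITY["kick"], "drums")
        )
        k += 1

    return StimulusScore(
        events=tuple(events),
        key=key,
        tempo_bpm=tempo_bpm,
        length_s=length_s,
        condition=CONDITION_CP,
        melody_id=melody_id,
    )


def shuffle_tonal_tracks(
    score: StimulusScore,
    rng_seed: int,
    offset_range_s: tuple[float, float] = (0.25, 2.0),
    mode: str = "jitter",
) -> StimulusScore:
    """Derive the no-chord-progression control from a chord-progression score.

    ``mode="jitter"`` (default) displaces each melody/chords/bass onset by an
    independent uniform draw with magnitude in ``offset_range_s`` and random
    sign, wrapped circularly into ``[0, length_s)``.  ``mode="permute"``
    instead permutes onsets among the notes of each tonal track.  Drum events
    are passed through untouched, and the per-track multiset of
    (pitch, duration) pairs is preserved exactly.
    """
    if score.condition != CONDITION_CP:
        raise ValueError("shuffle_tonal_tracks expects a chord_progression score")
    lo, hi = offset_range_s
    if not (0 < lo < hi):
        raise ValueError(f"offset range must satisfy 0 < lo < hi, got {offset_range_s}")
    if mode not in ("jitter", "permute"):
        raise ValueError(f"unknown mode {mode!r}")

    rng = np.random.default_rng(rng_seed)
    length = score.length_s
    new_events: list[NoteEvent] = []
    if mode == "jitter":
        for e in score.events:
            if e.track in TONAL_TRACKS and length > 0:
                mag = rng.uniform(lo, hi)
                sign = -1.0 if rng.random() < 0.5 else 1.0
                new_events.append(replace(e, onset=(e.onset + sign * mag) % length))
            else:
                new_events.append(e)
    else:
        for track in TONAL_TRACKS:
            evs = [e for e in score.events if e.track == track]
            onsets = np.array([e.onset for e in evs])
            for e, new_onset in zip(evs, rng.permutation(onsets)):
                new_events.append(replace(e, onset=float(new_onset)))
        new_events.extend(e for e in score.events if e.track == "drums")

    return replace(score, events=tuple(new_events), condition=CONDITION_NCP)


def build_stimulus_sets(
    rng_seed: int = 0,
) -> tuple[list[StimulusScore], list[StimulusScore]]:
    """Build the full stimulus sets: 12 chord-progression exemplars (one per
    major key, melody template randomly assigned) and their 12 note-shuffled
    controls."""
    rng = np.random.default_rng(rng_seed)
    cp_set: list[StimulusScore] = []
    ncp_set: list[StimulusScore] = []
    for key in KEYS:
        melody_id = int(rng.integers(1, 5))
        cp = compose_chord_progression(key=key, melody_id=melody_id)
        ncp = shuffle_tonal_tracks(cp, rng_seed=int(rng.integers(0, 2**31)))
        cp_set.append(cp)
        ncp_set.append(ncp)
    return cp_set, ncp_set


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _midi_to_hz(pitch: int) -> float:
    return 440.0 * 2.0 ** ((pitch - 69) / 12.0)


def _adsr_envelope(n: int, sr: int, duration: float, adsr: tuple) -> np.ndarray:
    attack, decay, sustain, release = adsr
    t = np.arange(n) / sr
    # breakpoints forced strictly increasing so np.interp is well defined
    xs, ys = [0.0], [0.0]
    for x, y in (
        (min(attack, duration), 1.0),
        (min(attack + decay, duration), sustain),
        (duration, sustain),
        (duration + release, 0.0),
    ):
        if x <= xs[-1]:
            x = xs[-1] + 1e-9
        xs.append(x)
        ys.append(y)
    return np.interp(t, xs, ys, left=0.0, right=0.0)


def _add_wrapped(buf: np.ndarray, start: int, chunk: np.ndarray) -> None:
    """Accumulate ``chunk`` into ``buf`` starting at ``start``, wrapping
    circularly so shuffled notes near the clip end keep their full energy."""
    n = len(buf)
    idx = (start + np.arange(len(chunk))) % n
    np.add.at(buf, idx, chunk)


def render_audio(
    score: StimulusScore,
    patch: SynthPatch | None = None,
    sample_rate: int = 22050,
) -> AudioClip:
    """Render a score to mono audio with additive tonal synthesis and
    enveloped noise/sine drum voices."""
    if sample_rate < 8000:
        raise ValueError("sample_rate must be >= 8000 Hz")
    if patch is None:
        patch = default_patch()
    if not patch.harmonics:
        raise ValueError("patch has no tonal harmonic definitions")

    tail = 0.3
    n = int(round((score.length_s + tail) * sample_rate))
    label = f"{score.condition}:{score.key}"
    if n == 0:
        return AudioClip(np.zeros(0), sample_rate, label)
    buf = np.zeros(n)
    rng = np.random.default_rng(patch.seed)
    nyq = sample_rate / 2.0

    order = sorted(
        range(len(score.events)),
        key=lambda i: (score.events[i].track, score.events[i].onset, score.events[i].pitch),
    )
    for i in order:
        e = score.events[i]
        start = int(round(e.onset * sample_rate))
        if e.track in TONAL_TRACKS:
            adsr = patch.adsr[e.track]
            m = max(1, int(round((e.duration + adsr[3]) * sample_rate)))
            t = np.arange(m) / sample_rate
            env = _adsr_envelope(m, sample_rate, e.duration, adsr)
            f0 = _midi_to_hz(e.pitch)
            wave = np.zeros(m)
            for h, amp in enumerate(patch.harmonics[e.track], start=1):
                if f0 * h < nyq:
                    wave += amp * np.sin(2 * np.pi * f0 * h * t)
            _add_wrapped(buf, start, e.velocity * patch.master_gain * env * wave)
        elif e.pitch == RIDE_PITCH:
            m = max(1, int(round(5 * patch.ride_decay_s * sample_rate)))
            t = np.arange(m) / sample_rate
            noise = rng.standard_normal(m)
            lo, hi = patch.ride_band_hz
            hi = min(hi, 0.95 * nyq)
            lo = min(lo, 0.5 * hi)
            sos = _signal.butter(2, [lo, hi], btype="bandpass", fs=sample_rate, output="sos")
            burst = _signal.sosfilt(sos, noise)
            burst /= max(1e-12, np.max(np.abs(burst)))
            env = np.exp(-t / patch.ride_decay_s)
            _add_wrapped(buf, start, e.velocity * patch.master_gain * env * burst)
        else:  # kick
            m = max(1, int(round(5 * patch.kick_decay_s * sample_rate)))
            t = np.arange(m) / sample_rate
            thump = np.sin(2 * np.pi * patch.kick_freq_hz * t) * np.exp(-t / patch.kick_decay_s)
            _add_wrapped(buf, start, e.velocity * patch.master_gain * thump)

    peak = np.max(np.abs(buf)) if n else 0.0
    if peak >= 0.99:
        buf *= 0.99 / peak
    return AudioClip(buf, sample_rate, label)


# ---------------------------------------------------------------------------
# Serialization: JSON event lists, standard MIDI files, WAV
# ---------------------------------------------------------------------------

def score_to_json(score: StimulusScore) -> str:
    """Serialize a score to the package's JSON event-list dialect."""
    return json.dumps(
        {
            "key": score.key,
            "tempo_bpm": score.tempo_bpm,
            "length_s": score.length_s,
            "condition": score.condition,
            "melody_id": score.melody_id,
            "events": [
                {
                    "onset": e.onset,
                    "duration": e.duration,
                    "pitch": e.pitch,
                    "velocity": e.velocity,
                    "track": e.track,
                }
                for e in score.events
            ],
        },
        indent=None,
    )


def score_from_json(text: str) -> StimulusScore:
    d = json.loads(text)
    return StimulusScore(
        events=tuple(NoteEvent(**e) for e in d["events"]),
        key=d["key"],
        tempo_bpm=d["tempo_bpm"],
        length_s=d["length_s"],
        condition=d["condition"],
        melody_id=d["melody_id"],
    )


def _varlen(value: int) -> bytes:
    out = [value & 0x7F]
    value >>= 7
    while value:
        out.append(0x80 | (value & 0x7F))
        value >>= 7
    return bytes(reversed(out))


_MIDI_CHANNELS = {"melody": 0, "chords": 1, "bass": 2, "drums": 9}
_MIDI_PROGRAMS = {"melody": 0, "chords": 0, "bass": 33}


def write_midi(score: StimulusScore, path: str | Path, ticks_per_quarter: int = 480) -> None:
    """Write the score as a format-1 Standard MIDI File, one track per
    instrument (drums on channel 10)."""
    path = Path(path)
    beat = score.beat_s

    def to_ticks(seconds: float) -> int:
        return int(round(seconds / beat * ticks_per_quarter))

    chunks: list[bytes] = []
    # tempo track
    tempo_us = int(round(60_000_000 / score.tempo_bpm))
    ev = b"\x00" + b"\xff\x51\x03" + struct.pack(">I", tempo_us)[1:]
    ev += b"\x00" + b"\xff\x2f\x00"
    chunks.append(b"MTrk" + struct.pack(">I", len(ev)) + ev)

    for track in TRACKS:
        ch = _MIDI_CHANNELS[track]
        msgs: list[tuple[int, bytes]] = []
        if track in _MIDI_PROGRAMS:
            msgs.append((0, bytes([0xC0 | ch, _MIDI_PROGRAMS[track]])))
        for e in score.track_events(track):
            vel = max(1, min(127, int(round(e.velocity * 127))))
            on = to_ticks(e.onset)
            off = to_ticks(e.onset + max(e.duration, 1e-3))
            msgs.append((on, bytes([0x90 | ch, e.pitch, vel])))
            msgs.append((max(off, on + 1), bytes([0x80 | ch, e.pitch, 0])))
        msgs.sort(key=lambda m: m[0])
        data = b""
        prev = 0
        for tick, msg in msgs:
            data += _varlen(tick - prev) + msg
            prev = tick
        data += b"\x00" + b"\xff\x2f\x00"
        chunks.append(b"MTrk" + struct.pack(">I", len(data)) + data)

    header = b"MThd" + struct.pack(">IHHH", 6, 1, len(chunks), ticks_per_quarter)
    path.write_bytes(header + b"".join(chunks))


def write_wav(clip: AudioClip, path: str | Path) -> None:
    """Write 16-bit PCM mono WAV."""
    x = np.clip(clip.samples, -1.0, 1.0)
    wavfile.write(str(path), clip.sample_rate, (x * 32767).astype(np.int16))


def read_wav(path: str | Path, label: str = "") -> AudioClip:
    """Read a PCM WAV (mono-summed, scaled to [-1, 1])."""
    sr, data = wavfile.read(str(path))
    x = np.asarray(data, dtype=np.float64)
    if x.ndim == 2:
        x = x.mean(axis=1)
    if np.issubdtype(np.asarray(data).dtype, np.integer):
        x /= float(np.iinfo(np.asarray(data).dtype).max)
    return AudioClip(x, int(sr), label)
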