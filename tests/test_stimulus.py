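"""Composition, shuffling and rendering of the musical stimuli."""
import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dyadtune import stimulus
from dyadtune.stimulus import (
    KEYS,
    KICK_PITCH,
    RIDE_PITCH,
    AudioClip,
    build_stimulus_sets,
    compose_chord_progression,
    default_patch,
    render_audio,
    score_from_json,
    score_to_json,
    shuffle_tonal_tracks,
    write_midi,
)


def chord_stack(score, track="chords"):
    """Group chord-track events into (onset, set of pitches) stacks."""
    stacks = {}
    for e in score.track_events(track):
        stacks.setdefault(round(e.onset, 6), set()).add(e.pitch)
    return sorted(stacks.items())


class TestCompose:
    def test_roots_and_qualities_in_c_major(self):
        """In C major the progression is Dm7, G7, Cmaj7, Am7."""
        score = compose_chord_progression(key="C", melody_id=1)
        stacks = chord_stack(score)
        expected = [
            (50, {0, 3, 7, 10}),   # D3 minor 7
            (55, {0, 4, 7, 10}),   # G3 dominant 7
            (48, {0, 4, 7, 11}),   # C3 major 7
            (57, {0, 3, 7, 10}),   # A3 minor 7
        ]
        for (onset, pitches), (root, intervals) in zip(stacks[:4], expected):
            assert min(pitches) == root
            assert {p - root for p in pitches} == intervals

    @pytest.mark.parametrize("key", KEYS)
    def test_cyclic_order_and_final_tonic_every_key(self, key):
        """Chord roots cycle ii->V->I->vi and the last chord is maj7 on the
        tonic, in all 12 keys."""
        tonic = KEYS.index(key)
        score = compose_chord_progression(key=key)
        stacks = chord_stack(score)
        expected_pcs = [(tonic + i) % 12 for i in (2, 7, 0, 9)]
        for k, (_onset, pitches) in enumerate(stacks[:-1]):
            assert min(pitches) % 12 == expected_pcs[k % 4]
        _last_onset, last = stacks[-1]
        root = min(last)
        assert root % 12 == tonic
        assert {p - root for p in last} == {0, 4, 7, 11}
        # the sustained final chord fills the clip to the end
        final = [e for e in score.track_events("chords") if e.pitch == root][-1]
        assert final.onset + final.duration == pytest.approx(score.length_s)

    def test_drum_grid_counts(self):
        """Ride on every beat, kick on every half note of a 15 s clip."""
        score = compose_chord_progression(key="C")
        beat, half = 60 / 140, 2 * 60 / 140
        expected_ride = sum(1 for k in range(1000) if k * beat < 15 - 1e-9)
        expected_kick = sum(1 for k in range(1000) if k * half < 15 - 1e-9)
        drums = score.track_events("drums")
        assert sum(1 for e in drums if e.pitch == RIDE_PITCH) == expected_ride == 35
        assert sum(1 for e in drums if e.pitch == KICK_PITCH) == expected_kick == 18

    def test_melody_is_pentatonic_half_notes(self):
        score = compose_chord_progression(key="E", melody_id=3)
        tonic = KEYS.index("E")
        pent = {(tonic + s) % 12 for s in (0, 2, 4, 7, 9)}
        melody = score.track_events("melody")
        assert all(e.pitch % 12 in pent for e in melody)
        assert all(e.duration <= 2 * 60 / 140 + 1e-9 for e in melody)

    def test_zero_length_is_valid_and_empty(self):
        score = compose_chord_progression(key="C", length_s=0)
        assert score.events == ()

    @pytest.mark.parametrize(
        "kwargs", [{"key": "H"}, {"melody_id": 0}, {"melody_id": 5}, {"tempo_bpm": 0}]
    )
    def test_invalid_arguments_rejected(self, kwargs):
        with pytest.raises(ValueError):
            compose_chord_progression(**kwargs)


class TestShuffle:
    def test_drums_bit_identical_and_label_flipped(self):
        cp = compose_chord_progression(key="A")
        ncp = shuffle_tonal_tracks(cp, rng_seed=5)
        assert ncp.track_events("drums") == cp.track_events("drums")
        assert ncp.condition == "no_chord_progression"
        assert cp.condition == "chord_progression"

    @given(seed=st.integers(0, 2**31 - 1), key=st.sampled_from(KEYS))
    def test_pitch_duration_multiset_preserved(self, seed, key):
        cp = compose_chord_progression(key=key)
        ncp = shuffle_tonal_tracks(cp, rng_seed=seed)
        for track in ("melody", "chords", "bass"):
            before = Counter((e.pitch, round(e.duration, 9)) for e in cp.track_events(track))
            after = Counter((e.pitch, round(e.duration, 9)) for e in ncp.track_events(track))
            assert before == after
        assert all(0 <= e.onset < cp.length_s for e in ncp.events)

    def test_offsets_respect_printed_range(self):
        cp = compose_chord_progression(key="C")
        ncp = shuffle_tonal_tracks(cp, rng_seed=11)
        originals = {id(e): e for e in cp.events}
        for before, after in zip(cp.events, ncp.events):
            if before.track == "drums":
                continue
            # circular displacement magnitude in [0.25, 2] s either way
            delta = abs(after.onset - before.onset)
            delta = min(delta, cp.length_s - delta)
            assert 0.25 - 1e-9 <= delta <= 2.0 + 1e-9

    def test_deterministic_under_fixed_seed(self):
        cp = compose_chord_progression(key="F")
        assert shuffle_tonal_tracks(cp, 3) == shuffle_tonal_tracks(cp, 3)

    def test_no_tonal_events_passthrough(self):
        cp = compose_chord_progression(key="C", length_s=0)
        ncp = shuffle_tonal_tracks(cp, 1)
        assert ncp.events == cp.events
        assert ncp.condition == "no_chord_progression"

    def test_rejections(self):
        cp = compose_chord_progression(key="C")
        with pytest.raises(ValueError):
            shuffle_tonal_tracks(cp, 0, offset_range_s=(2.0, 0.25))
        with pytest.raises(ValueError):
            shuffle_tonal_tracks(shuffle_tonal_tracks(cp, 0), 0)

    def test_permute_mode_preserves_onset_multiset(self):
        cp = compose_chord_progression(key="C")
        ncp = shuffle_tonal_tracks(cp, 4, mode="permute")
        for track in ("melody", "chords", "bass"):
            before = Counter(round(e.onset, 9) for e in cp.track_events(track))
            after = Counter(round(e.onset, 9) for e in ncp.track_events(track))
            assert before == after


class TestBuildSets:
    def test_twelve_per_condition_distinct_keys(self):
        cp, ncp = build_stimulus_sets(0)
        assert len(cp) == len(ncp) == 12
        assert {s.key for s in cp} == set(KEYS)
        assert all(s.condition == "chord_progression" for s in cp)
        assert all(s.condition == "no_chord_progression" for s in ncp)

    def test_same_seed_reproduces_and_drums_shared(self):
        a_cp, a_ncp = build_stimulus_sets(42)
        b_cp, b_ncp = build_stimulus_sets(42)
        assert a_cp == b_cp and a_ncp == b_ncp
        for cp, ncp in zip(a_cp, a_ncp):
            assert cp.track_events("drums") == ncp.track_events("drums")


class TestRender:
    def test_silence_score_all_zero(self):
        empty = stimulus.StimulusScore(events=(), key="C", length_s=2.0)
        clip = render_audio(empty)
        assert np.all(clip.samples == 0)
        assert clip.duration_s >= 2.0

    def test_single_a4_peaks_at_440(self):
        ev = stimulus.NoteEvent(0.2, 0.5, 69, 0.9, "melody")
        score = stimulus.StimulusScore(events=(ev,), key="C", length_s=1.0)
        clip = render_audio(score, sample_rate=22050)
        spec = np.abs(np.fft.rfft(clip.samples))
        freqs = np.fft.rfftfreq(len(clip.samples), 1 / 22050)
        assert abs(freqs[np.argmax(spec)] - 440.0) < 5

    def test_duration_and_determinism(self):
        score = compose_chord_progression(key="G")
        a = render_audio(score)
        b = render_audio(score)
        assert a.duration_s >= 15.0
        assert np.array_equal(a.samples, b.samples)
        assert np.max(np.abs(a.samples)) < 1.0

    def test_rejections(self):
        score = compose_chord_progression(key="C")
        with pytest.raises(ValueError):
            render_audio(score, sample_rate=4000)
        with pytest.raises(ValueError):
            render_audio(score, patch=stimulus.SynthPatch(harmonics={}))

    def test_note_energy_budget_preserved_by_shuffle(self):
        """CP and NCP carry the same total per-note energy (within 1%):
        shuffling moves notes but does not change what sounds."""
        cp = compose_chord_progression(key="C")
        ncp = shuffle_tonal_tracks(cp, 9)
        patch = default_patch()

        def note_energy(score):
            total = 0.0
            for e in score.events:
                single = stimulus.StimulusScore(
                    events=(e,), key=score.key, length_s=score.length_s
                )
                total += float(np.sum(render_audio(single, patch).samples ** 2))
            return total

        e_cp, e_ncp = note_energy(cp), note_energy(ncp)
        assert abs(e_cp - e_ncp) / e_cp < 0.01
        # and the mixed renders stay in the same energy regime
        r_cp = np.sqrt(np.mean(render_audio(cp, patch).samples ** 2))
        r_ncp = np.sqrt(np.mean(render_audio(ncp, patch).samples ** 2))
        assert abs(20 * math.log10(r_cp / r_ncp)) < 3.0


class TestSerialization:
    def test_json_roundtrip(self):
        score = compose_chord_progression(key="Bb", melody_id=2)
        assert score_from_json(score_to_json(score)) == score

    def test_midi_file_structure(self, tmp_path):
        score = compose_chord_progression(key="D")
        path = tmp_path / "cp_D.mid"
        write_midi(score, path)
        data = path.read_bytes()
        assert data[:4] == b"MThd"
        # format 1, five tracks (tempo + four instruments)
        assert data[8:10] == b"\x00\x01"
        assert data[10:12] == b"\x00\x05"
        assert data.count(b"MTrk") == 5

    def test_wav_roundtrip(self, tmp_path):
        clip = render_audio(compose_chord_progression(key="C"))
        p = tmp_path / "x.wav"
        stimulus.write_wav(clip, p)
        back = stimulus.read_wav(p)
        assert back.sample_rate == clip.sample_rate
        assert np.corrcoef(back.samples, clip.samples)[0, 1] > 0.999
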