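"""Scale construction, CWT, cross-brain coherence and the scrambled null."""
import math

import numpy as np
import pandas as pd
import pytest

from dyadtune import coherence, glm, simulate
from dyadtune.coherence import (
    band_compare,
    cross_brain_coherence,
    cwt_complex,
    make_scales,
    residualize_task,
    scrambled_pairs,
)


@pytest.fixture(scope="module")
def small_setup():
    par = simulate.make_paradigm(n_runs=2, order_seed=0)
    design = glm.build_design(par)
    scales = make_scales()
    return par, design, scales


class TestScales:
    def test_defaults_16_scales_min_period_2p5(self):
        s = make_scales()
        assert len(s) == 16
        assert s.periods_s[0] == pytest.approx(2.5)

    def test_adjacent_ratio_exactly_quarter_octave(self):
        s = make_scales()
        ratios = s.periods_s[1:] / s.periods_s[:-1]
        assert np.allclose(ratios, 2 ** 0.25, rtol=1e-12)

    def test_single_scale(self):
        s = make_scales(octaves=1, voices=1, f_min=0.2)
        assert len(s) == 1
        assert s.periods_s[0] == pytest.approx(2.5)

    def test_inconsistent_span_warns_and_span_wins(self):
        with pytest.warns(UserWarning):
            s = make_scales(f_max=0.4, f_min=0.05, octaves=4, voices=4)
        assert len(s) == 12  # 3 octaves x 4 voices

    def test_invalid_range(self):
        with pytest.raises(ValueError):
            make_scales(f_max=0.01, f_min=0.4)


class TestResidualize:
    def test_pure_task_signal_vanishes(self, small_setup):
        par, design, _ = small_setup
        y = 1.7 * design.column("face_chord") + 0.4
        r = residualize_task(y, design)
        assert np.sqrt(np.mean(r**2)) < 1e-8

    def test_orthogonal_signal_survives(self, small_setup):
        par, design, _ = small_setup
        n = design.X.shape[0]
        rng = np.random.default_rng(0)
        y = rng.standard_normal(n)
        r = residualize_task(y, design)
        assert np.corrcoef(r, y - y.mean())[0, 1] > 0.99


class TestCWT:
    def test_ridge_at_signal_period(self, small_setup):
        _, _, scales = small_setup
        fs = 30.0
        t = np.arange(int(240 * fs)) / fs
        x = np.sin(2 * np.pi * t / 15.0)
        coef, valid = cwt_complex(x, scales, fs)
        power = np.array(
            [np.mean(np.abs(coef[s, valid[s]]) ** 2) for s in range(len(scales))]
        )
        assert abs(scales.periods_s[int(np.argmax(power))] - 15.0) < 2.0

    def test_zero_series_and_linearity(self, small_setup):
        _, _, scales = small_setup
        fs = 30.0
        rng = np.random.default_rng(1)
        x = rng.standard_normal(int(200 * fs))
        z, _ = cwt_complex(np.zeros_like(x), scales, fs)
        assert np.all(z == 0)
        c1, _ = cwt_complex(x, scales, fs)
        c2, _ = cwt_complex(2 * x, scales, fs)
        assert np.max(np.abs(c2 - 2 * c1)) < 1e-8 * np.max(np.abs(c1))

    def test_too_short_series_rejected(self, small_setup):
        _, _, scales = small_setup
        with pytest.raises(ValueError):
            cwt_complex(np.zeros(100), scales, 30.0)


class TestCrossBrainCoherence:
    def test_self_coherence_is_one(self, small_setup):
        par, design, scales = small_setup
        fs = 30.0
        rng = np.random.default_rng(2)
        x = rng.standard_normal(int(par.total_duration_s * fs))
        coef, valid = cwt_complex(x, scales, fs)
        r = cross_brain_coherence(coef, coef, par, "face_chord", fs, valid=valid)
        finite = np.isfinite(r)
        assert finite.any()
        assert np.allclose(r[finite], 1.0)

    def test_partner_swap_symmetry(self, small_setup):
        par, design, scales = small_setup
        fs = 30.0
        rng = np.random.default_rng(3)
        n = int(par.total_duration_s * fs)
        ca, va = cwt_complex(rng.standard_normal(n), scales, fs)
        cb, vb = cwt_complex(rng.standard_normal(n), scales, fs)
        v = va & vb
        r_ab = cross_brain_coherence(ca, cb, par, "face_chord", fs, valid=v)
        r_ba = cross_brain_coherence(cb, ca, par, "face_chord", fs, valid=v)
        assert np.allclose(r_ab, r_ba, atol=1e-12, equal_nan=True)

    def test_independent_partners_centered_at_zero(self, small_setup):
        """Coherence of independent-noise partners averages to ~0 (within
        3 SE over repeated simulations)."""
        par, design, scales = small_setup
        fs = 30.0
        n = int(par.total_duration_s * fs)
        rng = np.random.default_rng(4)
        vals = []
        for _ in range(12):
            ca, va = cwt_complex(rng.standard_normal(n), scales, fs)
            cb, vb = cwt_complex(rng.standard_normal(n), scales, fs)
            r = cross_brain_coherence(ca, cb, par, "face_chord", fs, valid=va & vb)
            vals.append(np.nanmean(r[:8]))  # short scales: many samples/block
        se = np.std(vals) / math.sqrt(len(vals))
        assert abs(np.mean(vals)) < 3 * se

    def test_misaligned_arrays_rejected(self, small_setup):
        par, _, _ = small_setup
        with pytest.raises(ValueError):
            cross_brain_coherence(
                np.zeros((16, 100)), np.zeros((16, 99)), par, "face_chord", 30.0
            )


class TestBandCompare:
    def make_spectra(self, values_a, values_b):
        rows = []
        for d, (va, vb) in enumerate(zip(values_a, values_b)):
            for period in (10.0, 14.0, 20.0):
                rows.append({"dyad": f"d{d}", "channel_a": 0, "channel_b": 0,
                             "condition": "face_chord", "period_s": period,
                             "coherence": va})
                rows.append({"dyad": f"d{d}", "channel_a": 0, "channel_b": 0,
                             "condition": "face_nochord", "period_s": period,
                             "coherence": vb})
        return pd.DataFrame(rows)

    def test_identical_conditions_t_zero(self):
        spectra = self.make_spectra([0.4, 0.5, 0.6], [0.4, 0.5, 0.6])
        t, df, p = band_compare(spectra, "face_chord", "face_nochord")
        assert t == pytest.approx(0.0)
        assert df == 2

    def test_matches_paired_t_oracle(self):
        a = [0.52, 0.61, 0.47, 0.58, 0.66]
        b = [0.40, 0.50, 0.45, 0.38, 0.52]
        t, df, p = band_compare(self.make_spectra(a, b), "face_chord", "face_nochord")
        d = np.array(a) - np.array(b)
        t_oracle = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        assert t == pytest.approx(t_oracle, abs=1e-10)
        assert df == 4

    def test_empty_band_rejected(self):
        spectra = self.make_spectra([0.1] * 3, [0.2] * 3)
        with pytest.raises(ValueError):
            band_compare(spectra, "face_chord", "face_nochord", band=(100.0, 200.0))


class TestScrambledPairs:
    def test_zero_draws_empty(self, small_setup):
        par, design, scales = small_setup
        fs = 30.0
        n = int(par.total_duration_s * fs)
        rng = np.random.default_rng(5)
        hb = [(rng.standard_normal((1, n)), rng.standard_normal((1, n)))
              for _ in range(2)]
        out = scrambled_pairs(hb, par, design, [(0, 0)], n_draws=0)
        assert out.empty

    def test_fixed_seed_reproducible_and_deranged(self, small_setup):
        par, design, scales = small_setup
        fs = 30.0
        n = int(par.total_duration_s * fs)
        rng = np.random.default_rng(6)
        hb = [(rng.standard_normal((1, n)), rng.standard_normal((1, n)))
              for _ in range(3)]
        a = scrambled_pairs(hb, par, design, [(0, 0)], rng_seed=7, n_draws=2)
        b = scrambled_pairs(hb, par, design, [(0, 0)], rng_seed=7, n_draws=2)
        assert a.equals(b)
        # no scrambled dyad pairs a participant with their true partner
        for name in a["dyad"].unique():
            i, j = name.split("_")[1].split("x")
            assert i != j

    def test_single_dyad_rejected(self, small_setup):
        par, design, _ = small_setup
        with pytest.raises(ValueError):
            scrambled_pairs([(np.zeros((1, 10)), np.zeros((1, 10)))], par, design, [(0, 0)])
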