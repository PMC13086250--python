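"""Cross-brain wavelet coherence with a scrambled-pair null.

Each partner's HbDiff signal is first residualized against the task design
(so block-evoked structure does not masquerade as coupling, as in
psychophysiological-interaction analysis), then decomposed with a complex
Gaussian continuous wavelet transform over 16 geometrically spaced scales
(4 octaves x 4 voices, periods from 2.5 s upward, i.e. 0.4-0.025 Hz).  For
each dyad, channel pair, scale and condition, the Pearson correlation of
the partners' coefficient magnitudes over the concatenated samples of that
condition's blocks is the coherence value.  Condition contrasts average
coherence over the 10-20 s period band and compare conditions with a paired
t-test; the scrambled-pair null re-runs the identical pipeline on partners
who never interacted (derangement sampling across dyads).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy import stats as _stats

from .glm import DesignMatrix
from .simulate import CONDITIONS, Paradigm

__all__ = [
    "ScaleSet",
    "make_scales",
    "residualize_task",
    "cwt_complex",
    "cross_brain_coherence",
    "dyad_coherence",
    "experiment_coherence",
    "band_compare",
    "scrambled_pairs",
]

DEFAULT_WAVELET = "cgau4"


@dataclass
class ScaleSet:
    """Geometrically spaced wavelet scales for the coherence analysis."""

    periods_s: np.ndarray
    octaves: float
    voices_per_octave: int
    wavelet: str = DEFAULT_WAVELET
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.periods_s)

    def band_indices(self, band: tuple[float, float]) -> np.ndarray:
        lo, hi = band
        return np.where((self.periods_s >= lo) & (self.periods_s <= hi))[0]


def make_scales(
    f_max: float = 0.4,
    f_min: float = 0.025,
    octaves: int = 4,
    voices: int = 4,
    wavelet: str = DEFAULT_WAVELET,
) -> ScaleSet:
    """Build octaves x voices scales spanning [1/f_max, 1/f_min).

    Adjacent periods differ by exactly 2^(1/voices); the count is
    octaves * voices (the 1/f_min endpoint is the open edge of the last
    voice, one spacing step beyond the largest period).  If the stated
    octave count disagrees with log2(f_max/f_min), the frequency span takes
    precedence (with a warning).
    """
    if not (f_max > f_min > 0):
        raise ValueError("need f_max > f_min > 0")
    span = math.log2(f_max / f_min)
    if abs(span - octaves) > 1e-9:
        warnings.warn(
            f"octaves={octaves} inconsistent with frequency span "
            f"{span:.3f} octaves; span takes precedence",
            stacklevel=2,
        )
        octaves = span
    n = int(round(octaves * voices))
    periods = (1.0 / f_max) * 2.0 ** (np.arange(n) / voices)
    return ScaleSet(
        periods_s=periods,
        octaves=octaves,
        voices_per_octave=voices,
        wavelet=wavelet,
        meta={
            "shortest_period_s": float(periods[0]),
            "longest_period_s": float(periods[-1]),
            "endpoint_period_s": 1.0 / f_min,
            # the printed "2.5 s" admits two readings; both are recorded
            "spacing_interpretations": {
                "shortest_period_s": float(periods[0]),
                "first_spacing_s": float(periods[1] - periods[0]) if n > 1 else math.nan,
            },
        },
    )


def residualize_task(hbdiff: np.ndarray, design: DesignMatrix) -> np.ndarray:
    """OLS residuals of the signal on all task regressors plus intercept."""
    Y = np.atleast_2d(np.asarray(hbdiff, dtype=np.float64))
    X = design.X
    if Y.shape[1] != X.shape[0]:
        raise ValueError("signal length does not match design length")
    beta, _, _, _ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = (Y.T - X @ beta).T
    return resid[0] if np.asarray(hbdiff).ndim == 1 else resid


def cwt_complex(
    series: np.ndarray,
    scale_set: ScaleSet,
    sample_rate: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Complex-Gaussian continuous wavelet transform.

    Returns ``(coefficients, valid)`` where coefficients has shape
    (n_scales, n_samples) and ``valid`` is a per-scale boolean mask that is
    False inside the cone of influence of the series edges (within one
    e-folding time, period/sqrt(2), of either end).
    """
    x = np.asarray(series, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("cwt_complex expects a single channel")
    n = len(x)
    longest = scale_set.periods_s[-1]
    if n < 2 * longest * sample_rate:
        raise ValueError(
            f"series of {n} samples is shorter than twice the longest "
            f"period ({longest} s) at {sample_rate} Hz"
        )
    fc = pywt.central_frequency(scale_set.wavelet)
    scales = fc * scale_set.periods_s * sample_rate
    coef, _freqs = pywt.cwt(x, scales, scale_set.wavelet, method="fft")
    t = np.arange(n) / sample_rate
    total = n / sample_rate
    efold = scale_set.periods_s / math.sqrt(2.0)
    valid = (t[None, :] >= efold[:, None]) & (t[None, :] <= total - efold[:, None])
    return coef, valid


def cross_brain_coherence(
    coeff_a: np.ndarray,
    coeff_b: np.ndarray,
    paradigm: Paradigm,
    condition: str,
    sample_rate: float,
    valid: np.ndarray | None = None,
    statistic: str = "magnitude",
) -> np.ndarray:
    """Per-scale Pearson correlation between partner coefficient series over
    the concatenated samples of one condition's blocks.

    ``statistic="magnitude"`` (default) correlates coefficient magnitudes;
    ``"real"`` correlates real parts.  Scales with no valid samples (or zero
    variance) come back as NaN.
    """
    if coeff_a.shape != coeff_b.shape:
        raise ValueError("partner coefficient arrays must be aligned")
    n_scales, n = coeff_a.shape
    mask = paradigm.boxcar(condition, n, sample_rate).astype(bool)
    if statistic == "magnitude":
        A, B = np.abs(coeff_a), np.abs(coeff_b)
    elif statistic == "real":
        A, B = coeff_a.real, coeff_b.real
    else:
        raise ValueError(f"unknown coherence statistic {statistic!r}")
    out = np.full(n_scales, np.nan)
    for s in range(n_scales):
        m = mask if valid is None else (mask & valid[s])
        if m.sum() < 3:
            continue
        a, b = A[s, m], B[s, m]
        sa, sb = a.std(), b.std()
        if sa > 0 and sb > 0:
            out[s] = float(np.corrcoef(a, b)[0, 1])
    return out


def _coef_cache(
    hbdiff: np.ndarray,
    channels: set[int],
    design: DesignMatrix,
    scales: ScaleSet,
    sample_rate: float,
) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    resid = residualize_task(hbdiff[sorted(channels)], design)
    out = {}
    for i, ch in enumerate(sorted(channels)):
        out[ch] = cwt_complex(resid[i], scales, sample_rate)
    return out


def dyad_coherence(
    hbdiff_a: np.ndarray,
    hbdiff_b: np.ndarray,
    paradigm: Paradigm,
    design: DesignMatrix,
    pairs: list[tuple[int, int]],
    scales: ScaleSet | None = None,
    sample_rate: float = 30.0,
    dyad_id: str = "dyad00",
    conditions: tuple = CONDITIONS,
) -> pd.DataFrame:
    """Coherence spectra for one dyad over the given channel pairs.

    Returns a long-format frame (dyad, channel_a, channel_b, condition,
    period_s, coherence).
    """
    if scales is None:
        scales = make_scales()
    cache_a = _coef_cache(hbdiff_a, {a for a, _ in pairs}, design, scales, sample_rate)
    cache_b = _coef_cache(hbdiff_b, {b for _, b in pairs}, design, scales, sample_rate)
    rows = []
    for a, b in pairs:
        coef_a, valid_a = cache_a[a]
        coef_b, valid_b = cache_b[b]
        valid = valid_a & valid_b
        for cond in conditions:
            r = cross_brain_coherence(
                coef_a, coef_b, paradigm, cond, sample_rate, valid=valid
            )
            for s, period in enumerate(scales.periods_s):
                rows.append(
                    {"dyad": dyad_id, "channel_a": a, "channel_b": b,
                     "condition": cond, "period_s": float(period),
                     "coherence": r[s]}
                )
    return pd.DataFrame(rows)


def experiment_coherence(
    hbdiffs: list[tuple[np.ndarray, np.ndarray]],
    paradigm: Paradigm,
    design: DesignMatrix,
    pairs: list[tuple[int, int]],
    scales: ScaleSet | None = None,
    sample_rate: float = 30.0,
) -> pd.DataFrame:
    """True-pair coherence for every dyad; concatenated long-format frame."""
    if scales is None:
        scales = make_scales()
    frames = [
        dyad_coherence(
            a, b, paradigm, design, pairs, scales, sample_rate,
            dyad_id=f"dyad{d:02d}",
        )
        for d, (a, b) in enumerate(hbdiffs)
    ]
    return pd.concat(frames, ignore_index=True)


def band_compare(
    spectra: pd.DataFrame,
    cond_a: str,
    cond_b: str,
    band: tuple[float, float] = (10.0, 20.0),
) -> tuple[float, int, float]:
    """Paired t-test of band-mean coherence, cond_a vs cond_b.

    The pairing unit is one (dyad, channel pair) observation: per unit, the
    coherence values at scales whose period lies inside ``band`` are
    averaged within each condition, and the per-unit differences are tested
    with a paired t (df = n_units - 1).
    """
    sel = spectra[(spectra["period_s"] >= band[0]) & (spectra["period_s"] <= band[1])]
    if sel.empty:
        raise ValueError(f"no scales with period inside {band}")
    unit_cols = ["dyad", "channel_a", "channel_b"]
    means = (
        sel.groupby(unit_cols + ["condition"])["coherence"].mean().unstack("condition")
    )
    for c in (cond_a, cond_b):
        if c not in means.columns:
            raise ValueError(f"condition {c!r} missing from spectra")
    paired = means[[cond_a, cond_b]].dropna()
    if len(paired) < 3:
        raise ValueError("need at least 3 paired observations")
    diff = (paired[cond_a] - paired[cond_b]).to_numpy()
    if np.all(diff == 0):
        return 0.0, len(paired) - 1, 1.0
    t, p = _stats.ttest_rel(paired[cond_a], paired[cond_b])
    return float(t), len(paired) - 1, float(p)


def _sample_derangement(rng: np.random.Generator, n: int) -> np.ndarray:
    if n < 2:
        raise ValueError("a derangement needs at least 2 elements")
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


def scrambled_pairs(
    hbdiffs: list[tuple[np.ndarray, np.ndarray]],
    paradigm: Paradigm,
    design: DesignMatrix,
    pairs: list[tuple[int, int]],
    rng_seed: int = 0,
    n_draws: int = 1,
    scales: ScaleSet | None = None,
    sample_rate: float = 30.0,
) -> pd.DataFrame:
    """Scrambled-pair null: partner A of dyad i is paired with partner B of
    dyad j != i (derangement sampling) and the identical coherence pipeline
    is applied.  Returns the concatenated long-format spectra over draws,
    with a ``draw`` column."""
    if len(hbdiffs) < 2:
        raise ValueError("scrambled pairs need at least 2 dyads")
    if scales is None:
        scales = make_scales()
    rng = np.random.default_rng(rng_seed)
    if n_draws == 0:
        return pd.DataFrame(
            columns=["dyad", "channel_a", "channel_b", "condition",
                     "period_s", "coherence", "draw"]
        )

    # coefficients depend only on each participant's own data: cache once
    cache_a = [
        _coef_cache(a, {x for x, _ in pairs}, design, scales, sample_rate)
        for a, _ in hbdiffs
    ]
    cache_b = [
        _coef_cache(b, {y for _, y in pairs}, design, scales, sample_rate)
        for _, b in hbdiffs
    ]
    frames = []
    for draw in range(n_draws):
        perm = _sample_derangement(rng, len(hbdiffs))
        for i, j in enumerate(perm):
            rows = []
            for a, b in pairs:
                coef_a, valid_a = cache_a[i][a]
                coef_b, valid_b = cache_b[j][b]
                valid = valid_a & valid_b
                for cond in CONDITIONS:
                    r = cross_brain_coherence(
                        coef_a, coef_b, paradigm, cond, sample_rate, valid=valid
                    )
                    for s, period in enumerate(scales.periods_s):
                        rows.append(
                            {"dyad": f"scram{draw}_{i:02d}x{j:02d}",
                             "channel_a": a, "channel_b": b, "condition": cond,
                             "period_s": float(period), "coherence": r[s],
                             "draw": draw}
                        )
            frames.append(pd.DataFrame(rows))
    return pd.concat(frames, ignore_index=True)
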