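"""Optical density to chromophore conversion and denoising.

The processing chain is: invert the Beer-Lambert extinction matrix per
channel and timepoint (least squares over the three wavelengths), remove
baseline drift by discrete-wavelet detrending (approximation content at
periods beyond a cutoff is zeroed), remove spatially global systemic
components with a PCA spatial filter (principal components whose loadings
are near-uniform across channels are projected out), and finally combine
oxy- and deoxyhemoglobin into the analysis signal HbDiff.

HbDiff polarity: task-evoked deOxyHb responses are negative-going, so the
reliability-optimizing combination is OxyHb - deOxyHb; that is the default
``mode="difference"``, with ``mode="sum"`` available by configuration.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pywt

from .simulate import EXTINCTION, RawRecording

__all__ = [
    "ChromophoreSeries",
    "mbll_invert",
    "wavelet_detrend",
    "pca_global_filter",
    "combine_hbdiff",
    "preprocess_recording",
]


@dataclass
class ChromophoreSeries:
    """Relative chromophore concentration changes per channel and time."""

    oxy: np.ndarray                # (n_channels, n_samples)
    deoxy: np.ndarray
    sample_rate: float
    hbdiff: np.ndarray | None = None
    hbdiff_mode: str | None = None
    provenance: list = field(default_factory=list)

    def record(self, stage: str, **params) -> None:
        self.provenance.append({"stage": stage, **params})


def mbll_invert(
    rec: RawRecording, extinction: np.ndarray = EXTINCTION
) -> ChromophoreSeries:
    """Least-squares inversion of od = eps @ [oxy, deoxy]^T per channel and
    timepoint (unit pathlength, relative units)."""
    if rec.od.shape[0] != 3:
        raise ValueError("recording must carry three wavelengths")
    extinction = np.asarray(extinction, dtype=np.float64)
    if np.linalg.matrix_rank(extinction) < 2 or np.linalg.cond(extinction) > 1e6:
        raise ValueError("extinction matrix is rank deficient or ill conditioned")
    pinv = np.linalg.pinv(extinction)          # (2, 3)
    chrom = np.einsum("kw,wct->kct", pinv, rec.od)
    out = ChromophoreSeries(
        oxy=chrom[0], deoxy=chrom[1], sample_rate=rec.sample_rate
    )
    out.record("mbll_invert", extinction=extinction.tolist())
    return out


def _detrend_level(
    n_samples: int, sample_rate: float, cutoff_period_s: float, wavelet: str
) -> int:
    # approximation at level L covers frequencies below fs / 2^(L+1); choose
    # the smallest L whose approximation band lies beyond the cutoff period
    level = math.ceil(math.log2(sample_rate * cutoff_period_s)) - 1
    max_level = pywt.dwt_max_level(n_samples, wavelet)
    return max(1, min(level, max_level))


def wavelet_detrend(
    series: np.ndarray,
    sample_rate: float,
    cutoff_period_s: float = 128.0,
    wavelet: str = "sym4",
) -> np.ndarray:
    """Remove slow drift: decompose with a symmetric orthogonal wavelet and
    zero the approximation band at periods beyond ``cutoff_period_s``."""
    x = np.atleast_2d(np.asarray(series, dtype=np.float64))
    n = x.shape[1]
    if n < 2 * cutoff_period_s * sample_rate:
        raise ValueError(
            f"series of {n} samples is shorter than twice the "
            f"{cutoff_period_s} s cutoff at {sample_rate} Hz"
        )
    level = _detrend_level(n, sample_rate, cutoff_period_s, wavelet)
    out = np.empty_like(x)
    for ch in range(x.shape[0]):
        coeffs = pywt.wavedec(x[ch], wavelet, level=level)
        coeffs[0] = np.zeros_like(coeffs[0])
        rec = pywt.waverec(coeffs, wavelet)
        out[ch] = rec[:n]
    return out[0] if np.asarray(series).ndim == 1 else out


def pca_global_filter(
    series: np.ndarray,
    variance_threshold: float = 0.8,
    uniformity_threshold: float = 0.7,
    k: int | None = None,
    return_info: bool = False,
):
    """PCA spatial global mean filter.

    Principal components of the centered channel x time matrix whose spatial
    loadings are near-uniform (|mean loading| * sqrt(n_channels) above the
    uniformity threshold, for unit-norm loadings) are projected out.
    Components are examined in order of explained variance until the
    leading components jointly explain ``variance_threshold`` of the total
    (or ``k`` components have been removed); later, low-variance components
    are left alone.  The output is exactly orthogonal to every removed
    component.
    """
    X = np.asarray(series, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D array with at least 2 channels")
    n_ch, n_t = X.shape
    if n_t < n_ch:
        raise ValueError(
            f"{n_t} timepoints for {n_ch} channels: transpose the input so "
            "channels are rows, or provide more samples"
        )
    means = X.mean(axis=1, keepdims=True)
    Xc = X - means
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    total = var.sum()
    removed: list[int] = []
    removed_var = 0.0
    examined = 0.0
    for i in range(len(s)):
        if total == 0 or examined >= variance_threshold:
            break
        examined += var[i] / total
        uniformity = abs(U[:, i].mean()) * math.sqrt(n_ch)
        if uniformity >= uniformity_threshold:
            removed.append(i)
            removed_var += var[i] / total
            if k is not None and len(removed) >= k:
                break
    Xf = Xc.copy()
    for i in removed:
        u = U[:, i : i + 1]
        Xf -= u @ (u.T @ Xf)
    out = Xf + means
    if return_info:
        info = {
            "removed_components": removed,
            "removed_variance": removed_var,
            "loadings": U[:, removed],
            "uniformity": [abs(U[:, i].mean()) * math.sqrt(n_ch) for i in range(len(s))],
        }
        return out, info
    return out


def combine_hbdiff(
    oxy: np.ndarray, deoxy: np.ndarray, mode: str = "difference"
) -> np.ndarray:
    """Combine chromophores into the analysis signal.

    ``difference`` (default) returns OxyHb - deOxyHb; ``sum`` returns
    OxyHb + deOxyHb.
    """
    oxy = np.asarray(oxy, dtype=np.float64)
    deoxy = np.asarray(deoxy, dtype=np.float64)
    if oxy.shape != deoxy.shape:
        raise ValueError("oxy and deoxy must have the same shape")
    if mode == "difference":
        return oxy - deoxy
    if mode == "sum":
        return oxy + deoxy
    raise ValueError(f"unknown hbdiff mode {mode!r}")


def preprocess_recording(
    rec: RawRecording,
    extinction: np.ndarray = EXTINCTION,
    cutoff_period_s: float = 128.0,
    detrend: bool = True,
    global_filter: bool = True,
    hbdiff_mode: str = "difference",
) -> ChromophoreSeries:
    """Full chain: Beer-Lambert inversion -> wavelet detrending -> PCA
    global filter -> HbDiff combination, with provenance recorded."""
    chrom = mbll_invert(rec, extinction)
    if detrend:
        chrom.oxy = wavelet_detrend(chrom.oxy, rec.sample_rate, cutoff_period_s)
        chrom.deoxy = wavelet_detrend(chrom.deoxy, rec.sample_rate, cutoff_period_s)
        chrom.record("wavelet_detrend", cutoff_period_s=cutoff_period_s)
    if global_filter:
        chrom.oxy, info_o = pca_global_filter(chrom.oxy, return_info=True)
        chrom.deoxy, info_d = pca_global_filter(chrom.deoxy, return_info=True)
        chrom.record(
            "pca_global_filter",
            removed_oxy=info_o["removed_components"],
            removed_deoxy=info_d["removed_components"],
        )
    chrom.hbdiff = combine_hbdiff(chrom.oxy, chrom.deoxy, mode=hbdiff_mode)
    chrom.hbdiff_mode = hbdiff_mode
    chrom.record("combine_hbdiff", mode=hbdiff_mode)
    return chrom
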