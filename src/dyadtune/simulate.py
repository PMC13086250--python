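"""Synthetic dyadic fNIRS recordings with known ground truth.

The forward model mirrors the components an analysis pipeline must contend
with.  Per channel and participant, oxyhemoglobin is

    OxyHb(t) = sum_c beta_c * (boxcar_c (x) HRF)   task response
             + global(t)                            systemic physiology
             + coupled(t)                           cross-brain component
             + noise(t)

where ``global(t)`` is shared across the participant's channels (cardiac
~1 Hz, respiratory ~0.25 Hz, Mayer ~0.1 Hz sinusoids plus random-walk
drift, with mild per-channel gains), ``coupled(t)`` is a band-limited
Gaussian process at a chosen period, mixed into designated channels of both
partners only during designated condition blocks so that the partners'
components correlate at a chosen strength r, and deoxyhemoglobin is the
anticorrelated counterpart -gamma*(task + coupled) with its own systemic
terms and noise.  Chromophores are mapped to three-wavelength optical
densities through a forward Beer-Lambert extinction matrix, producing raw
recordings at 30 Hz over 29 abstract channels per participant.

The paradigm builder produces the 2x2 block design: per run, four 15 s task
blocks (one per condition, order shuffled) each followed by 15 s rest;
eight runs, 16 minutes total.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "WAVELENGTHS_NM",
    "EXTINCTION",
    "Block",
    "Paradigm",
    "Coupling",
    "DyadGroundTruth",
    "RawRecording",
    "make_paradigm",
    "default_truth",
    "simulate_dyad",
    "simulate_experiment",
    "forward_beer_lambert",
    "simulate_ratings",
    "save_recording",
    "load_recording",
]

CONDITIONS = ("face_chord", "face_nochord", "noface_chord", "noface_nochord")
WAVELENGTHS_NM = (780, 805, 830)

# Extinction coefficients (rows: 780/805/830 nm; columns: HbO, HbR), in
# arbitrary units proportional to mm^-1 mM^-1, following the shape of the
# standard compiled hemoglobin spectra: HbR dominates below the ~805 nm
# isosbestic point, HbO above it.
EXTINCTION = np.array(
    [
        [0.736, 1.102],
        [0.911, 0.822],
        [1.058, 0.781],
    ]
)


@dataclass(frozen=True)
class Block:
    run_index: int
    onset_s: float
    duration_s: float
    condition: str


@dataclass
class Paradigm:
    """Block timing of the 2x2 (face x chord) design plus rests."""

    blocks: list[Block]
    run_length_s: float
    n_runs: int

    @property
    def total_duration_s(self) -> float:
        return self.n_runs * self.run_length_s

    def task_blocks(self, condition: str | None = None) -> list[Block]:
        out = [b for b in self.blocks if b.condition != "rest"]
        if condition is not None:
            out = [b for b in out if b.condition == condition]
        return out

    def boxcar(self, condition: str, n_samples: int, sample_rate: float) -> np.ndarray:
        """0/1 indicator of the condition's blocks, sampled at sample_rate."""
        box = np.zeros(n_samples)
        for b in self.blocks:
            if b.condition == condition:
                i0 = int(round(b.onset_s * sample_rate))
                i1 = int(round((b.onset_s + b.duration_s) * sample_rate))
                box[i0:min(i1, n_samples)] = 1.0
        return box

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"run_index": b.run_index, "onset_s": b.onset_s,
                 "duration_s": b.duration_s, "condition": b.condition}
                for b in self.blocks
            ]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def make_paradigm(
    n_runs: int = 8,
    task_s: float = 15.0,
    rest_s: float = 15.0,
    order_seed: int = 0,
) -> Paradigm:
    """Build the block paradigm: per run, each of the four conditions once
    (order shuffled by ``order_seed``), each task block followed by rest."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = np.random.default_rng(order_seed)
    run_length = 4 * (task_s + rest_s)
    blocks: list[Block] = []
    for run in range(n_runs):
        order = rng.permutation(4)
        t = run * run_length
        for k in order:
            blocks.append(Block(run, t, task_s, CONDITIONS[k]))
            t += task_s
            blocks.append(Block(run, t, rest_s, "rest"))
            t += rest_s
    return Paradigm(blocks=blocks, run_length_s=run_length, n_runs=n_runs)


@dataclass(frozen=True)
class Coupling:
    """A cross-brain coupled component between one channel of each partner."""

    channel_a: int
    channel_b: int
    conditions: tuple[str, ...]
    period_s: float
    strength: float  # correlation r in [0, 1] between the partners' components

    def __post_init__(self) -> None:
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("coupling strength must be in [0, 1]")
        if not 2.5 <= self.period_s <= 40.0:
            raise ValueError("coupling period must lie in the 2.5-40 s analysis span")


@dataclass
class DyadGroundTruth:
    """Known simulation parameters: per-condition amplitudes, coupling
    targets, systemic amplitudes and noise level."""

    beta_true: np.ndarray                  # (2, n_channels, n_conditions)
    coupling: list[Coupling] = field(default_factory=list)
    noise_sd: float = 0.3
    coupled_sd: float = 0.4
    gamma: float = 1.0 / 3.0               # deOxyHb anticorrelation ratio
    global_amps: dict = field(
        default_factory=lambda: {
            "cardiac": 0.25, "respiratory": 0.2, "mayer": 0.3, "drift": 0.2
        }
    )

    @property
    def n_channels(self) -> int:
        return self.beta_true.shape[1]


SIGNAL_CHANNELS = tuple(range(10))
DEFAULT_COUPLING_PAIRS = ((4, 4), (12, 12), (20, 20))


def default_truth(n_channels: int = 29) -> DyadGroundTruth:
    """Default ground truth: ten signal channels responding to every
    condition with amplitude 0.5 and to face_chord with 1.0; cross-brain
    coupling r = 0.6 at period 15 s during face_chord on three channel
    pairs."""
    beta = np.zeros((2, n_channels, len(CONDITIONS)))
    for ch in SIGNAL_CHANNELS:
        beta[:, ch, :] = 0.5
        beta[:, ch, CONDITIONS.index("face_chord")] = 1.0
    coupling = [
        Coupling(a, b, ("face_chord",), period_s=15.0, strength=0.6)
        for a, b in DEFAULT_COUPLING_PAIRS
    ]
    return DyadGroundTruth(beta_true=beta, coupling=coupling)


@dataclass
class RawRecording:
    """Per-participant optical-density changes at three wavelengths."""

    od: np.ndarray                 # (3 wavelengths, n_channels, n_samples)
    sample_rate: float
    participant_id: str
    dyad_id: str
    wavelengths_nm: tuple = WAVELENGTHS_NM
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.od.shape[0] != 3:
            raise ValueError("recording must carry exactly three wavelengths")
        if not np.all(np.isfinite(self.od)):
            raise ValueError("optical densities must be finite")


def forward_beer_lambert(
    oxy: np.ndarray, deoxy: np.ndarray, extinction: np.ndarray = EXTINCTION
) -> np.ndarray:
    """Map chromophore series to optical densities, unit pathlength:
    od(lambda, t) = eps(lambda, HbO) oxy(t) + eps(lambda, HbR) deoxy(t).

    ``oxy``/``deoxy`` may be 1-D (single channel) or (channels, time).
    Returns (3, channels, time) (channel axis squeezed away for 1-D input).
    """
    oxy = np.asarray(oxy, dtype=np.float64)
    deoxy = np.asarray(deoxy, dtype=np.float64)
    if oxy.shape != deoxy.shape:
        raise ValueError("oxy and deoxy must have the same shape")
    if np.linalg.cond(extinction) > 1e6:
        raise ValueError("extinction matrix is ill conditioned")
    squeeze = oxy.ndim == 1
    chrom = np.stack([np.atleast_2d(oxy), np.atleast_2d(deoxy)])  # (2, ch, t)
    od = np.einsum("wk,kct->wct", extinction, chrom)
    return od[:, 0, :] if squeeze else od


def _band_limited_noise(
    rng: np.random.Generator, n: int, fs: float, period_s: float, rel_bw: float = 0.25
) -> np.ndarray:
    """Unit-variance Gaussian process band-limited around 1/period_s by a
    Gaussian spectral window with relative bandwidth ``rel_bw``."""
    white = rng.standard_normal(n)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    f0 = 1.0 / period_s
    window = np.exp(-0.5 * ((f - f0) / (rel_bw * f0)) ** 2)
    x = np.fft.irfft(np.fft.rfft(white) * window, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _systemic_global(
    rng: np.random.Generator, n: int, fs: float, amps: dict
) -> np.ndarray:
    """One participant's shared systemic waveform (unit channel gain)."""
    t = np.arange(n) / fs
    g = np.zeros(n)
    for name, f_lo, f_hi in (
        ("cardiac", 0.9, 1.1),
        ("respiratory", 0.22, 0.28),
        ("mayer", 0.09, 0.11),
    ):
        amp = amps.get(name, 0.0)
        if amp > 0:
            freq = rng.uniform(f_lo, f_hi)
            phase = rng.uniform(0, 2 * np.pi)
            g += amp * np.sin(2 * np.pi * freq * t + phase)
    drift_amp = amps.get("drift", 0.0)
    if drift_amp > 0:
        walk = np.cumsum(rng.standard_normal(n))
        walk -= walk.mean()
        sd = walk.std()
        if sd > 0:
            g += drift_amp * walk / sd
    return g


def simulate_dyad(
    paradigm: Paradigm,
    truth: DyadGroundTruth | None = None,
    rng_seed: int = 0,
    sample_rate: float = 30.0,
    dyad_id: str = "dyad00",
) -> tuple[RawRecording, RawRecording, DyadGroundTruth]:
    """Simulate both partners' raw three-wavelength recordings."""
    from .glm import canonical_hrf  # local import; glm imports Paradigm from here

    if truth is None:
        truth = default_truth()
    n_ch = truth.n_channels
    if truth.beta_true.shape != (2, n_ch, len(CONDITIONS)):
        raise ValueError("beta_true must have shape (2, n_channels, n_conditions)")
    for c in truth.coupling:
        if not (0 <= c.channel_a < n_ch and 0 <= c.channel_b < n_ch):
            raise ValueError("coupling channels out of range")

    rng = np.random.default_rng(rng_seed)
    n = int(round(paradigm.total_duration_s * sample_rate))
    hrf = canonical_hrf(1.0 / sample_rate)
    regs = np.stack(
        [
            np.convolve(paradigm.boxcar(c, n, sample_rate), hrf)[:n]
            for c in CONDITIONS
        ]
    )  # (n_cond, n)

    # cross-brain coupled components
    coupled = np.zeros((2, n_ch, n))
    for c in truth.coupling:
        shared = _band_limited_noise(rng, n, sample_rate, c.period_s)
        gate = np.zeros(n)
        for cond in c.conditions:
            gate += paradigm.boxcar(cond, n, sample_rate)
        gate = np.clip(gate, 0, 1)
        for p, ch in ((0, c.channel_a), (1, c.channel_b)):
            own = _band_limited_noise(rng, n, sample_rate, c.period_s)
            comp = math.sqrt(c.strength) * shared + math.sqrt(1 - c.strength) * own
            coupled[p, ch] += truth.coupled_sd * comp * gate

    recordings = []
    for p in range(2):
        task = np.einsum("ck,kt->ct", truth.beta_true[p], regs)  # (ch, n)
        g = _systemic_global(rng, n, sample_rate, truth.global_amps)
        gains_oxy = rng.uniform(0.8, 1.2, size=n_ch)
        gains_deoxy = rng.uniform(0.8, 1.2, size=n_ch)
        g_deoxy = _systemic_global(
            rng, n, sample_rate, {k: 0.4 * v for k, v in truth.global_amps.items()}
        )
        noise_oxy = truth.noise_sd * rng.standard_normal((n_ch, n))
        noise_deoxy = 0.5 * truth.noise_sd * rng.standard_normal((n_ch, n))

        evoked = task + coupled[p]
        oxy = evoked + gains_oxy[:, None] * g[None, :] + noise_oxy
        deoxy = (
            -truth.gamma * evoked + gains_deoxy[:, None] * g_deoxy[None, :] + noise_deoxy
        )
        od = forward_beer_lambert(oxy, deoxy)
        recordings.append(
            RawRecording(
                od=od,
                sample_rate=sample_rate,
                participant_id=f"{dyad_id}_{'AB'[p]}",
                dyad_id=dyad_id,
                meta={"rng_seed": rng_seed, "partner": "AB"[p]},
            )
        )
    return recordings[0], recordings[1], truth


def simulate_experiment(
    n_dyads: int = 20,
    seed: int = 0,
    truth: DyadGroundTruth | None = None,
    paradigm: Paradigm | None = None,
    sample_rate: float = 30.0,
) -> tuple[list[tuple[RawRecording, RawRecording]], Paradigm, DyadGroundTruth]:
    """Simulate a whole experiment: ``n_dyads`` dyads sharing one paradigm.

    Per-dyad seeds are spawned from a single root seed so the entire
    synthetic experiment is reproducible from one integer.
    """
    if paradigm is None:
        paradigm = make_paradigm(order_seed=seed)
    if truth is None:
        truth = default_truth()
    child_seeds = np.random.SeedSequence(seed).generate_state(n_dyads) % (2**31)
    dyads = []
    for d in range(n_dyads):
        a, b, _ = simulate_dyad(
            paradigm, truth, rng_seed=int(child_seeds[d]),
            sample_rate=sample_rate, dyad_id=f"dyad{d:02d}",
        )
        dyads.append((a, b))
    return dyads, paradigm, truth


# ---------------------------------------------------------------------------
# Synthetic connectedness ratings
# ---------------------------------------------------------------------------

RATING_CONDITIONS = CONDITIONS + ("baseline",)

DEFAULT_RATING_SHIFTS = {
    "face_chord": 3.4,
    "face_nochord": 2.6,
    "noface_chord": 2.1,
    "noface_nochord": 1.7,
    "baseline": 2.0,
}


def simulate_ratings(
    n_participants: int = 40,
    n_runs: int = 8,
    seed: int = 0,
    shifts: dict | None = None,
    rater_sd: float = 0.5,
    noise_sd: float = 0.8,
    retroactive_fraction: float = 0.6,
) -> pd.DataFrame:
    """Synthetic 0-5 connectedness ratings with the qualitative structure of
    the study: highest for face_chord, lowest for noface_nochord, baseline in
    between.  A latent per-rater offset plus condition shift plus noise is
    rounded and clipped into [0, 5]; zeros that arise are nonanswers."""
    if shifts is None:
        shifts = DEFAULT_RATING_SHIFTS
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_participants):
        offset = rng.normal(0.0, rater_sd)
        retro = bool(rng.random() < retroactive_fraction)
        for run in range(n_runs):
            cond = CONDITIONS[run % 4]
            latent = shifts[cond] + offset + rng.normal(0.0, noise_sd)
            rows.append(
                {"participant": p, "run_index": run, "condition": cond,
                 "rating": int(np.clip(round(latent), 0, 5)),
                 "retroactive_flag": False}
            )
        latent = shifts["baseline"] + offset + rng.normal(0.0, noise_sd)
        rows.append(
            {"participant": p, "run_index": -1, "condition": "baseline",
             "rating": int(np.clip(round(latent), 0, 5)),
             "retroactive_flag": retro}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# HDF5 serialization
# ---------------------------------------------------------------------------

def save_recording(rec: RawRecording, path) -> None:
    """Write a recording to HDF5 (groups /od/<wavelength>, attrs under /meta)."""
    with h5py.File(path, "w") as f:
        g = f.create_group("od")
        for i, wl in enumerate(rec.wavelengths_nm):
            g.create_dataset(str(wl), data=rec.od[i], compression="gzip")
        m = f.create_group("meta")
        m.attrs["sample_rate"] = rec.sample_rate
        m.attrs["participant_id"] = rec.participant_id
        m.attrs["dyad_id"] = rec.dyad_id
        m.attrs["wavelengths_nm"] = list(rec.wavelengths_nm)
        for k, v in rec.meta.items():
            m.attrs[f"x_{k}"] = v


def load_recording(path) -> RawRecording:
    with h5py.File(path, "r") as f:
        wls = tuple(int(w) for w in f["meta"].attrs["wavelengths_nm"])
        od = np.stack([f["od"][str(wl)][()] for wl in wls])
        meta = {
            k[2:]: v for k, v in f["meta"].attrs.items() if k.startswith("x_")
        }
        return RawRecording(
            od=od,
            sample_rate=float(f["meta"].attrs["sample_rate"]),
            participant_id=str(f["meta"].attrs["participant_id"]),
            dyad_id=str(f["meta"].attrs["dyad_id"]),
            wavelengths_nm=wls,
            meta=meta,
        )
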