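"""Block-design GLM per channel and participant, group contrasts, and
ratings-as-covariate association.

First-level model: per-condition boxcars convolved with a canonical
double-gamma hemodynamic response function (response peak 6 s, undershoot
peak 16 s, peak-to-undershoot ratio 6, 32 s support), fit per channel by
ordinary least squares.  Second level: one-sample t-test across participants
of a per-participant contrast of beta values, uncorrected p-values per
channel (a Benjamini-Hochberg option exists but is off by default, matching
the uncorrected p < 0.05 convention of block-design fNIRS maps).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special as _special
from scipy import stats as _stats

from .simulate import CONDITIONS, Paradigm

__all__ = [
    "DesignMatrix",
    "BetaTable",
    "canonical_hrf",
    "build_design",
    "fit_glm",
    "group_contrast",
    "covariate_association",
]


def canonical_hrf(dt_s: float, length_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at ``dt_s``, unit peak.

    h(t) = g(t; mode 6 s) - (1/6) g(t; mode 16 s) with gamma densities of
    unit rate, so the response peaks at 6 s and the undershoot at 16 s with
    a 6:1 peak ratio.
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    t = np.arange(0.0, length_s + dt_s / 2, dt_s)
    peak = t**6 * np.exp(-t) / _special.gamma(7)
    undershoot = t**16 * np.exp(-t) / _special.gamma(17)
    h = peak - undershoot / 6.0
    return h / np.max(h)


@dataclass
class DesignMatrix:
    """HRF-convolved condition regressors plus an intercept column."""

    X: np.ndarray                 # (n_samples, n_columns)
    labels: list[str]
    sample_rate: float

    @property
    def condition_labels(self) -> list[str]:
        return [c for c in self.labels if c != "intercept"]

    def column(self, label: str) -> np.ndarray:
        return self.X[:, self.labels.index(label)]


def build_design(
    paradigm: Paradigm,
    hrf: np.ndarray | None = None,
    sample_rate: float = 30.0,
    n_samples: int | None = None,
) -> DesignMatrix:
    """One HRF-convolved boxcar column per task condition, plus intercept."""
    if n_samples is None:
        n_samples = int(round(paradigm.total_duration_s * sample_rate))
    if hrf is None:
        hrf = canonical_hrf(1.0 / sample_rate)

    task_blocks = [b for b in paradigm.blocks if b.condition != "rest"]
    ends = sorted((b.onset_s, b.onset_s + b.duration_s) for b in task_blocks)
    for (s1, e1), (s2, _e2) in zip(ends, ends[1:]):
        if s2 < e1 - 1e-9:
            raise ValueError("overlapping task blocks in paradigm")

    conditions = [c for c in CONDITIONS if any(b.condition == c for b in task_blocks)]
    cols, labels = [], []
    for cond in conditions:
        box = paradigm.boxcar(cond, n_samples, sample_rate)
        cols.append(np.convolve(box, hrf)[:n_samples])
        labels.append(cond)
    cols.append(np.ones(n_samples))
    labels.append("intercept")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return DesignMatrix(X=X, labels=labels, sample_rate=sample_rate)


def fit_glm(y: np.ndarray, design: DesignMatrix) -> tuple[np.ndarray, np.ndarray]:
    """OLS fit of each channel onto the design.

    Parameters
    ----------
    y
        Signal array, either ``(n_samples,)`` or ``(n_channels, n_samples)``.

    Returns
    -------
    betas : (n_channels, n_columns)
    resid_var : (n_channels,) residual variance (denominator n - p)
    """
    Y = np.atleast_2d(np.asarray(y, dtype=np.float64))
    X = design.X
    if Y.shape[1] != X.shape[0]:
        raise ValueError(
            f"signal length {Y.shape[1]} does not match design length {X.shape[0]}"
        )
    beta, _, _, _ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y.T - X @ beta
    dof = max(1, X.shape[0] - X.shape[1])
    resid_var = (resid**2).sum(axis=0) / dof
    return beta.T, resid_var


@dataclass
class BetaTable:
    """Per-participant, per-channel, per-condition beta values."""

    beta: np.ndarray              # (n_participants, n_channels, n_conditions)
    conditions: list[str]
    resid_var: np.ndarray | None = None   # (n_participants, n_channels)

    @property
    def n_participants(self) -> int:
        return self.beta.shape[0]

    def contrast_values(self, contrast) -> np.ndarray:
        """Per-participant, per-channel contrast of condition betas."""
        w = np.asarray(contrast, dtype=np.float64)
        if w.shape != (len(self.conditions),):
            raise ValueError(
                f"contrast length {w.shape} does not match {len(self.conditions)} conditions"
            )
        return np.einsum("pck,k->pc", self.beta, w)

    def to_frame(self) -> pd.DataFrame:
        p, c, k = self.beta.shape
        idx = pd.MultiIndex.from_product(
            [range(p), range(c), self.conditions],
            names=["participant", "channel", "condition"],
        )
        return pd.DataFrame({"beta": self.beta.reshape(-1)}, index=idx).reset_index()


def group_contrast(
    betas: BetaTable, contrast, fdr: bool = False
) -> pd.DataFrame:
    """One-sample t-test across participants of the contrast value, per
    channel.  ``df = n - 1``; two-sided p.  Channels where every participant
    has an identical value are flagged degenerate."""
    if betas.n_participants < 3:
        raise ValueError("group contrast needs at least 3 participants")
    v = betas.contrast_values(contrast)         # (p, channels)
    n = v.shape[0]
    mean = v.mean(axis=0)
    sd = v.std(axis=0, ddof=1)
    rows = []
    for ch in range(v.shape[1]):
        if sd[ch] == 0:
            rows.append(
                {"channel": ch, "mean": mean[ch], "t": math.nan, "df": n - 1,
                 "p": math.nan, "flag": "degenerate"}
            )
        else:
            t = mean[ch] / (sd[ch] / math.sqrt(n))
            p = 2 * _stats.t.sf(abs(t), df=n - 1)
            rows.append(
                {"channel": ch, "mean": mean[ch], "t": float(t), "df": n - 1,
                 "p": float(p), "flag": ""}
            )
    out = pd.DataFrame(rows)
    if fdr:
        ok = out["p"].notna()
        out.loc[ok, "p_fdr"] = _stats.false_discovery_control(out.loc[ok, "p"])
    return out


def covariate_association(
    betas: BetaTable, ratings: pd.DataFrame, contrast
) -> pd.DataFrame:
    """Per-channel regression of participant contrast values on the matched
    contrast of their mean condition ratings.

    ``ratings`` needs columns ``participant``, ``condition`` and ``rating``
    (0 = nonanswer, excluded); participants are matched to the beta table by
    order of their sorted identifiers.
    """
    v = betas.contrast_values(contrast)
    n = v.shape[0]
    if n < 3:
        raise ValueError("covariate association needs at least 3 participants")

    valid = ratings[ratings["rating"] > 0]
    means = valid.pivot_table(index="participant", columns="condition",
                              values="rating", aggfunc="mean")
    participants = sorted(means.index)[:n]
    if len(participants) < n:
        raise ValueError("ratings table covers fewer participants than the beta table")
    w = np.asarray(contrast, dtype=np.float64)
    cov = np.zeros(n)
    for i, pid in enumerate(participants):
        cov[i] = sum(
            w[k] * means.loc[pid, cond]
            for k, cond in enumerate(betas.conditions)
            if w[k] != 0
        )
    if np.std(cov) == 0:
        raise ValueError("constant ratings covariate: association undefined")

    rows = []
    for ch in range(v.shape[1]):
        res = _stats.linregress(cov, v[:, ch])
        t = res.slope / res.stderr if res.stderr > 0 else math.nan
        rows.append(
            {"channel": ch, "slope": float(res.slope), "t": float(t),
             "p": float(res.pvalue), "df": n - 2,
             "significant": bool(res.pvalue < 0.05)}
        )
    return pd.DataFrame(rows)
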