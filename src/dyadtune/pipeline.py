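"""Configuration, provenance and the end-to-end orchestrator.

A single root seed deterministically derives one seed per stage (a CRC of
the stage label folded into the root), so re-running with the same config
reproduces every deterministic artifact bit-identically.  The orchestrator
runs stimuli -> acoustic features -> dyad simulation -> preprocessing ->
GLM contrasts -> cross-brain coherence (true + scrambled pairs) ->
behavioral statistics, and writes a manifest recording inputs, parameters,
seeds and output hashes.
"""
from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, coherence, features, glm, preprocess, simulate, stimulus

__all__ = ["RunConfig", "PipelineError", "derive_seed", "run_pipeline", "validate_io"]

logger = logging.getLogger("dyadtune")

VERSION = "0.1.0"


def derive_seed(root_seed: int, label: str) -> int:
    """Deterministic per-stage seed: CRC32 of the label folded into the
    root seed, reduced below 2^31."""
    return (root_seed * 1000003 + zlib.crc32(label.encode())) % (2**31)


@dataclass
class RunConfig:
    """Fully serializable pipeline configuration."""

    seed: int = 0
    outdir: str = "dyadtune_out"
    n_dyads: int = 20
    sample_rate_audio: int = 22050
    stimuli: dict = field(default_factory=dict)       # compose/render overrides
    simulation: dict = field(default_factory=dict)    # n_runs, noise overrides
    coherence_pairs: list = field(
        default_factory=lambda: [list(p) for p in simulate.DEFAULT_COUPLING_PAIRS]
    )
    n_scrambled_draws: int = 1
    hbdiff_mode: str = "difference"
    version: str = VERSION

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order; returns the summary report dict.

    Artifacts (CSV tables, manifest JSON) are written under
    ``config.outdir``.  Any stage failure halts with the stage name and
    cause.
    """
    if not config.outdir:
        raise ValueError("config field 'outdir' must name an output directory")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": config.config_hash()}
    outputs: dict[str, Path] = {}

    def stage(name):
        logger.info("stage: %s", name)

    # -- stimuli + acoustic features ------------------------------------
    try:
        stage("stimuli")
        cp, ncp = stimulus.build_stimulus_sets(derive_seed(config.seed, "stimuli"))
        patch = stimulus.default_patch(seed=derive_seed(config.seed, "patch"))
        clips = [
            stimulus.render_audio(s, patch, config.sample_rate_audio)
            for s in cp + ncp
        ]
    except Exception as e:  # noqa: BLE001
        raise PipelineError("stimuli", e) from e

    try:
        stage("acoustic_features")
        table = features.features_table(clips)
        table.to_csv(outdir / "features.csv", index=False)
        outputs["features.csv"] = outdir / "features.csv"
        comp = features.compare_conditions(table.iloc[:12], table.iloc[12:])
        comp.to_csv(outdir / "feature_comparison.csv", index=False)
        outputs["feature_comparison.csv"] = outdir / "feature_comparison.csv"
        report["feature_comparison"] = comp.to_dict("records")
    except Exception as e:  # noqa: BLE001
        raise PipelineError("acoustic_features", e) from e

    # -- simulate + preprocess + GLM ------------------------------------
    try:
        stage("simulate")
        sim_kwargs = dict(config.simulation)
        dyads, paradigm, truth = simulate.simulate_experiment(
            n_dyads=config.n_dyads, seed=derive_seed(config.seed, "simulate"),
            **sim_kwargs,
        )
        paradigm.to_csv(outdir / "paradigm.csv")
        outputs["paradigm.csv"] = outdir / "paradigm.csv"
    except Exception as e:  # noqa: BLE001
        raise PipelineError("simulate", e) from e

    try:
        stage("preprocess")
        hbdiffs = []
        for a, b in dyads:
            ca = preprocess.preprocess_recording(a, hbdiff_mode=config.hbdiff_mode)
            cb = preprocess.preprocess_recording(b, hbdiff_mode=config.hbdiff_mode)
            hbdiffs.append((ca.hbdiff, cb.hbdiff))
    except Exception as e:  # noqa: BLE001
        raise PipelineError("preprocess", e) from e

    try:
        stage("glm")
        design = glm.build_design(
            paradigm, sample_rate=dyads[0][0].sample_rate
        )
        all_betas = []
        for a_hb, b_hb in hbdiffs:
            for hb in (a_hb, b_hb):
                beta, _ = glm.fit_glm(hb, design)
                all_betas.append(beta[:, : len(simulate.CONDITIONS)])
        betas = glm.BetaTable(
            beta=np.stack(all_betas), conditions=list(simulate.CONDITIONS)
        )
        contrast = [1, -1, 0, 0]  # face_chord - face_nochord
        contrast_table = glm.group_contrast(betas, contrast)
        contrast_table.to_csv(outdir / "contrast_face_chord_vs_nochord.csv", index=False)
        outputs["contrast.csv"] = outdir / "contrast_face_chord_vs_nochord.csv"
        report["contrast_significant_channels"] = int(
            (contrast_table["p"] < 0.05).sum()
        )
    except Exception as e:  # noqa: BLE001
        raise PipelineError("glm", e) from e

    # -- coherence -------------------------------------------------------
    try:
        stage("coherence")
        pairs = [tuple(p) for p in config.coherence_pairs]
        scales = coherence.make_scales()
        spectra = coherence.experiment_coherence(
            hbdiffs, paradigm, design, pairs, scales,
            sample_rate=dyads[0][0].sample_rate,
        )
        spectra.to_csv(outdir / "coherence.csv", index=False)
        outputs["coherence.csv"] = outdir / "coherence.csv"
        band_summary = {}
        for other in simulate.CONDITIONS[1:]:
            t, dfree, p = coherence.band_compare(spectra, "face_chord", other)
            band_summary[f"face_chord_vs_{other}"] = {"t": t, "df": dfree, "p": p}
        report["coherence_band_10_20s"] = band_summary
        if config.n_scrambled_draws > 0 and config.n_dyads >= 2:
            null = coherence.scrambled_pairs(
                hbdiffs, paradigm, design, pairs,
                rng_seed=derive_seed(config.seed, "scrambled"),
                n_draws=config.n_scrambled_draws, scales=scales,
                sample_rate=dyads[0][0].sample_rate,
            )
            null.to_csv(outdir / "coherence_scrambled.csv", index=False)
            outputs["coherence_scrambled.csv"] = outdir / "coherence_scrambled.csv"
            t, dfree, p = coherence.band_compare(null, "face_chord", "face_nochord")
            report["scrambled_face_chord_vs_nochord"] = {"t": t, "df": dfree, "p": p}
    except Exception as e:  # noqa: BLE001
        raise PipelineError("coherence", e) from e

    # -- behavior --------------------------------------------------------
    try:
        stage("behavior")
        ratings = simulate.simulate_ratings(seed=derive_seed(config.seed, "ratings"))
        ratings.to_csv(outdir / "ratings.csv", index=False)
        outputs["ratings.csv"] = outdir / "ratings.csv"
        h, dfree, p = behavior.kruskal_wallis(ratings)
        report["ratings_kruskal"] = {"H": h, "df": dfree, "p": p}
        report["condition_means"] = behavior.condition_means(ratings).to_dict("records")
        behavior.games_howell(ratings).to_csv(outdir / "games_howell.csv", index=False)
        outputs["games_howell.csv"] = outdir / "games_howell.csv"
    except Exception as e:  # noqa: BLE001
        raise PipelineError("behavior", e) from e

    # -- manifest --------------------------------------------------------
    manifest = {
        "version": config.version,
        "config": json.loads(config.to_json()),
        "config_hash": config.config_hash(),
        "stage_seeds": {
            name: derive_seed(config.seed, name)
            for name in ("stimuli", "patch", "simulate", "scrambled", "ratings")
        },
        "outputs": {name: _sha256(p) for name, p in outputs.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    report["manifest"] = manifest
    return report


# ---------------------------------------------------------------------------
# Input validation
# ---------------------------------------------------------------------------

def validate_io(files: list[str | Path]) -> list[dict]:
    """Schema checks for CSV/HDF5/WAV inputs; per-file diagnostics."""
    out = []
    for f in files:
        p = Path(f)
        diag = {"file": str(p), "ok": True, "messages": []}
        if not p.exists():
            diag["ok"] = False
            diag["messages"].append("file does not exist")
            out.append(diag)
            continue
        suffix = p.suffix.lower()
        try:
            if suffix == ".csv":
                df = pd.read_csv(p)
                if {"participant", "condition", "rating"} <= set(df.columns):
                    bad = df[(df["rating"] < 0) | (df["rating"] > 5)]
                    for i in bad.index:
                        diag["ok"] = False
                        diag["messages"].append(
                            f"row {i}: rating {df.loc[i, 'rating']} outside [0, 5]"
                        )
                elif {"onset_s", "duration_s", "condition"} <= set(df.columns):
                    if (df["duration_s"] <= 0).any():
                        diag["ok"] = False
                        diag["messages"].append("nonpositive block duration")
                else:
                    diag["messages"].append("unrecognized CSV schema (no checks applied)")
            elif suffix in (".h5", ".hdf5"):
                import h5py

                with h5py.File(p, "r") as h:
                    if "od" not in h:
                        diag["ok"] = False
                        diag["messages"].append("missing /od group")
                    else:
                        n_wl = len(h["od"].keys())
                        if n_wl != 3:
                            diag["ok"] = False
                            diag["messages"].append(
                                f"expected 3 wavelengths under /od, found {n_wl}"
                            )
            elif suffix == ".wav":
                clip = stimulus.read_wav(p)
                if len(clip.samples) == 0:
                    diag["ok"] = False
                    diag["messages"].append("empty audio")
            else:
                diag["messages"].append("unknown file type (no checks applied)")
        except Exception as e:  # noqa: BLE001
            diag["ok"] = False
            diag["messages"].append(f"unreadable: {e}")
        out.append(diag)
    return out
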