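import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def stimulus_features():
    """The regenerated 24-stimulus set (default seed) with its feature table.

    Shared across tests: rendering and feature extraction run once.
    """
    from dyadtune import features, stimulus

    cp_set, ncp_set = stimulus.build_stimulus_sets(0)
    patch = stimulus.default_patch(0)
    clips = [stimulus.render_audio(s, patch) for s in cp_set + ncp_set]
    table = features.features_table(clips)
    return {
        "cp_scores": cp_set,
        "ncp_scores": ncp_set,
        "clips": clips,
        "table": table,
        "cp_rows": table.iloc[:12],
        "ncp_rows": table.iloc[12:],
    }


@pytest.fixture(scope="session")
def experiment20():
    """Twenty simulated dyads run through the full pipeline (default seed)."""
    from dyadtune import coherence, glm, preprocess, simulate

    dyads, paradigm, truth = simulate.simulate_experiment(n_dyads=20, seed=0)
    hbdiffs = [
        (
            preprocess.preprocess_recording(a).hbdiff,
            preprocess.preprocess_recording(b).hbdiff,
        )
        for a, b in dyads
    ]
    design = glm.build_design(paradigm, sample_rate=dyads[0][0].sample_rate)
    betas = np.stack(
        [
            glm.fit_glm(hb, design)[0][:, : len(simulate.CONDITIONS)]
            for pair in hbdiffs
            for hb in pair
        ]
    )
    beta_table = glm.BetaTable(beta=betas, conditions=list(simulate.CONDITIONS))
    pairs = [tuple(p) for p in simulate.DEFAULT_COUPLING_PAIRS]
    spectra = coherence.experiment_coherence(hbdiffs, paradigm, design, pairs)
    return {
        "dyads": dyads,
        "paradigm": paradigm,
        "truth": truth,
        "hbdiffs": hbdiffs,
        "design": design,
        "beta_table": beta_table,
        "pairs": pairs,
        "spectra": spectra,
    }
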