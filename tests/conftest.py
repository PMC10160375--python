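import numpy as np
import pandas as pd
import pytest

from eegsa import spectral, synth


@pytest.fixture(scope="session")
def clean_tone_spec():
    """Noise-free single-subject spec: one frontal channel, alpha tone only."""
    return synth.SynthSpec(
        duration=10.0,
        channels_per_region={"F": 1},
        band_amplitudes={"high": {"F": {"alpha": 10.0}}},
        pink_noise_sd=0.0,
        line_noise_amp=0.0,
        artifact_rate=0.0,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A short two-group cohort with the default planted F/C differences."""
    spec = synth.default_spec(duration=60.0, seed=11)
    return synth.generate_cohort(spec, n_high=4, n_low=4, seed=11)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    """Epoch feature table (all five metrics, four regions) for the cohort."""
    tables = []
    for rec in small_cohort:
        clean = spectral.remove_line_noise(rec)
        tables.append(
            spectral.extract_features(
                clean,
                metrics=spectral.METRICS,
                regions=("F", "C", "P", "O"),
            )
        )
    return pd.concat(tables, ignore_index=True)


@pytest.fixture(scope="session")
def selected_feature_table(small_features):
    """The 12-column selected feature table (mean/median of the F/C trio)."""
    cols = [
        spectral.feature_name(r, stat, m)
        for m in spectral.CORRELATED_METRICS
        for r in ("F", "C")
        for stat in ("mean", "median")
    ]
    meta = ["subject_id", "group", "epoch_index", "start_s"]
    return small_features[meta + cols]


@pytest.fixture(scope="session")
def labels(selected_feature_table):
    return (selected_feature_table["group"] == "low").astype(int).to_numpy()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
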