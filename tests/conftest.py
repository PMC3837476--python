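import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from megprime.containers import EpochSet
from megprime.synth import SimulationSpec, generate_design, simulate_rts

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_spec():
    """Four subjects, four trials/condition, quiet RTs: fast fixtures."""
    return SimulationSpec(
        n_subjects=4,
        trials_per_condition=4,
        n_nonword_trials=8,
        subject_sd=30.0,
        item_sd=10.0,
        residual_sd=20.0,
        seed=123,
    )


@pytest.fixture
def small_trials(small_spec):
    return simulate_rts(generate_design(small_spec), small_spec)


def crossed_table(n_subjects, n_items, rng, subject_sd=0.0, item_sd=0.0,
                  residual_sd=1.0, effect=0.0):
    """Fully crossed subject x item layout with a within-subject balanced
    two-level factor and a known generative model."""
    subj = np.repeat([f"S{j:02d}" for j in range(n_subjects)], n_items)
    item = np.tile([f"I{k:03d}" for k in range(n_items)], n_subjects)
    df = pd.DataFrame({"subject_id": subj, "item_id": item})
    # balanced within subject; the related half of the items swaps between
    # even and odd subjects (two-version counterbalancing)
    half = n_items // 2
    version_a = np.concatenate([np.ones(half), np.zeros(n_items - half)])
    related = np.concatenate(
        [version_a if j % 2 == 0 else 1 - version_a for j in range(n_subjects)]
    ).astype(bool)
    df["prime_type"] = np.where(related, "related", "unrelated")
    u_s = rng.normal(0, subject_sd, n_subjects)
    u_i = rng.normal(0, item_sd, n_items)
    si = np.repeat(np.arange(n_subjects), n_items)
    ii = np.tile(np.arange(n_items), n_subjects)
    df["y"] = (
        u_s[si] + u_i[ii] - effect * related
        + rng.normal(0, residual_sd, len(df))
    )
    return df


def make_epochs(data, t0=-150.0, fs=1000.0):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n, T = data.shape
    time_ms = t0 + 1000.0 / fs * np.arange(T)
    return EpochSet(data, time_ms, np.arange(n), fs)
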