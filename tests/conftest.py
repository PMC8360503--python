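"""Shared fixtures: small synthetic datasets kept cheap by coarse sampling."""

import numpy as np
import pytest

from cpdecode import (
    GeometrySpec,
    build_trial_schedule,
    make_sensor_layout,
    simulate_epochs,
    simulate_identification,
)


@pytest.fixture(scope="session")
def layout():
    return make_sensor_layout()


@pytest.fixture(scope="session")
def behavior():
    """Identification behavior for a small cohort (logistic, boundary 5.5)."""
    return simulate_identification(boundary=5.5, slope=0.5, n_trials=40, n_subjects=2, seed=11)


def make_epochs(
    layout,
    behavior,
    task="active",
    snr=0.3,
    sfreq=50.0,
    seed=5,
    subject_id=None,
    preset="active-like",
    **geometry_overrides,
):
    """Small-epoch factory: 50 Hz sampling keeps arrays light for unit tests."""
    preset_fn = GeometrySpec.active_like if preset == "active-like" else GeometrySpec.passive_like
    geometry = preset_fn(snr=snr, **geometry_overrides)
    schedule = build_trial_schedule(task, seed=seed)
    return simulate_epochs(
        schedule,
        behavior,
        geometry,
        layout,
        seed=seed,
        subject_id=subject_id,
        sfreq=sfreq,
    )


@pytest.fixture()
def small_epochs(layout, behavior):
    return make_epochs(layout, behavior)
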