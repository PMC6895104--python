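"""Shared fixtures: small synthetic runs reused across test modules."""

from __future__ import annotations

import importlib.util
from pathlib import Path

import numpy as np
import pytest

from ardic import adaptive, synth

ROOT = Path(__file__).resolve().parents[1]


@pytest.fixture(scope="session")
def acceptance():
    """The acceptance script loaded as a module (single implementation)."""
    spec = importlib.util.spec_from_file_location(
        "acceptance_script", ROOT / "scripts" / "acceptance.py"
    )
    mod = importlib.util.module_from_spec(spec)
    spec.loader.exec_module(mod)
    return mod


@pytest.fixture(scope="session")
def speckle_image():
    return synth.make_speckle(synth.SpeckleSpec(shape_px=(128, 128), seed=11))


@pytest.fixture(scope="session")
def beating_run():
    """One-origin beating fixture analysed end to end with AR-DIC."""
    stack, truth = synth.preset_beating(
        n_origins=1, duration_s=8.0, noise_sd=0.005, seed=7
    )
    t_adapt = adaptive.estimate_tadapt(stack, 0, 1)
    fields, trace = adaptive.run_ardic(stack, adaptive.ARConfig(t_adapt=t_adapt))
    return {
        "stack": stack,
        "truth": truth,
        "fields": fields,
        "trace": trace,
        "t_adapt": t_adapt,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
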