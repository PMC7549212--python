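"""Shared fixtures: small deterministic configs and one full default run.

The full 120-plant bundle is expensive (~10 s), so it is computed once per
session and shared by the pipeline and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from salipheno import GeneratorConfig, run_all


def zero_noise_config(**overrides) -> GeneratorConfig:
    """Default config with every stochastic term switched off."""
    cfg = GeneratorConfig()
    response = {trait: {t: (mean, 0.0) for t, (mean, _sd) in curve.items()}
                for trait, curve in cfg.response_curves.items()}
    biochem = {trait: {t: (mean, 0.0) for t, (mean, _sd) in curve.items()}
               for trait, curve in cfg.biochem_curves.items()}
    kwargs = dict(response_curves=response, biochem_curves=biochem,
                  assay_noise_sd=0.0, pixel_lab_sd=0.0)
    kwargs.update(overrides)
    return cfg.with_(**kwargs)


@pytest.fixture(scope="session")
def default_bundle():
    """Full default cohort (2 x 5 x 12) analysed end to end, seed 0."""
    return run_all(GeneratorConfig(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
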