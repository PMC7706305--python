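"""Shared fixtures: simulated experiments reused across test modules."""

from __future__ import annotations

import warnings

import pytest

from phenoheat import pipeline, synthdata


@pytest.fixture(scope="session")
def default_run():
    """Full default-condition experiment (20 reps/group, default seed).

    Returns ``(design, registry, filtered_table)`` — the table already has
    the exclusion filter applied, as the analyses expect.
    """
    params = synthdata.SimulationParams()
    design, _, table = pipeline.simulate_trait_table(params, n_reps=20)
    registry = synthdata.registry_frame(design)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        filtered = pipeline.apply_exclusion_filter(table, registry)
    return design, registry, filtered
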