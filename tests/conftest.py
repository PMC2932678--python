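"""Shared fixtures: zeroed-kinetics registries and cached scenario runs.

The full in-silico experiments (112 simulated days each) are expensive
relative to unit tests, so they are run once per session and shared by
every test that asserts on their outcomes.
"""

from __future__ import annotations

import numpy as np
import pytest

import callussim as cs
from callussim.kinetics import default_parameters
from callussim.scenarios import TreatmentEvent


def zeroed_params(keep: dict | None = None) -> cs.KineticParameters:
    """Registry with every rate constant scaled to zero except ``keep``
    (symbol -> absolute value to restore); capacities and half-
    saturation constants are untouched."""
    p = default_parameters()
    rate_syms = [s for s in p.symbols() if "/day" in p.entry(s).units]
    scaled = p.scale({s: 0.0 for s in rate_syms})
    if keep:
        entries = dict(scaled.items())
        from callussim.kinetics import ParamEntry

        for sym, val in keep.items():
            entries[sym] = ParamEntry(val, p.entry(sym).units, source="override")
        scaled = cs.KineticParameters(entries)
    return scaled


def _build_scenario(label: str):
    if label == "healing":
        return cs.make_healing_scenario()
    if label == "reduced_production":
        return cs.make_healing_scenario(overrides={"P_cs": 0.1, "P_bs": 0.1}, label=label)
    if label == "nonunion":
        return cs.make_nonunion_scenario()
    if label == "periosteum_only":
        return cs.make_nonunion_scenario(strip_periosteum=True, ream_marrow=False)
    if label == "marrow_only":
        return cs.make_nonunion_scenario(strip_periosteum=False, ream_marrow=True)
    site = {"central": "central", "excentral": "excentral", "carrier": "external_carrier"}[label]
    return cs.make_nonunion_scenario(treatments=[TreatmentEvent(site=site)], label=label)


@pytest.fixture(scope="session")
def runs():
    """Memoized access to full scenario runs: ``runs(label)`` returns
    ``(trajectory, grid, params, ledgers)``."""
    cache = {}

    def get(label: str):
        if label not in cache:
            cache[label] = cs.run_scenario(_build_scenario(label))
        return cache[label]

    return get


@pytest.fixture(scope="session")
def vascular_threshold(runs):
    """Cutoff convention: half the healing run's end-state median ROI m_v."""
    traj, grid, _, _ = runs("healing")
    return cs.vascularization_threshold(traj, grid)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
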