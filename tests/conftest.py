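"""Shared fixtures: each scenario is integrated once per session and reused."""

from __future__ import annotations

import logging

import pytest

from golgiflux import GolgiModel

logging.getLogger("golgiflux").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def run_scenario():
    """Memoized scenario runner: run_scenario(name, start=..., **overrides)."""
    cache: dict = {}

    def _run(name: str, start: str = "full", fit_interior=None, **overrides):
        key = (name, start, fit_interior, tuple(sorted(overrides.items())))
        if key not in cache:
            model = GolgiModel.from_scenario(name, **overrides)
            cache[key] = model.run(start=start, fit_interior=fit_interior)
        return cache[key]

    return _run


@pytest.fixture(scope="session")
def full_result(run_scenario):
    return run_scenario("full_mammalian")


@pytest.fixture(scope="session")
def enzymes_open_result(run_scenario):
    return run_scenario("enzymes_open")


@pytest.fixture(scope="session")
def enzymes_closed_result(run_scenario):
    return run_scenario("enzymes_closed")
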