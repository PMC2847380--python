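"""Shared fixtures: synthetic bundles generated once per session."""

from pathlib import Path

import pytest

from mpdkit.fixtures import FixtureSpec, generate


@pytest.fixture(scope="session")
def bundle(tmp_path_factory) -> dict:
    """Default study-shaped bundle (seed 42) plus its manifest and paths."""
    out = tmp_path_factory.mktemp("bundle")
    spec = FixtureSpec(seed=42)
    manifest = generate(spec, out)
    return {"dir": Path(out), "spec": spec, "manifest": manifest}


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory) -> dict:
    """A reduced bundle for fast clustering/network checks."""
    out = tmp_path_factory.mktemp("small_bundle")
    spec = FixtureSpec(
        seed=7,
        n_pathogen=60,
        n_triple=12,
        n_families=10,
        n_interactions=20,
        n_prioritized=5,
        n_flagged=2,
    )
    manifest = generate(spec, out)
    return {"dir": Path(out), "spec": spec, "manifest": manifest}
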