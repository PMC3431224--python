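"""Shared fixtures: the seeded default study and its end-to-end run.

The four-library preset and the pipeline bundle are expensive (minutes), so
they are built once per session and shared by every test that scores the
pipeline against simulation truth.
"""

from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from srna.pipeline import materialize_preset, run_pipeline
from srna.simulate import four_library_preset

PRESET_SEED = 1


@pytest.fixture(scope="session")
def preset():
    return four_library_preset(seed=PRESET_SEED)


@pytest.fixture(scope="session")
def bundle(preset, tmp_path_factory):
    out = tmp_path_factory.mktemp("preset_run")
    config = materialize_preset(preset, out)
    return run_pipeline(config)


@pytest.fixture(scope="session")
def genome_seq(preset) -> str:
    return preset.world.genome[preset.world.contig]
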