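"""Shared fixtures: toy structures and one end-to-end synthetic study.

Expensive artefacts (ideal-template warm-up, the pipeline run) are
session-scoped; tests must not mutate them.
"""

from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from mutpanel import synth_fixtures as sf
from mutpanel.structure_io import annotate_atom_types
from mutpanel.viz_export import run_pipeline


@pytest.fixture(scope="session")
def aga_extended():
    """Extended Ala-Gly-Ala tripeptide, annotated."""
    st, text = sf.make_toy_structure("AGA", "extended")
    return annotate_atom_types(st), text


@pytest.fixture(scope="session")
def leu_helix():
    """12-residue polyleucine alpha-helix, annotated."""
    st, _ = sf.make_toy_structure("L" * 12, "helix")
    return annotate_atom_types(st)


@pytest.fixture(scope="session")
def planted_small():
    """Planted GA instance with k=2 dominant columns among m=6."""
    return sf.make_planted_dataset(k=2, m=6, seed=1)


@pytest.fixture(scope="session")
def pipeline_workdir(tmp_path_factory):
    work = tmp_path_factory.mktemp("pipeline")
    return sf.make_pipeline_dataset(work, seed=1)


@pytest.fixture(scope="session")
def pipeline_result(pipeline_workdir):
    """One full synthetic-study run (read-only for all tests)."""
    return run_pipeline(pipeline_workdir)
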