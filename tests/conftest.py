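"""Shared fixtures: a rendered reference scene and its pipeline analysis."""

from __future__ import annotations

import warnings

import pytest

from repstress.imaging import analyze_scene
from repstress.simulate import SceneParams, render_nuclei_scene


@pytest.fixture(scope="session")
def reference_scene():
    """Default 50-nucleus scene with foci and micronuclei, plus ground truth."""
    stack, truth = render_nuclei_scene(SceneParams(seed=0))
    return stack, truth


@pytest.fixture(scope="session")
def reference_analysis(reference_scene):
    """Full pipeline result on the reference scene."""
    stack, _ = reference_scene
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return analyze_scene(stack)
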