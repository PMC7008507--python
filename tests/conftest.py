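"""Shared fixtures: fast small-scene parameters and session-scoped
generated stacks reused across test modules."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from thgratio import synthetic_skin as ss

#: Reduced geometry for fast unit tests: same intensity structure as the
#: full study conditions, smaller field and fewer depths, but still
#: enough cells and fibers to clear the screening floors.
SMALL = dict(pixel_count=160, n_depths=7, dej_depth_index=1, dej_band=4,
             cell_count=12, fiber_count=35)


def small_params(seed: int = 0, **overrides) -> ss.SkinSceneParams:
    kw = {**SMALL, **overrides, "seed": seed}
    return ss.SkinSceneParams(**kw)


def small_preset(name: str, seed: int = 0, **overrides) -> ss.SkinSceneParams:
    base = ss.preset(name, seed=seed)
    return dataclasses.replace(base, **{**SMALL, **overrides})


@pytest.fixture(scope="session")
def small_stack():
    """One small melanin-free stack with its truth."""
    return ss.generate_stack(small_params(seed=7))


@pytest.fixture(scope="session")
def small_melanin_stack():
    return ss.generate_stack(small_preset("melanin_containing", seed=7))


@pytest.fixture(scope="session")
def cohort_stack():
    """One full-geometry melanin-free stack (the study conditions)."""
    return ss.generate_stack(ss.SkinSceneParams(seed=1))


@pytest.fixture(scope="session")
def cohort_stacks_14():
    """The 14-stack synthetic cohort, seeds 1..14, at full geometry."""
    return [ss.generate_stack(ss.SkinSceneParams(seed=s))
            for s in range(1, 15)]
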