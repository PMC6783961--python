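"""Shared fixtures: prepared mAb contexts and annotated 48 h stressed runs."""

from __future__ import annotations

import pytest

from middleup.simulate import DesignRow
from middleup.workflow import MAbContext, RunResult, prepare_mab, simulate_and_annotate

#: base seed for every simulation in the suite
SUITE_SEED = 101

MAB_NAMES = ("bevacizumab-like", "infliximab-like")


@pytest.fixture(scope="session")
def contexts() -> dict[tuple[str, str], MAbContext]:
    """Prepared (digested, mapped, library-built) mAbs for both roles."""
    return {
        (name, role): prepare_mab(name, role)
        for name in MAB_NAMES
        for role in ("RP", "BS")
    }


@pytest.fixture(scope="session")
def oxi48_results(contexts) -> dict[str, RunResult]:
    """Fully annotated 48 h forced-oxidation BS runs of both mAbs."""
    out = {}
    for name in MAB_NAMES:
        ctx = contexts[(name, "BS")]
        row = DesignRow(name, "BS", "oxi", 48.0, 1)
        out[name] = simulate_and_annotate(ctx, row, base_seed=SUITE_SEED)
    return out
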