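"""End-to-end conveniences tying simulator and analysis together.

These helpers exist so the analysis drivers, the command-line interface and
the test suite all run the identical path: build the mAb and its proteoform
libraries, simulate a design row, annotate it, and (optionally) measure the
ar statistic against the simulator's ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

from .kinetics import KineticPreset, default_scenario
from .mab_model import MAbDefinition, SubunitChain
from .pipeline import (
    DEFAULT_AR_LEVELS,
    PeakAnnotation,
    RelAbundanceRecord,
    assign_run,
    measure_relative_abundance,
    species_calls,
)
from .proteoforms import LibraryConfig, Proteoform
from .sequences import digest_and_map, make_mab
from .simulate import (
    AcquisitionParams,
    ChromatographicRun,
    DesignRow,
    derive_run_seed,
    simulate_run,
)


@dataclass
class MAbContext:
    """A mAb with its mapped subunits, kinetic preset and search libraries."""

    mab: MAbDefinition
    subunits: dict[str, SubunitChain]
    preset: KineticPreset
    libraries: dict[str, list[Proteoform]]


def prepare_mab(
    name: str,
    role: str,
    library_config: LibraryConfig | None = None,
    kinetics_kwargs: dict | None = None,
) -> MAbContext:
    mab = make_mab(name, role)
    subunits = digest_and_map(mab)
    return MAbContext(
        mab=mab,
        subunits=subunits,
        preset=default_scenario(mab, subunits, **(kinetics_kwargs or {})),
        libraries={
            kind: list(lib)
            for kind, lib in _libs(subunits, library_config).items()
        },
    )


def _libs(subunits, config):
    from .pipeline import build_libraries

    return build_libraries(subunits, config)


@dataclass
class RunResult:
    run: ChromatographicRun
    annotations: list[PeakAnnotation]
    calls: dict[str, Proteoform]


def simulate_and_annotate(
    ctx: MAbContext,
    row: DesignRow,
    base_seed: int,
    acquisition: AcquisitionParams | None = None,
) -> RunResult:
    """Simulate one design row and run the full identification pipeline."""
    run = simulate_run(
        ctx.mab,
        ctx.subunits,
        ctx.preset,
        row,
        acquisition=acquisition,
        seed=derive_run_seed(base_seed, row),
    )
    annotations = assign_run(run, ctx.libraries)
    return RunResult(run=run, annotations=annotations, calls=species_calls(annotations))


def truth_ar(run: ChromatographicRun, subunit: str, ox_level: int) -> float:
    """ar computed from simulator ground-truth fractions by the same formula."""
    fractions = run.ground_truth[subunit]
    f0 = fractions.get(subunit, 0.0)  # plain unmodified form's name is the kind
    fn = fractions.get(f"{subunit} {ox_level} Ox", 0.0)
    if f0 + fn == 0:
        return 0.0
    return fn / (f0 + fn)


def measure_run_ar(
    result: RunResult,
    libraries: dict[str, list[Proteoform]],
    levels: dict[str, int] | None = None,
) -> list[RelAbundanceRecord]:
    """ar records for one annotated run at the configured oxidation levels."""
    levels = levels or DEFAULT_AR_LEVELS.get(result.run.mab_name, {})
    return [
        measure_relative_abundance(
            result.run, result.annotations, libraries, subunit, level
        )
        for subunit, level in sorted(levels.items())
    ]
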