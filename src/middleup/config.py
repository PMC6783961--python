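"""YAML run configuration for the command-line workflow.

A config file can override the synthetic instrument, the kinetic presets and
the matching/EIC tolerances, e.g.::

    acquisition:
      rt_span: [0, 41]
      noise_sigma: 1.0
    kinetics:
      fast_rate: 0.15
      slow_rate_rp: 0.002
      bs_slow_multiplier: 2.0
      unspecific_rate: 0.004
    tolerances:
      match_tol_ppm: 70
      eic_tol: 0.01

Omitted sections keep their defaults. Sequences default to the synthetic
fixture pair; real chains are supplied through the library API
(:func:`middleup.mab_model.load_mab_fasta` plus label offsets).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .simulate import AcquisitionParams

_KINETIC_KEYS = {"fast_rate", "slow_rate_rp", "bs_slow_multiplier", "unspecific_rate"}


@dataclass(frozen=True)
class WorkflowConfig:
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    kinetics: dict = field(default_factory=dict)
    match_tol_ppm: float = 70.0
    eic_tol: float = 0.01


def load_config(path) -> WorkflowConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    acq_raw = dict(raw.get("acquisition") or {})
    for key in ("mz_range", "rt_span", "z_range"):
        if key in acq_raw:
            acq_raw[key] = tuple(acq_raw[key])
    kinetics = dict(raw.get("kinetics") or {})
    unknown = set(kinetics) - _KINETIC_KEYS
    if unknown:
        raise ValueError(f"unknown kinetics keys {sorted(unknown)}")
    tol = raw.get("tolerances") or {}
    return WorkflowConfig(
        acquisition=AcquisitionParams(**acq_raw),
        kinetics=kinetics,
        match_tol_ppm=float(tol.get("match_tol_ppm", 70.0)),
        eic_tol=float(tol.get("eic_tol", 0.01)),
    )
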