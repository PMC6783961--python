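"""Synthetic reversed-phase LC-ESI-QTOF runs of IgG1 subunits.

Each run emulates a middle-up acquisition of the three subunits (~23-26 kDa)
over a 41-min gradient at 2 spectra/s in profile mode, m/z 600-3200:

* ground-truth proteoform fractions come from the per-site oxidation kinetics
  (:mod:`middleup.kinetics`) crossed with static modification fractions
  (glycan split, pyroglutamate, C-terminal lysine retention);
* every proteoform above an abundance floor elutes as a Gaussian RT peak at
  its subunit's base retention time, shifted earlier by a fixed amount per
  oxidation (oxidized forms are more hydrophilic), giving partially separated
  oxidation states;
* intensity is spread over a Gaussian ESI charge-state envelope centred at
  z* = round(M / 1200), each charge state an isotopically unresolved Gaussian
  in m/z with FWHM about 6/z Da, sampled on a fixed global m/z grid;
* a flat baseline plus Gaussian (optionally Poisson) noise is added.

Identical (seed, parameters) give bit-identical runs.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chem import PROTON_MASS
from .kinetics import KineticPreset
from .mab_model import MAbDefinition, SubunitChain
from .proteoforms import (
    LibraryConfig,
    Proteoform,
    enumerate_proteoforms,
)

DEFAULT_BASE_RT = {"Fc/2": 9.0, "LC": 15.0, "Fd'": 24.0}


@dataclass(frozen=True)
class AcquisitionParams:
    """Acquisition and peak-shape parameters of the synthetic instrument."""

    mz_range: tuple[float, float] = (600.0, 3200.0)
    rt_span: tuple[float, float] = (0.0, 41.0)   # minutes
    scan_rate: float = 2.0                        # spectra per second
    grid_pitch: float = 0.02                      # m/z sampling pitch (Th)
    z_range: tuple[int, int] = (8, 40)
    envelope_sigma_z: float = 2.5
    mass_per_charge: float = 1200.0               # z* = round(M / this)
    envelope_halfwidth: int = 7                   # charges kept around z*
    rt_sigma: float = 0.08                        # minutes
    rt_shift_per_ox: float = -0.15                # minutes per oxidation
    mz_fwhm_scale: float = 6.0                    # FWHM = this / z, Da
    base_rt: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASE_RT)
    )
    total_intensity: float = 3e5                  # apex counts per subunit
    baseline: float = 2.0
    noise_sigma: float = 1.0
    noise_frac: float = 0.01
    noise_model: str = "gaussian"                 # "gaussian" | "poisson" | "none"
    abundance_floor: float = 1e-4
    include_undigested_hc: bool = False
    seed: int = 0


@dataclass(frozen=True)
class CompositionConfig:
    """Static (non-kinetic) modification fractions of the product."""

    glycan_fractions: dict[str | None, float] = field(
        default_factory=lambda: {None: 0.05, "G0F": 0.55, "G1F": 0.40}
    )
    pyroglu_fraction: float = 0.06


@dataclass(frozen=True)
class DesignRow:
    """One experiment of the treatment matrix."""

    mab_name: str
    role: str          # RP | BS
    treatment: str     # con | oxi
    duration: float    # hours
    replicate: int


@dataclass
class Scan:
    rt: float                 # minutes
    mz: np.ndarray
    intensity: np.ndarray


@dataclass
class ChromatographicRun:
    """RT-indexed profile spectra plus run metadata and simulator truth."""

    mab_name: str
    role: str
    treatment: str
    duration: float
    replicate: int
    seed: int
    scans: list[Scan]
    #: subunit kind -> proteoform display name -> simulated fraction
    ground_truth: dict[str, dict[str, float]]
    acquisition: AcquisitionParams

    @property
    def metadata(self) -> dict:
        return {
            "mab_name": self.mab_name,
            "role": self.role,
            "treatment": self.treatment,
            "duration": self.duration,
            "replicate": self.replicate,
            "seed": self.seed,
        }


def build_design(
    mab_names: tuple[str, ...] = ("bevacizumab-like", "infliximab-like"),
    roles: tuple[str, ...] = ("RP", "BS"),
    durations: tuple[float, ...] = (0.0, 24.0, 48.0, 72.0),
    replicates: int = 3,
) -> pd.DataFrame:
    """Treatment matrix: control at every duration, forced oxidation from 24 h."""
    rows = []
    for name in mab_names:
        for role in roles:
            for duration in durations:
                treatments = ("con",) if duration == 0 else ("con", "oxi")
                for treatment in treatments:
                    for rep in range(1, replicates + 1):
                        rows.append(
                            {
                                "mab_name": name,
                                "role": role,
                                "treatment": treatment,
                                "duration": duration,
                                "replicate": rep,
                            }
                        )
    return pd.DataFrame(rows)


def design_rows(design: pd.DataFrame) -> list[DesignRow]:
    return [
        DesignRow(
            mab_name=r.mab_name,
            role=r.role,
            treatment=r.treatment,
            duration=float(r.duration),
            replicate=int(r.replicate),
        )
        for r in design.itertuples()
    ]


def derive_run_seed(base_seed: int, row: DesignRow) -> int:
    """Stable per-run seed below 2**31 derived from the base seed and metadata."""
    tag = f"{row.mab_name}|{row.role}|{row.treatment}|{row.duration}|{row.replicate}"
    return (base_seed * 2654435761 + zlib.crc32(tag.encode())) % (2**31)


def ground_truth_fractions(
    mab: MAbDefinition,
    subunits: dict[str, SubunitChain],
    preset: KineticPreset,
    row: DesignRow,
    library_config: LibraryConfig | None = None,
    composition: CompositionConfig | None = None,
) -> dict[str, dict[Proteoform, float]]:
    """Per-subunit proteoform fractional abundances for one design row.

    For each subunit the oxidation-count distribution (kinetics) is crossed
    with the independent static modification fractions; fractions per subunit
    sum to 1.
    """
    from .kinetics import oxidation_state_distribution

    lib_cfg = library_config or LibraryConfig()
    comp = composition or CompositionConfig()
    out: dict[str, dict[Proteoform, float]] = {}
    for kind, subunit in subunits.items():
        params = preset.params(kind, row.treatment, row.duration)
        ox_dist = oxidation_state_distribution(params, lib_cfg.unspecific_ox_cap)
        fractions: dict[Proteoform, float] = {}
        for pf in enumerate_proteoforms(subunit, lib_cfg):
            mods = pf.mods
            frac = ox_dist[mods.n_ox] if mods.n_ox < len(ox_dist) else 0.0
            if subunit.kind == "Fc/2":
                frac *= comp.glycan_fractions.get(mods.glycan, 0.0)
                lys_f = mab.cterm_lys_fraction
                frac *= lys_f if mods.cterm_lys else 1.0 - lys_f
            if mods.pyroglu:
                frac *= comp.pyroglu_fraction
            elif kind in lib_cfg.pyroglu_kinds and subunit.sequence[0] in "QE":
                frac *= 1.0 - comp.pyroglu_fraction
            fractions[pf] = frac
        total = sum(fractions.values())
        out[kind] = {pf: f / total for pf, f in fractions.items()}
    return out


def charge_envelope(
    mass: float, acq: AcquisitionParams
) -> tuple[np.ndarray, np.ndarray]:
    """Kept charge states and normalized envelope weights for a neutral mass."""
    z_star = int(round(mass / acq.mass_per_charge))
    lo = max(acq.z_range[0], z_star - acq.envelope_halfwidth)
    hi = min(acq.z_range[1], z_star + acq.envelope_halfwidth)
    zs = np.arange(lo, hi + 1)
    mz = (mass + zs * PROTON_MASS) / zs
    keep = (mz >= acq.mz_range[0]) & (mz <= acq.mz_range[1])
    zs = zs[keep]
    if zs.size == 0:
        return zs, np.empty(0)
    w = np.exp(-((zs - z_star) ** 2) / (2 * acq.envelope_sigma_z**2))
    return zs, w / w.sum()


def species_mz_template(
    mass: float, acq: AcquisitionParams
) -> tuple[np.ndarray, np.ndarray]:
    """Grid indices and unit-apex profile of one species' full charge envelope."""
    zs, weights = charge_envelope(mass, acq)
    mz0 = acq.mz_range[0]
    idx_parts, val_parts = [], []
    for z, w in zip(zs, weights):
        center = (mass + z * PROTON_MASS) / z
        sigma = acq.mz_fwhm_scale / z / 2.35482
        span = int(np.ceil(4 * sigma / acq.grid_pitch))
        k0 = int(round((center - mz0) / acq.grid_pitch))
        ks = np.arange(k0 - span, k0 + span + 1)
        mzs = mz0 + ks * acq.grid_pitch
        inside = (mzs >= acq.mz_range[0]) & (mzs <= acq.mz_range[1])
        ks, mzs = ks[inside], mzs[inside]
        idx_parts.append(ks)
        val_parts.append(w * np.exp(-((mzs - center) ** 2) / (2 * sigma**2)))
    if not idx_parts:
        return np.empty(0, dtype=int), np.empty(0)
    return np.concatenate(idx_parts), np.concatenate(val_parts)


def simulate_run(
    mab: MAbDefinition,
    subunits: dict[str, SubunitChain],
    preset: KineticPreset,
    row: DesignRow,
    acquisition: AcquisitionParams | None = None,
    seed: int | None = None,
    library_config: LibraryConfig | None = None,
    composition: CompositionConfig | None = None,
) -> ChromatographicRun:
    """Simulate one chromatographic run of the design.

    ``seed`` overrides the seed in ``acquisition``; noise is drawn from a
    generator seeded with it, so identical inputs give identical scans.
    """
    acq = acquisition or AcquisitionParams()
    if seed is not None:
        acq = replace(acq, seed=seed)
    rng = np.random.default_rng(acq.seed)
    truth = ground_truth_fractions(
        mab, subunits, preset, row, library_config, composition
    )

    dt = 1.0 / (acq.scan_rate * 60.0)  # minutes between scans
    n_scans = int(round((acq.rt_span[1] - acq.rt_span[0]) / dt)) + 1
    rts = acq.rt_span[0] + dt * np.arange(n_scans)

    # per-scan accumulation of (grid index, intensity) contributions
    contribs: dict[int, list[tuple[np.ndarray, np.ndarray]]] = {}
    for kind, fractions in truth.items():
        base_rt = acq.base_rt[kind]
        for pf, frac in fractions.items():
            if frac < acq.abundance_floor:
                continue
            idx, template = species_mz_template(pf.avg_mass, acq)
            if idx.size == 0:
                warnings.warn(
                    f"{pf.display_name}: no charge state inside the m/z range; "
                    "species dropped",
                    stacklevel=2,
                )
                continue
            rt_c = base_rt + acq.rt_shift_per_ox * pf.mods.n_ox
            amp = acq.total_intensity * frac
            active = np.nonzero(np.abs(rts - rt_c) <= 4 * acq.rt_sigma)[0]
            gains = amp * np.exp(
                -((rts[active] - rt_c) ** 2) / (2 * acq.rt_sigma**2)
            )
            for s_i, gain in zip(active, gains):
                contribs.setdefault(int(s_i), []).append((idx, gain * template))

    scans: list[Scan] = []
    mz0 = acq.mz_range[0]
    for i in range(n_scans):
        parts = contribs.get(i)
        if not parts:
            scans.append(
                Scan(rt=float(rts[i]), mz=np.empty(0), intensity=np.empty(0))
            )
            continue
        all_idx = np.concatenate([p[0] for p in parts])
        all_val = np.concatenate([p[1] for p in parts])
        uniq, inverse = np.unique(all_idx, return_inverse=True)
        intensity = np.bincount(inverse, weights=all_val, minlength=uniq.size)
        intensity = intensity + acq.baseline
        if acq.noise_model == "gaussian":
            sigma = acq.noise_sigma + acq.noise_frac * intensity
            intensity = intensity + rng.normal(0.0, 1.0, intensity.size) * sigma
        elif acq.noise_model == "poisson":
            intensity = rng.poisson(np.maximum(intensity, 0.0)).astype(float)
        elif acq.noise_model != "none":
            raise ValueError(f"unknown noise model {acq.noise_model!r}")
        np.maximum(intensity, 0.0, out=intensity)
        scans.append(
            Scan(
                rt=float(rts[i]),
                mz=mz0 + uniq * acq.grid_pitch,
                intensity=intensity,
            )
        )

    return ChromatographicRun(
        mab_name=mab.name,
        role=mab.product_role,
        treatment=row.treatment,
        duration=row.duration,
        replicate=row.replicate,
        seed=acq.seed,
        scans=scans,
        ground_truth={
            kind: {pf.display_name: float(f) for pf, f in fr.items()}
            for kind, fr in truth.items()
        },
        acquisition=acq,
    )


def ground_truth_sidecar(run: ChromatographicRun) -> dict:
    """JSON-serializable simulator-truth record for one run.

    Minor-species magnitudes (high oxidation states beyond the methionine
    count) are generator choices with no measured counterpart and are flagged
    as such.
    """
    return {
        "metadata": run.metadata,
        "fractions": run.ground_truth,
        "note": (
            "simulator ground truth; minor high-oxidation species magnitudes "
            "are arbitrary generator parameters"
        ),
    }
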