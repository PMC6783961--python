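"""Per-site pseudo-first-order methionine oxidation kinetics.

Forced oxidation with H2O2 is modelled as independent pseudo-first-order
conversion of each methionine: site *i* with rate constant ``k_i`` (per hour)
is oxidized after ``t`` hours with probability ``p_i = 1 - exp(-k_i t)``.
The subunit's methionine oxidation count is then Poisson-binomially
distributed over the site probabilities. Unspecific oxidation of other
residues (relevant under harsh peroxide stress) is an independent Poisson
count with mean ``k_u * t``, truncated at the library's unspecific cap and
renormalized. Control treatment (no peroxide) zeroes every effective rate.

The default scenario encodes the qualitative endpoint structure of the
forced-oxidation experiment as generator truth (fast conserved Fc methionines everywhere, fast
infliximab LC M55 / Fd' M18, slow everything else, a stronger slow-class rate
in the biosimilar); the rate constants themselves are free model parameters,
not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mab_model import MAbDefinition, MethionineSite, SubunitChain

#: defaults for the generator's kinetic classes (per hour)
FAST_RATE = 0.15          # >= 97% site conversion at 24 h
SLOW_RATE_RP = 0.002      # ~13% site conversion at 72 h: mostly unoxidized
BS_SLOW_MULTIPLIER = 2.0  # biosimilar slow-class rate relative to the RP
UNSPECIFIC_RATE = 0.004   # per chain, feeds the minor high-ox species

#: Fab-arm sites that are fast (surface exposed) in the default scenario
FAST_FAB_SITES: dict[str, frozenset[str]] = {
    "LC": frozenset({"M55"}),
    "Fd'": frozenset({"M18"}),
}


@dataclass(frozen=True)
class KineticParams:
    """Effective kinetics of one treatment arm for one subunit."""

    site_rates: tuple[float, ...]   # per MethionineSite, per hour
    unspecific_rate: float          # per chain, per hour
    duration: float                 # hours
    treatment: str                  # "con" | "oxi"

    def __post_init__(self) -> None:
        if self.treatment not in ("con", "oxi"):
            raise ValueError("treatment must be 'con' or 'oxi'")
        if self.duration < 0:
            raise ValueError("duration must be >= 0 hours")
        if any(k < 0 for k in self.site_rates) or self.unspecific_rate < 0:
            raise ValueError("rate constants must be >= 0")

    @property
    def effective_site_rates(self) -> tuple[float, ...]:
        if self.treatment == "con":
            return tuple(0.0 for _ in self.site_rates)
        return self.site_rates

    @property
    def effective_unspecific_rate(self) -> float:
        return 0.0 if self.treatment == "con" else self.unspecific_rate


def site_probabilities(params: KineticParams) -> np.ndarray:
    """Per-site oxidation probabilities 1 - exp(-k t) under the treatment."""
    k = np.asarray(params.effective_site_rates, dtype=float)
    return -np.expm1(-k * params.duration)


def poisson_binomial(probs: np.ndarray) -> np.ndarray:
    """Exact Poisson-binomial pmf over 0..n by iterative convolution."""
    pmf = np.array([1.0])
    for p in np.asarray(probs, dtype=float):
        pmf = np.convolve(pmf, [1.0 - p, p])
    return pmf


def truncated_poisson(mean: float, cap: int) -> np.ndarray:
    """Poisson pmf truncated at ``cap`` and renormalized."""
    if cap < 0:
        raise ValueError("cap must be >= 0")
    if mean == 0.0:
        pmf = np.zeros(cap + 1)
        pmf[0] = 1.0
        return pmf
    ks = np.arange(cap + 1)
    log_pmf = ks * np.log(mean) - mean - np.array(
        [float(np.sum(np.log(np.arange(1, k + 1)))) for k in ks]
    )
    pmf = np.exp(log_pmf)
    return pmf / pmf.sum()


def oxidation_state_distribution(
    params: KineticParams, unspecific_ox_cap: int = 4
) -> np.ndarray:
    """Distribution of a subunit's total oxidation count after ``t`` hours.

    Index ``n`` of the returned array is P(n oxidation events); the support is
    0 .. (n_sites + unspecific_ox_cap) and the probabilities sum to 1.
    """
    probs = site_probabilities(params)
    site_pmf = poisson_binomial(probs)
    unspecific_pmf = truncated_poisson(
        params.effective_unspecific_rate * params.duration, unspecific_ox_cap
    )
    dist = np.convolve(site_pmf, unspecific_pmf)
    return dist / dist.sum()


@dataclass(frozen=True)
class KineticPreset:
    """Per-subunit methionine sites with assigned rate constants for one mAb."""

    mab_name: str
    role: str
    sites: dict[str, tuple[MethionineSite, ...]]
    unspecific_rate: float

    def params(self, kind: str, treatment: str, duration: float) -> KineticParams:
        return KineticParams(
            site_rates=tuple(s.rate_constant for s in self.sites[kind]),
            unspecific_rate=self.unspecific_rate,
            duration=duration,
            treatment=treatment,
        )


def default_scenario(
    mab: MAbDefinition,
    subunits: dict[str, SubunitChain],
    *,
    fast_rate: float = FAST_RATE,
    slow_rate_rp: float = SLOW_RATE_RP,
    bs_slow_multiplier: float = BS_SLOW_MULTIPLIER,
    unspecific_rate: float = UNSPECIFIC_RATE,
) -> KineticPreset:
    """Default generator kinetics for one mAb.

    All Fc/2 methionines are fast; Fab-arm sites listed in
    :data:`FAST_FAB_SITES` (infliximab LC M55 and Fd' M18) are fast; every
    other site is slow. A biosimilar's slow-class rate is
    ``bs_slow_multiplier`` times the reference product's, so RP and BS presets
    differ only in the slow class.
    """
    slow_rate = slow_rate_rp * (
        bs_slow_multiplier if mab.product_role == "BS" else 1.0
    )
    sites: dict[str, tuple[MethionineSite, ...]] = {}
    for kind, subunit in subunits.items():
        kind_sites = []
        for label in subunit.site_labels:
            fast = kind == "Fc/2" or label in FAST_FAB_SITES.get(kind, frozenset())
            kind_sites.append(
                MethionineSite(
                    subunit_kind=kind,
                    site_label=label,
                    exposure_class="fast" if fast else "slow",
                    rate_constant=fast_rate if fast else slow_rate,
                )
            )
        sites[kind] = tuple(kind_sites)
    return KineticPreset(
        mab_name=mab.name,
        role=mab.product_role,
        sites=sites,
        unspecific_rate=unspecific_rate,
    )
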