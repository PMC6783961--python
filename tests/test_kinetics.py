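"""Per-site oxidation kinetics and the Poisson-binomial state distribution."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from middleup.kinetics import (
    KineticParams,
    default_scenario,
    oxidation_state_distribution,
    poisson_binomial,
    site_probabilities,
    truncated_poisson,
)
from middleup.sequences import bevacizumab_like, digest_and_map, infliximab_like


def brute_force_count_distribution(probs):
    """Oracle: exhaustive enumeration over all site subsets."""
    n = len(probs)
    pmf = np.zeros(n + 1)
    for states in itertools.product([0, 1], repeat=n):
        p = 1.0
        for s, q in zip(states, probs):
            p *= q if s else 1 - q
        pmf[sum(states)] += p
    return pmf


class TestStateDistribution:
    def test_no_reaction(self):
        params = KineticParams((0.0, 0.0), 0.0, 48.0, "oxi")
        dist = oxidation_state_distribution(params)
        assert dist[0] == pytest.approx(1.0)

    def test_saturation(self):
        params = KineticParams((5.0,), 0.0, 1000.0, "oxi")
        dist = oxidation_state_distribution(params)
        assert dist[1] == pytest.approx(1.0, abs=1e-9)

    def test_two_half_sites(self):
        """p = 0.5 each: {0: 0.25, 1: 0.5, 2: 0.25} by exhaustive enumeration."""
        t = np.log(2.0)
        params = KineticParams((1.0, 1.0), 0.0, t, "oxi")
        dist = oxidation_state_distribution(params)
        assert dist[:3] == pytest.approx([0.25, 0.5, 0.25], abs=1e-12)

    @settings(max_examples=40, derandomize=True)
    @given(
        probs=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=6),
    )
    def test_poisson_binomial_matches_enumeration(self, probs):
        assert poisson_binomial(probs) == pytest.approx(
            brute_force_count_distribution(probs), abs=1e-12
        )

    @settings(max_examples=40, derandomize=True)
    @given(
        rates=st.lists(st.floats(0.0, 0.3), min_size=0, max_size=5),
        ku=st.floats(0.0, 0.02),
        t=st.floats(0.0, 100.0),
    )
    def test_probability_conservation(self, rates, ku, t):
        params = KineticParams(tuple(rates), ku, t, "oxi")
        dist = oxidation_state_distribution(params, unspecific_ox_cap=4)
        assert dist.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(dist >= 0)

    def test_expected_count_monotone_in_time_and_rate(self):
        def expectation(rates, t):
            d = oxidation_state_distribution(KineticParams(rates, 0.002, t, "oxi"))
            return float(np.arange(d.size) @ d)

        e_t = [expectation((0.01, 0.1), t) for t in (0, 12, 24, 48, 96)]
        assert np.all(np.diff(e_t) >= 0)
        e_k = [expectation((k, 0.1), 48.0) for k in (0.0, 0.01, 0.05, 0.2)]
        assert np.all(np.diff(e_k) >= 0)

    def test_control_treatment_zeroes_rates(self):
        oxi = KineticParams((0.15, 0.01), 0.004, 72.0, "oxi")
        con = KineticParams((0.15, 0.01), 0.004, 72.0, "con")
        assert np.all(site_probabilities(con) == 0.0)
        assert oxidation_state_distribution(con)[0] == pytest.approx(1.0)
        assert oxidation_state_distribution(oxi)[0] < 0.1

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            KineticParams((0.1,), 0.0, -1.0, "oxi")

    def test_truncated_poisson_normalized(self):
        pmf = truncated_poisson(0.3, 4)
        assert pmf.sum() == pytest.approx(1.0)
        assert pmf.size == 5
        assert truncated_poisson(0.0, 4)[0] == 1.0


class TestDefaultScenario:
    def test_bevacizumab_fc_mode_is_three_ox_at_24h(self):
        mab = bevacizumab_like("RP")
        preset = default_scenario(mab, digest_and_map(mab))
        dist = oxidation_state_distribution(preset.params("Fc/2", "oxi", 24.0))
        assert int(np.argmax(dist)) == 3

    def test_infliximab_lc_mode_is_one_ox_at_24h(self):
        mab = infliximab_like("RP")
        preset = default_scenario(mab, digest_and_map(mab))
        dist = oxidation_state_distribution(preset.params("LC", "oxi", 24.0))
        assert int(np.argmax(dist)) == 1

    def test_roles_differ_only_in_slow_class(self):
        subs_rp = digest_and_map(bevacizumab_like("RP"))
        subs_bs = digest_and_map(bevacizumab_like("BS"))
        rp = default_scenario(bevacizumab_like("RP"), subs_rp)
        bs = default_scenario(bevacizumab_like("BS"), subs_bs)
        for kind in rp.sites:
            for s_rp, s_bs in zip(rp.sites[kind], bs.sites[kind]):
                assert s_rp.site_label == s_bs.site_label
                assert s_rp.exposure_class == s_bs.exposure_class
                if s_rp.exposure_class == "fast":
                    assert s_rp.rate_constant == s_bs.rate_constant
                else:
                    assert s_bs.rate_constant == pytest.approx(
                        2.0 * s_rp.rate_constant
                    )

    def test_fast_sites_outrun_slow_default(self):
        mab = infliximab_like("RP")
        preset = default_scenario(mab, digest_and_map(mab))
        fd_sites = {s.site_label: s for s in preset.sites["Fd'"]}
        assert fd_sites["M18"].exposure_class == "fast"
        assert fd_sites["M34"].exposure_class == "slow"
        assert fd_sites["M18"].rate_constant > fd_sites["M34"].rate_constant
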