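"""Mass computation, modification deltas, library enumeration and matching."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pyteomics import mass as pyteomics_mass

from middleup.chem import CANONICAL_RESIDUES
from middleup.mab_model import SubunitChain
from middleup.proteoforms import (
    REJECTED,
    Assignment,
    LibraryConfig,
    ModificationState,
    annotate_mass_error,
    average_mass,
    enumerate_proteoforms,
    glycan_delta,
    match_mass,
    modification_delta,
    monoisotopic_mass,
)

# IUPAC 2021 standard atomic weights, typed independently for the oracle.
ORACLE_WEIGHTS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}

sequences = st.text(
    alphabet="".join(sorted(CANONICAL_RESIDUES)), min_size=1, max_size=30
)


class TestMasses:
    def test_water_only(self):
        assert average_mass("") == pytest.approx(18.015, abs=5e-4)

    def test_diglycine(self):
        # C4H8N2O3 summed from IUPAC atomic weights
        assert average_mass("GG") == pytest.approx(132.12, abs=5e-3)

    def test_oxidation_step(self):
        seq = "QVQLMK"
        mods = ModificationState(n_ox=1)
        assert average_mass(seq, mods) - average_mass(seq) == pytest.approx(
            15.999, abs=1e-3
        )
        assert monoisotopic_mass(seq, mods) - monoisotopic_mass(seq) == pytest.approx(
            15.9949, abs=1e-3
        )

    def test_invalid_residue_rejected(self):
        with pytest.raises(ValueError, match="invalid residue"):
            average_mass("ABZ")

    @settings(max_examples=40, derandomize=True)
    @given(seq=sequences, n_ox=st.integers(0, 4), pg=st.booleans(), lys=st.booleans())
    def test_mass_additivity(self, seq, n_ox, pg, lys):
        """mass(seq, mods) == mass(seq) + sum of deltas, to 1e-6 Da."""
        if pg and seq[0] not in "QE":
            seq = "Q" + seq[1:]
        mods = ModificationState(n_ox=n_ox, pyroglu=pg, cterm_lys=lys)
        expected = average_mass(seq)
        expected += n_ox * modification_delta("ox")
        if pg:
            expected += modification_delta("pyroglu", nterm=seq[0])
        if lys:
            expected += modification_delta("cterm_lys")
        assert average_mass(seq, mods) == pytest.approx(expected, abs=1e-6)

    def test_average_mass_against_composition_oracle(self):
        """20 random decapeptides vs an independent elemental summation.

        Elemental counts come from pyteomics' residue composition tables;
        weights are an independently typed IUPAC table.
        """
        rng = np.random.default_rng(7)
        residues = sorted(CANONICAL_RESIDUES)
        for _ in range(20):
            seq = "".join(rng.choice(residues, size=10))
            comp = pyteomics_mass.Composition(sequence=seq)
            oracle = sum(ORACLE_WEIGHTS[el] * n for el, n in comp.items())
            assert average_mass(seq) == pytest.approx(oracle, abs=0.001)

    def test_monoisotopic_against_pyteomics(self):
        rng = np.random.default_rng(11)
        residues = sorted(CANONICAL_RESIDUES)
        for _ in range(10):
            seq = "".join(rng.choice(residues, size=12))
            ref = pyteomics_mass.calculate_mass(sequence=seq)
            assert monoisotopic_mass(seq) == pytest.approx(ref, abs=0.01)


class TestModificationDeltas:
    def test_pyroglu_from_gln_loses_ammonia(self):
        assert modification_delta("pyroglu", nterm="Q") == pytest.approx(
            -17.03, abs=5e-3
        )

    def test_pyroglu_from_glu_loses_water(self):
        assert modification_delta("pyroglu", nterm="E") == pytest.approx(
            -18.015, abs=5e-3
        )

    def test_pyroglu_invalid_nterm(self):
        with pytest.raises(ValueError):
            modification_delta("pyroglu", nterm="D")

    def test_galactose_increment(self):
        assert glycan_delta("G1F") - glycan_delta("G0F") == pytest.approx(
            162.14, abs=5e-3
        )

    def test_cterm_lys_is_lysine_residue(self):
        assert modification_delta("cterm_lys") == pytest.approx(128.17, abs=1e-2)


class TestEnumeration:
    def test_fc_cross_product_count(self):
        sub = SubunitChain(kind="Fc/2", sequence="GPSVMAMKM")  # 3 Met
        forms = enumerate_proteoforms(sub, LibraryConfig(unspecific_ox_cap=4))
        assert len(forms) == 3 * 8 * 2  # glycans x ox(0..7) x lysine

    def test_lc_count(self):
        sub = SubunitChain(kind="LC", sequence="DIQMK")  # 1 Met
        forms = enumerate_proteoforms(sub, LibraryConfig(unspecific_ox_cap=4))
        assert len(forms) == 6  # 0..5 oxidations

    def test_degenerate_single_form(self):
        sub = SubunitChain(kind="LC", sequence="DIQK")  # 0 Met
        cfg = LibraryConfig(unspecific_ox_cap=0, fc_glycans=(None,))
        assert len(enumerate_proteoforms(sub, cfg)) == 1

    def test_ox_series_monotone_constant_step(self):
        sub = SubunitChain(kind="Fd'", sequence="QVQLMKSSCPAPELLG")
        forms = [
            f for f in enumerate_proteoforms(sub)
            if f.mods.glycan is None and not f.mods.pyroglu and not f.mods.cterm_lys
        ]
        masses = [f.avg_mass for f in sorted(forms, key=lambda f: f.mods.n_ox)]
        steps = np.diff(masses)
        assert np.all(steps > 0)
        assert np.allclose(steps, modification_delta("ox"), atol=1e-9)


class TestMatching:
    @pytest.fixture()
    def library(self):
        sub = SubunitChain(kind="LC", sequence="DIQMK" * 40)  # ~24 kDa scale
        return enumerate_proteoforms(sub, LibraryConfig(unspecific_ox_cap=1))

    def test_exact_hit(self, library):
        pf = library[0]
        hits = match_mass(pf.avg_mass, library)
        assert hits[0].proteoform is pf
        assert hits[0].delta_ppm == 0.0
        assert hits[0].stars == "*"

    def test_just_outside_window_no_match(self, library):
        pf = max(library, key=lambda f: f.avg_mass)
        observed = pf.avg_mass * (1 + 71e-6)
        assert match_mass(observed, library) == []

    def test_window_contains_entry_at_boundary(self, library):
        """Matching symmetry: m*(1 +/- eps) within 70 ppm keeps the entry."""
        pf = library[0]
        for eps in (-69e-6, -1e-8, 0.0, 1e-8, 69e-6):
            hits = match_mass(pf.avg_mass * (1 + eps), library)
            assert any(h.proteoform is pf for h in hits)

    def test_nearer_of_two_entries_only(self, library):
        """16 Da oxidation spacing (~650 ppm at 24 kDa) vs the 70 ppm window."""
        pf0 = next(f for f in library if f.mods.n_ox == 0)
        pf1 = next(f for f in library if f.mods.n_ox == 1)
        observed = pf0.avg_mass + 1.0  # inside pf0's window, 15 Da from pf1
        hits = match_mass(observed, library)
        assert hits[0].proteoform is pf0
        assert all(h.proteoform is not pf1 for h in hits)
        assert hits[0].stars == "**"

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            match_mass(1000.0, [])


class TestStarNotation:
    @pytest.mark.parametrize(
        "delta,stars",
        [
            (0.0, "*"),
            (0.3, "*"),
            (0.5, "*"),
            (-0.4, "*"),
            (1.0, "**"),
            (1.5, "**"),
            (2.0, "***"),
            (4.0, "***"),
            (5.0, REJECTED),
            (-5.0, REJECTED),
        ],
    )
    def test_bands(self, delta, stars):
        assert annotate_mass_error(delta) == stars
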