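"""Composition module: peak integration, abundance algebra, dichotomy."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from venomics import (
    Band,
    BandAllocation,
    ToxinFamily,
    VenomComposition,
    allocate_band_abundance,
    classify_dichotomy,
    integrate_peaks,
    mass_to_molar,
    molar_ratio,
    molar_to_mass,
    molecule_fraction,
    reference,
    relative_abundance,
    round_half_away,
)


def _peaks(rows):
    return pd.DataFrame(
        [
            {
                "fraction_id": f"F{i}",
                "retention_time_min": float(i),
                "area": a,
                "family": fam,
            }
            for i, (fam, a) in enumerate(rows, start=1)
        ]
    )


class TestIntegratePeaks:
    def test_zero_trace_gives_zero_areas(self):
        t = np.linspace(0, 10, 101)
        table = integrate_peaks((t, np.zeros_like(t)), [(1, 3, 0.0), (5, 8, 0.0)])
        assert (table["area"] == 0).all()

    def test_unit_triangle_area(self):
        t = np.arange(0, 2.0001, 0.001)
        s = np.where(t <= 1, t, 2 - t)
        table = integrate_peaks((t, s), [(0, 2, 0.0)])
        assert table["area"].iloc[0] == pytest.approx(1.0, abs=1e-3)

    def test_two_identical_peaks_equal_areas(self):
        t = np.arange(0, 10.0001, 0.001)
        s = np.exp(-0.5 * ((t - 2) / 0.3) ** 2) + np.exp(-0.5 * ((t - 7) / 0.3) ** 2)
        table = integrate_peaks((t, s), [(0.5, 3.5, 0.0), (5.5, 8.5, 0.0)])
        assert table["area"].iloc[0] == pytest.approx(table["area"].iloc[1], rel=1e-9)

    def test_baseline_subtraction_clamps_at_zero(self):
        t = np.linspace(0, 1, 50)
        table = integrate_peaks((t, np.full_like(t, 0.1)), [(0, 1, 0.5)])
        assert table["area"].iloc[0] == 0.0

    def test_overlapping_bounds_error(self):
        t = np.linspace(0, 10, 101)
        with pytest.raises(ValueError, match="overlap"):
            integrate_peaks((t, np.zeros_like(t)), [(1, 5, 0.0), (4, 8, 0.0)])

    def test_empty_trace_error(self):
        with pytest.raises(ValueError, match="empty"):
            integrate_peaks(([], []), [(0, 1, 0.0)])


class TestRelativeAbundance:
    def test_single_family_is_100(self):
        assert relative_abundance(_peaks([("X", 5.0)])) == {"X": 100.0}

    @pytest.mark.parametrize(
        "rows, expect",
        [
            ([("X", 2.0), ("X", 2.0), ("Y", 4.0)], {"X": 50.0, "Y": 50.0}),
            ([("X", 1.0), ("Y", 3.0)], {"X": 25.0, "Y": 75.0}),
        ],
    )
    def test_hand_arithmetic(self, rows, expect):
        out = relative_abundance(_peaks(rows))
        for fam, pct in expect.items():
            assert out[fam] == pytest.approx(pct, abs=1e-12)

    def test_unassigned_counts_in_denominator(self):
        out = relative_abundance(_peaks([("X", 3.0), ("unassigned", 1.0)]))
        assert out["X"] == pytest.approx(75.0)
        assert out["unassigned"] == pytest.approx(25.0)
        assert sum(out.values()) == pytest.approx(100.0, abs=1e-9)

    def test_zero_total_area_error(self):
        with pytest.raises(ValueError, match="zero"):
            relative_abundance(_peaks([("X", 0.0)]))

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["A", "B", "C", "unassigned"]),
                st.floats(0, 1e6, allow_nan=False),
            ),
            min_size=1,
            max_size=20,
        ).filter(lambda rows: sum(a for _, a in rows) > 1e-6)
    )
    @settings(deadline=None, max_examples=50)
    def test_conservation_sums_to_100(self, rows):
        out = relative_abundance(_peaks(rows))
        assert sum(out.values()) == pytest.approx(100.0, abs=1e-9)


class TestMassToMolar:
    @pytest.mark.parametrize(
        "mass_pct, mw, expect",
        [(7.5, 1.40e4, 0.536), (12.8, 444.4, 28.803), (0.0, 123.0, 0.0)],
    )
    def test_reference_conversions(self, mass_pct, mw, expect):
        assert round_half_away(mass_to_molar(mass_pct, mw), 3) == expect

    @pytest.mark.parametrize("species", sorted(reference.MASS_PERCENT))
    def test_published_table_regression(self, species):
        """Every published mmoles % cell reproduces at +-0.001."""
        masses = reference.FAMILY_MASSES_DA
        for fam, mass_pct in reference.MASS_PERCENT[species].items():
            got = round_half_away(mass_to_molar(mass_pct, masses[fam]), 3)
            want = reference.MOLAR_PERCENT_PUBLISHED[species][fam]
            assert got == pytest.approx(want, abs=1e-3), (species, fam)

    def test_nonpositive_mass_error(self):
        with pytest.raises(ValueError):
            mass_to_molar(5.0, 0.0)

    @given(
        st.floats(1e-6, 100, allow_nan=False),
        st.floats(100, 1e6, allow_nan=False),
    )
    @settings(deadline=None, max_examples=100)
    def test_round_trip(self, mass_pct, mw):
        back = molar_to_mass(mass_to_molar(mass_pct, mw), mw)
        assert back == pytest.approx(mass_pct, rel=1e-12)


class TestMolarRatioAndFraction:
    def test_svmpi_to_svmp_ratio_mattogrossensis(self, matto):
        r = molar_ratio(matto, ["SVMPi"], ["PI-SVMP", "PIII-SVMP"])
        assert round_half_away(r, 1) == 20.4

    def test_svmpi_to_svmp_ratio_neuwiedi(self, compositions):
        r = molar_ratio(compositions["neuwiedi"], ["SVMPi"], ["PI-SVMP", "PIII-SVMP"])
        assert round_half_away(r, 1) == 25.4

    def test_identity_ratio(self, matto):
        assert molar_ratio(matto, ["SVSP"], ["SVSP"]) == pytest.approx(1.0)

    def test_zero_denominator_error(self, registry):
        comp = VenomComposition("x", {"SVMPi": 5.0}, registry)
        with pytest.raises(ValueError, match="denominator"):
            molar_ratio(comp, ["SVMPi"], ["PI-SVMP"])

    def test_svmpi_molecule_fraction_mattogrossensis(self, matto):
        assert round_half_away(molecule_fraction(matto, "SVMPi"), 1) == 89.8

    def test_single_family_is_all_molecules(self, registry):
        comp = VenomComposition("x", {"SVSP": 10.0}, registry)
        assert molecule_fraction(comp, "SVSP") == pytest.approx(100.0)

    def test_equal_molar_families_split_evenly(self, registry):
        comp = VenomComposition(
            "x", {"K49-PLA2": 7.0, "D49-PLA2": 7.0}, registry
        )
        assert molecule_fraction(comp, "K49-PLA2") == pytest.approx(50.0)

    def test_absent_family_error(self, matto):
        with pytest.raises(ValueError, match="absent"):
            molecule_fraction(matto, "BPP")


class TestDichotomy:
    @pytest.mark.parametrize(
        "species, pattern",
        [("diporus", "I"), ("erythromelas", "II"), ("mattogrossensis", "III")],
    )
    def test_reference_patterns(self, compositions, species, pattern):
        assert classify_dichotomy(compositions[species]) == pattern

    def test_low_piii_rescue_promotes_borderline(self, compositions):
        # pauloensis: K49/D49 ~ 1.24 but PIII depressed -> pattern I with rescue
        comp = compositions["pauloensis"]
        assert classify_dichotomy(comp) == "III"
        assert classify_dichotomy(comp, low_piii_rescue=0.2) == "I"


class TestBandAllocation:
    def test_single_band_single_protein(self):
        alloc = BandAllocation(10.0, [Band("b1", 1.0, {"p": (100.0,)})])
        assert allocate_band_abundance(alloc) == {"p": pytest.approx(10.0)}

    def test_ion_intensity_split(self):
        alloc = BandAllocation(
            10.0,
            [Band("b1", 1.0, {"p1": (100.0, 150.0, 50.0), "p2": (50.0, 30.0, 20.0)})],
        )
        out = allocate_band_abundance(alloc)
        assert out["p1"] == pytest.approx(7.5)
        assert out["p2"] == pytest.approx(2.5)

    def test_densitometry_split(self):
        alloc = BandAllocation(
            8.0,
            [
                Band("b1", 0.75, {"p1": (10.0,)}),
                Band("b2", 0.25, {"p2": (99.0,)}),
            ],
        )
        out = allocate_band_abundance(alloc)
        assert out == {"p1": pytest.approx(6.0), "p2": pytest.approx(2.0)}

    def test_conservation(self):
        alloc = BandAllocation(
            12.5,
            [
                Band("b1", 0.6, {"a": (3.0, 2.0, 1.0), "b": (9.0, 1.0, 0.5)}),
                Band("b2", 0.4, {"c": (7.0,), "d": (1.0, 1.0)}),
            ],
        )
        assert sum(allocate_band_abundance(alloc).values()) == pytest.approx(
            12.5, abs=1e-9
        )

    def test_zero_intensity_multi_protein_band_error(self):
        alloc = BandAllocation(
            5.0, [Band("b1", 1.0, {"a": (0.0,), "b": (0.0,)})]
        )
        with pytest.raises(ValueError, match="zero"):
            allocate_band_abundance(alloc)


class TestTypes:
    def test_toxin_family_rejects_nonpositive_mass(self):
        with pytest.raises(ValueError):
            ToxinFamily("X", -1.0)

    def test_composition_rejects_sum_above_100(self, registry):
        with pytest.raises(ValueError, match="100"):
            VenomComposition("x", {"SVSP": 60.0, "DISI": 50.0}, registry)

    def test_composition_rejects_negative(self, registry):
        with pytest.raises(ValueError, match="negative"):
            VenomComposition("x", {"SVSP": -1.0}, registry)
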