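"""Column model: slenderness, classification, critical loads, design scan."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retroprobe import mechanics as m
from retroprobe import presets as P


def geo(L, w, t):
    return m.ShankGeometry(L, w, t)


class TestSlenderness:
    @pytest.mark.parametrize(
        "L,t,expected",
        [
            (1000.0, 25.0, 96.99),  # silicon reference shank
            (312.0, 25.0, 30.26),
            (180.0, 3.0, 145.49),
        ],
    )
    def test_hand_computed_values(self, L, t, expected):
        lam = m.slenderness_ratio(geo(L, 100.0, t))
        assert lam == pytest.approx(expected, abs=0.01)

    @given(w=st.floats(min_value=25.0, max_value=500.0))
    @settings(max_examples=25, derandomize=True)
    def test_width_cancels(self, w):
        """r_x = t/sqrt(12) is width-independent, so lambda is too."""
        base = m.slenderness_ratio(geo(200.0, 25.0, 10.0))
        assert m.slenderness_ratio(geo(200.0, w, 10.0)) == pytest.approx(base)

    def test_radius_of_gyration_closed_form(self):
        g = geo(200.0, 80.0, 12.0)
        assert g.radius_of_gyration_m == pytest.approx(12e-6 / math.sqrt(12))

    @pytest.mark.parametrize("L,w,t", [(-1, 50, 5), (100, 0, 5), (100, 50, -2)])
    def test_nonpositive_dimension_rejected(self, L, w, t):
        with pytest.raises(m.InvalidGeometryError):
            geo(L, w, t)

    def test_thickness_exceeding_width_rejected(self):
        with pytest.raises(m.InvalidGeometryError):
            geo(100, 5, 50)


class TestClassification:
    @pytest.mark.parametrize(
        "lam,expected",
        [
            (145.49, m.ColumnClass.LONG),
            (120.0, m.ColumnClass.MEDIUM),  # inclusive boundary
            (32.0, m.ColumnClass.MEDIUM),
            (30.26, m.ColumnClass.SHORT),
            (120.001, m.ColumnClass.LONG),
            (31.999, m.ColumnClass.SHORT),
        ],
    )
    def test_boundaries(self, lam, expected):
        assert m.classify_column(lam) is expected

    def test_nonpositive_slenderness_rejected(self):
        with pytest.raises(ValueError):
            m.classify_column(0.0)


class TestCriticalLoads:
    @pytest.mark.parametrize(
        "material,L,w,t,expected_n",
        [
            (P.SILICON, 1000.0, 100.0, 25.0, 0.4094),
            (P.PARYLENE_C, 140.0, 100.0, 7.0, 6.94e-3),
            (P.POLYIMIDE, 140.0, 100.0, 3.0, 1.93e-3),
        ],
    )
    def test_rankine_hand_computed(self, material, L, w, t, expected_n):
        p_r = m.rankine_force(geo(L, w, t), material)
        assert p_r == pytest.approx(expected_n, rel=5e-3)

    def test_rankine_below_crushing_limit(self):
        g = geo(200.0, 50.0, 7.0)
        assert m.rankine_force(g, P.POLYIMIDE) < (
            P.POLYIMIDE.crushing_strength * g.cross_section_m2
        )

    def test_crushing_limit_as_slenderness_vanishes(self):
        g = geo(0.5, 100.0, 25.0)  # nearly zero length -> lambda -> 0
        expected = P.SILICON.crushing_strength * g.cross_section_m2
        assert m.rankine_force(g, P.SILICON) == pytest.approx(expected, rel=1e-3)

    @given(
        L=st.floats(min_value=100.0, max_value=1000.0),
        dL=st.floats(min_value=1.0, max_value=200.0),
    )
    @settings(max_examples=25, derandomize=True)
    def test_rankine_decreasing_in_length(self, L, dL):
        base = m.rankine_force(geo(L, 50.0, 7.0), P.POLYIMIDE)
        longer = m.rankine_force(geo(L + dL, 50.0, 7.0), P.POLYIMIDE)
        assert longer < base

    @given(scale=st.floats(min_value=1.05, max_value=4.0))
    @settings(max_examples=25, derandomize=True)
    def test_rankine_increasing_in_width_and_modulus(self, scale):
        g, ref = geo(200.0, 50.0, 7.0), P.PARYLENE_C
        assert m.rankine_force(geo(200.0, 50.0 * scale, 7.0), ref) > m.rankine_force(g, ref)
        stiffer = m.MaterialSpec("x", ref.youngs_modulus * scale, ref.crushing_strength)
        assert m.rankine_force(g, stiffer) > m.rankine_force(g, ref)

    def test_euler_scaling(self):
        g = geo(200.0, 50.0, 3.0)
        base = m.euler_force(g, P.POLYIMIDE)
        assert m.euler_force(geo(400.0, 50.0, 3.0), P.POLYIMIDE) == pytest.approx(base / 4)
        assert m.euler_force(geo(200.0, 100.0, 3.0), P.POLYIMIDE) == pytest.approx(base * 2)

    def test_euler_near_rankine_for_long_column(self):
        g = geo(225.0, 50.0, 3.0)  # lambda ~ 182, long column
        p_e = m.euler_force(g, P.POLYIMIDE)
        p_r = m.rankine_force(g, P.POLYIMIDE)
        assert 0 < p_e < 2 * p_r


@pytest.fixture(scope="module")
def scan():
    return m.feasibility_scan(
        P.flexible_design_space(),
        [P.PARYLENE_C, P.POLYIMIDE],
        m.FeasibilityConfig(2e-3),
    )


class TestFeasibilityScan:

    def test_one_row_per_pair_with_expected_columns(self, scan):
        assert len(scan) == 2 * 18
        assert list(scan.columns) == [
            "material", "name", "L_um", "w_um", "t_um",
            "lambda", "class", "P_R_mN", "P_E_mN", "feasible",
        ]

    def test_no_3um_design_feasible(self, scan):
        thin = scan[scan.t_um == 3.0]
        assert not thin.feasible.any()

    def test_pac_5um_only_shortest_widest(self, scan):
        sub = scan[(scan.material == "PaC") & (scan.t_um == 5.0)]
        feasible = sub[sub.feasible]
        assert len(feasible) == 1
        row = feasible.iloc[0]
        assert (row.L_um, row.w_um) == (140.0, 100.0)

    def test_pi_5um_all_but_longest_narrow(self, scan):
        sub = scan[(scan.material == "PI") & (scan.t_um == 5.0)]
        infeasible = sub[~sub.feasible]
        assert len(infeasible) == 1
        assert infeasible.iloc[0].L_um == 225.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            m.feasibility_scan([], [P.SILICON], m.FeasibilityConfig())

    def test_threshold_tie_is_feasible_and_marginal(self):
        g = geo(200.0, 50.0, 7.0)
        p_r = m.rankine_force(g, P.POLYIMIDE)
        a = m.assess_column(g, P.POLYIMIDE, m.FeasibilityConfig(p_r))
        assert a.feasible and a.marginal


def test_reference_fold_differences_material_order():
    """The weakest Si reference shank is ~59x stronger than the best PaC
    design and ~17x stronger than the best PI design (the softer polymer
    gives the larger ratio)."""
    ratios = m.reference_fold_differences(
        P.SILICON_REFERENCE_SHANKS,
        P.SILICON,
        {
            "PaC": (P.PARYLENE_C, P.flexible_design_space()),
            "PI": (P.POLYIMIDE, P.flexible_design_space()),
        },
    )
    assert round(ratios["PaC"]) == 59
    assert round(ratios["PI"]) == 17
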