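"""Linear analysis: sign structures, Turing inequalities, bands, suprema."""

import math

import numpy as np
import pytest

from turingforge.stability import (
    DimensionalRD,
    check_turing_dimensional,
    classify_sign_structure,
    critical_diffusion,
    dispersion,
    min_domain_length,
    nondimensionalize,
    sup_over_region,
    wavenumber_band,
)
from turingforge.kinetics import circle_region, hyperbolic_region


def _growth_dimensional(sys: DimensionalRD, k2: float) -> float:
    """Oracle: dominant eigenvalue of the dimensional mode matrix."""
    A = np.array(
        [[sys.fu - sys.Du * k2, sys.fv], [sys.gu, sys.gv - sys.Dv * k2]]
    )
    return float(np.max(np.linalg.eigvals(A).real))


class TestSignStructure:
    @pytest.mark.parametrize(
        "J,expected",
        [
            ([[1, 1], [-3, -2]], "cross"),
            ([[1, -1], [3, -2]], "pure"),
            ([[-1, 1], [1, -2]], "none"),  # fu <= 0 is excluded by convention
            ([[1, 0], [1, -2]], "none"),   # zero entry -> marginal, none
        ],
    )
    def test_classification(self, J, expected):
        assert classify_sign_structure(J) == expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify_sign_structure([[np.nan, 1], [-1, -1]])


class TestDimensionalReport:
    def test_unstable_band_matches_eigenvalue_sweep(self):
        sys = DimensionalRD(Du=1, Dv=20, fu=1, fv=1, gu=-3, gv=-2)
        rep = check_turing_dimensional(sys)
        assert rep.stable_without_diffusion and rep.diffusion_driven
        k2m, k2p = rep.band
        assert 0 < k2m < k2p
        # oracle: positive growth strictly inside, negative outside
        for k2 in np.linspace(k2m + 1e-3, k2p - 1e-3, 7):
            assert _growth_dimensional(sys, k2) > 0
        assert _growth_dimensional(sys, k2m - 0.01) < 0
        assert _growth_dimensional(sys, k2p + 0.01) < 0

    def test_equal_diffusivities_cannot_destabilize(self):
        rep = check_turing_dimensional(
            DimensionalRD(Du=1, Dv=1, fu=1, fv=1, gu=-3, gv=-2)
        )
        assert rep.stable_without_diffusion
        assert not rep.diffusion_driven

    def test_equality_case_flags_marginal(self):
        # choose Dv*fu + Du*gv == 2*sqrt(Du*Dv*det) exactly:
        # fu=1, gv=-1, det=1-fv*gu; take fv=1, gu=-3 -> det=4.
        # Dv - Du = 2*sqrt(4 Du Dv) -> Dv - 4sqrt(Du Dv) - Du = 0;
        # with Du=1: sqrt(Dv) = 2+sqrt(5).
        Dv = (2 + math.sqrt(5)) ** 2
        rep = check_turing_dimensional(
            DimensionalRD(Du=1, Dv=Dv, fu=1, fv=1, gu=-3, gv=-1)
        )
        assert rep.marginal

    def test_admissible_modes_listed_when_L_given(self):
        sys = DimensionalRD(Du=1, Dv=20, fu=1, fv=1, gu=-3, gv=-2, L=20.0)
        rep = check_turing_dimensional(sys)
        assert rep.band is not None
        k2m, k2p = rep.band
        for n in rep.admissible_modes:
            assert k2m < (n * math.pi / 20.0) ** 2 < k2p
        # no admissible mode missing
        missing = [
            n for n in range(1, 40)
            if k2m < (n * math.pi / 20.0) ** 2 < k2p and n not in rep.admissible_modes
        ]
        assert not missing


class TestNondimensionalize:
    def test_cross_example(self):
        nd = nondimensionalize(DimensionalRD(Du=1, Dv=16, fu=2, fv=4, gu=-3, gv=-4))
        assert nd.F == pytest.approx(3.0)
        assert nd.G == pytest.approx(2.0)
        assert nd.D == pytest.approx(16.0)
        assert nd.sign_type == "cross"
        assert nd.F_prime == pytest.approx(2.0)

    def test_identity_on_nondimensional_input(self):
        nd = nondimensionalize(DimensionalRD(Du=1, Dv=10, fu=1, fv=1, gu=-2.5, gv=-1.5))
        assert (nd.F, nd.G, nd.D) == pytest.approx((2.5, 1.5, 10.0))

    def test_pure_example(self):
        nd = nondimensionalize(DimensionalRD(Du=1, Dv=10, fu=1, fv=-1, gu=2, gv=-1.5))
        assert nd.F == pytest.approx(2.0)
        assert nd.G == pytest.approx(1.5)
        assert nd.sign_type == "pure"

    def test_eigenvalue_matching_oracle(self):
        """Growth rates of the dimensional system equal those of the reduced
        one after rescaling time by fu and length by sqrt(Du/fu)."""
        sys = DimensionalRD(Du=2, Dv=36, fu=2, fv=4, gu=-3, gv=-4)
        nd = nondimensionalize(sys)
        for k2nd in [0.0, 0.2, 0.5, 1.0]:
            k2dim = k2nd / nd.length_scale**2
            lam_dim = _growth_dimensional(sys, k2dim)
            lam_nd = dispersion(nd.F, nd.G, nd.D, [k2nd], nd.sign_type).growth_rate[0]
            assert lam_dim == pytest.approx(lam_nd / nd.time_scale, rel=1e-10)

    def test_fu_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            nondimensionalize(DimensionalRD(Du=1, Dv=10, fu=-1, fv=1, gu=1, gv=-2))

    def test_consistency_with_dimensional_report(self, rng):
        """Dimensional and nondimensional routes agree on the two stability
        verdicts for random admissible systems."""
        for _ in range(50):
            fu = rng.uniform(0.2, 2.0)
            fv = rng.uniform(0.2, 2.0)
            gu = -rng.uniform(0.2, 4.0)
            gv = -rng.uniform(0.2, 3.0)
            Du = rng.uniform(0.5, 2.0)
            Dv = Du * rng.uniform(1.0, 40.0)
            sys = DimensionalRD(Du=Du, Dv=Dv, fu=fu, fv=fv, gu=gu, gv=gv)
            rep = check_turing_dimensional(sys)
            nd = nondimensionalize(sys)
            stable_nd = nd.F > nd.G and nd.G > 1
            band = wavenumber_band(nd.F, nd.G, nd.D)
            driven_nd = stable_nd and band is not None and band[1] > band[0] >= 0
            if abs(nd.G - 1) > 1e-9 and abs(nd.F - nd.G) > 1e-9:
                assert rep.stable_without_diffusion == stable_nd
            if rep.stable_without_diffusion and stable_nd:
                assert rep.diffusion_driven == driven_nd


class TestDesignQuantities:
    def test_critical_diffusion_disc_value(self):
        assert critical_diffusion(2, 1) == pytest.approx((1 + math.sqrt(2)) ** 2,
                                                         abs=1e-12)

    def test_critical_diffusion_requires_F_gt_G(self):
        with pytest.raises(ValueError):
            critical_diffusion(2, 2)

    def test_critical_diffusion_against_bisection_oracle(self):
        """Dc is where the max growth over k^2 first touches zero."""
        F, G = 9.0, 1.0
        assert critical_diffusion(F, G) == pytest.approx(17 + 12 * math.sqrt(2))

        def max_growth(D):
            k2 = np.linspace(1e-6, 2.0, 20001)
            return dispersion(F, G, D, k2).growth_rate.max()

        lo, hi = 1.0, 200.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if max_growth(mid) > 0:
                hi = mid
            else:
                lo = mid
        assert critical_diffusion(F, G) == pytest.approx(hi, rel=1e-4)

    def test_band_endpoints_bracket_growth_sign_change(self):
        k2m, k2p = wavenumber_band(2, 1, 8)
        assert (k2m, k2p) == pytest.approx(
            ((7 - math.sqrt(17)) / 16, (7 + math.sqrt(17)) / 16), abs=1e-12
        )
        for edge in (k2m, k2p):
            lo = dispersion(2, 1, 8, [edge - 1e-6]).growth_rate[0]
            hi = dispersion(2, 1, 8, [edge + 1e-6]).growth_rate[0]
            assert (lo > 0) != (hi > 0)

    def test_band_degenerate_at_Dc(self):
        Dc = critical_diffusion(2, 1)
        k2m, k2p = wavenumber_band(2, 1, Dc)
        assert k2m == pytest.approx(k2p, abs=1e-9)

    def test_band_empty_below_Dc(self):
        assert wavenumber_band(2, 1, 4) is None

    def test_band_growth_equivalence_random(self, rng):
        """Growth is positive exactly for k^2 inside the band."""
        for _ in range(200):
            G = rng.uniform(1.01, 4.0)
            F = G + rng.uniform(0.05, 4.0)
            D = rng.uniform(1.5, 3.0) * critical_diffusion(F, G)
            band = wavenumber_band(F, G, D)
            assert band is not None
            k2m, k2p = band
            k2s = np.array([k2m + 1e-6, 0.5 * (k2m + k2p), k2p - 1e-6,
                            max(k2m - 1e-3, 0.0), k2p + 1e-3])
            g = dispersion(F, G, D, k2s).growth_rate
            assert g[0] > -1e-9 and g[1] > 0 and g[2] > -1e-9
            assert g[3] <= 1e-9 and g[4] <= 1e-9

    def test_max_growth_vanishes_at_Dc(self, rng):
        for _ in range(30):
            G = rng.uniform(1.01, 3.0)
            F = G + rng.uniform(0.1, 3.0)
            Dc = critical_diffusion(F, G)
            band = wavenumber_band(F, G, Dc)
            k2c = 0.5 * (band[0] + band[1])
            g = dispersion(F, G, Dc, [k2c]).growth_rate[0]
            assert abs(g) < 1e-8

    def test_min_domain_length_value(self):
        assert min_domain_length(2, 1, 8) == pytest.approx(
            4 * math.pi / math.sqrt(7 + math.sqrt(17)), abs=1e-12
        )

    def test_min_domain_length_limit_large_D(self):
        # k_+^2 -> fu = 1 as D -> inf, so Lc -> pi
        assert min_domain_length(2, 1, 1e9) == pytest.approx(math.pi, rel=1e-4)

    def test_min_domain_length_needs_band(self):
        with pytest.raises(ValueError):
            min_domain_length(2, 1, 5)


class TestDispersion:
    def test_zero_wavenumber_boundary_case(self):
        # det = F - G = 0 at the region boundary: neutral uniform mode
        g = dispersion(2, 2, 8, [0.0]).growth_rate[0]
        assert g == pytest.approx(0.0, abs=1e-12)

    def test_zero_wavenumber_saddle_outside_region(self):
        # det = F - G < 0: unstable to spatially constant modes
        g = dispersion(1.5, 2, 8, [0.0]).growth_rate[0]
        assert g > 0

    def test_band_interior_grows(self):
        assert dispersion(2, 1, 8, [0.43]).growth_rate[0] > 0

    def test_pure_and_cross_share_spectrum(self):
        k2 = np.linspace(0, 1.2, 25)
        gc = dispersion(2.5, 1.5, 12, k2, "cross").growth_rate
        gp = dispersion(2.5, 1.5, 12, k2, "pure").growth_rate
        np.testing.assert_allclose(gc, gp, atol=1e-12)

    def test_negative_k2_rejected(self):
        with pytest.raises(ValueError):
            dispersion(2, 1, 8, [-0.1])


class TestBandGrowthProperty:
    """Band membership and growth-rate sign agree for arbitrary admissible
    parameter combinations."""

    from hypothesis import given, settings, strategies as st

    @given(
        G=st.floats(1.01, 5.0),
        dF=st.floats(0.05, 5.0),
        mult=st.floats(1.05, 4.0),
        frac=st.floats(0.05, 0.95),
    )
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_interior_points_grow_exterior_decay(self, G, dF, mult, frac):
        F = G + dF
        D = mult * critical_diffusion(F, G)
        band = wavenumber_band(F, G, D)
        assert band is not None
        k2m, k2p = band
        inside = k2m + frac * (k2p - k2m)
        assert dispersion(F, G, D, [inside]).growth_rate[0] > 0
        assert dispersion(F, G, D, [k2p * 1.05]).growth_rate[0] < 1e-12
        if k2m > 0:
            assert dispersion(F, G, D, [k2m * 0.95]).growth_rate[0] < 1e-12


class TestSupOverRegion:
    def test_disc_critical_diffusion_at_origin(self):
        val, arg = sup_over_region(circle_region(), "Dc")
        assert val == pytest.approx((1 + math.sqrt(2)) ** 2, abs=1e-6)
        assert arg == pytest.approx((0.0, 0.0), abs=1e-6)

    def test_disc_F_supremum(self):
        val, arg = sup_over_region(circle_region(), "F")
        assert val == pytest.approx(2.0, abs=1e-9)
        assert arg[0] == pytest.approx(0.0, abs=1e-6)

    def test_disc_Lc_supremum(self):
        val, _ = sup_over_region(circle_region(), "Lc", D=8.0)
        assert val == pytest.approx(4 * math.pi / math.sqrt(7 + math.sqrt(17)),
                                    abs=1e-6)

    def test_two_branch_Dc_supremum(self):
        """The sup is approached as b -> 0 at the outer corners a in {0, 6},
        where F = 9, G = 1: Dc = 17 + 12 sqrt(2) ~ 33.97."""
        val, arg = sup_over_region(hyperbolic_region(), "Dc")
        assert val == pytest.approx(17 + 12 * math.sqrt(2), rel=1e-6)
        assert arg[0] == pytest.approx(0.0, abs=1e-6) or arg[0] == pytest.approx(
            6.0, abs=1e-6
        )
        # 1D reduction oracle along b = 0: Dc(a) = (sqrt(F-1)+sqrt(F))^2
        aa = np.linspace(0, 6, 2001)
        F = (aa - 3.0) ** 2
        ok = F > 1
        oracle = np.max((np.sqrt(F[ok] - 1) + np.sqrt(F[ok])) ** 2)
        assert val == pytest.approx(oracle, rel=1e-6)

    def test_empty_region_raises(self):
        from turingforge.kinetics import LevelSetRegion

        reg = LevelSetRegion(
            S=lambda a, b: -1.0 - 0 * a - 0 * b,
            param_names=("a", "b"),
            box=((-1, 1), (-1, 1)),
        )
        with pytest.raises(ValueError):
            sup_over_region(reg, "S")

    def test_report_serializes(self):
        import json

        rep = check_turing_dimensional(
            DimensionalRD(Du=1, Dv=20, fu=1, fv=1, gu=-3, gv=-2), L=10.0
        )
        d = json.loads(rep.to_json())
        assert d["diffusion_driven"] is True
        assert d["band"][0] < d["band"][1]
        assert d["admissible_modes"]
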