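"""Cluster/gap closed forms: internal identities, 1D reduction, oracles."""

import math

import numpy as np
import pytest

from dslattice import (
    BindingParameters,
    FiniteLatticeSpec,
    activity_at_density,
    binding_density,
    cluster_profile,
    cluster_size_no_gaps,
    cluster_size_with_gaps,
    enumerate_finite_lattice,
    gap_counts,
    gap_lengths,
    oneD_cluster_sizes,
)
from dslattice.cluster_stats import profile_frame, statistics_at_activity
from dslattice.ising_core import (
    GeneralSequenceWeights,
    quartic_coefficients_general,
)

GRID = [
    (0.5, 0.5, 1.0),
    (0.89, 5.0, 0.2),
    (1.0, 1.0, 1.0),
    (2.0, 5.0, 0.3),
    (17.0, 1.0, 0.1),
    (0.89, 36.2, 0.031),
    (17.0, 2.0, 0.05),
]


class TestPartitionIdentities:
    """The closed forms must satisfy the defining count identities:
    C_sgap * n_gap>=2 = nu + n_gap1 and C_nogap * (n_gap1 + n_gap>=2) = nu
    per site (bound and free clusters alternate on an infinite lattice)."""

    @pytest.mark.parametrize("w1,w2,x", GRID)
    def test_sgap_identity(self, w1, w2, x):
        p = BindingParameters(omega1=w1, omega2=w2)
        nu = binding_density(p, x)
        g1, g2 = gap_counts(p, x)
        assert cluster_size_with_gaps(p, x) * g2 - g1 == pytest.approx(nu, abs=1e-8)

    @pytest.mark.parametrize("w1,w2,x", GRID)
    def test_nogap_identity(self, w1, w2, x):
        p = BindingParameters(omega1=w1, omega2=w2)
        nu = binding_density(p, x)
        g1, g2 = gap_counts(p, x)
        assert cluster_size_no_gaps(p, x) * (g1 + g2) == pytest.approx(nu, abs=1e-8)

    @pytest.mark.parametrize("w1,w2,x", GRID)
    def test_gap_length_identities(self, w1, w2, x):
        # G_ge2 * n_gap>=2 = (1 - nu) - n_gap1 ; G_all * (n1 + n2) = 1 - nu
        p = BindingParameters(omega1=w1, omega2=w2)
        nu = binding_density(p, x)
        g1, g2 = gap_counts(p, x)
        g_ge2, g_all = gap_lengths(p, x)
        assert g_ge2 * g2 == pytest.approx(1 - nu - g1, abs=1e-8)
        assert g_all * (g1 + g2) == pytest.approx(1 - nu, abs=1e-8)


class TestGapCountDerivativeCrossCheck:
    """The printed gap-count forms are derivatives of ln(lambda1) with
    respect to ln(e0') and ln(c); verify by finite differences on the
    general-weights quartic."""

    def _lam_general(self, p, weights):
        roots = np.roots(quartic_coefficients_general(p, weights))
        real = roots[np.abs(roots.imag) < 1e-9].real
        return float(real.max())

    @pytest.mark.parametrize("w1,w2,x", [(2.0, 5.0, 0.3), (0.89, 5.0, 0.2), (17.0, 2.0, 0.05)])
    def test_fd_derivatives_match(self, w1, w2, x):
        p = BindingParameters(omega1=w1, omega2=w2)
        g1, g2 = gap_counts(p, x)
        h = 1e-6

        def w(e0p=1.0, c=1.0):
            return GeneralSequenceWeights(e0_iso=e0p, e0=1.0, x_iso=x, x=x, c=c)

        d_e0p = (
            math.log(self._lam_general(p, w(e0p=1 + h)))
            - math.log(self._lam_general(p, w(e0p=1 - h)))
        ) / (2 * h)
        d_c = (
            math.log(self._lam_general(p, w(c=1 + h)))
            - math.log(self._lam_general(p, w(c=1 - h)))
        ) / (2 * h)
        assert d_e0p == pytest.approx(g1, rel=1e-5, abs=1e-9)
        assert d_c == pytest.approx(g2, rel=1e-5, abs=1e-9)


class TestOneDReduction:
    def test_matches_2d_at_omega2_one(self):
        for omega in (0.5, 2.0, 22.0):
            p = BindingParameters(omega1=omega, omega2=1.0)
            for x in (0.05, 0.3, 1.0):
                nu = binding_density(p, x)
                cs, cn = oneD_cluster_sizes(omega, nu)
                assert cluster_size_with_gaps(p, x) == pytest.approx(cs, abs=1e-8)
                assert cluster_size_no_gaps(p, x) == pytest.approx(cn, abs=1e-8)

    def test_both_printed_nogap_forms_agree(self):
        for omega in (0.5, 3.0, 22.0, 54.4):
            for nu in (0.1, 0.5, 0.9):
                R = math.sqrt((1 - 2 * nu) ** 2 + 4 * omega * nu * (1 - nu))
                _, cn = oneD_cluster_sizes(omega, nu)
                assert cn == pytest.approx(2 * nu * (omega - 1) / (R - 1), rel=1e-10)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            oneD_cluster_sizes(22.0, 0.0)
        with pytest.raises(ValueError):
            oneD_cluster_sizes(-1.0, 0.5)


class TestLimits:
    def test_isolated_ligand_limit(self):
        p = BindingParameters(omega1=3.0, omega2=7.0)
        assert cluster_size_with_gaps(p, 1e-9) == pytest.approx(1.0, abs=1e-6)
        assert cluster_size_no_gaps(p, 1e-9) == pytest.approx(1.0, abs=1e-6)

    def test_empty_lattice(self):
        p = BindingParameters(omega1=2.0, omega2=2.0)
        assert gap_counts(p, 0.0) == (0.0, 0.0)
        assert gap_lengths(p, 0.0) == (math.inf, math.inf)
        with pytest.raises(ValueError):
            cluster_size_with_gaps(p, 0.0)

    def test_gap_lengths_diverge_at_low_occupancy(self):
        p = BindingParameters(omega1=2.0, omega2=2.0)
        g_ge2, g_all = gap_lengths(p, 1e-8)
        assert g_ge2 > 1e6 and g_all > 1e6

    def test_gap_length_floors(self):
        for w1, w2, x in GRID:
            g_ge2, g_all = gap_lengths(BindingParameters(omega1=w1, omega2=w2), x)
            assert g_ge2 >= 2.0 - 1e-12
            assert 1.0 - 1e-12 <= g_all <= g_ge2 + 1e-12


class TestEnumerationAgreement:
    """Ring enumeration converges to the infinite-lattice closed forms."""

    @pytest.mark.parametrize(
        "w1,w2,x", [(1.0, 1.0, 1.0), (0.89, 5.0, 0.2247), (0.5, 2.0, 1.0)]
    )
    def test_all_statistics_at_n18(self, w1, w2, x):
        p = BindingParameters(omega1=w1, omega2=w2)
        r = enumerate_finite_lattice(FiniteLatticeSpec(18, p, x))
        g1, g2 = gap_counts(p, x)
        assert r.nu == pytest.approx(binding_density(p, x), abs=5e-3)
        assert r.n_gap1_per_site == pytest.approx(g1, rel=0.02)
        assert r.n_gapGE2_per_site == pytest.approx(g2, rel=0.02)
        assert r.C_sgap == pytest.approx(cluster_size_with_gaps(p, x), rel=0.02)
        assert r.C_nogap == pytest.approx(cluster_size_no_gaps(p, x), rel=0.02)
        g_ge2, g_all = gap_lengths(p, x)
        assert r.G_ge2 == pytest.approx(g_ge2, rel=0.02)
        assert r.G_all == pytest.approx(g_all, rel=0.02)


class TestClusterProfile:
    def test_random_filling_run_lengths(self):
        # without cooperativity the gap-breaking cluster size is geometric:
        # C_nogap = 1/(1-nu)
        p = BindingParameters()
        for s in cluster_profile(p, [0.1, 0.3, 0.5, 0.7, 0.9]):
            assert s.C_nogap == pytest.approx(1.0 / (1.0 - s.nu), rel=1e-9)

    def test_empty_grid(self):
        assert cluster_profile(BindingParameters(), []) == []

    def test_profile_frame_columns(self, wt_params):
        frame = profile_frame(cluster_profile(wt_params, [0.25, 0.5]))
        assert list(frame.columns) == [
            "nu", "x", "C_sgap", "C_nogap", "G_ge2", "G_all",
            "n_gap1_per_site", "n_gapGE2_per_site",
        ]
        assert len(frame) == 2

    def test_longitudinal_dominance_creates_single_gaps(self, wt_params):
        """Strong omega2 produces many isolated single-site gaps at nu=0.5;
        strong omega1 at the same density produces almost none."""
        x_long, _ = activity_at_density(wt_params, 0.5)
        s_long = statistics_at_activity(wt_params, x_long)
        lat = BindingParameters(omega1=36.2, omega2=0.89)
        x_lat, _ = activity_at_density(lat, 0.5)
        s_lat = statistics_at_activity(lat, x_lat)
        assert s_long.n_gap1_per_site > s_long.n_gapGE2_per_site
        assert s_long.n_gap1_per_site > 5 * s_lat.n_gap1_per_site
        # and G_all is pulled far below G_ge2 only in the omega2-dominant case
        assert (s_long.G_ge2 - s_long.G_all) > (s_lat.G_ge2 - s_lat.G_all)
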