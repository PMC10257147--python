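"""Colocalization statistics, detection grouping, density profile and region."""

import warnings

import numpy as np
import pytest

from toccsl_sim import (
    AnalysisRegion,
    ColocalizationRule,
    detect_apparent_nmers,
    fit_density_profile,
    p_coloc,
    radial_density_profile,
    rho_crit,
)
from toccsl_sim.recovery import (
    RING_SPACING,
    DensityProfile,
    _recovery_profile,
    analysis_region,
    fit_cubic_optimum,
)

from conftest import make_ensemble


CENTER = (10.5, 10.5)


def region(r=3.0, rho=0.789):
    return AnalysisRegion(center=CENTER, r_analysis=r, rho_crit=rho)


class TestColocalizationProbability:
    def test_closed_form_values(self):
        assert p_coloc(0.0, 0.3) == 0.0
        assert p_coloc(0.79, 0.3) == pytest.approx(0.20, abs=0.005)
        assert rho_crit(0.2, 0.3) == pytest.approx(0.79, abs=0.005)

    def test_inverse_identity(self, rng):
        # below saturation (p < ~0.9), the round trip is exact to float precision
        for rho in rng.uniform(0.01, 8.0, size=20):
            assert rho_crit(p_coloc(rho, 0.3), 0.3) == pytest.approx(rho, rel=1e-12)

    def test_saturation_and_monotonicity(self):
        rhos = np.linspace(0, 100, 50)
        p = p_coloc(rhos, 0.3)
        assert np.all(np.diff(p) > 0)
        assert p_coloc(1e6, 0.3) == pytest.approx(1.0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            p_coloc(-1.0, 0.3)
        with pytest.raises(ValueError):
            rho_crit(1.2, 0.3)


class TestDetection:
    rule = ColocalizationRule()

    def test_isolated_dimer_single_event(self):
        ens = make_ensemble([CENTER], n=[2], m=[2])
        events = detect_apparent_nmers(ens, region(), self.rule, m_max=2)
        assert len(events) == 1
        assert events[0].n == 2
        assert not events[0].coloc_flag
        assert events[0].is_true_mmer

    def test_two_dimers_within_threshold_form_apparent_tetramer(self):
        ens = make_ensemble([(10.5, 10.5), (10.75, 10.5)], n=[2, 2], m=[2, 2])
        events = detect_apparent_nmers(ens, region(), self.rule, m_max=2)
        assert len(events) == 1
        assert events[0].n == 4
        assert events[0].coloc_flag
        assert events[0].member_m == (2, 2)
        assert not events[0].is_true_mmer

    def test_chain_grouping_is_single_linkage(self):
        # A-B and B-C are 250 nm apart, A-C is 500 nm: one event of n=3.
        pts = [(10.0, 10.5), (10.25, 10.5), (10.5, 10.5)]
        ens = make_ensemble(pts, n=[1, 1, 1], m=[1, 1, 1])
        events = detect_apparent_nmers(ens, region(), self.rule, m_max=1)
        assert len(events) == 1
        assert events[0].n == 3

    def test_dark_molecules_invisible(self):
        ens = make_ensemble([(10.5, 10.5), (10.6, 10.5)], n=[0, 2], m=[2, 2])
        events = detect_apparent_nmers(ens, region(), self.rule, m_max=2)
        assert len(events) == 1
        assert events[0].n == 2
        assert not events[0].coloc_flag

    def test_member_outside_region_joins_inside_seed(self):
        r = 1.0
        inside = (10.5 + r - 0.05, 10.5)
        outside = (10.5 + r + 0.15, 10.5)  # outside region, within R of inside
        ens = make_ensemble([inside, outside], n=[1, 2], m=[1, 2])
        events = detect_apparent_nmers(ens, region(r=r), self.rule, m_max=2)
        assert len(events) == 1
        assert events[0].n == 3

    def test_fully_outside_group_not_counted(self):
        ens = make_ensemble([(10.5 + 2.0, 10.5)], n=[2], m=[2])
        events = detect_apparent_nmers(ens, region(r=1.0), self.rule, m_max=2)
        assert events == []

    def test_n_cap_discards_oversized_events(self):
        # chain of 11 monomers inside the region exceeds 5 * m_max = 10
        pts = [(10.0 + 0.2 * i, 10.5) for i in range(11)]
        ens = make_ensemble(pts, n=[1] * 11, m=[1] * 11)
        events = detect_apparent_nmers(ens, region(), ColocalizationRule(), m_max=2)
        assert events == []
        # one molecule fewer is kept
        ens10 = make_ensemble(pts[:10], n=[1] * 10, m=[1] * 10)
        events = detect_apparent_nmers(ens10, region(), ColocalizationRule(), m_max=2)
        assert len(events) == 1 and events[0].n == 10

    @staticmethod
    def brute_force_components(pos, R):
        """O(N^2) union-find oracle for pairwise-threshold grouping."""
        n = len(pos)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if np.hypot(*(pos[i] - pos[j])) <= R:
                    parent[find(i)] = find(j)
        groups = {}
        for i in range(n):
            groups.setdefault(find(i), []).append(i)
        return {frozenset(g) for g in groups.values()}

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_grouping_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_mol = rng.integers(20, 200)
        pos = rng.uniform(8.5, 12.5, size=(n_mol, 2))
        n = rng.integers(1, 3, size=n_mol)
        ens = make_ensemble(pos, n=n, m=n)
        rule = ColocalizationRule(R=0.3, n_cap_factor=1000)  # disable the cap
        big_region = region(r=50.0)  # everything inside
        events = detect_apparent_nmers(ens, big_region, rule, m_max=2)
        got = {frozenset(ev.member_ids) for ev in events}
        expected = self.brute_force_components(pos, 0.3)
        assert got == expected
        # single-linkage sums: per-event n equals the sum over members
        by_members = {frozenset(ev.member_ids): ev.n for ev in events}
        for members, total in by_members.items():
            assert total == sum(int(n[i]) for i in members)

    def test_events_partition_molecules(self, rng):
        pos = rng.uniform(9, 12, size=(150, 2))
        ens = make_ensemble(pos, n=np.ones(150, dtype=int), m=np.ones(150, dtype=int))
        events = detect_apparent_nmers(
            ens, region(r=2.0), ColocalizationRule(n_cap_factor=1000), m_max=1
        )
        seen = [i for ev in events for i in ev.member_ids]
        assert len(seen) == len(set(seen))


class TestDensityProfile:
    def test_uniform_field_is_flat(self, rng):
        L, density, runs = 21.0, 60.0, 8
        snaps = []
        for _ in range(runs):
            k = int(density * L * L)
            pos = rng.uniform(0, L, size=(k, 2))
            snaps.append(make_ensemble(pos, n=np.ones(k, int), m=np.ones(k, int), L=L))
        prof = radial_density_profile(snaps, d_ap=7.0)
        sel = prof.r_outer > 1.0  # skip tiny inner rings (few counts)
        rel = prof.density[sel] / density
        assert np.all(np.abs(rel.mean() - 1.0) < 0.02)
        assert rel.std() < 0.2

    def test_all_dark_gives_empty_profile(self):
        pos = np.full((50, 2), 10.5)
        snap = make_ensemble(pos, n=np.zeros(50, int), m=np.full(50, 2))
        prof = radial_density_profile([snap], d_ap=7.0)
        assert prof.mean_count.sum() == 0

    def test_bleached_disk_profile(self, rng):
        L, density = 21.0, 80.0
        k = int(density * L * L)
        pos = rng.uniform(0, L, size=(k, 2))
        r = np.hypot(pos[:, 0] - 10.5, pos[:, 1] - 10.5)
        n = (r >= 2.0).astype(int)  # fully bleached disk of radius 2 um
        prof = radial_density_profile([make_ensemble(pos, n=n, m=np.ones(k, int), L=L)], d_ap=7.0)
        inner = prof.r_outer < 1.9
        outer = (prof.r_outer > 2.2) & (prof.r_outer < 6.0)
        assert prof.density[inner].max() == 0.0
        assert prof.density[outer].mean() == pytest.approx(density, rel=0.05)

    def test_ring_binning_half_open(self):
        # a molecule exactly at r = k * spacing belongs to ring k (inclusive upper edge)
        pos = np.array([[10.5 + 2 * RING_SPACING, 10.5], [10.5, 10.5]])
        prof = radial_density_profile(
            [make_ensemble(pos, n=[1, 1], m=[1, 1])], d_ap=7.0
        )
        assert prof.mean_count[1] == 1.0  # second ring: (spacing, 2*spacing]
        assert prof.mean_count[0] == 1.0  # r = 0 falls in the innermost disk

    def test_empty_run_list_rejected(self):
        with pytest.raises(ValueError):
            radial_density_profile([], d_ap=7.0)


class TestDensityFitAndRegion:
    def make_profile(self, rho0=100.0, d_prime=7.0, tau=1.0, noise=0.0, seed=0):
        r = RING_SPACING * np.arange(1, int(1.5 * 7.0 / RING_SPACING) + 1)
        rho = _recovery_profile(r, rho0, d_prime, tau)
        if noise:
            rho = rho * (1 + np.random.default_rng(seed).normal(0, noise, size=r.size))
        area = np.pi * (r**2 - (r - RING_SPACING) ** 2)
        return DensityProfile(d_ap=7.0, r_outer=r, mean_count=rho * area, n_runs=100)

    def test_parameter_recovery_under_noise(self):
        prof = self.make_profile(rho0=100, d_prime=7.0, tau=1.0, noise=0.02, seed=1)
        fit = fit_density_profile(prof)
        assert fit.rho0 == pytest.approx(100, rel=0.05)
        assert fit.d_prime == pytest.approx(7.0, rel=0.05)
        assert fit.tau == pytest.approx(1.0, rel=0.05)

    def test_limits_of_fitted_curve(self):
        prof = self.make_profile()
        fit = fit_density_profile(prof)
        assert fit(1e6) == pytest.approx(fit.rho0, rel=1e-6)
        from scipy.special import erf

        expected0 = fit.rho0 * (1 - erf(fit.d_prime / (2 * fit.tau)))
        assert fit(0.0) == pytest.approx(expected0, rel=1e-9)

    def test_region_matches_fine_scan_oracle(self):
        prof = self.make_profile()
        fit = fit_density_profile(prof)
        target = 0.789
        reg = analysis_region(fit, target, CENTER)
        # brute force: finest 1 nm scan for the largest radius below the cutoff
        scan = np.arange(0.0, fit.fit_r_max, 1e-3)
        below = scan[fit(scan) <= target]
        assert reg.r_analysis == pytest.approx(below.max(), abs=2e-3)
        assert fit(reg.r_analysis) == pytest.approx(target, rel=1e-6)
        assert reg.area == pytest.approx(np.pi * reg.r_analysis**2)

    def test_region_capped_when_cutoff_unreachable(self):
        prof = self.make_profile(rho0=0.5)  # plateau below the cutoff
        fit = fit_density_profile(prof)
        with pytest.warns(UserWarning):
            reg = analysis_region(fit, 0.789, CENTER)
        assert reg.r_analysis == pytest.approx(fit.fit_r_max)

    def test_degenerate_region_when_center_too_dense(self):
        prof = self.make_profile(rho0=100, d_prime=0.01, tau=0.05)  # no depletion
        fit = fit_density_profile(prof)
        with pytest.warns(UserWarning):
            reg = analysis_region(fit, 0.789, CENTER)
        assert reg.r_analysis == 0.0


class TestCubicOptimum:
    def test_symmetric_counts_peak_at_center(self):
        x = np.array([0.1, 0.4, 0.7, 1.0, 1.3])
        y = -((x - 0.7) ** 2)
        with warnings.catch_warnings():
            warnings.simplefilter("error")  # no boundary warning expected
            x_opt, _, at_boundary = fit_cubic_optimum(x, y)
        assert x_opt == pytest.approx(0.7, abs=1e-6)
        assert not at_boundary

    def test_monotone_counts_hit_boundary_with_warning(self):
        x = np.array([0.1, 0.4, 0.7, 1.0, 1.3])
        y = 2 * x
        with pytest.warns(UserWarning):
            x_opt, _, at_boundary = fit_cubic_optimum(x, y)
        assert at_boundary
        assert x_opt == pytest.approx(1.3)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_cubic_optimum([0.1, 0.2, 0.3], [1, 2, 3])
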