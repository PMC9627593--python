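"""State-level analysis: Gaussian fits, clustering, moduli, correlations."""

import itertools

import numpy as np
import pytest

import filatwist as ft
from filatwist.segmentation import StateSegment
from filatwist.state_analysis import (
    BOLTZMANN_J_PER_K,
    cluster_state_means,
    fit_state_gaussian,
    mode_histogram,
    select_n_clusters,
    twist_bend_correlation,
    twist_modulus,
)


def make_catalog(means, sigmas=None, lifetimes=None):
    sigmas = sigmas if sigmas is not None else [1.0] * len(means)
    lifetimes = lifetimes if lifetimes is not None else [100.0] * len(means)
    entries = []
    start = 0
    for mu, sig, life in zip(means, sigmas, lifetimes):
        n = max(int(life), 2)
        entries.append(
            (
                StateSegment(
                    start_frame=start,
                    end_frame=start + n,
                    mean_twist=float(mu),
                    sigma=float(sig),
                    lifetime_ns=float(life),
                ),
                "test",
            )
        )
        start += n
    return ft.StateCatalog(entries=entries)


class TestFitStateGaussian:
    def test_recovers_generating_parameters(self):
        rng = np.random.default_rng(0)
        n = 10_000
        trace = ft.TwistTrace(
            time=np.arange(n, dtype=float), twist=rng.normal(5.0, 1.0, n)
        )
        seg = StateSegment(0, n, 5.0, 1.0, float(n))
        mean, sigma = fit_state_gaussian(trace, seg)
        assert mean == pytest.approx(5.0, abs=0.03)
        assert sigma == pytest.approx(1.0, abs=0.03)

    def test_constant_segment_rejected(self):
        trace = ft.TwistTrace(time=np.arange(100.0), twist=np.full(100, 2.0))
        seg = StateSegment(0, 100, 2.0, 1.0, 100.0)
        with pytest.raises(ValueError, match="constant|positive"):
            fit_state_gaussian(trace, seg)

    def test_too_few_frames_rejected(self):
        trace = ft.TwistTrace(time=np.arange(100.0), twist=np.random.default_rng(1).normal(size=100))
        seg = StateSegment(0, 20, 0.0, 1.0, 20.0)
        with pytest.raises(ValueError, match="need >="):
            fit_state_gaussian(trace, seg)

    def test_adp1_preset_single_low_twist_state(self):
        trace = ft.gen_twist_trace(ft.preset_schedule("adp1", seed=11))
        segments = ft.detect_states(trace)
        assert len(segments) == 1
        mean, sigma = fit_state_gaussian(trace, segments[0])
        assert mean == pytest.approx(0.5, abs=3 * 1.0 / np.sqrt(1000))


class TestClusterStateMeans:
    def test_recovers_four_tight_modes(self):
        rng = np.random.default_rng(2)
        means = np.concatenate(
            [rng.normal(mu, 0.2, 15) for mu in (0.0, 5.0, 10.0, 12.5)]
        )
        catalog = make_catalog(means)
        clustered = cluster_state_means(catalog, n_clusters=4, seed=0)
        np.testing.assert_allclose(
            clustered.centroids, [0.0, 5.0, 10.0, 12.5], atol=0.5
        )
        # labels renumbered ascending: lowest-twist cluster is label 0
        assert clustered.labels[0] == 0 and clustered.labels[-1] == 3

    def test_identical_means_flagged_as_degenerate(self):
        catalog = make_catalog([3.0] * 6)
        with pytest.raises(ValueError, match="degenerate"):
            cluster_state_means(catalog, n_clusters=4, seed=0)

    def test_fewer_entries_than_clusters(self):
        with pytest.raises(ValueError, match="cannot form"):
            cluster_state_means(make_catalog([1.0, 2.0]), n_clusters=4)

    def test_small_catalogs_match_exhaustive_partition(self):
        # In 1D the optimal k-means partition is contiguous on sorted values,
        # so enumerating all contiguous 4-way splits of <= 12 entries is an
        # exhaustive oracle for the minimum-inertia assignment.
        rng = np.random.default_rng(3)
        for rep in range(10):
            means = np.sort(
                np.concatenate(
                    [rng.normal(mu, 0.3, 3) for mu in (0.0, 5.0, 10.0, 12.5)]
                )
            )
            best_inertia, best_labels = np.inf, None
            n = means.size
            for splits in itertools.combinations(range(1, n), 3):
                bounds = [0, *splits, n]
                inertia, labels = 0.0, np.empty(n, dtype=int)
                for lab, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
                    chunk = means[a:b]
                    inertia += ((chunk - chunk.mean()) ** 2).sum()
                    labels[a:b] = lab
                if inertia < best_inertia:
                    best_inertia, best_labels = inertia, labels
            clustered = cluster_state_means(make_catalog(means), 4, seed=rep)
            np.testing.assert_array_equal(clustered.labels, best_labels)


class TestSelectNClusters:
    def test_two_well_separated_levels(self):
        rng = np.random.default_rng(4)
        means = np.concatenate([rng.normal(0, 0.3, 10), rng.normal(10, 0.3, 10)])
        assert select_n_clusters(make_catalog(means), seed=0) == 2

    def test_paper_modes_catalog_selects_four(self, paper_modes_catalog):
        assert select_n_clusters(paper_modes_catalog, seed=0) == 4

    def test_single_blob_warns_and_returns_smallest_k(self):
        rng = np.random.default_rng(5)
        catalog = make_catalog(rng.normal(5.0, 1.0, 40))
        with pytest.warns(UserWarning, match="weak cluster structure"):
            assert select_n_clusters(catalog, seed=0) == 2

    def test_insufficient_entries(self):
        with pytest.raises(ValueError, match="too few"):
            select_n_clusters(make_catalog([1.0, 2.0, 3.0]), seed=0)


class TestModeHistogram:
    def test_single_state_single_bin(self):
        counts, edges = mode_histogram(make_catalog([5.2]), bin_width=0.5)
        assert counts.sum() == 1

    def test_occupancy_weighting_ratio(self):
        catalog = make_catalog([0.0, 10.0], lifetimes=[900.0, 100.0])
        counts, _ = mode_histogram(catalog, bin_width=0.5, weighted=True)
        occupied = counts[counts > 0]
        assert occupied.tolist() == [900.0, 100.0]

    def test_mass_conservation(self, paper_modes_catalog):
        counts, _ = mode_histogram(paper_modes_catalog, bin_width=0.5)
        assert counts.sum() == len(paper_modes_catalog)
        wcounts, _ = mode_histogram(paper_modes_catalog, bin_width=0.5, weighted=True)
        assert wcounts.sum() == pytest.approx(
            paper_modes_catalog.lifetimes_ns.sum()
        )

    def test_paper_modes_histogram_has_four_local_maxima(self, paper_modes_catalog):
        counts, edges = mode_histogram(paper_modes_catalog, bin_width=0.5)
        centers = 0.5 * (edges[:-1] + edges[1:])
        occupied = centers[counts > 0]
        for mode in (0.0, 5.0, 10.0, 12.5):
            assert np.any(np.abs(occupied - mode) < 0.5)

    def test_invalid_bin_width(self):
        with pytest.raises(ValueError, match="bin_width"):
            mode_histogram(make_catalog([1.0]), bin_width=0.0)


class TestTwistModulus:
    def test_unit_case_exact(self):
        # sigma = 1 rad, l = 5 nm: K = 5 kBT nm exactly
        est = twist_modulus(sigma=np.degrees(1.0), monomer_length=5.0)
        assert est.K_kT_nm == pytest.approx(5.0, rel=1e-12)

    def test_inverse_square_scaling(self):
        k1 = twist_modulus(sigma=2.0).K_kT_nm
        k2 = twist_modulus(sigma=1.0).K_kT_nm
        assert k2 == pytest.approx(4 * k1, rel=1e-12)

    def test_pn_nm2_units(self):
        est = twist_modulus(sigma=np.degrees(1.0), temperature=310.0)
        kbt_pn_nm = BOLTZMANN_J_PER_K * 310.0 * 1e21
        assert est.K_pN_nm2 == pytest.approx(5.0 * kbt_pn_nm, rel=1e-12)
        assert est.K_pN_nm2 == pytest.approx(21.4, abs=0.05)

    def test_recovery_from_synthetic_state(self):
        rng = np.random.default_rng(6)
        sigma_gen = 2.0
        x = rng.normal(0.0, sigma_gen, 10_000)
        est = twist_modulus(sigma=float(x.std()), temperature=310.0)
        expected = 5.0 / np.radians(sigma_gen) ** 2
        assert est.K_kT_nm == pytest.approx(expected, rel=0.05)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError, match="sigma"):
            twist_modulus(sigma=0.0)

    def test_slow_drift_inflates_sigma_and_deflates_K(self):
        # A linear drift within a state is indistinguishable from extra
        # fluctuation: fitted sigma rises and the modulus is underestimated.
        rng = np.random.default_rng(7)
        n = 5000
        base = rng.normal(0.0, 1.0, n)
        drift = np.linspace(0.0, 2.0, n)
        k_flat = twist_modulus(sigma=float(base.std())).K_kT_nm
        k_drift = twist_modulus(sigma=float((base + drift).std())).K_kT_nm
        assert (base + drift).std() > base.std()
        assert k_drift < k_flat


class TestTwistBendCorrelation:
    def _traces(self, twist, bend):
        n = len(twist)
        t = np.arange(n, dtype=float)
        return (
            ft.TwistTrace(time=t, twist=np.asarray(twist)),
            ft.BendTrace(time=t, in_plane=np.zeros(n), out_of_plane=np.asarray(bend)),
        )

    def test_injected_negative_coupling_recovered(self):
        rng = np.random.default_rng(8)
        n = 2000
        twist = rng.normal(5.0, 2.0, n)
        noise = rng.normal(0.0, 1.0, n)
        bend = -0.3 * twist + noise
        rho = -0.3 * 2.0 / np.sqrt((0.3 * 2.0) ** 2 + 1.0)
        r, sign = twist_bend_correlation(*self._traces(twist, bend))
        assert sign == -1
        assert abs(r - rho) < 3 * (1 - rho**2) / np.sqrt(n)

    def test_independent_traces_near_zero(self):
        hits = 0
        n = 1000
        for seed in range(40):
            rng = np.random.default_rng(100 + seed)
            r, _ = twist_bend_correlation(
                *self._traces(rng.normal(0, 1, n), rng.normal(0, 1, n))
            )
            hits += abs(r) < 3 / np.sqrt(n)
        assert hits >= 36  # >= 90% of 40 within the 3-SE null band

    def test_perfect_correlation(self):
        x = np.random.default_rng(9).normal(0, 1, 100)
        r, sign = twist_bend_correlation(*self._traces(x, x))
        assert r == pytest.approx(1.0) and sign == 1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            twist_bend_correlation(*self._traces(np.zeros(50), np.arange(50.0)))


class TestModulusRecoveryInvariant:
    def test_median_relative_error_below_five_percent(self):
        # K = kB T l / sigma^2 across generating sigmas 1/2/4 deg, n = 1e4.
        for sigma_gen in (1.0, 2.0, 4.0):
            errors = []
            expected = 5.0 / np.radians(sigma_gen) ** 2
            for rep in range(200):
                rng = np.random.default_rng(rep * 3 + int(sigma_gen))
                x = rng.normal(0.0, sigma_gen, 10_000)
                est = twist_modulus(sigma=float(x.std()))
                errors.append(abs(est.K_kT_nm - expected) / expected)
            assert np.median(errors) < 0.05
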