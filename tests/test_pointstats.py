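"""Spacing/order estimators: closed-form limits, lattice identities,
oracle agreement, symmetry invariances, ordering of min vs average
spacing measures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import glycomesh as gm
from glycomesh.datatypes import TerminiPattern
from glycomesh.exceptions import (
    EmptyResultError,
    InsufficientDataError,
    ParameterError,
    ResolutionError,
)

from conftest import brute_force_pair_histogram


def _pattern(points, pad=50.0):
    pts = np.asarray(points, dtype=float)
    lo, hi = pts.min(axis=0) - pad, pts.max(axis=0) + pad
    return TerminiPattern(points=pts, extent=np.column_stack([lo, hi]))


class TestNearestNeighbor:
    def test_three_collinear_points(self):
        pat = _pattern([[0.0, 0.0], [40.0, 0.0], [80.0, 0.0]])
        res = gm.nearest_neighbor_stats(pat, edge_buffer=0.0)
        assert np.allclose(sorted(res.nn_distances), [40.0, 40.0, 40.0])
        assert res.mean == pytest.approx(40.0)

    def test_perfect_lattice_point_mass(self):
        pat = gm.generate_termini_pattern(
            "hexagonal", 31.0, 0.0, ((0, 600), (0, 600)), seed=1
        )
        res = gm.nearest_neighbor_stats(pat, edge_buffer=0.0)
        assert res.mean == pytest.approx(31.0, abs=1e-9)
        assert res.sd == pytest.approx(0.0, abs=1e-9)

    def test_csr_mean_matches_poisson_closed_form(self):
        lam = 0.001  # points / nm^2
        ext = ((0.0, 1500.0), (0.0, 1500.0))
        pat = gm.generate_csr_pattern(lam, ext, seed=5)
        buffer = 3.0 / np.sqrt(lam)
        res = gm.nearest_neighbor_stats(pat, edge_buffer=buffer)
        expected = 1.0 / (2.0 * np.sqrt(lam))
        sem = res.sd / np.sqrt(res.n)
        assert abs(res.mean - expected) <= 3 * sem

    def test_all_points_excluded_raises(self):
        pat = _pattern([[0.0, 0.0], [10.0, 0.0]], pad=5.0)
        with pytest.raises(EmptyResultError):
            gm.nearest_neighbor_stats(pat, edge_buffer=1000.0)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(
        angle=st.floats(0.0, 2 * np.pi, allow_nan=False),
        tx=st.floats(-500.0, 500.0),
        ty=st.floats(-500.0, 500.0),
    )
    def test_rigid_motion_invariance(self, angle, tx, ty):
        rng = np.random.default_rng(12)
        pts = rng.uniform(0, 400, size=(80, 2))
        rot = np.array(
            [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
        )
        moved = pts @ rot.T + [tx, ty]
        r0 = gm.nearest_neighbor_stats(_pattern(pts), edge_buffer=0.0)
        r1 = gm.nearest_neighbor_stats(_pattern(moved), edge_buffer=0.0)
        assert r1.mean == pytest.approx(r0.mean, rel=1e-9)
        assert r1.sd == pytest.approx(r0.sd, rel=1e-9, abs=1e-9)


class TestRadialDistribution:
    def test_lattice_first_peak_at_lattice_constant(self):
        pat = gm.generate_termini_pattern(
            "hexagonal", 31.0, 0.0, ((0, 800), (0, 800)), seed=1
        )
        res = gm.radial_distribution(pat, bin_width=1.0, r_max=100.0)
        assert res.first_peak_r == pytest.approx(31.0, abs=0.5)

    def test_csr_normalization(self):
        pat = gm.generate_csr_pattern(0.001, ((0, 1500), (0, 1500)), seed=6)
        res = gm.radial_distribution(pat, bin_width=2.0, r_max=150.0)
        upper = res.g[len(res.g) // 2 :]
        assert 0.9 <= upper.mean() <= 1.1

    def test_jittered_lattice_peak_matches_pair_histogram_oracle(self):
        pat = gm.generate_termini_pattern(
            "liquid_crystal", 32.0, 4.0, ((0, 900), (0, 900)), seed=8
        )
        bw, rmax = 1.0, 60.0
        res = gm.radial_distribution(pat, bin_width=bw, r_max=rmax)
        edges = np.arange(0.0, rmax + bw, bw)
        counts = brute_force_pair_histogram(pat.points, edges)
        # compare against the peak of the raw pair histogram, ignoring the
        # shell-area trend over the narrow peak neighborhood
        centers = 0.5 * (edges[:-1] + edges[1:])
        sel = centers > 10
        oracle_peak = centers[sel][np.argmax(counts[sel] / centers[sel])]
        assert abs(res.first_peak_r - oracle_peak) <= 2 * bw

    def test_parameter_preconditions(self):
        pat = gm.generate_csr_pattern(0.001, ((0, 800), (0, 800)), seed=1)
        with pytest.raises(ParameterError):
            gm.radial_distribution(pat, bin_width=20.0, r_max=100.0)
        with pytest.raises(ParameterError):
            gm.radial_distribution(pat, bin_width=1.0, r_max=600.0)

    def test_too_few_interior_points(self):
        pat = gm.generate_csr_pattern(0.0002, ((0, 450), (0, 450)), seed=2)
        with pytest.raises(InsufficientDataError):
            gm.radial_distribution(pat, bin_width=5.0, r_max=200.0)


class TestAutocorrelation:
    def test_lattice_offpeak_at_lattice_constant(self):
        pat = gm.generate_termini_pattern(
            "hexagonal", 31.0, 0.0, ((0, 800), (0, 800)), seed=1
        )
        res = gm.autocorrelation_spacing(pat, render_px=1.0)
        assert res.first_offpeak_r == pytest.approx(31.0, abs=1.0)

    def test_agrees_with_rdf_on_same_pattern(self):
        # large enough that both estimators resolve a single first peak
        pat = gm.generate_termini_pattern(
            "hexagonal", 35.0, 3.0, ((0, 1600), (0, 1600)), seed=4
        )
        rdf = gm.radial_distribution(pat, bin_width=1.0, r_max=80.0)
        ac = gm.autocorrelation_spacing(pat, render_px=1.0)
        assert abs(ac.first_offpeak_r - rdf.first_peak_r) <= 2.0

    def test_single_point_flagged(self):
        pat = _pattern([[100.0, 100.0]])
        res = gm.autocorrelation_spacing(pat, render_px=1.0)
        assert np.isnan(res.first_offpeak_r)
        assert res.warnings

    def test_zero_lag_is_global_maximum(self, lc_pattern):
        res = gm.autocorrelation_spacing(lc_pattern, render_px=1.0)
        assert np.argmax(res.profile) == 0

    def test_render_too_coarse_rejected(self, lc_pattern):
        with pytest.raises(ResolutionError):
            gm.autocorrelation_spacing(lc_pattern, render_px=20.0)


class TestHexagonalOrder:
    def test_perfect_lattice_psi6_is_one(self):
        pat = gm.generate_termini_pattern(
            "hexagonal", 31.0, 0.0, ((0, 700), (0, 700)), seed=1
        )
        res = gm.hexagonal_order(pat)
        assert res.psi6 == pytest.approx(1.0, abs=1e-6)
        assert res.regime_call == "hexagonal"
        assert res.fft_sixfold_ratio > 2.0

    def test_csr_psi6_small_across_simulations(self):
        # the CSR null: psi6 stays low for every replicate
        vals = []
        for seed in range(100):
            pat = gm.generate_csr_pattern(0.002, ((0, 1000), (0, 1000)), seed=seed)
            vals.append(gm.hexagonal_order(pat).psi6)
        assert np.quantile(vals, 0.99) < 0.25

    def test_rotation_invariance(self):
        pat = gm.generate_termini_pattern(
            "hexagonal", 31.0, 0.0, ((0, 700), (0, 700)), seed=1
        )
        angle = 0.7
        rot = np.array(
            [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
        )
        moved = pat.points @ rot.T
        lo, hi = moved.min(0) - 10, moved.max(0) + 10
        pat2 = TerminiPattern(points=moved, extent=np.column_stack([lo, hi]))
        r1 = gm.hexagonal_order(pat)
        r2 = gm.hexagonal_order(pat2)
        assert r2.psi6 == pytest.approx(r1.psi6, abs=1e-6)

    def test_psi6_monotone_in_jitter(self):
        # jitter ladder 0 -> 0.3a, psi6 regression slope < 0 over 10 seeds
        ratios = [0.0, 0.05, 0.1, 0.15, 0.2, 0.3]
        means = []
        for rho in ratios:
            vals = []
            for seed in range(10):
                pat = gm.generate_termini_pattern(
                    "liquid_crystal" if rho > 0.1 else "hexagonal",
                    32.0,
                    rho * 32.0,
                    ((0, 900), (0, 900)),
                    seed=seed,
                )
                vals.append(gm.hexagonal_order(pat).psi6)
            means.append(np.mean(vals))
        slope = np.polyfit(ratios, means, 1)[0]
        assert slope < 0
        assert all(a >= b - 0.02 for a, b in zip(means, means[1:]))

    def test_regime_calls_match_generator_regimes(self):
        hexa = gm.generate_termini_pattern(
            "hexagonal", 32.0, 1.0, ((0, 900), (0, 900)), seed=3
        )
        lc = gm.generate_termini_pattern(
            "liquid_crystal", 32.0, 4.0, ((0, 900), (0, 900)), seed=3
        )
        liq = gm.generate_termini_pattern(
            "liquid", 32.0, 0.0, ((0, 900), (0, 900)), seed=3
        )
        assert gm.hexagonal_order(hexa).regime_call == "hexagonal"
        assert gm.hexagonal_order(lc).regime_call == "liquid_crystal"
        assert gm.hexagonal_order(liq).regime_call == "liquid"


class TestMinVsAverageOrdering:
    def test_nn_mean_below_rdf_and_autocorrelation_peaks(self):
        """The three spacing measures disagree in a fixed order: per-point
        minimum (NN) <= average-spacing measures (RDF peak, autocorrelation
        peak), on jittered-lattice patterns spanning the hexagonal,
        liquid-crystalline and liquid psi6 regimes."""
        cases = []
        for seed in range(7):
            cases.append(("hexagonal", 2.5, seed))  # psi6 ~ hexagonal
            cases.append(("liquid_crystal", 4.0, seed))  # psi6 ~ lc band
            cases.append(("liquid_crystal", 8.0, seed))  # psi6 ~ liquid band
        assert len(cases) >= 20
        tol = 1.5  # bin/render quantization slack, nm
        for regime, jitter, seed in cases:
            pat = gm.generate_termini_pattern(
                regime, 32.0, jitter, ((0, 900), (0, 900)), seed=seed
            )
            nn = gm.nearest_neighbor_stats(pat, edge_buffer=40.0).mean
            rdf = gm.radial_distribution(pat, bin_width=1.0, r_max=80.0).first_peak_r
            ac = gm.autocorrelation_spacing(pat, render_px=1.0).first_offpeak_r
            assert nn <= rdf + tol, (regime, seed, nn, rdf)
            assert nn <= ac + tol, (regime, seed, nn, ac)

    def test_hard_core_liquid_rdf_first_peak_is_contact_peak(self):
        """For a dense hard-core (Matern II) liquid the first g(r) maximum
        is the contact peak, which sits at the hard-core distance *below*
        the mean NN spacing — the one regime where the min-vs-average
        ordering genuinely inverts."""
        pat = gm.generate_termini_pattern(
            "liquid", 32.0, 0.0, ((0, 1200), (0, 1200)), seed=0
        )
        d_hc = pat.meta["hard_core_diameter"]
        rdf = gm.radial_distribution(pat, bin_width=1.0, r_max=80.0)
        nn = gm.nearest_neighbor_stats(pat, edge_buffer=40.0)
        assert d_hc - 1.5 <= rdf.first_peak_r <= nn.mean
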