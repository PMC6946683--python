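"""Morphometry estimators against designed geometries, stored ground truth
and sampling-distribution bounds."""

import numpy as np
import pytest
import glycomesh as gm
from glycomesh.datatypes import CoatedCrossSection, TerminiPattern
from glycomesh.exceptions import (
    CoatingModelError,
    EmptyResultError,
    GroupingError,
    TopologyError,
)
from glycomesh.morphometry import opening_diameters, pore_sizes


def _grid_image(spacing=40, n_cells=8, px_width=1):
    """Square grid of zero-diameter (1 px) filaments."""
    size = spacing * n_cells + 1
    img = np.zeros((size, size), dtype=bool)
    for k in range(0, size, spacing):
        img[k : k + px_width, :] = True
        img[:, k : k + px_width] = True
    return img


class TestPoreSizes:
    def test_grid_openings_match_brute_force_polygon_oracle(self):
        img = _grid_image(spacing=40)
        diam = opening_diameters(img, pixel_size=1.0)
        assert len(diam) == 64
        # brute-force all-pairs oracle on each opening's pixels
        from scipy import ndimage

        void = ~img
        labels, n = ndimage.label(
            void, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        )
        border = set(
            np.concatenate(
                [labels[0], labels[-1], labels[:, 0], labels[:, -1]]
            ).tolist()
        ) - {0}
        oracle = []
        for lab in range(1, n + 1):
            if lab in border:
                continue
            ys, xs = np.nonzero(labels == lab)
            pts = np.column_stack([ys, xs]).astype(float)
            d2 = ((pts[:, None] - pts[None]) ** 2).sum(-1)
            oracle.append(np.sqrt(d2.max()) + 1.0)
        assert len(oracle) == len(diam)
        assert np.allclose(np.sort(diam), np.sort(oracle), rtol=0.01)

    def test_grid_opening_diagonal_value(self):
        s = 40
        img = _grid_image(spacing=s)
        diam = opening_diameters(img, pixel_size=1.0)
        # continuous geometry: diagonal of an s x s opening
        assert np.allclose(diam, s * np.sqrt(2), atol=2 * np.sqrt(2))

    def test_thick_filament_grid_measures_surface_to_surface(self):
        # axes s apart, diameter d: the surface-to-surface cell is
        # (s - d) x (s - d), so the caliper is (s - d) * sqrt(2)
        s, d = 40, 7
        size = s * 4 + d
        img = np.zeros((size, size), dtype=bool)
        for k in range(0, size, s):
            img[k : k + d, :] = True
            img[:, k : k + d] = True
        diam = opening_diameters(img, pixel_size=1.0)
        assert len(diam) == 16
        assert np.allclose(diam, (s - d) * np.sqrt(2), atol=2 * np.sqrt(2))

    def test_no_openings_raises_topology_error(self):
        img = np.ones((50, 50), dtype=bool)
        with pytest.raises(TopologyError):
            pore_sizes(img, n_openings=10, seed=0)

    def test_sampling_determinism(self, small_network):
        a = pore_sizes(small_network, n_openings=25, seed=4)
        b = pore_sizes(small_network, n_openings=25, seed=4)
        assert np.array_equal(a.samples, b.samples)


class TestFilamentDiameters:
    def test_coating_arithmetic(self):
        secs = [CoatedCrossSection(np.nan, 2.0, 9.3)]
        res = gm.filament_diameters(secs, coating_thickness=2.0)
        assert res.mean == pytest.approx(5.3)

    def test_zero_coating_identity(self):
        secs = [CoatedCrossSection(np.nan, 0.0, 5.3)]
        res = gm.filament_diameters(secs, coating_thickness=0.0)
        assert res.mean == pytest.approx(5.3)

    def test_coating_model_error_when_cores_impossible(self):
        secs = [CoatedCrossSection(np.nan, 2.0, 3.0) for _ in range(10)]
        with pytest.raises(CoatingModelError):
            gm.filament_diameters(secs, coating_thickness=2.0)

    def test_round_trip_inverts_rasterized_coating(self):
        """Rasterize known cores with a coating, measure, correct: the
        recovered core mean must sit within one voxel of the ground truth."""
        from glycomesh.datatypes import Filament, GlycocalyxNetwork

        rng = np.random.default_rng(13)
        cores = np.clip(rng.normal(5.3, 1.3, size=12), 2.0, None)
        vols = []
        for c in cores:
            nodes = np.array([[15.0, 15.0, 0.0], [15.0, 15.0, 20.0]])
            net = GlycocalyxNetwork(
                anchors=nodes[:1],
                per_tip_counts=np.array([1]),
                filaments=[Filament(nodes, 0, 0, float(c))],
                contacts=[],
                termini_points=nodes[-1:],
                termini_diameters=np.array([10.0]),
                extent=np.array([[0, 30], [0, 30], [-1, 21]]),
            )
            vols.append(
                gm.rasterize_network(
                    net, 0.5, coating_thickness=2.0,
                    bbox=np.array([[0.0, 30.0], [0.0, 30.0], [5.0, 15.0]]),
                )
            )
        res = gm.filament_diameters(vols, coating_thickness=2.0)
        assert abs(res.mean - cores.mean()) <= 0.5


class TestLayerThickness:
    def test_constant_thickness_network(self):
        params = gm.GeneratorParams(layer_thickness_sd=0.0, terminal_plane_sd=0.0)
        net = gm.generate_network(params, seed=2, n_tips=20)
        res = gm.layer_thickness(net, n_profiles=20, seed=0)
        assert np.allclose(res.samples, 1000.0, atol=1e-6)

    def test_sample_sd_within_chi_square_band(self):
        params = gm.GeneratorParams(layer_thickness_sd=100.0)
        net = gm.generate_network(params, seed=6, n_tips=60)
        res = gm.layer_thickness(net, n_profiles=53, seed=1)
        assert abs(res.sd - 100.0) <= 40.0

    def test_mean_recovery(self, small_network):
        res = gm.layer_thickness(small_network, n_profiles=53, seed=0)
        sem = 100.0 / np.sqrt(53)
        assert abs(res.mean - 1000.0) <= 2 * sem + 3 * small_network.params.terminal_plane_sd


class TestFilamentsPerTip:
    def test_uniform_counts(self):
        pts = np.array([[10.0 * i, 5.0 * j] for i in range(10) for j in range(7)])
        pat = TerminiPattern(
            points=pts,
            extent=np.array([[-5.0, 105.0], [-5.0, 40.0]]),
            tip_ids=np.repeat(np.arange(10), 7),
        )
        res = gm.filaments_per_tip(pat)
        assert res.mean == pytest.approx(7.0)
        assert res.sd == pytest.approx(0.0)

    def test_missing_tip_ids_raises(self):
        pat = TerminiPattern(
            points=np.array([[0.0, 0.0], [10.0, 10.0]]),
            extent=np.array([[-5.0, 15.0], [-5.0, 15.0]]),
        )
        with pytest.raises(GroupingError):
            gm.filaments_per_tip(pat)

    def test_undercount_monotone_in_merge_fraction(self):
        """Resolution-limited counts can only fall as filaments merge."""
        fractions = [0.0, 0.1, 0.2, 0.3, 0.4]
        means = {f: [] for f in fractions}
        for seed in range(10):
            for f in fractions:
                params = gm.GeneratorParams(merge_fraction=f)
                net = gm.generate_network(params, seed=seed, n_tips=16)
                z = net.terminal_plane_z - 40.0
                sec = gm.cross_section(net, z)
                res = gm.filaments_per_tip(sec, dedup_tolerance=0.5)
                means[f].append(res.mean)
                # undercount property: measured <= generated, per tip
                stored = net.per_tip_counts.sum()
                assert res.samples.sum() <= stored + 1e-9
        ladder = [np.mean(means[f]) for f in fractions]
        slope = np.polyfit(fractions, ladder, 1)[0]
        assert slope < 0


class TestTipDiameters:
    def test_constant_diameters(self):
        params = gm.GeneratorParams(tip_diameter_sd=0.0)
        net = gm.generate_network(params, seed=2, n_tips=20)
        res = gm.tip_diameters(net, n=50, seed=0)
        assert res.mean == pytest.approx(10.2)
        assert res.sd == pytest.approx(0.0)

    def test_zero_n_raises(self, small_network):
        with pytest.raises(EmptyResultError):
            gm.tip_diameters(small_network, n=0, seed=0)

    def test_sd_uses_n_minus_one(self):
        res = gm.MorphometryResult.from_samples("tip_diameter", [1.0, 2.0, 3.0])
        assert res.sd == pytest.approx(1.0)


class TestRigidInvariance:
    def test_pore_sizes_invariant_under_network_translation(self, small_network):
        import copy

        net2 = copy.deepcopy(small_network)
        shift = np.array([37.0, -12.0, 0.0])
        net2.anchors = net2.anchors + shift
        net2.termini_points = net2.termini_points + shift
        for f in net2.filaments:
            f.nodes = f.nodes + shift
        net2.extent = net2.extent + shift[:, None]
        a = pore_sizes(small_network, n_openings=None, seed=0)
        b = pore_sizes(net2, n_openings=None, seed=0)
        assert b.mean == pytest.approx(a.mean, rel=0.1)
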