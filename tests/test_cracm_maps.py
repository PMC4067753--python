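"""Circuit-mapping geometry, spatial statistics, and worked examples."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nigranet.cracm_maps import (
    DendriteSkeleton,
    SN_ASPECT,
    align_grid,
    axon_overlay_correlation,
    com_dendrite,
    com_map,
    com_points,
    conduction_velocity,
    convergence_radius,
    estimate_n_inputs,
    frame_raster,
    isocontour,
    map_correlation_vs_distance,
    smooth_map,
    spatial_falloff,
)
from nigranet.errors import (
    AnnotationError,
    InsufficientDataError,
    InvalidSpecError,
    ResampleRequiredError,
)
from nigranet.synth_data import GridGenSpec, gen_cracm_dataset, gen_stim_grid


class TestAlignGrid:
    def test_identity_on_reference(self):
        g = gen_stim_grid(GridGenSpec())
        aligned, tf = align_grid(g)
        assert np.allclose(aligned.sites, g.sites, atol=1e-9)
        assert np.allclose(tf.matrix, np.eye(2), atol=1e-12)

    def test_rotation_round_trip(self):
        ref, _ = align_grid(gen_stim_grid(GridGenSpec(seed=1)))
        rot, _ = align_grid(gen_stim_grid(GridGenSpec(rotation=90.0, seed=1)))
        assert np.allclose(ref.sites, rot.sites, atol=1e-6)

    def test_aspect_stretch_factor(self):
        g = gen_stim_grid(GridGenSpec(aspect=1.5))
        aligned, tf = align_grid(g)
        width = np.ptp(aligned.sites[:, 0])
        height = np.ptp(aligned.sites[:, 1])
        assert width / height == pytest.approx(SN_ASPECT, rel=1e-9)
        assert tf.matrix[0, 0] == pytest.approx(1.67 / 1.5, rel=1e-6)

    def test_idempotent(self):
        g = gen_stim_grid(GridGenSpec(rotation=33.0, aspect=1.4, seed=2))
        a1, _ = align_grid(g)
        a2, _ = align_grid(a1)
        assert np.allclose(a1.sites, a2.sites, atol=1e-9)

    def test_parallel_annotations_rejected(self):
        g = gen_stim_grid(GridGenSpec())
        g.medial_edge = list(g.dorsal_edge)
        with pytest.raises(AnnotationError):
            align_grid(g)

    def test_com_commutes_with_transform(self, rng):
        g = gen_stim_grid(GridGenSpec(rotation=25.0, seed=3))
        amps = rng.uniform(0, 10, g.sites.shape[0])
        aligned, tf = align_grid(g)
        before = tf.apply(com_points(g.sites, amps))
        after = com_points(aligned.sites, amps)
        assert np.allclose(before, after, atol=1e-6)


class TestSmoothAndContours:
    def _gaussian_image(self, sigma=150.0, center=(800.0, 500.0), amp=1.0):
        x, y = frame_raster()
        xx, yy = np.meshgrid(x, y)
        return amp * np.exp(-((xx - center[0]) ** 2 + (yy - center[1]) ** 2)
                            / (2 * sigma ** 2))

    def test_halfmax_contour_radius(self):
        img = self._gaussian_image(sigma=150.0)
        (poly,) = isocontour(img, 0.5)
        radii = np.linalg.norm(poly - [800.0, 500.0], axis=1)
        assert radii.mean() == pytest.approx(
            150.0 * np.sqrt(2 * np.log(2)), rel=0.02)

    def test_contour_nesting(self):
        img = self._gaussian_image(sigma=150.0)
        (inner,) = isocontour(img, 0.8)
        (outer,) = isocontour(img, 0.3)
        r_in = np.linalg.norm(inner - [800.0, 500.0], axis=1).max()
        r_out = np.linalg.norm(outer - [800.0, 500.0], axis=1).min()
        assert r_in < r_out

    def test_two_blobs_two_polygons(self):
        img = (self._gaussian_image(120.0, (400.0, 500.0))
               + self._gaussian_image(120.0, (1300.0, 500.0)))
        polys = isocontour(img, 0.5)
        assert len(polys) == 2

    def test_empty_image_rejected(self):
        with pytest.raises(InvalidSpecError):
            isocontour(np.zeros((101, 168)), 0.5)

    def test_smooth_map_peak_and_integral(self):
        spec = GridGenSpec(noise_sd=0.0)
        grid, maps = gen_cracm_dataset(spec, 1,
                                       soma_positions=[(835.0, 500.0)])
        aligned, _ = align_grid(grid)
        # single-site map: zero out all but the strongest site
        amps = np.zeros_like(maps[0].amplitudes)
        k = int(np.argmax(maps[0].amplitudes))
        amps[k] = 50.0
        maps[0].amplitudes = amps
        img = smooth_map(aligned, maps[0], sigma=60.0)
        # the site sits up to half a raster pixel off the image lattice
        assert img.max() == pytest.approx(50.0, rel=5e-3)
        integral = img.sum() * 10.0 * 10.0
        assert integral == pytest.approx(50.0 * 2 * np.pi * 60.0 ** 2,
                                         rel=0.005)


class TestCOM:
    def test_single_site(self):
        assert np.allclose(com_points([[100.0, 200.0]], [5.0]),
                           [100.0, 200.0])

    def test_two_equal_sites_midpoint(self):
        assert np.allclose(
            com_points([[0.0, 0.0], [100.0, 0.0]], [3.0, 3.0]), [50.0, 0.0])

    def test_dendrite_segments(self):
        # one straight segment -> its midpoint; symmetric pair -> origin
        sk = DendriteSkeleton(nodes=[[0, 0], [100, 0]], edges=[[0, 1]],
                              widths=[2.0])
        assert np.allclose(com_dendrite(sk), [50.0, 0.0])
        sk2 = DendriteSkeleton(
            nodes=[[-100, -50], [0, 0], [100, 50]],
            edges=[[0, 1], [1, 2]], widths=[1.5, 1.5])
        assert np.allclose(com_dendrite(sk2), [0.0, 0.0])

    def test_dendrite_matches_discretization_oracle(self, rng):
        nodes = rng.uniform(0, 1000, (6, 2))
        edges = [[i, i + 1] for i in range(5)]
        widths = rng.uniform(0.5, 3.0, 5)
        sk = DendriteSkeleton(nodes=nodes, edges=edges, widths=widths)
        # brute force: sample each segment at 1 um steps
        pts, ws = [], []
        for (a, b), w in zip(edges, widths):
            pa, pb = nodes[a], nodes[b]
            L = np.linalg.norm(pb - pa)
            n = max(int(L), 2)
            for f in (np.arange(n) + 0.5) / n:
                pts.append(pa + f * (pb - pa))
                ws.append(w * L / n)
        oracle = com_points(pts, ws)
        assert np.linalg.norm(com_dendrite(sk) - oracle) < 1.0


class TestMapCorrelation:
    def test_identical_and_negated(self):
        spec = GridGenSpec(noise_sd=0.5, seed=1)
        _, maps = gen_cracm_dataset(spec, 2,
                                    soma_positions=[(800, 500), (810, 500)],
                                    field_centers=[(800, 500), (800, 500)])
        out = map_correlation_vs_distance(maps, fit=False)
        assert out["r"][0] > 0.95

    def test_length_scale_recovery(self):
        """Fitted exponential scale tracks the analytic Gaussian-overlap
        oracle computed at the same soma geometry."""
        from scipy.optimize import curve_fit
        sigma = 150.0
        xs = np.linspace(200.0, 1400.0, 8)
        somas = [(x, 500.0) for x in xs]
        rs_all, ds_all = [], []
        for seed in range(10):
            spec = GridGenSpec(field_sigma=sigma, noise_sd=2.0, seed=seed)
            _, maps = gen_cracm_dataset(spec, len(somas),
                                        soma_positions=somas)
            out = map_correlation_vs_distance(maps, fit=False)
            rs_all.append(out["r"])
            ds_all.append(out["distance"])
        d = np.concatenate(ds_all)
        r = np.concatenate(rs_all)

        def expfn(x, a, lam, c):
            return a * np.exp(-x / lam) + c

        lam_fit = curve_fit(expfn, d, r, p0=[1, 300, 0], maxfev=20000)[0][1]
        # oracle: noiseless correlation of two offset Gaussians
        r_true = np.exp(-d ** 2 / (4 * sigma ** 2))
        lam_true = curve_fit(expfn, d, r_true, p0=[1, 300, 0],
                             maxfev=20000)[0][1]
        assert lam_fit == pytest.approx(lam_true, rel=0.25)


class TestAxonOverlay:
    def test_identical_images(self):
        img = np.random.default_rng(0).random((101, 168))
        d, r = axon_overlay_correlation(img, img, (0, 0), (500, 500))
        assert r == pytest.approx(1.0)
        assert d == pytest.approx(np.hypot(500, 500))

    def test_independent_images(self, rng):
        a = rng.random((101, 168))
        b = rng.random((101, 168))
        _, r = axon_overlay_correlation(a, b, (0, 0), (0, 0))
        assert abs(r) < 0.05

    def test_raster_mismatch(self):
        with pytest.raises(ResampleRequiredError):
            axon_overlay_correlation(np.zeros((10, 10)), np.zeros((20, 20)),
                                     (0, 0), (0, 0))


class TestSpatialFalloff:
    def test_all_at_focus(self):
        pos = [[0, 0], [0, 0], [0, 0], [500, 0]]
        amp = [5, 5, 5, 0.0]
        # zero-amplitude distant site cannot shift the half-response point
        _, _, half = spatial_falloff(amp, pos, (0, 0))
        assert half == 0.0

    def test_uniform_ring(self):
        th = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        pos = np.column_stack([300 * np.cos(th), 300 * np.sin(th)])
        _, _, half = spatial_falloff(np.ones(12), pos, (0.0, 0.0))
        assert half == pytest.approx(300.0)

    def test_matches_cumulative_oracle(self, rng):
        spec = GridGenSpec(noise_sd=0.0, seed=6)
        grid, maps = gen_cracm_dataset(spec, 1,
                                       soma_positions=[(700.0, 450.0)])
        aligned, _ = align_grid(grid)
        d, cum, half = spatial_falloff(maps[0].amplitudes, aligned.sites,
                                       (700.0, 450.0))
        dist = np.linalg.norm(aligned.sites - [700.0, 450.0], axis=1)
        order = np.argsort(dist)
        oracle = np.cumsum(maps[0].amplitudes[order])
        oracle /= oracle[-1]
        assert np.allclose(cum, oracle)
        assert half == dist[order][np.searchsorted(oracle, 0.5)]


class TestWorkedExamples:
    def test_convergent_input_count(self):
        exact, nearest = estimate_n_inputs(10_000.0, 150.0)
        assert exact == pytest.approx(66.7, abs=0.1)
        assert 50 <= exact <= 100
        assert estimate_n_inputs(150.0, 150.0)[0] == 1.0
        assert estimate_n_inputs(0.0, 150.0)[0] == 0.0

    def test_convergence_radius(self):
        r = convergence_radius(30_000 / 4.0, 0.01, 66.7)
        assert r == pytest.approx(597.0, abs=2.0)

    def test_radius_scaling_law(self):
        r1 = convergence_radius(7500, 0.01, 50)
        r2 = convergence_radius(7500, 0.01, 100)
        assert r2 / r1 == pytest.approx(2 ** (1 / 3))

    def test_velocity_conversion(self):
        d = np.array([0.0, 300.0, 600.0, 1000.0])
        slope, v = conduction_velocity(1.93 + 0.5 * d / 1e3, d)
        assert slope == pytest.approx(0.5)
        assert v == pytest.approx(2.0)
        _, v1 = conduction_velocity(1.0 + 1.0 * d / 1e3, d)
        assert v1 == pytest.approx(1.0)

    def test_velocity_noisy_regression(self, rng):
        d = np.linspace(0, 1500, 30)
        vs = []
        for _ in range(100):
            lat = 1.93 + 0.5 * d / 1e3 + rng.normal(0, 0.3, d.size)
            _, v = conduction_velocity(lat, d)
            vs.append(v)
        assert np.mean(vs) == pytest.approx(2.0, rel=0.10)

    def test_span_requirement(self):
        with pytest.raises(InsufficientDataError):
            conduction_velocity([1.0, 1.1, 1.2], [0.0, 100.0, 200.0])
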