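"""Phantom generators: tree combinatorics, rasterization volume, signal models."""

import numpy as np
import pytest
from scipy.integrate import quad

from perfusemri import (
    ImageVolume,
    PhantomSpec,
    generate_vessel_tree,
    rasterize_tree,
    simulate_dce,
    simulate_dwi,
    simulate_histology,
    simulate_t2_volume,
)
from perfusemri.morphometrics import network_summary, segment_metrics

from conftest import straight_vessel_graph


def spec(**kw) -> PhantomSpec:
    base = dict(
        grid_shape=(90, 70, 70),
        voxel_spacing_mm=(0.66, 0.66, 0.66),
        tree_depth=2,
        root_radius_mm=3.0,
        segment_length_mm=12.0,
        seed=0,
    )
    base.update(kw)
    return PhantomSpec(**base)


class TestGenerateVesselTree:
    def test_depth1_single_unperturbed_chord(self):
        g = generate_vessel_tree(spec(tree_depth=1, tortuosity_amplitude_mm=0.0))
        assert g.n_segments == 1
        assert len(g.terminal_nodes()) == 2
        assert segment_metrics(g.segments[0]).tortuosity == pytest.approx(1.0)

    def test_depth2_tree_combinatorics(self):
        g = generate_vessel_tree(spec(tree_depth=2, tortuosity_amplitude_mm=0.0))
        assert g.n_segments == 3
        degrees = g.degrees()
        assert sorted(degrees.values()) == [1, 1, 1, 3]
        assert len(g.branching_nodes()) == 1

    def test_deterministic_for_fixed_seed(self):
        a = generate_vessel_tree(spec(seed=7))
        b = generate_vessel_tree(spec(seed=7))
        assert a.n_segments == b.n_segments
        for sa, sb in zip(a.segments, b.segments):
            np.testing.assert_array_equal(sa.points, sb.points)
            np.testing.assert_array_equal(sa.radii_mm, sb.radii_mm)

    def test_true_tortuosity_matches_numerical_arc_length(self):
        # the generated half-sine bow must carry the analytic arc length of
        # the parametric curve (x, a*sin(pi*x/L)) to fine-sampling accuracy
        amplitude, gspec = 2.0, spec(tree_depth=1, tortuosity_amplitude_mm=2.0)
        g = generate_vessel_tree(gspec)
        seg = g.segments[0]
        L = seg.straight_length_mm
        arc, _ = quad(
            lambda s: np.hypot(1.0, amplitude * np.pi / L * np.cos(np.pi * s / L)), 0, L
        )
        assert segment_metrics(seg).tortuosity == pytest.approx(arc / L, abs=1e-3)

    def test_radii_taper_per_generation(self):
        g = generate_vessel_tree(spec(tree_depth=3, radius_decay=0.7))
        radii = sorted({float(s.radii_mm[0]) for s in g.segments}, reverse=True)
        np.testing.assert_allclose(radii, [3.0, 2.1, 1.47])

    def test_out_of_bounds_error_names_generation(self):
        with pytest.raises(ValueError, match="generation"):
            generate_vessel_tree(spec(grid_shape=(40, 30, 30), segment_length_mm=40.0))


class TestRasterizeTree:
    def test_cylinder_volume_within_10_percent(self):
        g = straight_vessel_graph(length_mm=30.0, radius_mm=3.0, start=(5.0, 10.5, 10.5))
        sp = spec(grid_shape=(45, 20, 20), voxel_spacing_mm=(1.0, 1.0, 1.0))
        vol = rasterize_tree(g, sp)
        voxel_volume = float(np.sum(vol.values)) * 1.0
        # analytic volume of the rasterized solid: capsule = cylinder + caps
        analytic = np.pi * 3.0**2 * 30.0 + 4.0 / 3.0 * np.pi * 3.0**3
        assert abs(voxel_volume - analytic) / analytic < 0.10

    def test_voxel_volume_converges_with_spacing(self):
        g = straight_vessel_graph(length_mm=24.0, radius_mm=3.0, start=(4.0, 10.5, 10.5))
        analytic = np.pi * 3.0**2 * 24.0 + 4.0 / 3.0 * np.pi * 3.0**3
        errs = []
        for spacing in (1.0, 0.5):
            sp = spec(
                grid_shape=tuple(int(round(n / spacing)) for n in (36, 20, 20)),
                voxel_spacing_mm=(spacing,) * 3,
            )
            v = rasterize_tree(g, sp)
            errs.append(abs(float(v.values.sum()) * spacing**3 - analytic) / analytic)
        assert errs[1] < errs[0]

    def test_empty_graph_gives_background_volume(self):
        from perfusemri import SpatialGraph

        vol = rasterize_tree(SpatialGraph({}, []), spec())
        assert not vol.values.any()

    def test_subvoxel_radius_warns(self):
        g = straight_vessel_graph(length_mm=10.0, radius_mm=0.2, start=(5.0, 10.0, 10.0))
        with pytest.warns(UserWarning, match="unresolvable"):
            rasterize_tree(g, spec(grid_shape=(30, 30, 30), voxel_spacing_mm=(1, 1, 1)))


class TestSimulateT2:
    def test_noise_free_is_two_valued(self):
        mask = ImageVolume(np.eye(4, dtype=bool)[..., None] * np.ones(4, bool), (1, 1, 1))
        img = simulate_t2_volume(mask, 200, 100, noise_sd=0.0)
        assert set(np.unique(img.values)) == {100.0, 200.0}

    def test_threshold_recovers_mask(self):
        from skimage.filters import threshold_otsu

        rng = np.random.default_rng(0)
        mask = ImageVolume(rng.random((20, 20, 20)) > 0.5, (1, 1, 1))
        img = simulate_t2_volume(mask, 200, 100, noise_sd=5.0, seed=1)
        thr = threshold_otsu(img.values)
        agreement = np.mean((img.values > thr) == mask.values)
        assert agreement >= 0.99

    def test_all_background_constant(self):
        mask = ImageVolume(np.zeros((5, 5, 5), bool), (1, 1, 1))
        img = simulate_t2_volume(mask, 200, 100, noise_sd=0.0)
        assert np.all(img.values == 100.0)

    def test_negative_noise_rejected(self):
        mask = ImageVolume(np.zeros((2, 2, 2), bool), (1, 1, 1))
        with pytest.raises(ValueError):
            simulate_t2_volume(mask, 200, 100, noise_sd=-1)


class TestSimulateDwi:
    def test_closed_form_signal(self):
        D = ImageVolume(np.full((3, 3, 3), 1.0e-3), (1, 1, 1))
        dwi = simulate_dwi(D, S0=100, b_values=(2000.0,), directions=1)
        np.testing.assert_allclose(dwi[0][2000.0].values, 100 * np.exp(-2.0))

    def test_zero_diffusion_gives_S0(self):
        D = ImageVolume(np.zeros((3, 3, 3)), (1, 1, 1))
        dwi = simulate_dwi(D, S0=80.0)
        for b, vol in dwi[0].items():
            np.testing.assert_allclose(vol.values, 80.0)

    def test_noise_free_signal_monotone_in_b(self):
        rng = np.random.default_rng(5)
        D = ImageVolume(rng.uniform(0, 3e-3, (4, 4, 4)), (1, 1, 1))
        dwi = simulate_dwi(D)
        bs = sorted(dwi[0])
        stack = np.stack([dwi[0][b].values for b in bs], axis=-1)
        assert np.all(np.diff(stack, axis=-1) <= 1e-12)
        assert np.all(stack >= 0)

    def test_duplicate_b_rejected(self):
        D = ImageVolume(np.zeros((2, 2, 2)), (1, 1, 1))
        with pytest.raises(ValueError):
            simulate_dwi(D, b_values=(500.0, 500.0))


class TestSimulateDce:
    def test_zero_velocity_only_inlet_enhances(self):
        g = straight_vessel_graph(length_mm=40.0, radius_mm=3.0, start=(5.0, 10.0, 10.0))
        sp = spec(grid_shape=(55, 20, 20), voxel_spacing_mm=(1, 1, 1))
        mask = rasterize_tree(g, sp)
        vol = simulate_dce(g, mask, velocity_cm_per_min=0.0, n_frames=4)
        enhanced = vol.values[..., -1] > vol.values[..., 0]
        # only voxels mapping to the path-distance-0 point may enhance
        centers = mask.voxel_to_world(np.argwhere(enhanced))
        if centers.size:
            assert np.all(np.linalg.norm(centers - g.nodes[0], axis=1) <= 3.0 + 2.0)

    def test_onset_monotone_in_path_distance(self):
        g = straight_vessel_graph(length_mm=60.0, radius_mm=2.5, start=(5.0, 10.0, 10.0))
        sp = spec(grid_shape=(75, 20, 20), voxel_spacing_mm=(1, 1, 1))
        mask = rasterize_tree(g, sp)
        vol = simulate_dce(g, mask, velocity_cm_per_min=15.0, frame_interval_s=5.0, n_frames=10)
        xs = np.arange(6, 64, 4)
        onsets = []
        for x in xs:
            series = vol.values[x, 10, 10, :]
            onset = np.argmax(series > series[0]) if np.any(series > series[0]) else np.inf
            onsets.append(onset)
        assert all(a <= b for a, b in zip(onsets, onsets[1:]))

    def test_missing_inlet_rejected(self):
        g = straight_vessel_graph()
        g.inlet_node = None
        mask = ImageVolume(np.zeros((4, 4, 4), bool), (1, 1, 1))
        with pytest.raises(ValueError, match="inlet"):
            simulate_dce(g, mask)


class TestSimulateHistology:
    def test_zero_dispersion_integer_means_exact(self):
        df = simulate_histology(
            {("Perfused", "Baseline"): (1, 1, 2, 2)}, dispersion=0.0, n_biopsies=5
        )
        assert (df["composite"] == 6).all()

    def test_rubric_ceiling_all_twelve(self):
        df = simulate_histology({("SCS", "30 min"): (3, 3, 3, 3)}, dispersion=0.5, n_biopsies=8)
        assert (df["composite"] == 12).all()

    def test_large_n_reproduces_group_mean_composite(self):
        # severe static-cold-storage damage: category means (2.9, 3, 3, 3)
        df = simulate_histology(
            {("SCS", "30 min"): (2.9, 3.0, 3.0, 3.0)},
            dispersion=0.0,
            n_biopsies=4000,
            seed=11,
        )
        assert df["composite"].mean() == pytest.approx(11.9, abs=0.05)

    def test_mean_outside_rubric_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 3\]"):
            simulate_histology({("A", "t"): (4, 1, 1, 1)})

    def test_reproducible_for_fixed_seed(self):
        kw = dict(dispersion=0.4, n_biopsies=6, seed=3)
        a = simulate_histology({("A", "t"): (1.5, 2.2, 0.7, 2.9)}, **kw)
        b = simulate_histology({("A", "t"): (1.5, 2.2, 0.7, 2.9)}, **kw)
        assert a.equals(b)
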