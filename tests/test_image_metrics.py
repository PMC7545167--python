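"""Morphometry tests: coverage, orientation, tracing, pairing, periodicity,
registry, layers — mostly round-trips against rendered ground truth."""

import math

import numpy as np
import pytest

from septasm.image_metrics import (
    FilamentSet,
    Topograph,
    axial_difference,
    detect_clusters,
    filament_periodicity,
    interlayer_angular_correlation,
    layer_decomposition,
    layer_topograph,
    length_histogram,
    orientation_distribution,
    pair_registry_offset,
    paired_centerlines,
    pairing_fraction,
    periodicity,
    registry_offset_for_pair,
    surface_coverage,
    trace_filaments,
)
from septasm.synthetic_data import FilamentSpec, SceneSpec, render_topograph

from conftest import single_filament_scene, straight_filament


class TestSurfaceCoverage:
    def test_empty_and_half(self):
        assert surface_coverage(Topograph(np.zeros((32, 32)), 1.0)) == 0.0
        h = np.zeros((32, 32))
        h[:16] = 4.0
        assert surface_coverage(Topograph(h, 1.0)) == 0.5

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(2)
        topo = Topograph(rng.uniform(0, 8, (64, 64)), 1.0)
        covs = [surface_coverage(topo, thr) for thr in np.linspace(0, 8, 17)]
        assert all(a >= b for a, b in zip(covs, covs[1:]))

    def test_rendered_scene_hits_target(self):
        # 10 parallel filaments, 6 nm wide, in a 128x128 nm field:
        # expected covered area ~ 10 * length * width
        fil = [FilamentSpec(p0=(4.0, 6.0 + 12 * i), p1=(124.0, 6.0 + 12 * i))
               for i in range(10)]
        spec = SceneSpec(size_px=(128, 128), filaments=fil, psf_sigma=0.0,
                         noise_sigma=0.0, seed=0)
        topo, _ = render_topograph(spec)
        # half-cylinder cross-section crosses the 2 nm threshold at ~87% of
        # its width: sqrt(1 - 0.5^2)
        expected = 10 * 120 * 6 * math.sqrt(0.75) / 128**2
        assert surface_coverage(topo) == pytest.approx(expected, abs=0.03)

    def test_all_nan_rejected(self):
        with pytest.raises(ValueError):
            surface_coverage(Topograph(np.full((8, 8), np.nan), 1.0))


class TestOrientation:
    def test_single_filament_mode(self):
        topo, _ = single_filament_scene(angle_deg=30.0, psf=2.0, noise=0.1,
                                        size=(400, 400), start=(60.0, 60.0))
        ali = orientation_distribution(topo)
        assert axial_difference(ali.center, 30.0) <= 2.0
        assert not ali.multimodal

    def test_orthogonal_families_flagged_multimodal(self):
        fil = []
        for gy in range(4):
            for gx in range(4):
                cx, cy = 60 + gx * 120, 60 + gy * 120
                ang = 0.0 if (gx + gy) % 2 == 0 else 90.0
                u = (math.cos(math.radians(ang)), math.sin(math.radians(ang)))
                fil.append(FilamentSpec(p0=(cx - 40 * u[0], cy - 40 * u[1]),
                                        p1=(cx + 40 * u[0], cy + 40 * u[1])))
        spec = SceneSpec(size_px=(480, 480), filaments=fil, psf_sigma=2.0,
                         noise_sigma=0.1, seed=0)
        topo, _ = render_topograph(spec)
        ali = orientation_distribution(topo)
        assert ali.multimodal
        assert math.isnan(ali.fwhh)

    def test_fwhh_tracks_angular_spread(self):
        # orientations ~ Normal(45, 10): FWHH should come out near
        # 2.355 * 10 = 23.5 degrees
        rng = np.random.default_rng(0)
        fil = []
        for gy in range(10):
            for gx in range(10):
                cx, cy = 90 + gx * 110, 90 + gy * 110
                ang = rng.normal(45.0, 10.0)
                u = (math.cos(math.radians(ang)), math.sin(math.radians(ang)))
                fil.append(FilamentSpec(p0=(cx - 45 * u[0], cy - 45 * u[1]),
                                        p1=(cx + 45 * u[0], cy + 45 * u[1])))
        spec = SceneSpec(size_px=(1180, 1180), filaments=fil, psf_sigma=2.0,
                         noise_sigma=0.1, seed=0)
        topo, _ = render_topograph(spec)
        ali = orientation_distribution(topo)
        assert ali.fwhh == pytest.approx(23.5, abs=4.0)

    def test_empty_image_insufficient_signal(self):
        with pytest.raises(ValueError, match="insufficient"):
            orientation_distribution(Topograph(np.zeros((64, 64)), 1.0))


class TestTracing:
    def test_single_filament_length(self):
        topo, _ = single_filament_scene(length=320.0)
        fs = trace_filaments(topo)
        assert len(fs) == 1
        assert fs.filaments[0].length == pytest.approx(320.0, abs=2.0)

    def test_empty_topograph_empty_set(self):
        fs = trace_filaments(Topograph(np.zeros((64, 64)), 1.0))
        assert len(fs) == 0

    def test_two_parallel_filaments_two_traces(self):
        fil = [FilamentSpec(p0=(30.0, 60.0), p1=(220.0, 60.0)),
               FilamentSpec(p0=(30.0, 140.0), p1=(220.0, 140.0))]
        spec = SceneSpec(size_px=(200, 256), filaments=fil, psf_sigma=1.0,
                         noise_sigma=0.05, seed=0)
        topo, _ = render_topograph(spec)
        fs = trace_filaments(topo)
        assert len(fs) == 2

    def test_rotation_invariance_of_length(self):
        lengths = {}
        for ang in (0.0, 37.0):
            topo, _ = single_filament_scene(angle_deg=ang, length=256.0,
                                            psf=1.0, noise=0.05,
                                            size=(400, 400), start=(70.0, 70.0))
            fs = trace_filaments(topo)
            assert len(fs) == 1
            lengths[ang] = fs.filaments[0].length
        assert lengths[0.0] == pytest.approx(lengths[37.0], abs=4.0)


class TestLengthHistogram:
    def test_direct_binning(self):
        fs = FilamentSet([straight_filament(0, 0, L, 0) for L in (32, 64, 64)])
        assert length_histogram(fs) == {1: 1, 2: 2}

    def test_round_half_up(self):
        fs = FilamentSet([straight_filament(0, 0, 48, 0)])
        assert length_histogram(fs) == {2: 1}

    def test_short_fragments_count_as_rods(self):
        fs = FilamentSet([straight_filament(0, 0, 10, 0)])
        assert length_histogram(fs) == {1: 1}

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            length_histogram(FilamentSet([]))


class TestPairing:
    def test_full_pair_is_100(self):
        fs = FilamentSet([straight_filament(0, 0, 200, 0),
                          straight_filament(0, 6, 200, 6)])
        assert pairing_fraction(fs) == 100.0

    def test_isolated_filament_is_0(self):
        fs = FilamentSet([straight_filament(0, 0, 200, 0)])
        assert pairing_fraction(fs) == 0.0

    def test_half_overlap_near_50(self):
        fs = FilamentSet([straight_filament(0, 0, 200, 0),
                          straight_filament(100, 6, 300, 6)])
        assert pairing_fraction(fs) == pytest.approx(50.0, abs=5.0)

    def test_orthogonal_neighbors_not_paired(self):
        fs = FilamentSet([straight_filament(0, 0, 200, 0),
                          straight_filament(100, -50, 100, 50)])
        # crossing but not parallel: only a negligible sliver may count
        assert pairing_fraction(fs) <= 10.0

    def test_bounded(self):
        rng = np.random.default_rng(3)
        fils = [straight_filament(rng.uniform(0, 100), rng.uniform(0, 100),
                                  rng.uniform(100, 300), rng.uniform(0, 100))
                for _ in range(6)]
        frac = pairing_fraction(FilamentSet(fils))
        assert 0.0 <= frac <= 100.0


class TestPeriodicity:
    def test_cosine_profile(self):
        x = np.arange(0, 320.0, 1.0)
        prof = np.cos(2 * np.pi * x / 32.0)
        assert periodicity(prof, sample_spacing=1.0) == pytest.approx(32.0, abs=1.0)

    def test_discrete_positions(self):
        assert periodicity([0.0, 32.0, 64.0, 96.0]) == pytest.approx(32.0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            periodicity([0.0, 32.0])
        with pytest.raises(ValueError):
            periodicity([1.0, 2.0], sample_spacing=1.0)

    def test_rendered_octamer_chain(self):
        # blurred and noisy rod chain still reads ~32 nm along its axis
        topo, _ = single_filament_scene(length=416.0, psf=3.0, noise=0.2,
                                        size=(256, 560), start=(60.0, 128.0))
        fs = trace_filaments(topo)
        assert len(fs) == 1
        assert filament_periodicity(topo, fs.filaments[0]) == pytest.approx(32.0, abs=2.0)


class TestRegistry:
    def test_identical_trains(self):
        train = np.arange(0.0, 320.0, 32.0)
        assert pair_registry_offset(train, train) == pytest.approx(0.0, abs=0.1)

    def test_shifted_train(self):
        a = np.arange(0.0, 320.0, 32.0)
        assert pair_registry_offset(a, a + 4.0) == pytest.approx(4.0, abs=0.1)

    def test_incommensurate_rejected(self):
        a = np.arange(0.0, 320.0, 32.0)
        b = np.arange(0.0, 320.0, 20.0)
        with pytest.raises(ValueError, match="incommensurate"):
            pair_registry_offset(a, b)

    def test_rendered_mismatched_pair(self):
        # two members, one-subunit (4 nm) stagger, traced and compared
        fil = [
            FilamentSpec(p0=(40.0, 96.0), p1=(460.0, 96.0), width=4.0, phase=0.0),
            FilamentSpec(p0=(40.0, 104.0), p1=(460.0, 104.0), width=4.0, phase=4.0),
        ]
        spec = SceneSpec(size_px=(200, 512), filaments=fil, psf_sigma=1.5,
                         noise_sigma=0.15, seed=3)
        topo, _ = render_topograph(spec)
        fs = trace_filaments(topo)
        long = [f for f in fs.filaments if f.length > 300]
        assert len(long) == 2
        off = registry_offset_for_pair(long[0], long[1])
        assert off == pytest.approx(4.0, abs=1.5)


class TestLayers:
    def test_three_flat_levels(self):
        h = np.zeros((60, 60))
        h[20:40] = 4.0
        h[40:] = 8.0
        dec = layer_decomposition(Topograph(h, 1.0))
        assert dec.n_layers == 2
        assert np.allclose(dec.step_heights, [4.0, 4.0])
        assert dec.coverage[0] == 1.0
        assert dec.coverage[1] == pytest.approx(2 / 3)
        assert dec.coverage[2] == pytest.approx(1 / 3)

    def test_single_layer_scene(self):
        topo, _ = single_filament_scene()
        dec = layer_decomposition(topo)
        assert dec.n_layers == 1

    def test_two_layer_coverage_roundtrip(self):
        # second-layer coverage from the decomposition tracks the rendered
        # pre-blur ground-truth masks
        fil = [FilamentSpec(p0=(10.0, 16.0 + 12 * i), p1=(245.0, 16.0 + 12 * i),
                            layer=1, width=8.0) for i in range(19)]
        fil += [FilamentSpec(p0=(30.0, 40.0 + 40 * i), p1=(225.0, 40.0 + 40 * i),
                             layer=2, width=8.0) for i in range(5)]
        spec = SceneSpec(size_px=(256, 256), filaments=fil, psf_sigma=1.0,
                         noise_sigma=0.1, seed=0)
        topo, gt = render_topograph(spec)
        dec = layer_decomposition(topo)
        true_cov2 = gt["layer_masks"][2].mean()
        assert dec.coverage[2] == pytest.approx(true_cov2, abs=0.05)

    def test_interlayer_correlation_extremes(self):
        lower = FilamentSet([straight_filament(0, 20 * i, 200, 20 * i)
                             for i in range(5)])
        upper_parallel = FilamentSet([straight_filament(20, 10 + 20 * i, 180, 10 + 20 * i)
                                      for i in range(4)])
        assert interlayer_angular_correlation(lower, upper_parallel) == 100.0
        upper_ortho = FilamentSet([straight_filament(40 * i + 20, 0, 40 * i + 20, 90)
                                   for i in range(4)])
        assert interlayer_angular_correlation(lower, upper_ortho) == 0.0


class TestPairedCenterlines:
    def test_edge_contact_pair_top_to_top(self):
        fil = [
            FilamentSpec(p0=(40.0, 98.0), p1=(460.0, 98.0), width=4.0),
            FilamentSpec(p0=(40.0, 102.0), p1=(460.0, 102.0), width=4.0),
        ]
        spec = SceneSpec(size_px=(200, 512), filaments=fil, psf_sigma=1.0,
                         noise_sigma=0.1, seed=5)
        topo, _ = render_topograph(spec)
        fs = trace_filaments(topo)
        assert len(fs) == 1  # merged mask
        _, _, dists = paired_centerlines(topo, fs.filaments[0], max_sep=10.0)
        assert np.median(dists) == pytest.approx(4.0, abs=1.0)
        assert np.all(dists <= 10.0)

    def test_single_filament_not_a_pair(self):
        topo, _ = single_filament_scene(psf=1.0, noise=0.05)
        fs = trace_filaments(topo)
        with pytest.raises(ValueError, match="pair"):
            paired_centerlines(topo, fs.filaments[0], max_sep=10.0)


class TestClusters:
    def test_cluster_spacing_roundtrip(self):
        fil = [FilamentSpec(p0=(30.0, 100.0), p1=(450.0, 100.0), width=6.0,
                            clusters=True)]
        spec = SceneSpec(size_px=(200, 512), filaments=fil, psf_sigma=3.0,
                         noise_sigma=0.2, seed=2)
        topo, gt = render_topograph(spec)
        found = detect_clusters(topo, min_height=4.0, min_distance_nm=12.0)
        true = gt["filaments"][0]["cluster_centers"]
        assert len(found) == len(true)
        xs = np.sort(found[:, 0])
        assert periodicity(xs) == pytest.approx(32.0, abs=2.0)


class TestRotationInvariance:
    @pytest.mark.parametrize("rot", [0, 1, 2])
    def test_coverage_under_rotation(self, rot):
        topo, _ = single_filament_scene(psf=2.0, noise=0.1)
        rotated = Topograph(np.rot90(topo.heights, rot).copy(), topo.pixel_size)
        assert surface_coverage(rotated) == pytest.approx(surface_coverage(topo))
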