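"""GQI reconstruction: direction sets, the sinc kernel, and scalar indices."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra import numpy as hnp

from gqipipe.gqi import (
    GQIConfig,
    IndexMap,
    ODFField,
    build_index_maps,
    compute_gfa,
    compute_iso,
    compute_qa_nqa,
    make_direction_set,
    nearest_neighbor_angle,
    reconstruct_odf,
)
from gqipipe.synthetic import (
    CohortSpec,
    DWIVolume,
    FiberCompartment,
    FiberConfig,
    simulate_voxel_signal,
)


def brute_force_odf(signal, gtab, dirs, cfg):
    """Independent scalar double-loop evaluation of the GQI kernel sum."""
    out = np.zeros(len(dirs))
    for j, u in enumerate(dirs.vectors):
        acc = 0.0
        for i in range(len(gtab)):
            x = (
                cfg.sampling_length_ratio
                * math.sqrt(6.0 * cfg.free_diffusion_constant * gtab.bvals[i])
                * float(gtab.bvecs[i] @ u)
            )
            acc += signal[i] * (math.sin(x) / x if x != 0.0 else 1.0)
        out[j] = acc
    return np.maximum(out, 0.0)


class TestDirectionSet:
    @pytest.mark.parametrize("order,count", [(0, 6), (1, 21), (2, 81), (3, 321)])
    def test_hemisphere_counts(self, order, count):
        assert len(make_direction_set(order)) == count == (10 * 4**order + 2) // 2

    def test_no_duplicate_or_antipodal_directions(self, dirs3):
        dots = np.abs(dirs3.vectors @ dirs3.vectors.T)
        np.fill_diagonal(dots, 0.0)
        assert dots.max() < 1.0 - 1e-8

    def test_unit_norms(self, dirs3):
        assert np.allclose(np.linalg.norm(dirs3.vectors, axis=1), 1.0, atol=1e-8)

    def test_negative_order_rejected(self):
        with pytest.raises(ValueError):
            make_direction_set(-1)

    def test_nearest_neighbor_angle_is_a_few_degrees_at_order3(self, dirs3):
        ang = nearest_neighbor_angle(dirs3)
        assert 5.0 < ang < 12.0


class TestReconstruction:
    def test_zero_signal_gives_zero_odf(self, small_gtab, gqi_cfg):
        odf = reconstruct_odf(np.zeros(len(small_gtab)), small_gtab, make_direction_set(1), gqi_cfg)
        assert np.allclose(odf, 0.0)

    def test_linearity_in_signal(self, small_gtab, gqi_cfg):
        dirs = make_direction_set(1)
        rng = np.random.default_rng(0)
        s1, s2 = rng.uniform(0.2, 1.0, (2, len(small_gtab)))
        lhs = reconstruct_odf(2.0 * s1 + 3.0 * s2, small_gtab, dirs, gqi_cfg)
        rhs = 2.0 * reconstruct_odf(s1, small_gtab, dirs, gqi_cfg) + 3.0 * reconstruct_odf(
            s2, small_gtab, dirs, gqi_cfg
        )
        # signals positive, so no truncation occurs and linearity is exact
        assert np.allclose(lhs, rhs, rtol=1e-12)

    def test_isotropic_voxel_gives_flat_odf(self, gtab, dirs3, gqi_cfg, isotropic_voxel):
        s = simulate_voxel_signal(isotropic_voxel, gtab)
        odf = reconstruct_odf(s, gtab, dirs3, gqi_cfg)
        assert odf.max() / odf.min() <= 1.05

    def test_single_fiber_peak_aligned_with_axis(self, gtab, dirs3, gqi_cfg, single_fiber):
        s = simulate_voxel_signal(single_fiber(direction=(0, 0, 1)), gtab)
        odf = reconstruct_odf(s, gtab, dirs3, gqi_cfg)
        peak = dirs3.vectors[int(np.argmax(odf))]
        angle = math.degrees(math.acos(min(1.0, abs(float(peak @ np.array([0.0, 0.0, 1.0]))))))
        assert angle <= nearest_neighbor_angle(dirs3)

    def test_matches_brute_force_oracle(self, small_gtab, gqi_cfg):
        dirs = make_direction_set(1)
        rng = np.random.default_rng(42)
        for _ in range(5):
            signal = rng.uniform(0.0, 2.0, len(small_gtab))
            expected = brute_force_odf(signal, small_gtab, dirs, gqi_cfg)
            got = reconstruct_odf(signal, small_gtab, dirs, gqi_cfg)
            assert np.allclose(got, expected, rtol=1e-10, atol=1e-12)

    def test_length_mismatch_rejected(self, small_gtab, gqi_cfg):
        with pytest.raises(ValueError):
            reconstruct_odf(np.ones(len(small_gtab) + 1), small_gtab, make_direction_set(1), gqi_cfg)

    def test_crossing_fibers_give_two_separated_maxima(self, gtab, dirs3, gqi_cfg):
        fibers = FiberConfig(
            compartments=(
                FiberCompartment(fraction=0.45, direction=(0, 0, 1)),
                FiberCompartment(fraction=0.45, direction=(1, 0, 0)),
            ),
            isotropic_fraction=0.1,
        )
        s = simulate_voxel_signal(fibers, gtab)
        odf = reconstruct_odf(s, gtab, dirs3, gqi_cfg)
        vectors = dirs3.vectors
        # local maxima over the antipodally folded neighborhood graph
        neighbor_cos = math.cos(math.radians(1.5 * nearest_neighbor_angle(dirs3)))
        peaks = []
        for j in range(len(vectors)):
            neighbors = np.abs(vectors @ vectors[j]) >= neighbor_cos
            neighbors[j] = False
            if odf[j] >= odf[neighbors].max():
                peaks.append(j)
        peaks.sort(key=lambda j: -odf[j])
        assert len(peaks) >= 2
        a, b = vectors[peaks[0]], vectors[peaks[1]]
        sep = math.degrees(math.acos(min(1.0, abs(float(a @ b)))))
        assert sep >= 60.0


class TestScalarIndices:
    def test_constant_odf_has_zero_gfa(self):
        assert compute_gfa(np.full(4, 0.5)) == 0.0

    @pytest.mark.parametrize("n", [2, 4, 10, 321])
    def test_one_hot_closed_form(self, n):
        odf = np.zeros(n)
        odf[0] = 1.0
        assert compute_gfa(odf) == pytest.approx(math.sqrt((n - 1) / n), rel=1e-12)

    def test_all_zero_odf_maps_to_zero(self):
        assert compute_gfa(np.zeros(5)) == 0.0

    def test_empty_odf_rejected(self):
        with pytest.raises(ValueError):
            compute_gfa(np.array([]))
        with pytest.raises(ValueError):
            compute_iso(np.array([]))

    @given(
        odf=hnp.arrays(
            float,
            st.integers(min_value=1, max_value=50),
            elements=st.floats(min_value=0.0, max_value=1e3),
        ),
        scale=st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_gfa_bounds_and_scale_invariance(self, odf, scale):
        n = odf.size
        g = compute_gfa(odf)
        assert 0.0 <= g <= math.sqrt((n - 1) / n) + 1e-12 if n > 1 else g == 0.0
        assert compute_gfa(scale * odf) == pytest.approx(g, abs=1e-9)

    def test_iso_is_minimum_and_permutation_invariant(self):
        odf = np.array([0.2, 0.5, 0.3])
        assert compute_iso(odf) == 0.2
        assert compute_iso(odf[::-1]) == 0.2
        assert compute_iso(np.full(7, 0.4)) == pytest.approx(0.4)

    def test_qa_nqa_degenerate_and_normalized_cases(self, dirs3):
        dirs = make_direction_set(0)
        const = np.full((2, 2, 1, len(dirs)), 0.3)
        qa, nqa = compute_qa_nqa(ODFField(values=const, direction_set=dirs))
        assert np.allclose(qa.data, 0.0) and np.allclose(nqa.data, 0.0)

        vals = np.zeros((2, 1, 1, len(dirs)))
        vals[0, 0, 0] = [0.5, 0.1, 0.1, 0.1, 0.1, 0.1]  # QA 0.4
        vals[1, 0, 0] = [0.3, 0.1, 0.1, 0.1, 0.1, 0.1]  # QA 0.2
        qa, nqa = compute_qa_nqa(ODFField(values=vals, direction_set=dirs))
        assert qa.data[0, 0, 0] == pytest.approx(0.4)
        assert qa.data[1, 0, 0] == pytest.approx(0.2)
        assert nqa.data[0, 0, 0] == pytest.approx(1.0)
        assert nqa.data[1, 0, 0] == pytest.approx(0.5)


def _uniform_fiber_volume(fibers, gtab, shape=(4, 4, 4), noise=0.0, seed=0):
    signal = simulate_voxel_signal(fibers, gtab, noise_sigma=noise, seed=seed)
    data = np.broadcast_to(signal, shape + (len(gtab),)).copy()
    return DWIVolume(data=data, gradient_table=gtab)


class TestIndexMaps:
    def test_isotropic_volume_has_near_zero_gfa(self, gtab, isotropic_voxel):
        dwi = _uniform_fiber_volume(isotropic_voxel, gtab)
        gfa, iso, nqa = build_index_maps(dwi, GQIConfig(odf_direction_order=2))
        assert gfa.data.max() <= 0.05
        assert iso.data.min() > 0.0

    def test_map_shapes_match_grid(self, small_gtab, isotropic_voxel):
        dwi = _uniform_fiber_volume(isotropic_voxel, small_gtab, shape=(3, 4, 5))
        for imap in build_index_maps(dwi, GQIConfig(odf_direction_order=1)):
            assert imap.data.shape == (3, 4, 5)

    def test_fiber_region_has_higher_gfa_than_isotropic(self, gtab, single_fiber, isotropic_voxel):
        cfg = GQIConfig(odf_direction_order=2)
        fiber_vol = _uniform_fiber_volume(single_fiber(), gtab)
        iso_vol = _uniform_fiber_volume(isotropic_voxel, gtab)
        gfa_fiber = build_index_maps(fiber_vol, cfg)[0]
        gfa_iso = build_index_maps(iso_vol, cfg)[0]
        assert gfa_fiber.data.mean() > gfa_iso.data.mean()

    def test_outside_mask_is_zero(self, small_gtab, single_fiber):
        dwi = _uniform_fiber_volume(single_fiber(), small_gtab, shape=(4, 4, 4))
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[:2] = True
        gfa, iso, nqa = build_index_maps(dwi, GQIConfig(odf_direction_order=1), mask=mask)
        assert np.allclose(gfa.data[~mask], 0.0)
        assert np.allclose(iso.data[~mask], 0.0)
        assert gfa.data[mask].max() > 0.0

    def test_gfa_monotone_in_anisotropy(self, gtab):
        """GFA does not decrease as axial-radial diffusivity gap widens."""
        cfg = GQIConfig(odf_direction_order=2)
        gfas = []
        for radial in np.linspace(1.7e-3, 0.1e-3, 5):  # gap 0 .. 1.6e-3
            fib = FiberConfig(
                compartments=(
                    FiberCompartment(
                        fraction=1.0, direction=(0, 0, 1),
                        axial_diffusivity=1.7e-3, radial_diffusivity=radial,
                    ),
                ),
            )
            s = simulate_voxel_signal(fib, gtab)
            odf = reconstruct_odf(s, gtab, make_direction_set(2), cfg)
            gfas.append(compute_gfa(odf))
        assert all(b >= a - 1e-12 for a, b in zip(gfas, gfas[1:]))

    def test_effect_roi_lowers_gfa_in_cohort_maps(self):
        spec = CohortSpec(
            group_sizes={"HC": 2, "SI": 2},
            grid_shape=(10, 10, 10),
            n_per_shell=16,
            effect_delta=0.5,
            noise_sigma=0.0,
            fraction_jitter_sd=0.0,
            seed=2,
        )
        from gqipipe.synthetic import make_cohort

        cfg = GQIConfig(odf_direction_order=1)
        roi = spec.roi_mask()
        means = {}
        for s in make_cohort(spec):
            gfa = build_index_maps(s.dwi, cfg)[0]
            means.setdefault(s.group, []).append(gfa.data[roi].mean())
        assert np.mean(means["SI"]) < np.mean(means["HC"])


class TestFiberRecovery:
    def test_random_orientations_recovered_within_grid_spacing(self, gtab, dirs3, gqi_cfg):
        """Noise-free single-fiber peak direction lands within one
        direction-set spacing of the true axis, 20/20 orientations."""
        rng = np.random.default_rng(2024)
        tol = nearest_neighbor_angle(dirs3)
        failures = 0
        for _ in range(20):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            fib = FiberConfig(
                compartments=(FiberCompartment(fraction=0.8, direction=tuple(v)),),
                isotropic_fraction=0.2,
            )
            s = simulate_voxel_signal(fib, gtab)
            odf = reconstruct_odf(s, gtab, dirs3, gqi_cfg)
            peak = dirs3.vectors[int(np.argmax(odf))]
            angle = math.degrees(math.acos(min(1.0, abs(float(peak @ v)))))
            if angle > tol:
                failures += 1
        assert failures == 0
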