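"""Geometry extraction, nucleus-Golgi pairing, angles and circular summary."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import cdist

import vasckinetics as vk
from vasckinetics.errors import SchemaError


def geom(label, centroid_xy, boundary_xy=None, z=0.0):
    """Build an ObjectGeometry from x-y points (z constant)."""
    c = np.array([*centroid_xy, z], dtype=float)
    if boundary_xy is None:
        b = c[np.newaxis, :]
    else:
        b = np.array([[x, y, z] for x, y in boundary_xy], dtype=float)
    return vk.ObjectGeometry(label_id=label, centroid=c, boundary=b)


def random_point_cloud_objects(rng, n, spread=50.0, pts=6):
    objs = []
    for i in range(n):
        center = rng.uniform(0, spread, size=3)
        boundary = center + rng.normal(scale=1.0, size=(pts, 3))
        objs.append(vk.ObjectGeometry(label_id=i + 1, centroid=center, boundary=boundary))
    return objs


def oracle_greedy_pairing(nuclei, golgi):
    """Exhaustive all-pairs greedy oracle: explicit distance matrix, assign
    candidate pairs in ascending order, each object used at most once."""
    d = np.full((len(nuclei), len(golgi)), np.inf)
    for i, nuc in enumerate(nuclei):
        for j, gol in enumerate(golgi):
            d[i, j] = cdist(nuc.boundary, gol.boundary).min()
    flat = sorted(
        ((d[i, j], i, j) for i in range(len(nuclei)) for j in range(len(golgi)))
    )
    used_n, used_g, out = set(), set(), {}
    for dist, i, j in flat:
        if i not in used_n and j not in used_g:
            out[nuclei[i].label_id] = (golgi[j].label_id, dist)
            used_n.add(i)
            used_g.add(j)
    return out


def oracle_rotation_angle(a_xy, b_xy):
    """Rotate the frame so the reference points along +y, then read the
    compass angle clockwise from +y with atan2."""
    b = np.asarray(b_xy, float) / np.linalg.norm(b_xy)
    rot = np.array([[b[1], -b[0]], [b[0], b[1]]])
    ax, ay = rot @ np.asarray(a_xy, float)
    return math.degrees(math.atan2(ax, ay)) % 360.0


class TestExtractGeometry:
    def test_single_voxel_centroid_in_um(self):
        arr = np.zeros((5, 6, 7), dtype=np.uint8)
        arr[2, 3, 4] = 1
        mask = vk.LabelMask(arr, (2.0, 1.0, 1.0))
        (g,) = vk.extract_geometry(mask)
        assert np.allclose(g.centroid, [4.0, 3.0, 4.0])  # (x, y, z) µm
        assert np.allclose(g.boundary, [[4.0, 3.0, 4.0]])

    def test_solid_sphere_centroid_near_center(self):
        spacing = np.array([2.0, 0.5, 0.5])
        shape = (20, 60, 60)
        center = np.array([20.0, 15.0, 15.0])  # (z, y, x) µm
        grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
        d2 = sum(((g * s - c) ** 2 for g, s, c in zip(grids, spacing, center)))
        arr = (d2 <= 6.0**2).astype(np.uint8)
        (g,) = vk.extract_geometry(vk.LabelMask(arr, tuple(spacing)))
        expect_xyz = center[::-1]
        assert np.all(np.abs(g.centroid - expect_xyz) <= spacing[::-1] / 2)

    def test_empty_mask_gives_empty_list(self):
        mask = vk.LabelMask(np.zeros((4, 4, 4), dtype=np.uint8), (1, 1, 1))
        assert vk.extract_geometry(mask) == []

    def test_random_blobs_match_bruteforce_accumulation(self):
        rng = np.random.default_rng(0)
        arr = rng.integers(0, 5, size=(10, 12, 14)).astype(np.uint8)
        spacing = (2.0, 1.0, 0.5)
        geoms = {g.label_id: g for g in vk.extract_geometry(vk.LabelMask(arr, spacing))}
        sp = np.array(spacing)
        for lab in range(1, 5):
            # independent per-label accumulation of voxel centers
            acc, cnt = np.zeros(3), 0
            boundary = []
            for idx in np.ndindex(arr.shape):
                if arr[idx] != lab:
                    continue
                acc += np.array(idx) * sp
                cnt += 1
                for ax in range(3):
                    for d in (-1, 1):
                        nb = list(idx)
                        nb[ax] += d
                        outside = not (0 <= nb[ax] < arr.shape[ax])
                        if outside or arr[tuple(nb)] == 0:
                            boundary.append(np.array(idx) * sp)
                            break
                    else:
                        continue
                    break
            g = geoms[lab]
            assert np.allclose(g.centroid, (acc / cnt)[::-1], atol=1e-12)
            expect_b = {tuple(b[::-1]) for b in boundary}
            assert {tuple(b) for b in g.boundary} == expect_b


class TestPairing:
    def test_single_close_pair_included(self):
        n = geom(1, (0, 0), [(-1, 0), (1, 0)])
        g = geom(7, (4, 0), [(4, 0)])
        res = vk.pair_nuclei_golgi([n], [g])
        (pair,) = res.pairs
        assert pair.nucleus_id == 1 and pair.golgi_id == 7
        assert pair.border_distance == pytest.approx(3.0)
        assert pair.included

    def test_pair_beyond_5um_excluded(self):
        n = geom(1, (0, 0), [(1, 0)])
        g = geom(2, (8, 0), [(7, 0)])
        (pair,) = vk.pair_nuclei_golgi([n], [g]).pairs
        assert pair.border_distance == pytest.approx(6.0)
        assert not pair.included
        assert pair.exclusion_reason == "border_distance"

    def test_no_golgi_all_unmatched(self, caplog):
        res = vk.pair_nuclei_golgi([geom(1, (0, 0)), geom(2, (5, 5))], [])
        assert res.pairs == []
        assert res.unmatched_nuclei == [1, 2]

    def test_random_scene_matches_exhaustive_greedy_oracle(self):
        rng = np.random.default_rng(1)
        nuclei = random_point_cloud_objects(rng, 10)
        golgi = random_point_cloud_objects(rng, 12)
        res = vk.pair_nuclei_golgi(nuclei, golgi, max_dist=np.inf)
        expected = oracle_greedy_pairing(nuclei, golgi)
        assert len(res.pairs) == 10
        for pair in res.pairs:
            gid, dist = expected[pair.nucleus_id]
            assert pair.golgi_id == gid
            assert pair.border_distance == pytest.approx(dist, abs=1e-12)
        assert len(res.unmatched_golgi) == 2

    def test_greedy_and_optimal_agree_when_well_separated(self, small_scene):
        _, nuclei_mask, golgi_mask, _, _ = small_scene
        nuclei = vk.extract_geometry(nuclei_mask)
        golgi = vk.extract_geometry(golgi_mask)
        greedy = vk.pair_nuclei_golgi(nuclei, golgi, method="greedy")
        optimal = vk.pair_nuclei_golgi(nuclei, golgi, method="optimal")
        as_set = lambda r: {(p.nucleus_id, p.golgi_id) for p in r.pairs}
        assert as_set(greedy) == as_set(optimal)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(2)
        nuclei = random_point_cloud_objects(rng, 15, spread=30)
        golgi = random_point_cloud_objects(rng, 15, spread=30)
        previous = -1
        for max_dist in (0.5, 2.0, 5.0, 10.0, 50.0):
            n_inc = len(vk.pair_nuclei_golgi(nuclei, golgi, max_dist=max_dist).included)
            assert n_inc >= previous
            previous = n_inc

    def test_every_nucleus_accounted_once(self):
        rng = np.random.default_rng(3)
        nuclei = random_point_cloud_objects(rng, 12, spread=40)
        golgi = random_point_cloud_objects(rng, 9, spread=40)
        res = vk.pair_nuclei_golgi(nuclei, golgi)
        n_inc = len(res.included)
        n_exc = sum(1 for p in res.pairs if not p.included)
        assert n_inc + n_exc + len(res.unmatched_nuclei) == 12


class TestPolarityAngle:
    @pytest.mark.parametrize(
        "golgi_xy,expected",
        [((0, 1), 0.0), ((1, 0), 90.0), ((0, -1), 180.0), ((-1, 0), 270.0),
         ((1, 1), 45.0), ((-1, 1), 315.0)],
    )
    def test_compass_anchors(self, golgi_xy, expected):
        pair = vk.NucleusGolgiPair(1, 1, 0.0, np.zeros(3), np.array([*golgi_xy, 0.0]))
        assert vk.compute_polarity_angle(pair) == pytest.approx(expected)

    def test_left_side_mirrors_lateral(self):
        pair = vk.NucleusGolgiPair(1, 1, 0.0, np.zeros(3), np.array([1.0, 0.0, 0.0]))
        assert vk.compute_polarity_angle(pair, lateral_side="left") == pytest.approx(270.0)

    def test_matches_rotation_matrix_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(300):
            a = rng.normal(size=2)
            b = rng.normal(size=2)
            if min(np.linalg.norm(a), np.linalg.norm(b)) < 1e-3:
                continue
            pair = vk.NucleusGolgiPair(1, 1, 0.0, np.zeros(3), np.array([*a, 0.0]))
            got = vk.compute_polarity_angle(pair, reference_axis=b)
            want = oracle_rotation_angle(a, b)
            assert abs((got - want + 180) % 360 - 180) < 1e-9

    @given(phi=st.floats(min_value=0.0, max_value=2 * math.pi))
    @settings(deadline=None, max_examples=50)
    def test_rotation_equivariance(self, phi):
        rng = np.random.default_rng(5)
        rot = np.array([[math.cos(phi), -math.sin(phi)], [math.sin(phi), math.cos(phi)]])
        for _ in range(10):
            a = rng.normal(size=2)
            if np.linalg.norm(a) < 1e-2:
                continue
            p0 = vk.NucleusGolgiPair(1, 1, 0.0, np.zeros(3), np.array([*a, 0.0]))
            p1 = vk.NucleusGolgiPair(1, 1, 0.0, np.zeros(3), np.array([*(rot @ a), 0.0]))
            t0 = vk.compute_polarity_angle(p0, reference_axis=(0.0, 1.0))
            t1 = vk.compute_polarity_angle(p1, reference_axis=rot @ np.array([0.0, 1.0]))
            assert abs((t1 - t0 + 180) % 360 - 180) < 1e-6

    def test_degenerate_xy_pair_excluded_with_reason(self):
        # Golgi directly above the nucleus in z: zero-length x-y projection
        from vasckinetics.polarity import assign_angles

        res = vk.PairingResult(pairs=[vk.NucleusGolgiPair(3, 3, 0.0, np.zeros(3),
                                                          np.array([0.0, 0.0, 4.0]))])
        out = assign_angles(res)
        assert out.size == 0
        assert not res.pairs[0].included
        assert res.pairs[0].exclusion_reason == "degenerate_xy"


class TestSummarizeAngles:
    def test_all_identical_angles(self):
        d = vk.summarize_angles(np.full(50, 90.0))
        assert d.resultant_length == pytest.approx(1.0)
        assert d.mean_deg == pytest.approx(90.0)
        assert d.rayleigh_p == pytest.approx(math.exp(-50) * (1 + (100 - 2500) / 200), abs=1e-12)

    def test_cardinal_directions_cancel(self):
        d = vk.summarize_angles([0.0, 90.0, 180.0, 270.0] * 5)
        assert d.resultant_length == pytest.approx(0.0, abs=1e-12)
        assert d.rayleigh_p > 0.99

    @pytest.mark.parametrize("n_bins", [4, 24, 36, 100])
    def test_histogram_conserves_counts(self, n_bins):
        rng = np.random.default_rng(6)
        angles = rng.uniform(0, 360, size=333)
        d = vk.summarize_angles(angles, n_bins=n_bins)
        assert d.counts.sum() == 333 == d.n_included
        assert len(d.bin_edges) == n_bins + 1

    def test_von_mises_sample_detected_as_directional(self):
        angles = vk.sample_polarity_angles(0.0, 2.0, 2000, seed=7)
        d = vk.summarize_angles(angles)
        assert d.rayleigh_p < 0.001
        assert abs((d.mean_deg + 180) % 360 - 180) < 5.0

    def test_monte_carlo_agrees_with_approximation(self):
        angles = vk.sample_polarity_angles(0.0, 0.3, 80, seed=8)
        d_a = vk.summarize_angles(angles, uniformity="approx")
        d_mc = vk.summarize_angles(angles, uniformity="monte_carlo", seed=9)
        assert abs(d_a.rayleigh_p - d_mc.rayleigh_p) < 0.05

    def test_empty_input_errors(self):
        with pytest.raises(SchemaError):
            vk.summarize_angles([])


class TestSceneRoundTrip:
    def test_pipeline_recovers_generated_angles_within_voxel_error(self, small_scene):
        params, nuclei_mask, golgi_mask, _, truth = small_scene
        res, dist = vk.polarity_pipeline(nuclei_mask, golgi_mask)
        by_id = {p.nucleus_id: p.angle_deg for p in res.included}
        assert len(by_id) == len(truth.cells)
        bound = math.degrees(
            math.atan(max(params.voxel_spacing[1:]) / params.golgi_offset)
        )
        for _, row in truth.cells.iterrows():
            err = abs((by_id[row["cell_id"]] - row["angle_deg"] + 180) % 360 - 180)
            assert err <= bound
        assert dist.n_included == len(truth.cells)

    def test_rose_plot_writes_svg(self, tmp_path, small_scene):
        _, nuclei_mask, golgi_mask, _, _ = small_scene
        _, dist = vk.polarity_pipeline(nuclei_mask, golgi_mask)
        out = tmp_path / "rose.svg"
        vk.rose_plot(dist, out)
        assert out.read_text().lstrip().startswith("<?xml")
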