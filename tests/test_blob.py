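"""Generalized moment method: clustering, constraints, centroids, moments,
orientation and streak geometry."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import ndimage

import subpix as sp
from subpix.blob import BlobConstraints, PixelBlob


def make_blob(coords, intensities=None, threshold=0.0):
    coords = np.asarray(coords)
    inten = (np.ones(len(coords)) if intensities is None
             else np.asarray(intensities, dtype=float))
    return PixelBlob(x=coords[:, 0], y=coords[:, 1], intensity=inten,
                     threshold_used=threshold)


def closure_oracle(coords, r):
    """O(n^2) transitive closure of the distance-<=r relation."""
    n = len(coords)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            d2 = ((coords[i][0] - coords[j][0]) ** 2
                  + (coords[i][1] - coords[j][1]) ** 2)
            if d2 <= r * r:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(coords[i])
    return {frozenset(g) for g in groups.values()}


def blob_partition(blobs):
    return {frozenset(zip(b.x.tolist(), b.y.tolist())) for b in blobs}


class TestExtractBlobs:
    def test_corner_adjacency_depends_on_radius(self):
        img = np.zeros((5, 5))
        img[1, 1] = img[2, 2] = 1.0  # diagonal pair, distance sqrt(2)
        assert len(sp.extract_blobs(img, 0.5, r=1.0)) == 2
        assert len(sp.extract_blobs(img, 0.5, r=1.5)) == 1

    def test_single_pixel_particle(self):
        img = np.zeros((5, 5))
        img[2, 3] = 0.8
        blobs = sp.extract_blobs(img, 0.5, r=1.0)
        assert len(blobs) == 1 and len(blobs[0]) == 1
        assert (blobs[0].x[0], blobs[0].y[0]) == (3, 2)

    def test_nothing_above_threshold_gives_empty_list(self):
        assert sp.extract_blobs(np.zeros((4, 4)), 0.5, r=1.0) == []

    def test_threshold_is_strict(self):
        img = np.full((3, 3), 0.5)
        assert sp.extract_blobs(img, 0.5, r=1.0) == []

    @pytest.mark.parametrize("r", [1.0, 1.5, 2.5])
    def test_matches_transitive_closure_oracle(self, r, rng):
        img = (rng.random((50, 50)) < 0.08).astype(float)
        blobs = sp.extract_blobs(img, 0.5, r=r)
        ys, xs = np.nonzero(img > 0.5)
        expected = closure_oracle(list(zip(xs.tolist(), ys.tolist())), r)
        assert blob_partition(blobs) == expected

    @pytest.mark.parametrize("r,connectivity", [(1.0, 1), (1.2, 1),
                                                (math.sqrt(2), 2), (1.5, 2)])
    def test_small_radii_reproduce_connected_labeling(self, r, connectivity, rng):
        img = (rng.random((40, 40)) < 0.2).astype(float)
        blobs = sp.extract_blobs(img, 0.5, r=r)
        structure = ndimage.generate_binary_structure(2, connectivity)
        labels, n = ndimage.label(img > 0.5, structure=structure)
        assert len(blobs) == n
        expected = set()
        for k in range(1, n + 1):
            ys, xs = np.nonzero(labels == k)
            expected.add(frozenset(zip(xs.tolist(), ys.tolist())))
        assert blob_partition(blobs) == expected

    def test_invalid_radius_rejected(self):
        with pytest.raises(ValueError):
            sp.extract_blobs(np.zeros((4, 4)), 0.1, r=0.0)


class TestFilterBlobs:
    def test_zero_minima_are_identity(self):
        blobs = [make_blob([(0, 0)]), make_blob([(3, 3), (4, 3)])]
        assert sp.filter_blobs(blobs, BlobConstraints()) == blobs

    def test_min_pixel_count(self):
        blobs = [make_blob([(0, 0)]), make_blob([(3, 3), (4, 3)])]
        kept = sp.filter_blobs(blobs, BlobConstraints(m_p=2))
        assert kept == [blobs[1]]

    def test_matches_predicate_oracle(self, rng):
        img = (rng.random((60, 60)) < 0.1) * rng.random((60, 60))
        blobs = sp.extract_blobs(img, 0.05, r=1.5)
        c = BlobConstraints(m_p=2, m_x=1.0, m_y=0.0, m_d=0.3, m_bd=0.3)
        kept = sp.filter_blobs(blobs, c)
        for b in blobs:
            xd = b.x.max() - b.x.min()
            yd = b.y.max() - b.y.min()
            dens = len(b) / (xd * yd) if xd * yd > 0 else math.inf
            expected = (len(b) >= 2 and xd >= 1.0 and dens >= 0.3
                        and b.intensity.mean() >= 0.3)
            assert (b in kept) == expected

    def test_invalid_constraints_rejected(self):
        with pytest.raises(ValueError):
            BlobConstraints(r=0)
        with pytest.raises(ValueError):
            BlobConstraints(m_p=-1)


class TestCentroid:
    def test_symmetric_block_centers_on_middle_pixel(self):
        coords = [(x, y) for x in (6, 7, 8) for y in (8, 9, 10)]
        assert sp.centroid(make_blob(coords)) == (7.0, 9.0)

    def test_weighted_two_pixel_example(self):
        b = make_blob([(0, 0), (1, 0)], intensities=[1.0, 3.0])
        xc, yc = sp.centroid(b, i_base=0.0)
        assert xc == pytest.approx(0.75)

    def test_base_intensity_shifts_weights(self):
        b = make_blob([(0, 0), (1, 0)], intensities=[2.0, 4.0])
        xc, _ = sp.centroid(b, i_base=1.0)  # weights 1 and 3
        assert xc == pytest.approx(0.75)

    def test_half_integer_particle_recovered_exactly(self):
        img = sp.render_particle(sp.ParticleTruth(19.5, 3.5, 1, 1), (12, 40))
        img /= img.max()
        blob = sp.extract_blobs(img, 1e-4, r=1.0)[0]
        xc, yc = sp.centroid(blob, i_base=0.0)
        assert xc == pytest.approx(19.5, abs=1e-9)
        assert yc == pytest.approx(3.5, abs=1e-9)

    def test_degenerate_weight_sum_rejected(self):
        b = make_blob([(0, 0)], intensities=[0.5])
        with pytest.raises(ValueError):
            sp.centroid(b, i_base=0.5)

    def test_zero_base_equals_raw_moment_centroid(self, rng):
        b = make_blob(list({(int(x), int(y)) for x, y in rng.integers(0, 20, (30, 2))}),
                      threshold=0.0)
        b.intensity = rng.random(len(b)) + 0.1
        ms = sp.moments(b, 1)
        xc, yc = sp.centroid(b, 0.0)
        assert xc == pytest.approx(ms.raw[(1, 0)] / ms.raw[(0, 0)], rel=1e-12)
        assert yc == pytest.approx(ms.raw[(0, 1)] / ms.raw[(0, 0)], rel=1e-12)


class TestMoments:
    def test_single_pixel_raw_moments(self):
        b = make_blob([(2, 3)], intensities=[5.0])
        ms = sp.moments(b, 1)
        assert ms.raw[(0, 0)] == 5.0
        assert ms.raw[(1, 0)] == 10.0
        assert ms.raw[(0, 1)] == 15.0

    def test_first_central_moments_vanish(self, rng):
        coords = list({(int(x), int(y)) for x, y in rng.integers(0, 15, (25, 2))})
        b = make_blob(coords, intensities=rng.random(len(coords)) + 0.05)
        ms = sp.moments(b, 3)
        assert abs(ms.central[(1, 0)]) < 1e-10
        assert abs(ms.central[(0, 1)]) < 1e-10

    def test_central_consistent_with_raw_shift_identities(self, rng):
        coords = list({(int(x), int(y)) for x, y in rng.integers(0, 12, (20, 2))})
        b = make_blob(coords, intensities=rng.random(len(coords)) + 0.1)
        ms = sp.moments(b, 2)
        m00, m10, m01 = ms.raw[(0, 0)], ms.raw[(1, 0)], ms.raw[(0, 1)]
        m20, m02, m11 = ms.raw[(2, 0)], ms.raw[(0, 2)], ms.raw[(1, 1)]
        assert ms.central[(2, 0)] == pytest.approx(m20 - m10 ** 2 / m00, rel=1e-9)
        assert ms.central[(0, 2)] == pytest.approx(m02 - m01 ** 2 / m00, rel=1e-9)
        assert ms.central[(1, 1)] == pytest.approx(m11 - m10 * m01 / m00, rel=1e-9)


class TestOrientation:
    def test_horizontal_row_of_pixels(self):
        b = make_blob([(x, 5) for x in range(6)])
        assert sp.orientation(sp.moments(b, 2)) == pytest.approx(0.0, abs=1e-9)

    def test_diagonal_is_45_degrees(self):
        b = make_blob([(k, k) for k in range(6)])
        assert sp.orientation(sp.moments(b, 2)) == pytest.approx(45.0)

    def test_degenerate_circular_blob_rejected(self):
        b = make_blob([(1, 0), (0, 1), (2, 1), (1, 2), (1, 1)])
        with pytest.raises(ValueError, match="undefined orientation"):
            sp.orientation(sp.moments(b, 2))

    @pytest.mark.parametrize("angle", [0, 20, 45, 70, 90])
    def test_rendered_streak_angle_recovered(self, angle):
        th = math.radians(angle)
        t = sp.ParticleTruth(25.3, 24.8, 1, 1,
                             v_x=15 * math.cos(th), v_y=15 * math.sin(th))
        img = sp.render_streak(t, (51, 51), 64)
        img /= img.max()
        blob = sp.extract_blobs(img, 0.5, r=1.5)[0]
        est = sp.orientation(sp.moments(blob, 2))
        assert sp.angle_difference_deg(est, angle) < 2.0


def invert(area, lm):
    """Drive the stadium inversion with exact analytic (A, l_m): a two-pixel
    blob at distance l_m carrying the desired area through intensity mode."""
    b = PixelBlob(x=np.array([0.0, lm]), y=np.zeros(2),
                  intensity=np.full(2, area / 2.0), threshold_used=0.0)
    return sp.streak_length(b, area_mode="intensity", plateau=1.0).length


class TestStreakLength:
    def test_still_disk_recovers_zero_length(self):
        # A = pi r^2, l_m = 2r: the quadratic's constant term vanishes
        geom = invert(28.274333882308138, 6.0)
        assert geom == pytest.approx(0.0, abs=1e-9)

    def test_stadium_inversion_exact(self):
        # r=2, l=10: A = 4 pi + 40, l_m = 14
        geom = invert(4 * math.pi + 40.0, 14.0)
        assert geom == pytest.approx(10.0, abs=1e-9)

    @given(st.floats(0.0, 40.0), st.floats(0.3, 6.0))
    def test_forward_model_inversion_identity(self, length, radius):
        area = math.pi * radius ** 2 + 2 * radius * length
        lm = length + 2 * radius
        assert invert(area, lm) == pytest.approx(length, abs=1e-7)

    def test_rendered_streak_lengths_track_truth(self):
        errors = {}
        for L in (5, 15, 21):
            t = sp.ParticleTruth(25.0, 25.0, 0.5, 0.5, v_x=float(L))
            img = sp.render_streak(t, (51, 51), 64)
            img /= img.max()
            blob = sp.extract_blobs(img, 0.5, r=1.5)[0]
            errors[L] = abs(sp.streak_length(blob).length - L)
        assert all(err < 3.0 for err in errors.values())

    def test_intensity_mode_requires_plateau(self):
        b = make_blob([(0, 0), (1, 0)], intensities=[0.5, 0.5])
        with pytest.raises(ValueError):
            sp.streak_length(b, area_mode="intensity")
        with pytest.warns(UserWarning, match="inconsistent"):
            g = sp.streak_length(b, area_mode="intensity", plateau=0.5)
        assert g.area == pytest.approx(2.0)
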