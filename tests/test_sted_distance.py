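"""Tests for STED preprocessing, boundary/puncta detection and distances."""

import math

import numpy as np
import pytest
from scipy.ndimage import label

from endokit import sted_distance as st
from endokit import synthetic_data as sd

PITCH = 30.0


def render_field(blobs, puncta=(), shape=(64, 64), psf_sigma=0.0, seed=0):
    spec = sd.GroundTruthField(
        reference_blobs=list(blobs),
        target_puncta=list(puncta),
        shape=shape,
        pixel_pitch_nm=PITCH,
        psf_sigma_nm=psf_sigma,
        noise="none",
        seed=seed,
    )
    images, _ = sd.make_sted_field(spec)
    return images


def full_roi(images):
    side = min(images["reference"].shape)
    return st.extract_rois(images, [(side // 2, side // 2)], side)[0]


def brute_force_signed_distance(point, vertices, n_samples=100_000):
    """Independent oracle: dense sampling of the closed contour plus an
    even-odd ray-casting inside test."""
    v = np.asarray(vertices, float)
    if not np.allclose(v[0], v[-1]):
        v = np.vstack([v, v[0]])
    seg = np.diff(v, axis=0)
    lengths = np.linalg.norm(seg, axis=1)
    total = lengths.sum()
    per_seg = np.maximum((lengths / total * n_samples).astype(int), 2)
    pts = np.vstack(
        [
            v[i] + np.linspace(0, 1, per_seg[i])[:, None] * seg[i]
            for i in range(len(seg))
        ]
    )
    d = np.min(np.linalg.norm(pts - np.asarray(point), axis=1))

    # even-odd ray casting along +x
    x, y = point
    inside = False
    for (x1, y1), (x2, y2) in zip(v[:-1], v[1:]):
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (y - y1) / (y2 - y1) * (x2 - x1)
            if x_cross > x:
                inside = not inside
    return -d if inside else d


class TestPreprocess:
    def test_uniform_image_is_fixed_point(self):
        img = st.Image2D(np.full((40, 40), 5.0), PITCH)
        out, _ = st.preprocess_image(img, st.gaussian_psf(60.0, PITCH))
        assert np.allclose(out.intensities, 5.0, atol=1e-9)

    def test_point_source_is_sharpened(self):
        images = render_field(
            [sd.GaussianBlob(975.0, 975.0, 1000.0, 60.0)], shape=(65, 65),
            psf_sigma=60.0,
        )
        img = images["reference"]
        out, _ = st.preprocess_image(img, st.gaussian_psf(60.0, PITCH))
        assert out.intensities.max() > img.intensities.max()

    def test_flux_conserved_and_nonnegative(self):
        images = render_field(
            [sd.GaussianBlob(700.0, 900.0, 800.0, 90.0),
             sd.GaussianBlob(1300.0, 1000.0, 500.0, 75.0)],
            shape=(65, 65), psf_sigma=60.0,
        )
        img = images["reference"]
        out, _ = st.preprocess_image(img, st.gaussian_psf(60.0, PITCH))
        ratio = out.intensities.sum() / img.intensities.sum()
        assert 0.99 <= ratio <= 1.01
        assert out.intensities.min() >= 0.0

    def test_psf_larger_than_image_rejected(self):
        img = st.Image2D(np.ones((9, 9)), PITCH)
        with pytest.raises(ValueError, match="larger"):
            st.preprocess_image(img, st.gaussian_psf(120.0, PITCH, radius_px=10))

    def test_zero_psf_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            st.PSF(np.zeros((5, 5)), PITCH)


class TestExtractRois:
    def test_window_pixel_count(self):
        images = render_field([sd.GaussianBlob(960.0, 960.0, 10.0, 90.0)])
        roi = st.extract_rois(images, [(32, 32)], 30)[0]
        assert roi.channels["reference"].size == 900

    def test_default_geometry_area(self):
        images = render_field([sd.GaussianBlob(960.0, 960.0, 10.0, 90.0)])
        roi = st.extract_rois(images, [(32, 32)], 30)[0]
        assert roi.area_um2 == pytest.approx(0.81)

    def test_border_center_skipped(self):
        images = render_field([sd.GaussianBlob(960.0, 960.0, 10.0, 90.0)])
        rois = st.extract_rois(images, [(0, 0), (32, 32)], 30)
        assert len(rois) == 1


class TestDetectActiveZones:
    def test_halfmax_contour_radius_of_gaussian(self):
        sigma = 3.0 * PITCH
        cx = cy = 32.5 * PITCH  # a pixel center
        images = render_field(
            [sd.GaussianBlob(cx, cy, 1000.0, sigma)], shape=(65, 65)
        )
        roi = full_roi(images)
        contours = st.detect_active_zones(roi, min_peak_intensity=100.0)
        assert len(contours) == 1
        radii = np.hypot(contours[0].vertices_nm[:, 0] - cx,
                         contours[0].vertices_nm[:, 1] - cy)
        expected = sigma * math.sqrt(2 * math.log(2))
        assert np.max(np.abs(radii - expected)) < 0.5 * PITCH

    def test_blob_touching_border_excluded(self):
        images = render_field(
            [sd.GaussianBlob(90.0, 975.0, 1000.0, 120.0)], shape=(65, 65)
        )
        roi = full_roi(images)
        assert st.detect_active_zones(roi, min_peak_intensity=100.0) == []

    def test_two_separated_blobs_two_contours(self):
        b1 = sd.GaussianBlob(600.0, 960.0, 1000.0, 75.0)
        b2 = sd.GaussianBlob(1400.0, 960.0, 800.0, 75.0)
        images = render_field([b1, b2], shape=(65, 65))
        roi = full_roi(images)
        contours = st.detect_active_zones(roi, min_peak_intensity=100.0)
        assert len(contours) == 2
        # brute-force check: the thresholded component of each peak is its own
        from shapely.geometry import Point

        arr = roi.channels["reference"]
        for c, blob in zip(sorted(contours, key=lambda c: c.peak_xy_nm[0]), (b1, b2)):
            labeled, _ = label(arr >= c.level)
            peak_px = (int(blob.y_nm / PITCH), int(blob.x_nm / PITCH))
            other = b2 if blob is b1 else b1
            other_px = (int(other.y_nm / PITCH), int(other.x_nm / PITCH))
            assert labeled[peak_px] != labeled[other_px]
            assert c.polygon().contains(Point(blob.x_nm, blob.y_nm))

    def test_flat_image_no_contours(self):
        img = {"reference": st.Image2D(np.full((30, 30), 3.0), PITCH)}
        roi = st.extract_rois(img, [(15, 15)], 30)[0]
        assert st.detect_active_zones(roi, min_peak_intensity=10.0) == []


class TestDetectPuncta:
    def test_subpixel_recovery_of_ground_truth(self):
        truth = [(505.0, 842.0), (1309.0, 651.0), (930.0, 1402.0)]
        images = render_field(
            [sd.GaussianBlob(960.0, 960.0, 1.0, 90.0)],
            puncta=[sd.PointSource(x, y, 500.0) for x, y in truth],
            shape=(65, 65), psf_sigma=60.0,
        )
        roi = full_roi(images)
        puncta = st.detect_puncta(roi, min_peak_intensity=50.0)
        assert len(puncta) == len(truth)
        for tx, ty in truth:
            err = min(
                math.hypot(p.x_nm - tx, p.y_nm - ty) for p in puncta
            )
            assert err < 0.5 * PITCH

    def test_close_pair_suppressed_to_one(self):
        images = render_field(
            [sd.GaussianBlob(960.0, 960.0, 1.0, 90.0)],
            puncta=[sd.PointSource(900.0, 960.0, 500.0),
                    sd.PointSource(990.0, 960.0, 500.0)],
            shape=(65, 65), psf_sigma=60.0,
        )
        roi = full_roi(images)
        puncta = st.detect_puncta(roi, min_separation_nm=150.0,
                                  min_peak_intensity=50.0)
        assert len(puncta) == 1

    def test_flat_image_empty(self):
        img = {"target": st.Image2D(np.full((30, 30), 2.0), PITCH)}
        roi = st.extract_rois(img, [(15, 15)], 30)[0]
        assert st.detect_puncta(roi, min_peak_intensity=5.0) == []


class TestSignedDistance:
    def circle_contour(self, cx, cy, r, n=256):
        th = np.linspace(0, 2 * math.pi, n, endpoint=False)
        verts = np.column_stack([cx + r * np.cos(th), cy + r * np.sin(th)])
        return st.Contour(verts, (cx, cy), 1.0, 0)

    def test_punctum_on_vertex_distance_zero(self):
        c = self.circle_contour(500.0, 500.0, 300.0)
        vx, vy = c.vertices_nm[17]
        rec = st.signed_boundary_distance(st.Punctum(vx, vy, 1.0), [c])
        assert rec.distance_nm == pytest.approx(0.0, abs=1e-9)

    def test_center_of_circle_is_minus_radius(self):
        c = self.circle_contour(500.0, 500.0, 300.0)
        rec = st.signed_boundary_distance(st.Punctum(500.0, 500.0, 1.0), [c])
        # polygonal approximation of the circle: inradius slightly below r
        assert rec.distance_nm == pytest.approx(-300.0, rel=1e-3)
        assert rec.distance_nm < 0

    def test_square_contour_matches_brute_force(self, rng):
        square = np.array(
            [[100.0, 100.0], [700.0, 100.0], [700.0, 700.0], [100.0, 700.0]]
        )
        contour = st.Contour(square, (400.0, 400.0), 1.0, 0)
        for _ in range(20):
            pt = rng.uniform(0, 800, size=2)
            rec = st.signed_boundary_distance(st.Punctum(pt[0], pt[1], 1.0), [contour])
            oracle = brute_force_signed_distance(pt, square)
            assert rec.distance_nm == pytest.approx(oracle, abs=0.1)

    def test_nearest_of_several_contours_used(self):
        near = self.circle_contour(300.0, 300.0, 100.0)
        far = st.Contour(self.circle_contour(2000.0, 2000.0, 100.0).vertices_nm,
                         (2000.0, 2000.0), 1.0, 1)
        rec = st.signed_boundary_distance(st.Punctum(500.0, 300.0, 1.0), [far, near])
        assert rec.contour_id == 0
        assert rec.distance_nm == pytest.approx(100.0, rel=1e-3)

    def test_empty_contour_list_rejected(self):
        with pytest.raises(ValueError):
            st.signed_boundary_distance(st.Punctum(0.0, 0.0, 1.0), [])


class TestColocalization:
    def test_no_guests_zero_host_fraction(self):
        c = TestSignedDistance().circle_contour(300.0, 300.0, 100.0)
        summary = st.colocalization_summary([c], [])
        assert summary["fraction_hosts_with_guest"] == 0.0

    def test_guests_at_host_centers_all_negative(self):
        helper = TestSignedDistance()
        hosts = [helper.circle_contour(300.0, 300.0, 100.0)]
        guests = [st.Punctum(300.0, 300.0, 1.0)]
        summary = st.colocalization_summary(hosts, guests)
        assert all(r.distance_nm < 0 for r in summary["records"])
        assert summary["fraction_guests_inside"] == 1.0

    def test_zero_hosts_reports_missing(self):
        summary = st.colocalization_summary([], [st.Punctum(1.0, 1.0, 1.0)])
        assert summary["fraction_hosts_with_guest"] is None
        assert summary["fraction_guests_inside"] is None


class TestEndToEnd:
    def test_distance_distribution_translation_invariant(self):
        base = [(600.0, 900.0), (1500.0, 900.0)]
        guests = [(700.0, 900.0), (1530.0, 980.0)]
        shift = 8 * PITCH  # whole-pixel rigid translation

        def distances(dx):
            images = render_field(
                [sd.GaussianBlob(x + dx, y, 1000.0, 90.0) for x, y in base],
                puncta=[sd.PointSource(x + dx, y, 500.0) for x, y in guests],
                shape=(80, 80), psf_sigma=60.0,
            )
            roi = full_roi(images)
            hosts = st.detect_active_zones(roi, min_peak_intensity=100.0)
            pts = st.detect_puncta(roi, min_peak_intensity=50.0)
            return sorted(
                st.signed_boundary_distance(p, hosts).distance_nm for p in pts
            )

        d0, d1 = distances(0.0), distances(shift)
        assert len(d0) == len(guests)
        assert np.allclose(d0, d1, atol=1e-6)

    def test_analyze_roi_schema(self):
        images, _ = sd.demo_colocalization_field(n_hosts=3, n_guests=3, n_inside=2)
        roi = full_roi(images)
        df = st.analyze_roi(roi, min_peak_intensity=100.0)
        assert list(df.columns) == [
            "roi_id", "punctum_id", "channel", "x_nm", "y_nm",
            "contour_id", "signed_distance_nm",
        ]
        assert len(df) == 3


def test_tiff_roundtrip(tmp_path):
    images = render_field([sd.GaussianBlob(960.0, 960.0, 10.0, 90.0)],
                          puncta=[sd.PointSource(500.0, 500.0, 5.0)],
                          psf_sigma=60.0)
    st.write_image_stack(images, tmp_path / "field.tif")
    back = st.read_image_stack(tmp_path / "field.tif")
    assert set(back) == {"reference", "target"}
    assert back["reference"].pixel_pitch_nm == PITCH
    assert np.allclose(back["target"].intensities,
                       images["target"].intensities, atol=1e-4)
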