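"""Segmentation, photometry, and lattice assignment against simulator truth."""

import math

import numpy as np
import pytest
from scipy.stats import spearmanr

import colonyscreen as cs
from colonyscreen.colony_quant import flag_merged
from colonyscreen.plate_layout import GridPosition


def disc_image(shape, centers, radius, height=200.0, background=10.0):
    img = np.full(shape, background)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    for cy, cx in centers:
        img[np.hypot(yy - cy, xx - cx) <= radius] = background + height
    return img


class TestSegment:
    def test_blank_image_has_no_components(self):
        rng = np.random.default_rng(0)
        flat = np.full((200, 200), 100.0)
        noisy = rng.normal(100.0, 3.0, size=(200, 200))
        assert cs.segment_colonies(flat).max() == 0
        assert cs.segment_colonies(noisy).max() == 0

    def test_noise_free_plate_yields_one_component_per_colony(self, rendered_small_plate):
        gt, rendered = rendered_small_plate
        proj = np.stack(list(rendered.images.values())).max(axis=0)
        labels = cs.segment_colonies(proj)
        assert labels.max() == gt.occupied_count

    def test_touching_colonies_merge_and_get_flagged(self):
        # two discs closer than 2r fuse into one component spanning two nodes
        img = disc_image((60, 80), [(30, 30), (30, 42)], radius=8)
        labels = cs.segment_colonies(img)
        assert labels.max() == 1
        records = cs.measure_colonies(labels, {"b": img})
        flag_merged(records, pitch_px=12.0)
        assert "merged" in records[0].flags

    def test_count_invariant_under_linear_rescaling(self):
        img = disc_image((100, 150), [(30, 30), (30, 90), (70, 60)], radius=6)
        rng = np.random.default_rng(1)
        img = img + rng.normal(0, 1.0, img.shape)
        assert cs.segment_colonies(img).max() == 3
        assert cs.segment_colonies(img * 7.3 + 55.0).max() == 3

    def test_non_2d_input_rejected(self):
        with pytest.raises(ValueError, match="2-D"):
            cs.segment_colonies(np.zeros((4, 5, 6)))

    def test_min_area_filter(self):
        img = disc_image((50, 50), [(25, 25)], radius=1.5)  # ~9 px disc
        assert cs.segment_colonies(img, min_area_px=5).max() == 1
        assert cs.segment_colonies(img, min_area_px=50).max() == 0


class TestMeasure:
    def test_uniform_offset_invariance(self):
        img = disc_image((60, 60), [(30, 30)], radius=6)
        labels = cs.segment_colonies(img)
        for mode in ("local-median", "global"):
            base = cs.measure_colonies(labels, {"b": img}, background=mode)
            shifted = cs.measure_colonies(labels, {"b": img + 37.0}, background=mode)
            assert shifted[0].intensities["b"] == pytest.approx(
                base[0].intensities["b"], rel=1e-6
            )

    def test_disc_area_near_pi_r_squared(self):
        for r in (5, 8, 12):
            img = disc_image((80, 80), [(40, 40)], radius=r)
            labels = cs.segment_colonies(img)
            rec = cs.measure_colonies(labels, {"b": img})[0]
            assert rec.area_px == pytest.approx(math.pi * r * r, rel=0.05)

    def test_noise_free_intensity_matches_truth(self, quantified_small_plate):
        # measured background-subtracted intensity = brightness * gain * band
        # fraction within 1%
        gt, rendered, records, _, _, _ = quantified_small_plate
        truth = {(s.row, s.col): s for s in gt.sites}
        fractions = {
            v: {b.name: cs.band_intensity(spec, b) for b in cs.DEFAULT_BANDS}
            for v, spec in cs.REFERENCE_SPECTRA.items()
        }
        checked = 0
        for rec in records:
            site = truth[(rec.grid_pos.row, rec.grid_pos.col)]
            for band_name, got in rec.intensities.items():
                want = sum(
                    b * rendered.optics.gain * fractions[v][band_name]
                    for v, b in zip(site.variant_ids, site.brightnesses)
                )
                if want > 50.0:
                    assert got == pytest.approx(want, rel=0.01)
                    checked += 1
        assert checked > 100

    def test_missing_band_shape_rejected(self):
        labels = np.zeros((10, 10), dtype=np.int32)
        with pytest.raises(ValueError, match="shape"):
            cs.measure_colonies(labels, {"b": np.zeros((5, 5))})


class TestAssign:
    def test_full_noise_free_plate_assigns_everything(self, quantified_small_plate):
        gt, _, records, unoccupied, transform, qc = quantified_small_plate
        assert unoccupied == []
        assert qc["n_assigned"] == gt.occupied_count
        got = {(r.grid_pos.row, r.grid_pos.col) for r in records}
        assert got == {(s.row, s.col) for s in gt.sites}
        assert transform.median_residual_px < 0.5

    def test_unoccupied_bookkeeping_at_partial_viability(self, small_layout, noiseless_optics):
        gt = cs.sample_ground_truth(small_layout, viability=0.7, doublet_rate=0.0, seed=2)
        rendered = cs.render_plate(gt, optics=noiseless_optics, seed=2)
        records, unoccupied, _, _ = cs.quantify_plate(
            rendered.images, small_layout, pixel_um=noiseless_optics.pixel_um
        )
        assert len(unoccupied) == small_layout.n_points - gt.occupied_count
        truth_empty = {(p.row, p.col) for p in small_layout.positions()} - {
            (s.row, s.col) for s in gt.sites
        }
        assert {(p.row, p.col) for p in unoccupied} == truth_empty

    def test_round_trip_brightness_ranking(self, quantified_small_plate):
        # simulate -> segment -> measure -> assign preserves the ordering of
        # total in-band emission (brightness x the variant's summed band
        # fractions, since the filter set samples the two spectra unequally)
        gt, _, records, _, _, _ = quantified_small_plate
        frac_sum = {
            v: sum(cs.band_intensity(spec, b) for b in cs.DEFAULT_BANDS)
            for v, spec in cs.REFERENCE_SPECTRA.items()
        }
        truth = {
            (s.row, s.col): sum(
                b * frac_sum[v] for v, b in zip(s.variant_ids, s.brightnesses)
            )
            for s in gt.sites
        }
        pairs = [
            (truth[(r.grid_pos.row, r.grid_pos.col)], sum(r.intensities.values()))
            for r in records
        ]
        rho, _ = spearmanr(*zip(*pairs))
        assert rho > 0.99

    def test_jittered_centroids_mostly_assign_correctly(self, small_layout):
        # centroid jitter SD = pitch/10 -> >= 99% of colonies snap to the
        # right node (Monte-Carlo at fixed seed, large synthetic plate)
        layout = cs.PlateLayout(40, 60, pitch_um=500.0)
        pixel_um, pitch_px = 25.0, 20.0
        rng = np.random.default_rng(9)
        records = []
        for i, p in enumerate(layout.positions()):
            x = p.col * pitch_px + rng.normal(0, pitch_px / 10)
            y = p.row * pitch_px + rng.normal(0, pitch_px / 10)
            records.append(
                cs.ColonyRecord(i + 1, (float(x), float(y)), 50, {"b": 1.0})
            )
        assigned, _, _ = cs.assign_to_grid(records, layout, pixel_um)
        correct = sum(
            1
            for rec, p in zip(assigned, layout.positions())
            if rec.grid_pos is not None and (rec.grid_pos.row, rec.grid_pos.col) == (p.row, p.col)
        )
        assert correct / layout.n_points >= 0.99

    def test_conflicting_colonies_flagged(self, small_layout):
        pitch_px = 20.0
        records = []
        for i, p in enumerate(small_layout.positions()):
            records.append(
                cs.ColonyRecord(i + 1, (p.col * pitch_px, p.row * pitch_px), 50, {"b": 1.0})
            )
        # an extra colony close to node (0, 0) must lose the conflict
        records.append(cs.ColonyRecord(99, (3.0, 3.0), 50, {"b": 1.0}))
        assigned, unoccupied, _ = cs.assign_to_grid(records, small_layout, 25.0)
        assert unoccupied == []
        assert "conflict" in assigned[-1].flags

    def test_too_few_colonies_rejected(self, small_layout):
        records = [cs.ColonyRecord(1, (0.0, 0.0), 10, {"b": 1.0})]
        with pytest.raises(cs.GridFitError):
            cs.assign_to_grid(records, small_layout, 25.0)

    def test_garbage_centroids_fail_the_fit(self, small_layout):
        # centroids scattered uniformly over the plate bear no lattice
        # structure: the median nearest-node residual must reject the fit
        rng = np.random.default_rng(3)
        records = [
            cs.ColonyRecord(i, (float(x), float(y)), 10, {"b": 1.0})
            for i, (x, y) in enumerate(
                rng.uniform((0, 0), (220, 140), size=(60, 2))
            )
        ]
        with pytest.raises(cs.GridFitError):
            cs.assign_to_grid(records, small_layout, 25.0)


def test_mean_colony_area_decreases_with_density():
    # render plates across the printable density range; measured mean area
    # must be monotone non-increasing in matrix density
    mean_areas = []
    for d in (7.0, 44.0, 89.0, 174.0):
        # choose the pitch that realises density d on a 6x9 grid
        n_rows, n_cols = 6, 9
        pitch_um = math.sqrt(
            n_rows * n_cols * 1e8 / (d * (n_rows - 1) * (n_cols - 1))
        )
        layout = cs.PlateLayout(n_rows, n_cols, pitch_um=pitch_um)
        gt = cs.sample_ground_truth(layout, viability=1.0, doublet_rate=0.0, seed=4)
        optics = cs.OpticsModel(psf_sigma_px=0.0, background_level=20.0,
                                read_noise_sd=0.0, shot_noise=False)
        rendered = cs.render_plate(gt, optics=optics, seed=4)
        records, _, _, _ = cs.quantify_plate(rendered.images, layout, optics.pixel_um)
        mean_areas.append(np.mean([r.area_px for r in records]))
    assert all(a >= b for a, b in zip(mean_areas, mean_areas[1:]))
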