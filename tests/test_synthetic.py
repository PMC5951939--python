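"""Unit tests for the synthetic well generator."""

import numpy as np
import pytest

from spheroquant import (
    SimConfig,
    TreatmentEffect,
    generate_assay_readouts,
    generate_ground_truth,
    render_tiles,
)
from spheroquant.synthetic import (
    PlacementError,
    render_field,
    true_cell_count,
)


def vol(o):
    return (4.0 / 3.0) * np.pi * o.radius_um**3


class TestGroundTruth:
    def test_empty_well(self):
        truth = generate_ground_truth(SimConfig(n_spheroids=0, debris_count=0))
        assert truth.objects == []

    def test_identity_effect_matches_untreated_draw(self):
        cfg = SimConfig(seed=5, n_spheroids=30)
        base = generate_ground_truth(cfg)
        same = generate_ground_truth(cfg, TreatmentEffect("X", volume_fold=1.0))
        assert [o.radius_um for o in base.objects] == [o.radius_um for o in same.objects]

    def test_volume_fold_scales_paired_mean_volume(self):
        # treated arm shares the base draw, so the mean-volume ratio is exact
        cfg = SimConfig(seed=7)
        ctrl = generate_ground_truth(cfg, TreatmentEffect("CTR", 1.0))
        trt = generate_ground_truth(cfg, TreatmentEffect("TRT", 1.0 / 3.0))
        ratio = np.mean([vol(o) for o in trt.spheroids()]) / np.mean(
            [vol(o) for o in ctrl.spheroids()]
        )
        assert ratio == pytest.approx(1.0 / 3.0, rel=0.01)

    def test_volume_fold_conserves_object_count(self):
        cfg = SimConfig(seed=3, n_spheroids=40, debris_count=10)
        a = generate_ground_truth(cfg, TreatmentEffect("A", 1.0))
        b = generate_ground_truth(cfg, TreatmentEffect("B", 0.2))
        assert len(a.objects) == len(b.objects)

    def test_size_classes_partition_at_50um(self):
        truth = generate_ground_truth(SimConfig(seed=2, n_spheroids=60, debris_count=25))
        for o in truth.objects:
            if o.klass == "spheroid":
                assert 2 * o.radius_um >= 50.0
            else:
                assert 2 * o.radius_um < 50.0

    def test_nonfused_spheroids_do_not_overlap(self):
        truth = generate_ground_truth(SimConfig(seed=4, n_spheroids=80))
        objs = truth.spheroids()
        for i, a in enumerate(objs):
            for b in objs[i + 1 :]:
                d = np.hypot(a.center_x_um - b.center_x_um, a.center_y_um - b.center_y_um)
                assert d > a.radius_um + b.radius_um

    def test_fused_pairs_overlap_within_declared_band(self):
        truth = generate_ground_truth(
            SimConfig(seed=9, n_spheroids=40, fused_fraction=0.3)
        )
        by_id = {o.object_id: o for o in truth.objects}
        pairs = [
            (o, by_id[o.fused_with])
            for o in truth.spheroids()
            if o.fused_with is not None and o.object_id < o.fused_with
        ]
        assert pairs
        for a, b in pairs:
            d = np.hypot(a.center_x_um - b.center_x_um, a.center_y_um - b.center_y_um)
            depth = a.radius_um + b.radius_um - d
            rmin = min(a.radius_um, b.radius_um)
            assert 0.1 * rmin <= depth <= 0.4 * rmin + 1e-9

    def test_kill_fraction_flags_dead(self):
        truth = generate_ground_truth(
            SimConfig(seed=6, n_spheroids=40), TreatmentEffect("T", 1.0, 0.5)
        )
        dead = [o for o in truth.spheroids() if not o.alive]
        assert len(dead) == 20

    def test_overcrowded_field_raises_with_density_message(self):
        cfg = SimConfig(
            seed=0, n_spheroids=400, well_width_um=1500.0, well_height_um=1500.0,
            tile_rows=2, tile_cols=2,
        )
        with pytest.raises(PlacementError, match="crowded"):
            generate_ground_truth(cfg, max_tries=200)

    def test_determinism(self):
        cfg = SimConfig(seed=42, n_spheroids=20, debris_count=5)
        eff = TreatmentEffect("T", 0.5, 0.2)
        t1 = generate_ground_truth(cfg, eff)
        t2 = generate_ground_truth(cfg, eff)
        assert t1.objects == t2.objects

    def test_json_round_trip(self, tmp_path):
        truth = generate_ground_truth(SimConfig(seed=8, n_spheroids=10))
        truth.to_json(tmp_path / "gt.json")
        back = type(truth).from_json(tmp_path / "gt.json")
        assert back.objects == truth.objects
        assert back.config == truth.config


class TestConfigValidation:
    def test_rejects_nonpositive_scale(self):
        with pytest.raises(ValueError):
            SimConfig(um_per_px=0.0)

    def test_rejects_distribution_without_support_above_50um(self):
        with pytest.raises(ValueError):
            SimConfig(diameter_max_um=40.0)

    def test_warns_on_unusual_overlap(self):
        with pytest.warns(UserWarning, match="overlap"):
            SimConfig(overlap_frac=0.05)


class TestRendering:
    def test_noiseless_single_spheroid_is_bimodal(self):
        cfg = SimConfig(
            seed=1, n_spheroids=1, noise_sd=0.0, jitter_px=0,
            well_width_um=1000.0, well_height_um=1000.0, tile_rows=1, tile_cols=1,
        )
        truth = generate_ground_truth(cfg)
        tile = render_tiles(truth, cfg).tiles[0].raster
        vals, counts = np.unique(tile, return_counts=True)
        plateaus = vals[counts > 50]
        assert set(plateaus) == {
            int(round(0.25 * 65535)), int(round(0.60 * 65535))
        }

    def test_adjacent_tiles_duplicate_overlap_content(self):
        cfg = SimConfig(
            seed=2, n_spheroids=6, jitter_px=0, tile_rows=2, tile_cols=2,
            overlap_frac=0.25, well_width_um=2000.0, well_height_um=2000.0,
        )
        truth = generate_ground_truth(cfg)
        ts = render_tiles(truth, cfg)
        left = next(t for t in ts.tiles if (t.row, t.col) == (0, 0))
        right = next(t for t in ts.tiles if (t.row, t.col) == (0, 1))
        h, w = left.raster.shape
        shift = right.nominal_offset_px[0] - left.nominal_offset_px[0]
        ov = w - shift
        assert ov >= int(0.25 * w)  # at least the requested 25% of tile width
        assert np.array_equal(left.raster[:, shift:], right.raster[:, :ov])

    def test_render_determinism(self):
        cfg = SimConfig(seed=3, n_spheroids=10, tile_rows=2, tile_cols=2,
                        well_width_um=2000.0, well_height_um=2000.0)
        truth = generate_ground_truth(cfg)
        a = render_tiles(truth, cfg)
        b = render_tiles(truth, cfg)
        for ta, tb in zip(a.tiles, b.tiles):
            assert np.array_equal(ta.raster, tb.raster)
            assert ta.true_offset_px == tb.true_offset_px

    def test_rendered_centroid_matches_annotation(self):
        cfg = SimConfig(
            seed=4, n_spheroids=1, noise_sd=0.0, roughness=0.0, jitter_px=0,
            well_width_um=1200.0, well_height_um=1200.0, tile_rows=1, tile_cols=1,
        )
        truth = generate_ground_truth(cfg)
        obj = truth.spheroids()[0]
        field = render_field(truth, cfg)
        bg = 0.60 * 65535
        cov = np.clip((bg - field) / (bg - 0.25 * 65535), 0, 1)
        yy, xx = np.mgrid[0 : field.shape[0], 0 : field.shape[1]]
        cx = (cov * xx).sum() / cov.sum() * cfg.um_per_px
        cy = (cov * yy).sum() / cov.sum() * cfg.um_per_px
        half_px_um = 0.5 * cfg.um_per_px
        assert abs(cx - obj.center_x_um) < half_px_um
        assert abs(cy - obj.center_y_um) < half_px_um

    def test_dead_spheroids_render_as_subthreshold_fragments(self):
        cfg = SimConfig(
            seed=5, n_spheroids=1, noise_sd=0.0, jitter_px=0,
            well_width_um=1200.0, well_height_um=1200.0, tile_rows=1, tile_cols=1,
        )
        alive = render_field(generate_ground_truth(cfg, TreatmentEffect("A", 1.0, 0.0)), cfg)
        dead = render_field(generate_ground_truth(cfg, TreatmentEffect("B", 1.0, 1.0)), cfg)
        # the intact disk is gone: far fewer dark pixels, but not zero
        assert 0 < (dead < 30000).sum() < 0.5 * (alive < 30000).sum()


class TestAssayReadouts:
    def test_empty_well_reads_blank(self):
        truth = generate_ground_truth(SimConfig(n_spheroids=0))
        rlu, od = generate_assay_readouts(truth, noise_cv=0.0,
                                          blank_rlu=50.0, blank_od=0.04)
        assert rlu.value == pytest.approx(50.0)
        assert od.value == pytest.approx(0.04)

    def test_blank_subtracted_signal_is_linear_in_cell_number(self):
        cfg = SimConfig(seed=1, n_spheroids=10)
        t1 = generate_ground_truth(cfg)
        t2 = generate_ground_truth(cfg, TreatmentEffect("T", volume_fold=2.0))
        n1, n2 = true_cell_count(t1), true_cell_count(t2)
        assert n2 == pytest.approx(2 * n1)
        r1 = generate_assay_readouts(t1, noise_cv=0.0, blank_rlu=10.0)[0]
        r2 = generate_assay_readouts(t2, noise_cv=0.0, blank_rlu=10.0)[0]
        assert (r2.value - 10.0) / (r1.value - 10.0) == pytest.approx(2.0)

    def test_od_tracks_surviving_volume_by_direct_summation(self):
        cfg = SimConfig(seed=3, n_spheroids=20)
        ctrl = generate_ground_truth(cfg, TreatmentEffect("CTR", 1.0, 0.0))
        kill = generate_ground_truth(cfg, TreatmentEffect("K", 1.0, 0.5))
        od_c = generate_assay_readouts(ctrl, noise_cv=0.0, blank_od=0.0)[1].value
        od_k = generate_assay_readouts(kill, noise_cv=0.0, blank_od=0.0)[1].value
        expected = true_cell_count(kill) / true_cell_count(ctrl)
        assert od_k / od_c == pytest.approx(expected, rel=1e-12)

    def test_negative_constants_rejected(self):
        truth = generate_ground_truth(SimConfig(n_spheroids=0))
        with pytest.raises(ValueError):
            generate_assay_readouts(truth, atp_amol_per_cell=-1.0)

    def test_effector_atp_biases_luminescence_not_od(self):
        cfg = SimConfig(seed=5, n_spheroids=30)
        ctrl = generate_ground_truth(cfg, TreatmentEffect("CTR", 1.0, 0.0))
        trt = generate_ground_truth(cfg, TreatmentEffect("TRT", 1.0, 0.5))
        truth_viab = true_cell_count(trt) / true_cell_count(ctrl)

        def readout(t, eff):
            r = generate_assay_readouts(t, noise_cv=0.0, blank_rlu=0.0,
                                        blank_od=0.0, effector_cells=eff)
            return r[0].value, r[1].value

        rlu_c, od_c = readout(ctrl, 0.0)
        rlu_t, od_t = readout(trt, 5e4)  # effectors only in the co-culture well
        assert rlu_t / rlu_c > truth_viab  # ATP-based estimate biased upward
        assert od_t / od_c == pytest.approx(truth_viab, rel=1e-12)
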