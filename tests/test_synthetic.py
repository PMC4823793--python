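import numpy as np
import pytest

from ishquant.errors import GenerationError, ParameterError
from ishquant.points import SignalLabel
from ishquant.synthetic import (
    CorePrototype,
    DiskMask,
    GroundTruth,
    SyntheticCoreSpec,
    generate_point_set,
    generate_slide,
    generate_training_set,
    render_core,
    spec_for_prototype,
)

FAST = dict(canvas_size=1280, core_radius=400.0, n_cells=160)


class TestPrototypeSpecs:
    def test_six_prototypes(self):
        assert len(CorePrototype) == 6

    @pytest.mark.parametrize(
        "proto,expected",
        [
            ("NON_DELETION", 1.0),
            ("HEMIZYGOUS_DELETION", 0.5),
            ("CELLULAR_HET_HOMOGENEOUS_GENOTYPE", 1.0),
        ],
    )
    def test_uniform_prototype_expected_ratio(self, proto, expected):
        truth = generate_point_set(spec_for_prototype(proto, seed=1, **FAST))
        assert truth.expected_global_ratio == pytest.approx(expected)

    def test_homozygous_deletion_keeps_benign_rim(self):
        truth = generate_point_set(spec_for_prototype("HOMOZYGOUS_DELETION", seed=2, **FAST))
        # centre region 0 copies, rim 2 copies -> low but nonzero ratio
        assert 0.0 < truth.expected_global_ratio <= 0.35
        assert set(truth.region_table.gene_copies) == {0, 2}

    def test_intratumour_het_half_planes(self):
        truth = generate_point_set(spec_for_prototype("INTRATUMOUR_HET", seed=3, **FAST))
        f = truth.frame
        cx = truth.mask.cx
        left = f[(f.region_id == 0)]
        right = f[(f.region_id == 1)]
        # regions are assigned by cell position; dots jitter within a cell
        pad = truth.spec.cell_radius
        assert (left.x < cx + pad).all() and (right.x >= cx - pad).all()
        # left side carries gene dots, right side none
        assert (left.true_label == "GENE").sum() > 50
        assert (right.true_label == "GENE").sum() == 0

    def test_geometry_region_count_validated(self):
        with pytest.raises(ParameterError):
            SyntheticCoreSpec(region_geometry="half_plane", gene_copies_per_region=(2,))

    def test_infeasible_packing_rejected(self):
        with pytest.raises(GenerationError):
            generate_point_set(
                SyntheticCoreSpec(n_cells=5000, core_radius=100.0, canvas_size=512)
            )


class TestPointSets:
    def test_realized_ratio_near_expected(self):
        truth = generate_point_set(spec_for_prototype("NON_DELETION", seed=4, **FAST))
        f = truth.frame
        g = (f.true_label == "GENE").sum() + (f.true_label == "GENE_CEP_MIXED").sum()
        c = (f.true_label == "CEP").sum() + (f.true_label == "GENE_CEP_MIXED").sum()
        # binomial loss hits both channels equally; 3 SE tolerance
        se = np.sqrt(1 / g + 1 / c)
        assert abs(g / c - 1.0) <= 3 * se

    def test_ratio_expectation_independent_of_loss(self):
        for loss in (0.0, 0.3):
            truth = generate_point_set(
                spec_for_prototype("HEMIZYGOUS_DELETION", seed=5, signal_loss_prob=loss, **FAST)
            )
            assert truth.expected_global_ratio == pytest.approx(0.5)

    def test_default_density_in_realistic_band(self):
        truth = generate_point_set(spec_for_prototype("NON_DELETION", seed=6))
        assert 1000 <= len(truth.points) <= 5000

    def test_points_inside_mask_with_cell_jitter_margin(self):
        truth = generate_point_set(spec_for_prototype("NON_DELETION", seed=7, **FAST))
        f = truth.frame
        pad = DiskMask(
            truth.mask.cx, truth.mask.cy, truth.mask.r + truth.spec.cell_radius + 1
        )
        assert pad.contains(f.x.values, f.y.values).all()

    def test_seeded_determinism(self):
        a = generate_point_set(spec_for_prototype("INTRATUMOUR_HET", seed=8, **FAST))
        b = generate_point_set(spec_for_prototype("INTRATUMOUR_HET", seed=8, **FAST))
        assert a.frame.equals(b.frame)


class TestRendering:
    def test_pixel_identical_rerender(self):
        spec = spec_for_prototype("NON_DELETION", seed=9, **FAST)
        truth = generate_point_set(spec)
        img_a = render_core(truth)
        img_b = render_core(generate_point_set(spec))
        np.testing.assert_array_equal(img_a.pixels, img_b.pixels)

    def test_zero_signal_core_yields_no_detections(self):
        from ishquant.detection import detect_signals

        spec = SyntheticCoreSpec(
            gene_copies_per_region=(0,),
            cep_copies=0,
            noise_density=0.0,
            stain_density=0.0,
            seed=10,
            **{**FAST, "n_cells": 10},
        )
        truth = generate_point_set(spec)
        assert len(truth.points) == 0
        img = render_core(truth, spec)
        assert len(detect_signals(img)) <= 5

    def test_single_core_slide_equals_render_core(self):
        spec = spec_for_prototype("NON_DELETION", seed=11, **FAST)
        img, slide_truth = generate_slide([[spec]])
        direct = render_core(generate_point_set(spec))
        np.testing.assert_array_equal(img.pixels, direct.pixels)
        assert len(slide_truth.points) == len(slide_truth.cores[0].points)

    def test_slide_truth_offsets(self):
        spec_a = spec_for_prototype("NON_DELETION", seed=12, **FAST)
        spec_b = spec_for_prototype("HEMIZYGOUS_DELETION", seed=13, **FAST)
        img, truth = generate_slide([[spec_a, spec_b]])
        assert img.shape == (1280, 2560)
        right = truth.cores[1].frame
        assert (right.x >= 1280).all()


class TestTrainingSet:
    def test_balance_and_labels(self, training_set):
        from collections import Counter

        counts = Counter(a.label for a in training_set)
        assert set(counts) == set(SignalLabel)
        assert all(v == 80 for v in counts.values())

    def test_crop_colours_match_labels(self, training_set):
        for want, pred in [(SignalLabel.GENE, "dark"), (SignalLabel.CEP, "red")]:
            ex = next(a for a in training_set if a.label is want)
            img = ex.image
            x, y = int(ex.point.x), int(ex.point.y)
            r, g, b = img.pixels[y, x].astype(int)
            if pred == "dark":
                assert r < 80 and g < 80 and b < 80
            else:
                assert r > 100 and r > 2 * g

    def test_too_few_crops_rejected(self):
        with pytest.raises(GenerationError):
            generate_training_set(crops_per_class=5)


class TestDiskMask:
    def test_contains_and_rasterize_agree(self, rng):
        m = DiskMask(60, 70, 30, canvas=(128, 128))
        raster = m.rasterize()
        xs = rng.uniform(0, 128, 500)
        ys = rng.uniform(0, 128, 500)
        # the raster is evaluated at integer pixel centres; skip the 1-px
        # annulus where the two discretizations legitimately disagree
        d = np.hypot(xs - 60, ys - 70)
        away = np.abs(d - 30) > 1.5
        np.testing.assert_array_equal(
            m.contains(xs, ys)[away], raster.contains(xs, ys)[away]
        )
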