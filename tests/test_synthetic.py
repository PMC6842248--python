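"""Determinism and planted-structure contracts of the data generators."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mycoscreen import synthetic
from mycoscreen.coexpression import spearman_rho


def two_modules(rho=0.9):
    return [
        synthetic.ModuleSpec("a", tuple(f"a{i}" for i in range(10)), rho),
        synthetic.ModuleSpec("b", tuple(f"b{i}" for i in range(10)), rho),
    ]


class TestExpressionGenerator:
    def test_noise_free_module_has_perfect_spearman(self):
        module = synthetic.ModuleSpec("m", tuple(f"m{i}" for i in range(10)), 0.9)
        matrix = synthetic.generate_expression_matrix(
            n_genes=20, n_conditions=30, modules=[module], noise_sd=0.0, seed=0
        )
        rows = [matrix.row(g) for g in module.member_genes]
        for x, y in itertools.combinations(rows, 2):
            assert spearman_rho(x, y) == pytest.approx(1.0)

    def test_between_module_correlation_is_null(self):
        """Independent latents: between-module |rho| stays at the null level."""
        cross_medians = []
        for seed in range(20):
            matrix = synthetic.generate_expression_matrix(
                n_genes=20,
                n_conditions=155,
                modules=two_modules(),
                noise_sd=0.3,
                seed=seed,
            )
            cross = [
                abs(spearman_rho(matrix.row(f"a{i}"), matrix.row(f"b{j}")))
                for i in range(10)
                for j in range(10)
            ]
            cross_medians.append(np.median(cross))
        assert max(cross_medians) < 0.3

    def test_within_module_spearman_near_target(self):
        matrix = synthetic.generate_expression_matrix(
            n_genes=20, n_conditions=155, modules=two_modules(0.9), noise_sd=0.3, seed=1
        )
        rhos = [
            spearman_rho(matrix.row(f"a{i}"), matrix.row(f"a{j}"))
            for i, j in itertools.combinations(range(10), 2)
        ]
        assert np.mean(rhos) == pytest.approx(0.9, abs=0.05)

    def test_determinism(self):
        args = dict(
            n_genes=50, n_conditions=20, modules=two_modules(), noise_sd=0.5, seed=7
        )
        first = synthetic.generate_expression_matrix(**args)
        second = synthetic.generate_expression_matrix(**args)
        assert first.gene_ids == second.gene_ids
        np.testing.assert_array_equal(first.values, second.values)

    def test_overlapping_modules_rejected(self):
        overlapping = [
            synthetic.ModuleSpec("a", ("g1", "g2"), 0.9),
            synthetic.ModuleSpec("b", ("g2", "g3"), 0.9),
        ]
        with pytest.raises(ValueError, match="share"):
            synthetic.generate_expression_matrix(10, 20, overlapping, 0.1, 0)

    def test_too_few_conditions_rejected(self):
        with pytest.raises(ValueError):
            synthetic.generate_expression_matrix(10, 4, [], 0.1, 0)


class TestAnnotationGenerator:
    def test_planted_term_exactly_on_module(self):
        genes = [f"g{i}" for i in range(1000)]
        module = synthetic.ModuleSpec("m", tuple(genes[:20]), 0.9, ("GO:X",))
        table = synthetic.generate_go_annotations(genes, [module], 50, 3, seed=0)
        with_term = set(table[table["term"] == "GO:X"]["gene"])
        assert with_term == set(genes[:20])

    def test_no_background_pool_gives_planted_terms_only(self):
        genes = [f"g{i}" for i in range(30)]
        module = synthetic.ModuleSpec("m", tuple(genes[:5]), 0.9, ("GO:X",))
        table = synthetic.generate_go_annotations(
            genes, [module], background_terms=0, terms_per_gene=1, seed=0
        )
        assert set(table["gene"]) == set(genes[:5])
        assert set(table["term"]) == {"GO:X"}

    def test_every_annotated_gene_has_a_term(self):
        genes = [f"g{i}" for i in range(100)]
        table = synthetic.generate_go_annotations(genes, [], 20, 2, seed=1)
        counts = table.groupby("gene").size()
        assert set(counts.index) == set(genes)
        assert (counts >= 1).all()

    def test_determinism(self):
        genes = [f"g{i}" for i in range(50)]
        a = synthetic.generate_go_annotations(genes, [], 30, 3, seed=9)
        b = synthetic.generate_go_annotations(genes, [], 30, 3, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            synthetic.generate_go_annotations([], [], 10, 1, seed=0)


class TestImageRenderer:
    def test_circle_ground_truth(self):
        spec = synthetic.ImageSpec(
            image_width_px=200,
            image_height_px=200,
            pixel_size_um=1.0,
            pellet_specs=(
                synthetic.EllipseSpec(center_um=(100, 100), major_um=100, minor_um=100),
            ),
        )
        image, truth = synthetic.render_culture_image(spec)
        assert truth.loc[0, "size_class"] == "pellet"
        rendered_area = (image > 0).sum() * spec.pixel_size_um**2
        assert rendered_area == pytest.approx(np.pi * 50**2, rel=0.03)

    def test_fragment_in_dispersed_window(self):
        spec = synthetic.ImageSpec(
            image_width_px=100,
            image_height_px=100,
            pixel_size_um=1.0,
            fragment_specs=(
                synthetic.FragmentSpec(center_um=(50, 50), area_um2=200.0),
            ),
        )
        image, truth = synthetic.render_culture_image(spec)
        assert truth.loc[0, "size_class"] == "dispersed"
        assert (image > 0).sum() == pytest.approx(200, rel=0.03)

    def test_empty_spec_blank_image(self):
        spec = synthetic.ImageSpec(50, 50, 1.0)
        image, truth = synthetic.render_culture_image(spec)
        assert not image.any()
        assert truth.empty

    def test_rendered_area_within_tolerance(self, culture_image):
        spec, image, truth = culture_image
        # per-object pixel areas recovered by an independent flood count
        from mycoscreen.morphology import label_structures

        masks = label_structures(image, spec.pixel_size_um)
        areas = sorted(m.n_pixels * spec.pixel_size_um**2 for m in masks)
        expected = sorted(truth["true_area_um2"])
        for got, want in zip(areas, expected):
            assert got == pytest.approx(want, rel=0.03)

    def test_overlapping_objects_rejected(self):
        spec = synthetic.ImageSpec(
            image_width_px=200,
            image_height_px=200,
            pixel_size_um=1.0,
            pellet_specs=(
                synthetic.EllipseSpec(center_um=(90, 100), major_um=80, minor_um=80),
                synthetic.EllipseSpec(center_um=(130, 100), major_um=80, minor_um=80),
            ),
        )
        with pytest.raises(ValueError, match="overlap"):
            synthetic.render_culture_image(spec)

    def test_out_of_bounds_object_rejected(self):
        spec = synthetic.ImageSpec(
            image_width_px=100,
            image_height_px=100,
            pixel_size_um=1.0,
            pellet_specs=(
                synthetic.EllipseSpec(center_um=(95, 50), major_um=40, minor_um=40),
            ),
        )
        with pytest.raises(ValueError, match="border"):
            synthetic.render_culture_image(spec)

    def test_determinism(self):
        spec = synthetic.example_image_spec(seed=33, n_pellets=2, n_fragments=2)
        first, truth_a = synthetic.render_culture_image(spec)
        second, truth_b = synthetic.render_culture_image(spec)
        np.testing.assert_array_equal(first, second)
        pd.testing.assert_frame_equal(truth_a, truth_b)


class TestFermentationGenerator:
    def test_zero_cv_returns_exact_means(self):
        spec = synthetic.example_dose_response_spec(seed=0, noise_cv=0.0)
        table = synthetic.generate_fermentation_table(spec)
        for row in table.itertuples(index=False):
            model = spec.effect_model[row.strain][row.dox_ug_ml]
            assert row.protein_mg == model["protein_mg"]
            assert row.citric_g_l == model["citric_g_l"]

    def test_citric_absent_at_low_dose_pattern(self):
        table = synthetic.generate_fermentation_table(
            synthetic.example_dose_response_spec(seed=1)
        )
        secg_low = table[(table.strain == "TC4.4") & (table.dox_ug_ml <= 0.2)]
        secg_high = table[(table.strain == "TC4.4") & (table.dox_ug_ml == 20.0)]
        assert (secg_low["citric_g_l"] == 0).all()
        assert (secg_high["citric_g_l"] > 0).all()

    def test_essential_gene_strains_lack_zero_dose(self):
        table = synthetic.generate_fermentation_table(
            synthetic.example_dose_response_spec(seed=2)
        )
        for strain in ("TC5.5", "TC6.1"):
            assert 0.0 not in set(table[table.strain == strain]["dox_ug_ml"])

    def test_noise_multiplier_unit_mean(self):
        model = {
            "s": {0.0: dict.fromkeys(
                ["protein_mg", "dry_weight_g", "citric_g_l",
                 "oxaloacetate_g_l", "glucose_depleted_g_l"], 10.0)}
        }
        spec = synthetic.DoseResponseSpec(
            strains=("s",), effect_model=model, dox_levels=(0.0,),
            replicate_count=4000, noise_cv=0.2, seed=3,
        )
        table = synthetic.generate_fermentation_table(spec)
        assert table["protein_mg"].mean() == pytest.approx(10.0, rel=0.02)
        assert table["protein_mg"].std() / 10.0 == pytest.approx(0.2, rel=0.1)

    def test_determinism_and_invalid_cv(self):
        spec = synthetic.example_dose_response_spec(seed=5)
        pd.testing.assert_frame_equal(
            synthetic.generate_fermentation_table(spec),
            synthetic.generate_fermentation_table(spec),
        )
        with pytest.raises(ValueError):
            synthetic.example_dose_response_spec(seed=5, noise_cv=-0.1)
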