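"""Synthetic measurement tables, section profiles and section images."""

import math
import warnings

import numpy as np
import pytest

from xylokinetics import (GenerativeParams, GroundTruth, ImageSpec,
                          extension_from_profile, generate_profile,
                          generate_section_image, generate_trajectory)

# exponential through the printed 7- and 21-DAG area means:
# k = ln(352557.62/1519.56)/14, a0 chosen so a(7 DAG) = 1519.56 um^2
K_ENDPOINT = math.log(352557.62 / 1519.56) / 14.0


class TestTrajectory:
    def test_zero_noise_is_exact_forward_model(self):
        p = GenerativeParams(cv_area=0.0, cv_height=0.0, count_noise=0.0,
                             n_reps=3)
        table = generate_trajectory(p, seed=0)
        for _, row in table.iterrows():
            t = row["dag"]
            assert row["area_mm2"] == pytest.approx(
                p.a0 * math.exp(p.k_A * t), rel=1e-12)
            assert row["cell_count"] == pytest.approx(
                p.N0 * math.exp(p.k_Ncount * t), rel=1e-12)
            assert row["extension_mm"] == pytest.approx(
                p.h0 * math.exp(p.k_h * t), rel=1e-12)

    def test_deterministic_for_fixed_seed(self):
        p = GenerativeParams(seed=42)
        t1 = generate_trajectory(p)
        t2 = generate_trajectory(p)
        assert t1.equals(t2)

    def test_endpoint_parameterisation_hits_21dag_mean(self):
        a0_um2 = 1519.56 * math.exp(-K_ENDPOINT * 7.0)
        p = GenerativeParams(a0=a0_um2 / 1e6, k_A=K_ENDPOINT,
                             cv_area=0.0, cv_height=0.0, count_noise=0.0,
                             n_reps=1)
        table = generate_trajectory(p, seed=0)
        a21_um2 = table.loc[table["dag"] == 21.0, "area_mm2"].iloc[0] * 1e6
        assert a21_um2 == pytest.approx(352557.62, rel=1e-3)

    def test_monte_carlo_means_converge_to_forward_model(self):
        p = GenerativeParams(cv_area=0.15, cv_height=0.15, count_noise=1.0,
                             n_reps=600)
        table = generate_trajectory(p, seed=3)
        for t in p.times:
            sub = table[table["dag"] == t]
            for col, truth in (
                ("area_mm2", p.a0 * math.exp(p.k_A * t)),
                ("extension_mm", p.h0 * math.exp(p.k_h * t)),
                ("cell_count", p.N0 * math.exp(p.k_Ncount * t)),
            ):
                mean = sub[col].mean()
                se = sub[col].std(ddof=1) / math.sqrt(len(sub))
                assert abs(mean - truth) < 3.0 * max(se, 1e-12), (col, t)

    @pytest.mark.parametrize("field,value", [
        ("a0", -1.0), ("N0", 0.0), ("h0", -0.5), ("cv_area", -0.1),
        ("n_reps", 0), ("times", (11.0, 7.0)),
    ])
    def test_invalid_params_name_field(self, field, value):
        with pytest.raises(ValueError):
            GenerativeParams(**{field: value})


class TestProfile:
    def test_presence_boundary(self):
        prof = generate_profile(12.0)
        last_true = prof.positions[prof.present].max()
        first_false = prof.positions[~prof.present].min()
        assert last_true <= 12.0 < first_false

    def test_zero_extension_all_absent(self):
        prof = generate_profile(0.0)
        assert not prof.present.any()
        assert extension_from_profile(prof) == 0.0

    def test_roundtrip_within_section_thickness(self):
        # 7-DAG printed extension 0.2805 cm = 2.805 mm; +-5 um sections
        recovered = extension_from_profile(generate_profile(2.805))
        assert abs(recovered - 2.805) <= 0.005

    def test_grid_matches_thickness(self):
        prof = generate_profile(1.0, section_thickness_um=5.0)
        steps = np.diff(prof.positions)
        np.testing.assert_allclose(steps, 0.005, rtol=1e-9)

    def test_negative_extension_rejected(self):
        with pytest.raises(ValueError):
            generate_profile(-1.0)


class TestSectionImage:
    def test_empty_canvas(self):
        img, gt = generate_section_image(ImageSpec(n_cells=0, seed=1))
        assert gt.true_count == 0
        assert not gt.label_map.any()
        assert np.all(np.abs(img.astype(float) - 200.0) < 30)

    def test_disjoint_cells_counted_in_truth(self):
        spec = ImageSpec(n_cells=10, touching_fraction=0.0, noise_sd=0.0,
                         seed=2)
        img, gt = generate_section_image(spec)
        assert gt.true_count == 10
        assert len(np.unique(gt.label_map)) == 11  # background + 10 cells

    def test_byte_identical_for_fixed_seed(self):
        spec = ImageSpec(seed=11)
        i1, g1 = generate_section_image(spec)
        i2, g2 = generate_section_image(spec)
        assert np.array_equal(i1, i2)
        assert np.array_equal(g1.label_map, g2.label_map)

    def test_impossible_packing_warns_not_lies(self):
        spec = ImageSpec(width=96, height=96, n_cells=200, seed=3)
        with pytest.warns(UserWarning):
            img, gt = generate_section_image(spec)
        assert gt.true_count < 200
        assert gt.true_count == len(np.unique(gt.label_map)) - 1

    def test_ground_truth_invariant_enforced(self):
        with pytest.raises(ValueError):
            GroundTruth(label_map=np.zeros((4, 4), dtype=int), true_count=1)

    def test_wall_darker_than_lumen_required(self):
        with pytest.raises(ValueError):
            ImageSpec(wall_intensity=250.0, lumen_intensity=100.0)

    def test_truth_always_matches_labels(self):
        for seed in (5, 6, 7):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, gt = generate_section_image(ImageSpec(seed=seed, n_cells=80))
            assert gt.true_count == len(np.unique(gt.label_map)) - 1
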