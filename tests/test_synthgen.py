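import math

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage as ndi

from lysoquant import synthgen
from lysoquant.synthgen import (
    KineticsProfile,
    MarkerCurve,
    PlateDesign,
    SilacSimConfig,
    SimulationConfig,
    default_plate_design,
    generate_field,
    generate_plate,
    generate_silac_dataset,
    generate_timecourse,
    protein_id,
)


class TestSimulationConfig:
    def test_invalid_shape_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(image_shape=(0, 64))

    def test_invalid_pixel_size_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(pixel_size=-1.0)

    def test_positivity_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(positivity_fraction={"ubiquitin_FK2": 1.2})

    def test_roundtrip_dict(self):
        cfg = SimulationConfig(rng_seed=7, n_cells=3)
        assert SimulationConfig.from_dict(cfg.to_dict()) == cfg


class TestGenerateField:
    def test_empty_field(self):
        cfg = SimulationConfig(rng_seed=0, n_cells=0)
        field, truth = generate_field(cfg)
        assert truth.cells == [] and truth.vesicles == []
        # image is background + noise only: nothing near saturation, and the
        # median sits at the configured background offset
        img = field.channel("lysosome")
        assert abs(np.median(img) - cfg.background["lysosome"]) < 15

    def test_determinism(self, small_config):
        f1, t1 = generate_field(small_config)
        f2, t2 = generate_field(small_config)
        for role in f1.channels:
            np.testing.assert_array_equal(f1.channels[role], f2.channels[role])
        assert t1.to_dict() == t2.to_dict()

    def test_seed_changes_output(self, small_config):
        cfg2 = SimulationConfig.from_dict({**small_config.to_dict(), "rng_seed": 99})
        f1, _ = generate_field(small_config)
        f2, _ = generate_field(cfg2)
        assert not np.array_equal(f1.channels["nucleus"], f2.channels["nucleus"])

    def test_realized_fraction_binomial_bound(self):
        # f = 0.5 over >= 500 vesicles: |realized - 0.5| <= 3 sqrt(0.25/n)
        cfg = SimulationConfig(
            rng_seed=42,
            image_shape=(512, 512),
            n_cells=25,
            vesicles_per_cell_mean=22.0,
            positivity_fraction={"ubiquitin_FK2": 0.5},
        )
        _, truth = generate_field(cfg)
        n = len(truth.vesicles)
        assert n >= 500
        realized = truth.realized_fraction("ubiquitin_FK2")
        assert abs(realized - 0.5) <= 3 * math.sqrt(0.25 / n)

    def test_vesicle_parents_exist_and_inside_cell(self, small_field):
        _, truth = small_field
        cell_ids = {c.cell_id for c in truth.cells}
        cell_map = truth.cell_label_map((256, 256))
        for v in truth.vesicles:
            assert v.cell_id in cell_ids
            r, c = int(v.center[0]), int(v.center[1])
            assert cell_map[r, c] == v.cell_id

    def test_conservation_zero_noise(self, noiseless_field):
        # count connected components at half amplitude in the noise-free
        # lysosome channel; non-overlapping placement makes this exact
        field, truth = noiseless_field
        img = field.channel("lysosome")
        cfg_amp = 4000.0
        bg = 100.0
        _, n = ndi.label(img > bg + cfg_amp / 2)
        assert n == len(truth.vesicles)

    def test_override_scalar(self):
        cfg = SimulationConfig(rng_seed=3, n_cells=10, vesicles_per_cell_mean=15)
        _, truth = generate_field(cfg, overrides={"ubiquitin_FK2": 0.0})
        assert truth.realized_fraction("ubiquitin_FK2") == 0.0
        _, truth = generate_field(cfg, overrides={"ubiquitin_FK2": 1.0})
        assert truth.realized_fraction("ubiquitin_FK2") == 1.0

    def test_override_per_cell(self):
        cfg = SimulationConfig(rng_seed=3, n_cells=6, vesicles_per_cell_mean=15)
        _, truth = generate_field(cfg, overrides={"ubiquitin_FK2": {1: 1.0}})
        for v in truth.vesicles:
            if v.cell_id == 1:
                assert v.positive_for["ubiquitin_FK2"]

    def test_override_bad_role(self, small_config):
        with pytest.raises(ValueError, match="non-secondary"):
            generate_field(small_config, overrides={"nucleus": 0.5})


class TestPlateDesign:
    def test_default_counts(self):
        design = default_plate_design()
        damaged_lib = [
            w
            for w in design.wells
            if w.treatment == "damaged" and w.gene not in synthgen.CONTROL_GENES
        ]
        assert len(damaged_lib) == 37 * 4
        assert len({w.well_id for w in design.wells}) == len(design.wells)

    def test_single_reagents(self):
        design = default_plate_design(n_genes=3, reagent="singles")
        reagents = {w.reagent for w in design.wells if w.gene == "E2G01"}
        assert reagents == {"single_1", "single_2", "single_3", "single_4"}

    def test_duplicate_well_rejected(self):
        w = synthgen.WellSpec("A01", "G1", "pool", "damaged", 1)
        with pytest.raises(ValueError, match="duplicate"):
            PlateDesign(wells=[w, w])

    def test_frame_roundtrip(self):
        design = default_plate_design(n_genes=4)
        again = PlateDesign.from_frame(design.to_frame())
        assert again == design


class TestGeneratePlate:
    def test_unknown_gene_named_in_error(self, small_config):
        design = default_plate_design(n_genes=4)
        with pytest.raises(ValueError, match="NOSUCH"):
            generate_plate(design, small_config, gene_effects={"NOSUCH": 0.5})

    def test_effect_arithmetic(self, small_config):
        # effect 0.25 on baseline 0.8 -> planted fraction 0.2 (zero well noise)
        design = default_plate_design(n_genes=4)
        plate = generate_plate(
            design,
            small_config,
            gene_effects={"E2G01": 0.25},
            well_fraction_sd=0.0,
        )
        for w in design.wells:
            if w.gene == "E2G01":
                assert plate.planted_fraction[w.well_id]["ubiquitin_FK2"] == pytest.approx(0.2)

    def test_null_plate_all_wells_same_distribution(self, small_config):
        design = default_plate_design(n_genes=6)
        plate = generate_plate(design, small_config, well_fraction_sd=0.0)
        fracs = {
            plate.planted_fraction[w.well_id]["ubiquitin_FK2"]
            for w in design.wells
            if w.treatment == "damaged" and w.gene not in synthgen.CONTROL_GENES
        }
        assert fracs == {0.8}

    def test_metric_dataset_counts(self, small_config):
        design = default_plate_design()
        plate = generate_plate(design, small_config, cells_per_well=30)
        df = plate.cell_table
        assert df["well_id"].nunique() == len(design.wells)
        assert (df.groupby("well_id").size() >= 30).all()
        # 37 genes x 4 replicates plus control wells
        lib_wells = df["well_id"].nunique() - sum(
            w.gene in synthgen.CONTROL_GENES for w in design.wells
        )
        assert lib_wells == 37 * 4

    def test_effect_monotonicity(self, small_config):
        design = default_plate_design(n_genes=4)
        planted = []
        for effect in (0.2, 0.5, 0.8, 1.0):
            plate = generate_plate(
                design, small_config, gene_effects={"E2G02": effect}, well_fraction_sd=0.0
            )
            vals = [
                plate.planted_fraction[w.well_id]["ubiquitin_FK2"]
                for w in design.wells
                if w.gene == "E2G02"
            ]
            planted.append(np.mean(vals))
        assert all(a < b for a, b in zip(planted, planted[1:]))

    def test_true_hits_from_cutoff(self, small_config):
        design = default_plate_design(n_genes=5)
        plate = generate_plate(
            design, small_config, gene_effects={"E2G01": 0.4, "E2G02": 0.9}
        )
        assert plate.true_hits == ["E2G01"]

    def test_image_fidelity_produces_fields(self):
        cfg = SimulationConfig(rng_seed=1, n_cells=4, image_shape=(128, 128))
        design = default_plate_design(n_genes=1, replicates=1, n_control_wells=1, n_untreated_wells=0)
        plate = generate_plate(design, cfg, fidelity="image")
        assert plate.fields is not None and len(plate.fields) == len(design.wells)
        for field, truth in plate.fields.values():
            assert field.shape == (128, 128)
            assert truth.cells

    def test_bad_fidelity(self, small_config):
        design = default_plate_design(n_genes=2)
        with pytest.raises(ValueError, match="fidelity"):
            generate_plate(design, small_config, fidelity="pixel")


class TestKinetics:
    def test_default_profile_ordering(self):
        prof = KineticsProfile()
        assert prof.curves["ubiquitin_K63"].peak_time < prof.curves["ubiquitin_K48"].peak_time
        assert prof.curves["gal3"].peak_time < prof.curves["poi"].peak_time

    def test_baseline_at_t0(self):
        prof = KineticsProfile()
        fracs = prof.fractions_at(0.0)
        for role, curve in prof.curves.items():
            assert fracs[role] == pytest.approx(curve.baseline)

    def test_k63_planted_max_at_60(self):
        prof = KineticsProfile()
        vals = {t: prof.curves["ubiquitin_K63"].fraction(t) for t in prof.time_points}
        assert max(vals, key=vals.get) == 60.0

    def test_k48_planted_max_in_late_window(self):
        prof = KineticsProfile()
        vals = {t: prof.curves["ubiquitin_K48"].fraction(t) for t in prof.time_points}
        assert max(vals, key=vals.get) in (120.0, 180.0)

    def test_fractions_stay_in_unit_interval(self):
        prof = KineticsProfile()
        for t in np.linspace(0, 300, 61):
            for f in prof.fractions_at(float(t)).values():
                assert 0.0 <= f <= 1.0

    def test_out_of_range_curve_rejected(self):
        bad = MarkerCurve(baseline=0.5, onset=0.0, peak_time=60.0, peak_fraction=1.8)
        with pytest.raises(ValueError, match="outside"):
            bad.fraction(60.0)

    def test_unsorted_time_points_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            KineticsProfile(time_points=(60.0, 30.0))

    def test_generate_timecourse_planted_fractions(self):
        cfg = SimulationConfig(rng_seed=5, n_cells=10, vesicles_per_cell_mean=20)
        prof = KineticsProfile()
        series = generate_timecourse(prof, cfg)
        assert [t for t, _, _ in series] == list(prof.time_points)
        # realized marker fractions track the curve within binomial noise
        for t, _, truth in series:
            n = len(truth.vesicles)
            for role in ("ubiquitin_K63", "ubiquitin_K48"):
                planted = prof.curves[role].fraction(t)
                bound = 4 * math.sqrt(max(planted * (1 - planted), 0.01) / n)
                assert abs(truth.realized_fraction(role) - planted) <= bound


class TestSilac:
    def test_degenerate_null(self):
        cfg = SilacSimConfig(rng_seed=0, n_proteins=20, null_log2_sd=0.0)
        table, truth = generate_silac_dataset(cfg)
        for k in range(1, 5):
            np.testing.assert_allclose(
                np.log2(table[f"intensity_H_{k}"] / table[f"intensity_L_{k}"]), 0.0, atol=1e-12
            )

    def test_true_ratio_four_gives_log2_two(self):
        pid = protein_id(0)
        cfg = SilacSimConfig(
            rng_seed=0, n_proteins=5, null_log2_sd=0.0, enriched_set={pid: math.log2(4.0)}
        )
        table, _ = generate_silac_dataset(cfg)
        row = table.loc[table.protein_id == pid].iloc[0]
        ratios = [math.log2(row[f"intensity_H_{k}"] / row[f"intensity_L_{k}"]) for k in range(1, 5)]
        assert np.mean(ratios) == pytest.approx(2.0)

    def test_clt_bound_null_means(self):
        # 1000 null proteins, sd 0.3, n = 4 -> grand mean within
        # 3 * (0.3 / sqrt(4)) / sqrt(1000) of 0
        cfg = SilacSimConfig(rng_seed=17, n_proteins=1000, null_log2_sd=0.3)
        table, _ = generate_silac_dataset(cfg)
        means = np.mean(
            [np.log2(table[f"intensity_H_{k}"] / table[f"intensity_L_{k}"]) for k in range(1, 5)],
            axis=0,
        )
        assert abs(means.mean()) <= 3 * (0.3 / 2) / math.sqrt(1000)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError, match="n_replicates"):
            SilacSimConfig(n_replicates=1)

    def test_unknown_enriched_id_rejected(self):
        with pytest.raises(ValueError, match="unknown protein"):
            SilacSimConfig(n_proteins=5, enriched_set={"P99999": 2.0})

    def test_flags_and_missingness(self):
        cfg = SilacSimConfig(
            rng_seed=2,
            n_proteins=2000,
            contaminant_fraction=0.05,
            reverse_fraction=0.02,
            site_only_fraction=0.01,
            missingness=0.2,
        )
        table, truth = generate_silac_dataset(cfg)
        assert abs(table["contaminant"].mean() - 0.05) < 0.02
        assert abs(table["reverse"].mean() - 0.02) < 0.01
        missing = table["intensity_H_1"].isna().mean()
        assert abs(missing - 0.2) < 0.03
        assert (truth["flagged"] == (table[["contaminant", "reverse", "site_only"]].any(axis=1))).all()

    def test_determinism(self):
        cfg = SilacSimConfig(rng_seed=9, n_proteins=50, missingness=0.1)
        t1, _ = generate_silac_dataset(cfg)
        t2, _ = generate_silac_dataset(cfg)
        pd.testing.assert_frame_equal(t1, t2)


class TestFidelityAgreement:
    def test_metric_and_image_routes_agree(self):
        # one well simulated both ways (zero noise, well-separated objects):
        # the pooled percent-positive readout differs by < 2 points
        from lysoquant import coloc, imgquant

        img_cfg = SimulationConfig(
            rng_seed=71,
            image_shape=(1024, 1024),
            n_cells=90,
            vesicles_per_cell_mean=22,
            noise_gaussian_sd=0.0,
            noise_poisson_gain=0.0,
            positivity_fraction={"ubiquitin_FK2": 0.8, "ubiquitin_K48": 0.8},
        )
        field, truth = generate_field(img_cfg)
        assert len(truth.vesicles) >= 1500
        _, _, by_role, _ = imgquant.quantify_field(field, marker_roles=["ubiquitin_FK2"])
        ves = by_role["lysosome"]
        coloc.mark_positive_vesicles(
            ves, "ubiquitin_FK2", marker_puncta=by_role["ubiquitin_FK2"]
        )
        img_pct = 100.0 * np.mean([v.positive_for["ubiquitin_FK2"] for v in ves])

        design = PlateDesign(wells=[synthgen.WellSpec("A01", "G1", "pool", "damaged", 1)])
        plate = generate_plate(
            design,
            SimulationConfig(rng_seed=72, vesicles_per_cell_mean=22),
            well_fraction_sd=0.0,
            cells_per_well=300,
        )
        df = plate.cell_table
        met_pct = 100.0 * df["n_pos_ubiquitin_FK2"].sum() / df["n_vesicles"].sum()
        assert abs(img_pct - met_pct) < 2.0
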