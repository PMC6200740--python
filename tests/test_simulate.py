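import numpy as np
import pandas as pd
import pytest

import rzscreen as rz
from rzscreen.io import VEHICLE


class TestSimulateScreen:
    def test_same_seed_bit_identical(self):
        kw = dict(seed=7, n_genes=50, n_drugs=5, n_disease_up=5,
                  n_disease_down=5)
        s1, t1 = rz.simulate_screen(rz.ScreenConfig.scaled_down(**kw))
        s2, t2 = rz.simulate_screen(rz.ScreenConfig.scaled_down(**kw))
        assert (s1.matrix.values.to_numpy()
                == s2.matrix.values.to_numpy()).all()
        np.testing.assert_array_equal(t1.base_effect, t2.base_effect)

    def test_twelve_vehicle_wells_per_plate_and_cell(self, small_screen):
        screen, truth, cfg = small_screen
        ann = screen.annotation
        veh = ann[ann["treatment"] == VEHICLE]
        counts = veh.groupby(["plate_id", "cell_line_id"]).size()
        assert (counts == cfg.n_vehicle_wells).all()
        assert cfg.n_vehicle_wells == 12

    def test_vehicle_wells_carry_no_drug_effect(self):
        """With noise off, vehicle wells equal baseline + offsets."""
        cfg = rz.ScreenConfig.scaled_down(
            seed=2, n_genes=20, n_drugs=3, noise_sd=1e-12, batch_sd=0.0,
            cell_line_sd=0.0, n_plates=1, n_phases=1, n_disease_up=3,
            n_disease_down=3)
        screen, truth = rz.simulate_screen(cfg)
        ann = screen.annotation
        veh_wells = ann[ann["treatment"] == VEHICLE]["well_id"]
        veh = screen.matrix.values[list(veh_wells)].to_numpy()
        spread = veh.max(axis=1) - veh.min(axis=1)
        assert spread.max() < 1e-9

    def test_zero_vehicle_wells_rejected(self):
        with pytest.raises(ValueError, match="n_vehicle_wells"):
            rz.ScreenConfig.scaled_down(n_vehicle_wells=0)

    def test_planted_effect_recovered_downstream(self):
        """A 3.0 log2 shift at noise_sd 0.1 always crosses the DE
        threshold after the RZS transform (sampled seeds)."""
        hits = trials = 0
        for seed in range(20):
            cfg = rz.ScreenConfig.scaled_down(
                seed=seed, n_genes=40, n_drugs=4, noise_sd=0.1,
                effect_size=3.0, de_fraction=0.05,
                celltype_fraction=0.0, diagnosis_fraction=0.0,
                n_reversers=0, n_disease_up=5, n_disease_down=5)
            screen, truth = rz.simulate_screen(cfg)
            tensor = rz.build_signature_tensor(screen)
            med = np.median(tensor.group_slice("CCL"), axis=1)
            planted = truth.base_effect != 0
            trials += planted.sum()
            hits += (np.abs(med)[planted] >= 2).sum()
        assert trials > 0 and hits / trials >= 0.95

    def test_reverser_effect_negates_disease_signature(self, small_screen):
        screen, truth, cfg = small_screen
        gi = {g: i for i, g in enumerate(truth.genes)}
        for drug in truth.reverser_drugs:
            d = truth.drugs.index(drug)
            up = [gi[g] for g in truth.disease_up]
            down = [gi[g] for g in truth.disease_down]
            assert (truth.base_effect[d, up]
                    == -cfg.reverser_strength).all()
            assert (truth.base_effect[d, down]
                    == cfg.reverser_strength).all()

    def test_modifiers_sparse_and_sized(self, small_screen):
        """Modifiers are zero outside the planted entries and planted
        entries carry the configured magnitude (reverser drugs have their
        modifiers cleared, so the count is bounded by the fraction)."""
        screen, truth, cfg = small_screen
        nonzero = truth.celltype_modifier[truth.celltype_modifier != 0]
        expected = round(cfg.celltype_fraction * cfg.n_drugs * cfg.n_genes)
        assert 0 < len(nonzero) <= expected
        assert set(np.abs(nonzero)) == {cfg.effect_size}


class TestBatchCancellation:
    def test_rzs_removes_batch_variance(self):
        """Plate variance components dominate raw vehicle expression but
        vanish from plate-matched vehicle pseudo-signatures."""
        cfg = rz.ScreenConfig.scaled_down(
            seed=4, n_genes=100, n_drugs=5, noise_sd=0.3, batch_sd=3.0,
            n_disease_up=10, n_disease_down=10)
        screen, truth = rz.simulate_screen(cfg)
        ann = screen.annotation
        cell = "CCL_00"
        veh = ann[(ann["treatment"] == VEHICLE)
                  & (ann["cell_line_id"] == cell)]
        raw = screen.matrix.values[list(veh["well_id"])].to_numpy()
        assert rz.variance_component_fraction(
            raw, list(veh["plate_id"])) > 0.5
        rzs, plates = rz.vehicle_pseudo_signatures(screen, cell)
        assert rz.variance_component_fraction(rzs, plates) < 0.01


class TestSimulateGeneSets:
    def test_sizes_and_subset(self):
        universe = [f"G{i}" for i in range(1000)]
        coll, update = rz.simulate_gene_sets(universe, 10, 50, seed=0)
        assert len(coll) == 10
        for name, genes in coll:
            assert len(genes) == 50 and genes <= set(universe)
        assert update["enriched_sets"] == []

    def test_planted_set_flagged_with_shifts(self):
        universe = [f"G{i}" for i in range(100)]
        coll, update = rz.simulate_gene_sets(
            universe, 5, 10, planted={"S": ("SZ_vs_control", 1.0)},
            seed=1)
        assert ("S", "SZ_vs_control", 1.0) in update["enriched_sets"]
        shifted = {g for g in update["set_shifts"]}
        assert shifted == set(coll.sets["S"])
        assert all(v == {"SZ_vs_control": 1.0}
                   for v in update["set_shifts"].values())

    def test_null_sets_receive_no_shift(self):
        universe = [f"G{i}" for i in range(100)]
        coll, update = rz.simulate_gene_sets(
            universe, 5, 10, planted={"S": ("NPC_vs_CCL", 2.0)}, seed=2)
        for name, genes in coll:
            if name == "S":
                continue
            outside = genes - coll.sets["S"]
            assert not any(g in update["set_shifts"] for g in outside)

    def test_name_collision_rejected(self):
        with pytest.raises(ValueError, match="collides"):
            rz.simulate_gene_sets([f"G{i}" for i in range(50)], 2, 5,
                                  planted={"null_set_000":
                                           ("NPC_vs_CCL", 1.0)})


class TestSimulateSequences:
    def test_planted_density_mean(self):
        seqs, _, truth = rz.simulate_sequences_and_variants(
            200, 1000, "ACUK", 4.0, 1.0, {}, {}, seed=0)
        high = [s for n, s in seqs.items() if n.startswith("high")]
        densities = [rz.motif_density(s, "ACUK") for s in high]
        assert np.mean(densities) == pytest.approx(4.0, abs=0.5)

    def test_zero_fraction_means_no_overlap(self):
        _, variants, _ = rz.simulate_sequences_and_variants(
            2, 50, "ACUK", 0.0, 0.0, {"control": 100}, {"control": 0.0},
            seed=1)
        hits = variants.apply(
            lambda r: rz.variant_in_motif(r["window_seq"],
                                          int(r["offset"]), "ACUK"),
            axis=1)
        assert not hits.any()

    def test_full_fraction_means_all_overlap(self):
        _, variants, _ = rz.simulate_sequences_and_variants(
            2, 50, "ACUK", 0.0, 0.0, {"SZ": 50}, {"SZ": 1.0}, seed=2)
        hits = variants.apply(
            lambda r: rz.variant_in_motif(r["window_seq"],
                                          int(r["offset"]), "ACUK"),
            axis=1)
        assert hits.all()

    def test_seed_reproducibility(self):
        a = rz.simulate_sequences_and_variants(
            5, 100, "ACUK", 2.0, 1.0, {"SZ": 10}, {"SZ": 0.5}, seed=9)
        b = rz.simulate_sequences_and_variants(
            5, 100, "ACUK", 2.0, 1.0, {"SZ": 10}, {"SZ": 0.5}, seed=9)
        assert a[0] == b[0]
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_motif_longer_than_sequence_rejected(self):
        with pytest.raises(ValueError, match="longer"):
            rz.simulate_sequences_and_variants(
                2, 3, "ACUK", 1.0, 1.0, {}, {}, seed=0)


class TestSimulateDrugAnnotations:
    def test_every_feature_in_catalog(self):
        drugs = [f"d{i}" for i in range(30)]
        table, truth = rz.simulate_drug_annotations(
            drugs, ["target", "side_effect"], n_features=5, seed=0)
        for cls, sub in table.groupby("class"):
            assert set(sub["feature"]) <= set(truth["catalog"][cls])

    def test_planted_feature_over_represented(self):
        drugs = [f"d{i:02d}" for i in range(50)]
        group = drugs[:5]
        table, _ = rz.simulate_drug_annotations(
            drugs, ["target"], n_features=10,
            planted=[(group, "target", "target_feat03")], seed=1)
        has = table[table["feature"] == "target_feat03"]["drug"]
        in_group = len(set(has) & set(group)) / len(group)
        background = len(set(has) - set(group)) / (len(drugs)
                                                   - len(group))
        assert in_group > background

    def test_no_planting_prevalence_roughly_uniform(self):
        drugs = [f"d{i:03d}" for i in range(200)]
        table, _ = rz.simulate_drug_annotations(
            drugs, ["target"], n_features=8, seed=2)
        prevalence = table.groupby("feature")["drug"].nunique() \
            / len(drugs)
        # each feature ~ annotated_fraction * base_prevalence = 0.16
        assert prevalence.between(0.08, 0.28).all()

    def test_some_drugs_unannotated_per_class(self):
        drugs = [f"d{i:03d}" for i in range(100)]
        table, _ = rz.simulate_drug_annotations(
            drugs, ["side_effect"], n_features=5, seed=3)
        assert 0 < table["drug"].nunique() < len(drugs)

    def test_planted_feature_outside_catalog_rejected(self):
        with pytest.raises(ValueError, match="catalog"):
            rz.simulate_drug_annotations(
                ["d1", "d2"], ["target"], n_features=2,
                planted=[(["d1"], "target", "bogus")], seed=0)
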