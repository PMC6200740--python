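import numpy as np
import pandas as pd
import pytest

import rzscreen as rz


def signature_from(values, genes=None):
    genes = genes or [f"g{i}" for i in range(len(values))]
    return rz.DrugSignature("d", "c", pd.Series(values, index=genes,
                                                dtype=float))


def make_disease(n_up=3, n_down=3, n_genes=20):
    genes = [f"g{i}" for i in range(n_genes)]
    return rz.DiseaseSignature(frozenset(genes[:n_up]),
                               frozenset(genes[n_up:n_up + n_down]))


class TestConnectivityScore:
    def test_perfect_concordance_plus_one(self):
        """Up tags at the very top, down tags at the very bottom."""
        values = np.zeros(20)
        values[:3] = [30, 29, 28]        # up tags g0..g2 rank first
        values[3:6] = [-28, -29, -30]    # down tags g3..g5 rank last
        values[6:] = np.linspace(10, 1, 14)
        disease = make_disease()
        rec = rz.connectivity_score(signature_from(values), disease)
        assert rec.es_up == pytest.approx(1.0)
        assert rec.es_down == pytest.approx(-1.0)
        assert rec.score == pytest.approx(1.0)

    def test_perfect_reversal_minus_one(self):
        values = np.zeros(20)
        values[:3] = [-28, -29, -30]     # up tags at the bottom
        values[3:6] = [30, 29, 28]       # down tags at the top
        values[6:] = np.linspace(10, 1, 14)
        disease = make_disease()
        rec = rz.connectivity_score(signature_from(values), disease)
        assert rec.score == pytest.approx(-1.0)

    def test_same_sign_es_scores_zero(self):
        # up and down tags interleaved near the top: both es positive
        values = np.zeros(20)
        values[[0, 3, 6]] = [30, 28, 26]   # up tags high
        values[[1, 4, 7]] = [29, 27, 25]   # down tags high too
        rec = rz.connectivity_score(signature_from(values), make_disease())
        assert np.sign(rec.es_up) == np.sign(rec.es_down)
        assert rec.score == 0.0

    def test_sign_antisymmetry(self):
        """Negating the RZS vector reverses the ranking, swapping the up-
        and down-tail enrichment and negating any nonzero score."""
        rng = np.random.default_rng(0)
        disease = make_disease(5, 5, 50)
        genes = [f"g{i}" for i in range(50)]
        for _ in range(50):
            values = rng.normal(size=50)
            fwd = rz.connectivity_score(signature_from(values, genes),
                                        disease)
            rev = rz.connectivity_score(signature_from(-values, genes),
                                        disease)
            assert abs(rev.es_up) == pytest.approx(abs(fwd.es_up),
                                                   abs=1e-12)
            if fwd.score != 0:
                assert rev.score == pytest.approx(-fwd.score, abs=1e-12)

    def test_random_scores_center_on_zero(self):
        rng = np.random.default_rng(1)
        disease = make_disease(10, 10, 200)
        genes = [f"g{i}" for i in range(200)]
        scores = [rz.connectivity_score(
            signature_from(rng.normal(size=200), genes), disease).score
            for _ in range(500)]
        assert abs(np.mean(scores)) < 0.02

    def test_no_tag_genes_errors(self):
        disease = rz.DiseaseSignature(frozenset({"xx"}), frozenset({"yy"}))
        with pytest.raises(ValueError, match="tag genes"):
            rz.connectivity_score(signature_from(np.arange(5.0)), disease)


class TestMatrix:
    def make_tensor(self, seed=0, n_drugs=2, n_lines=4, n_genes=30):
        rng = np.random.default_rng(seed)
        cells = [f"NPC_SZ_{i}" for i in range(n_lines // 2)] + \
                [f"NPC_control_{i}" for i in range(n_lines - n_lines // 2)]
        groups = {c: "_".join(c.split("_")[:-1]) for c in cells}
        return rz.SignatureTensor(
            rng.normal(size=(n_drugs, n_lines, n_genes)),
            [f"d{i}" for i in range(n_drugs)], cells,
            [f"g{i}" for i in range(n_genes)], groups)

    def test_matrix_matches_individual_scores(self):
        tensor = self.make_tensor()
        disease = make_disease(4, 4, 30)
        mat = rz.build_connectivity_matrix(tensor, disease,
                                           aggregate="none")
        for drug in tensor.drugs:
            for cell in tensor.cell_lines:
                rec = rz.connectivity_score(tensor.signature(drug, cell),
                                            disease)
                assert mat.loc[drug, cell] == pytest.approx(rec.score)

    def test_identical_lines_aggregate_equals_individual(self):
        tensor = self.make_tensor(n_lines=4)
        tensor.data[:, :2, :] = tensor.data[:, :1, :]  # SZ lines identical
        disease = make_disease(4, 4, 30)
        by_group = rz.build_connectivity_matrix(tensor, disease,
                                                aggregate="by_group")
        percell = rz.build_connectivity_matrix(tensor, disease,
                                               aggregate="none")
        assert by_group.loc["d0", "NPC_SZ"] == pytest.approx(
            percell.loc["d0", "NPC_SZ_0"])


class TestReversalScreen:
    def test_planted_reverser_flagged(self, small_tensor):
        tensor, truth = small_tensor
        disease = rz.DiseaseSignature(frozenset(truth.disease_up),
                                      frozenset(truth.disease_down))
        mat = rz.build_connectivity_matrix(tensor, disease,
                                           aggregate="by_group")
        out = rz.reversal_screen(mat, disease, n_genes=len(tensor.genes),
                                 n_permutations=500, seed=4)
        flagged = set(out[out["reversing"]]["drug"])
        assert set(truth.reverser_drugs) <= flagged

    def test_same_seed_identical(self, small_tensor):
        tensor, truth = small_tensor
        disease = rz.DiseaseSignature(frozenset(truth.disease_up),
                                      frozenset(truth.disease_down))
        mat = rz.build_connectivity_matrix(tensor, disease,
                                           aggregate="by_group")
        a = rz.reversal_screen(mat, disease, n_genes=len(tensor.genes),
                               n_permutations=200, seed=5)
        b = rz.reversal_screen(mat, disease, n_genes=len(tensor.genes),
                               n_permutations=200, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_seed_required(self, small_tensor):
        tensor, truth = small_tensor
        disease = rz.DiseaseSignature(frozenset(truth.disease_up),
                                      frozenset(truth.disease_down))
        mat = rz.build_connectivity_matrix(tensor, disease,
                                           aggregate="by_group")
        with pytest.raises(ValueError, match="seed"):
            rz.reversal_screen(mat, disease, n_genes=len(tensor.genes))

    def test_specificity_classification(self):
        mat = pd.DataFrame({"NPC_SZ": [-0.9, -0.9, 0.1],
                            "NPC_control": [-0.9, 0.1, 0.1]},
                           index=["dA", "dB", "dC"])
        disease = make_disease(5, 5, 200)
        out = rz.reversal_screen(mat, disease, n_genes=200,
                                 n_permutations=400, seed=1)
        spec = out.drop_duplicates("drug").set_index("drug")["specificity"]
        assert spec["dA"] == "both"
        assert spec["dB"] == "SZ_only"
        assert spec["dC"] == "none"


class TestMds:
    def test_collinear_ordering_recovered(self):
        # profiles on a line: distances 1, 2, 3
        mat = pd.DataFrame([[0.0, 1.0, 3.0]], index=["d0"],
                           columns=["c1", "c2", "c3"])
        emb = rz.mds_embed(mat, n_dims=1)
        order = emb["dim1"].sort_values().index.tolist()
        assert order in (["c1", "c2", "c3"], ["c3", "c2", "c1"])

    def test_duplicated_lines_coincide(self):
        rng = np.random.default_rng(3)
        profiles = rng.normal(size=(5, 4))
        profiles[:, 1] = profiles[:, 0]
        mat = pd.DataFrame(profiles, columns=["a", "a2", "b", "c"])
        emb = rz.mds_embed(mat)
        np.testing.assert_allclose(emb.loc["a"], emb.loc["a2"], atol=1e-9)

    def test_distances_reconstructed_for_planar_input(self):
        rng = np.random.default_rng(4)
        coords = rng.normal(size=(6, 2))
        # embed 2-D points into a 10-D drug-score space by rotation
        basis = np.linalg.qr(rng.normal(size=(10, 2)))[0]
        profiles = coords @ basis.T
        mat = pd.DataFrame(profiles.T,
                           columns=[f"c{i}" for i in range(6)])
        emb = rz.mds_embed(mat, n_dims=2).to_numpy()
        orig = np.linalg.norm(coords[:, None] - coords[None], axis=2)
        rec = np.linalg.norm(emb[:, None] - emb[None], axis=2)
        np.testing.assert_allclose(rec, orig, atol=1e-8)

    def test_too_few_lines_errors(self):
        mat = pd.DataFrame([[0.0, 1.0]], index=["d0"],
                           columns=["c1", "c2"])
        with pytest.raises(ValueError, match="need >="):
            rz.mds_embed(mat, n_dims=2)


class TestPrioritize:
    def test_planted_reverser_ranked_first(self, small_tensor):
        tensor, truth = small_tensor
        sets = rz.GeneSetCollection(
            {"disease_up": frozenset(truth.disease_up),
             "disease_down": frozenset(truth.disease_down)})
        ranked = rz.prioritize_drugs(tensor, sets)
        assert ranked.index[0] in truth.reverser_drugs

    def test_ties_break_by_drug_id(self):
        rng = np.random.default_rng(0)
        data = np.tile(rng.normal(size=(1, 1, 30)), (2, 1, 1))
        cells = ["CCL_0"]
        tensor = rz.SignatureTensor(data, ["dB", "dA"], cells,
                                    [f"g{i}" for i in range(30)],
                                    {"CCL_0": "CCL"})
        sets = rz.GeneSetCollection({"S": frozenset(tensor.genes[:6])})
        ranked = rz.prioritize_drugs(tensor, sets, aggregate="none")
        assert list(ranked.index) == ["dA", "dB"]

    def test_top_k_larger_than_library(self, small_tensor):
        tensor, truth = small_tensor
        sets = rz.GeneSetCollection({"S": frozenset(tensor.genes[:10])})
        ranked = rz.prioritize_drugs(tensor, sets, top_k=10_000)
        assert len(ranked) == len(tensor.drugs)
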