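"""Structure/ensemble comparison objects: matrices, vectors, centroids, PCA."""

import numpy as np
import pytest

from sdckit import bruteforce as bf
from sdckit.ensemble import (
    PairProbabilityMatrix,
    cluster_centroid_structure,
    ensemble_partition_matrix,
    pairing_vector,
    pca_project,
    structure_binary_vector,
    structure_to_pair_matrix,
    z_centroid,
)
from sdckit.fold import RnaSequence, SecondaryStructure, StructureEnsemble

from .conftest import random_sequence

HAIRPIN = SecondaryStructure.from_dotbracket("(((...)))")
EMPTY9 = SecondaryStructure(n=9, pairs=frozenset())


def ensemble_of(structures, n=9, residues=None):
    seq = RnaSequence(id="s", residues=residues or "GGGAAACCC"[:n].ljust(n, "A"))
    return StructureEnsemble(sequence=seq, structures=list(structures))


class TestPairMatrix:
    def test_single_pair_sets_two_entries(self):
        m = structure_to_pair_matrix(SecondaryStructure(n=9, pairs={(1, 9)}))
        assert m[0, 8] == 1 and m[8, 0] == 1 and m.sum() == 2

    def test_empty_structure_gives_zero_matrix(self):
        assert not structure_to_pair_matrix(EMPTY9).any()

    def test_hairpin_has_six_entries(self):
        assert structure_to_pair_matrix(HAIRPIN).sum() == 6

    def test_row_sums_are_binary(self):
        m = structure_to_pair_matrix(HAIRPIN)
        assert set(m.sum(axis=1)) <= {0.0, 1.0}


class TestPartitionMatrix:
    def test_two_structure_mean(self):
        ens = ensemble_of([SecondaryStructure(n=9, pairs={(1, 9)}), EMPTY9])
        P = ensemble_partition_matrix(ens)
        assert P.p[0, 8] == pytest.approx(0.5)
        assert P.provenance == "sampled(2)"

    def test_identical_structures_give_binary_matrix(self):
        ens = ensemble_of([HAIRPIN] * 7)
        np.testing.assert_array_equal(
            ensemble_partition_matrix(ens).p, structure_to_pair_matrix(HAIRPIN)
        )

    def test_sampled_matrix_converges_to_exact(self, engine):
        seq = RnaSequence(id="s", residues="GGGACAAUCC")
        exact = engine.pair_probabilities(seq).p
        ens = engine.sample_structures(seq, 8000, seed=11)
        sampled = ensemble_partition_matrix(ens).p
        assert np.abs(sampled - exact).max() < 0.03

    def test_matrix_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            PairProbabilityMatrix(n=2, p=np.array([[0, 1], [0, 0.0]]))

    def test_sparse_text_round_trip(self, tmp_path, engine, rng):
        seq = random_sequence(rng, 12)
        P = engine.pair_probabilities(seq)
        path = tmp_path / "p.txt"
        P.to_sparse_text(path)
        back = PairProbabilityMatrix.from_sparse_text(path, n=12)
        np.testing.assert_allclose(back.p, P.p, atol=1e-12)


class TestVectors:
    def test_zero_matrix_means_fully_unpaired(self):
        P = PairProbabilityMatrix(n=4, p=np.zeros((4, 4)))
        np.testing.assert_array_equal(pairing_vector(P), np.ones(4))

    def test_deterministic_hairpin_vector(self):
        P = ensemble_partition_matrix(ensemble_of([HAIRPIN] * 3))
        np.testing.assert_array_equal(pairing_vector(P), [0, 0, 0, 1, 1, 1, 0, 0, 0])

    def test_binary_vector_of_hairpin(self):
        np.testing.assert_array_equal(
            structure_binary_vector(HAIRPIN), [0, 0, 0, 1, 1, 1, 0, 0, 0]
        )

    def test_empty_structure_is_all_ones(self):
        assert structure_binary_vector(EMPTY9).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_pairing_vector_of_single_structure_matrix_is_binary_vector(self, engine, seed):
        rng = np.random.default_rng(seed)
        s = engine.mfe_structure(random_sequence(rng, 20))
        P = PairProbabilityMatrix(n=20, p=structure_to_pair_matrix(s), provenance="sampled(1)")
        np.testing.assert_array_equal(pairing_vector(P), structure_binary_vector(s))

    def test_sampled_vector_near_exact_vector(self, engine):
        seq = RnaSequence(id="s", residues="GGGACAAUCC")
        v_exact = pairing_vector(engine.pair_probabilities(seq))
        ens = engine.sample_structures(seq, 8000, seed=2)
        v_sampled = pairing_vector(ensemble_partition_matrix(ens))
        assert np.abs(v_exact - v_sampled).max() < 0.03


class TestZCentroid:
    def test_single_confident_pair(self):
        p = np.zeros((9, 9))
        p[0, 8] = p[8, 0] = 0.9
        s = z_centroid(PairProbabilityMatrix(n=9, p=p))
        assert s.pairs == frozenset({(1, 9)})

    def test_no_pair_above_half_gives_empty_structure(self):
        p = np.zeros((9, 9))
        p[0, 8] = p[8, 0] = 0.5
        assert not z_centroid(PairProbabilityMatrix(n=9, p=p)).pairs

    def test_agrees_with_enumerated_pair_frequencies(self, engine, rng):
        seq = random_sequence(rng, 12)
        P = engine.pair_probabilities(seq)
        expected = {
            (i + 1, j + 1)
            for i in range(12)
            for j in range(i + 1, 12)
            if bf.brute_force_pair_probabilities(seq)[i, j] > 0.5
        }
        assert z_centroid(P).pairs == frozenset(expected)

    @pytest.mark.parametrize("seed", range(30))
    def test_always_valid_on_sampled_matrices(self, engine, seed):
        # conflicting pairs are mutually exclusive events, so both cannot
        # exceed probability one half: the >0.5 pair set must be a structure
        rng = np.random.default_rng(seed)
        seq = random_sequence(rng, int(rng.integers(10, 25)))
        ens = engine.sample_structures(seq, 60, seed=seed)
        z_centroid(ensemble_partition_matrix(ens)).validate()


class TestLandscape:
    def _two_hairpin_ensembles(self, engine):
        # same length, disjoint hairpins: variants concentrate on different stems
        a = SecondaryStructure.from_dotbracket("(((...)))......")
        b = SecondaryStructure.from_dotbracket("......(((...)))")
        seq = RnaSequence(id="s", residues="GGGAAACCCAAAGGG")
        ens_a = StructureEnsemble(sequence=seq, structures=[a] * 40 + [b] * 2)
        ens_b = StructureEnsemble(sequence=seq, structures=[b] * 40 + [a] * 2)
        return [("WT", ens_a), ("MUT", ens_b)]

    def test_disjoint_hairpins_separate_into_clusters(self, engine):
        proj = pca_project(self._two_hairpin_ensembles(engine), k=2, seed=0)
        occ = proj.occupancies
        assert occ.loc["WT"].max() >= 0.95
        assert occ.loc["MUT"].max() >= 0.95
        assert occ.loc["WT"].idxmax() != occ.loc["MUT"].idxmax()

    def test_occupancies_sum_to_one_per_variant(self, engine):
        proj = pca_project(self._two_hairpin_ensembles(engine), k=2, seed=0)
        np.testing.assert_allclose(proj.occupancies.sum(axis=1), 1.0)

    def test_point_count_matches_pooled_size(self, engine):
        proj = pca_project(self._two_hairpin_ensembles(engine), k=2, seed=0)
        assert len(proj.points) == 84

    def test_degenerate_pool_is_an_error(self):
        seq = RnaSequence(id="s", residues="GGGAAACCC")
        ens = StructureEnsemble(sequence=seq, structures=[HAIRPIN] * 20)
        with pytest.raises(ValueError, match="zero-variance"):
            pca_project([("WT", ens)], k=2, seed=0)

    def test_reproducible_under_seed(self, engine):
        a = pca_project(self._two_hairpin_ensembles(engine), k=2, seed=3)
        b = pca_project(self._two_hairpin_ensembles(engine), k=2, seed=3)
        np.testing.assert_array_equal(a.points["cluster"], b.points["cluster"])


class TestClusterCentroid:
    def test_dominant_mode_is_returned(self, engine):
        a = SecondaryStructure.from_dotbracket("(((...)))......")
        b = SecondaryStructure.from_dotbracket("......(((...)))")
        seq = RnaSequence(id="s", residues="GGGAAACCCAAAGGG")
        ens = StructureEnsemble(sequence=seq, structures=[a] * 40 + [b] * 10)
        assert cluster_centroid_structure(ens, k=2, seed=0).pairs == a.pairs

    def test_k1_returns_whole_ensemble_medoid(self, engine):
        a = SecondaryStructure.from_dotbracket("(((...)))......")
        b = SecondaryStructure.from_dotbracket("......(((...)))")
        seq = RnaSequence(id="s", residues="GGGAAACCCAAAGGG")
        ens = StructureEnsemble(sequence=seq, structures=[a] * 9 + [b])
        assert cluster_centroid_structure(ens, k=1, seed=0).pairs == a.pairs

    def test_deterministic_under_seed(self, engine, rng):
        seq = random_sequence(rng, 20)
        ens = engine.sample_structures(seq, 300, seed=4)
        s1 = cluster_centroid_structure(ens, k=4, seed=7)
        s2 = cluster_centroid_structure(ens, k=4, seed=7)
        assert s1.pairs == s2.pairs
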