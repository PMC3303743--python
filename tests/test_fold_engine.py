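"""Folding engine vs the exhaustive enumeration reference, plus adapters."""

import math
from collections import Counter

import numpy as np
import pytest

from sdckit import bruteforce as bf
from sdckit.fold import (
    FoldEngine,
    RnaSequence,
    SecondaryStructure,
    apply_mutation,
    parse_mutation,
    read_dotbracket_ensemble,
    write_dotbracket_ensemble,
)

from .conftest import random_sequence


class TestMutations:
    def test_single_substitution(self):
        m = parse_mutation("C77G")
        assert m.substitutions == (("C", 77, "G"),)

    def test_double_substitution_order_preserved(self):
        m = parse_mutation("U22G.A196G")
        assert m.substitutions == (("U", 22, "G"), ("A", 196, "G"))

    @pytest.mark.parametrize("bad", ["C77X", "77G", "C-1G", "CxG", ""])
    def test_malformed_tokens_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_mutation(bad)

    def test_substitution_limit_configurable(self):
        with pytest.raises(ValueError, match="limit"):
            parse_mutation("A1C.A2C.A3C")
        assert len(parse_mutation("A1C.A2C.A3C", max_substitutions=None).substitutions) == 3

    def test_apply_substitutes_listed_positions(self):
        seq = RnaSequence(id="s", residues="GGGAAACCC")
        assert apply_mutation(seq, parse_mutation("A4U")).residues == "GGGUAACCC"

    def test_apply_empty_is_identity(self):
        seq = RnaSequence(id="s", residues="GGGAAACCC")
        from sdckit.fold import MutationSpec

        assert apply_mutation(seq, MutationSpec(())).residues == seq.residues

    def test_reference_mismatch_names_position(self):
        seq = RnaSequence(id="s", residues="GGGAAACCC")
        with pytest.raises(ValueError, match="position 4"):
            apply_mutation(seq, parse_mutation("C4U"))


class TestMfe:
    def test_canonical_hairpin(self, engine):
        s = engine.mfe_structure(RnaSequence(id="h", residues="GGGAAACCC"))
        assert s.to_dotbracket() == "(((...)))"

    def test_unpairable_sequence(self, engine):
        assert not engine.mfe_structure(RnaSequence(id="a", residues="AAAAAA")).pairs

    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    def test_too_short_for_minimum_loop(self, engine, n):
        seq = RnaSequence(id="s", residues=("GCAU" * 2)[:n])
        assert not engine.mfe_structure(seq).pairs

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration_with_tiebreak(self, engine, seed):
        rng = np.random.default_rng(seed)
        for _ in range(5):
            seq = random_sequence(rng, int(rng.integers(5, 13)))
            e_bf, s_bf = bf.brute_force_mfe(seq)
            assert engine.mfe_energy(seq) == pytest.approx(e_bf, abs=1e-12)
            assert engine.mfe_structure(seq).pairs == s_bf.pairs


class TestPartitionFunction:
    @pytest.mark.parametrize("seed", range(8))
    def test_inside_value_matches_enumerated_sum(self, engine, seed):
        rng = np.random.default_rng(100 + seed)
        seq = random_sequence(rng, int(rng.integers(6, 13)))
        z_dp = math.exp(engine.partition_log(seq))
        z_bf = bf.brute_force_partition(seq)
        assert z_dp == pytest.approx(z_bf, rel=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_pair_probabilities_match_enumeration(self, engine, seed):
        rng = np.random.default_rng(200 + seed)
        seq = random_sequence(rng, 12)
        p_dp = engine.pair_probabilities(seq).p
        p_bf = bf.brute_force_pair_probabilities(seq)
        assert np.abs(p_dp - p_bf).max() < 1e-9

    def test_no_complementary_pairs_gives_zero_matrix(self, engine):
        p = engine.pair_probabilities(RnaSequence(id="a", residues="AAAAAAAA")).p
        assert not p.any()

    def test_infinite_temperature_limit_is_uniform_counting(self):
        # at huge kT all structures weigh equally: pair probabilities equal
        # the frequency of each pair among enumerated structures
        hot = FoldEngine(kT=1e9)
        seq = RnaSequence(id="s", residues="GGCAAAGCCA")
        p_dp = hot.pair_probabilities(seq).p
        structures = bf.enumerate_structures(seq)
        p_cnt = np.zeros((seq.n, seq.n))
        for s in structures:
            for i, j in s.pairs:
                p_cnt[i - 1, j - 1] += 1
                p_cnt[j - 1, i - 1] += 1
        p_cnt /= len(structures)
        assert np.abs(p_dp - p_cnt).max() < 1e-6


class TestSampling:
    def test_same_seed_reproduces_ensemble(self, engine, rng):
        seq = random_sequence(rng, 15)
        a = engine.sample_structures(seq, 50, seed=9)
        b = engine.sample_structures(seq, 50, seed=9)
        assert [s.pairs for s in a.structures] == [s.pairs for s in b.structures]

    def test_single_sample_is_valid(self, engine, rng):
        seq = random_sequence(rng, 20)
        ens = engine.sample_structures(seq, 1, seed=0)
        assert ens.size == 1
        ens.structures[0].validate()

    def test_frequencies_track_boltzmann_probabilities(self, engine):
        seq = RnaSequence(id="s", residues="GGGACAAUCC")
        probs = bf.brute_force_structure_probabilities(seq)
        ens = engine.sample_structures(seq, 8000, seed=3)
        counts = Counter(s.pairs for s in ens.structures)
        for pairs, p in probs.items():
            if p > 0.02:
                assert counts[pairs] / 8000 == pytest.approx(p, abs=0.02)

    def test_all_samples_satisfy_structure_invariants(self, engine, rng):
        seq = random_sequence(rng, 25)
        for s in engine.sample_structures(seq, 200, seed=5).structures:
            s.validate()


class TestDotBracket:
    def test_bracket_matching(self):
        s = SecondaryStructure.from_dotbracket("(((...)))")
        assert s.pairs == frozenset({(1, 9), (2, 8), (3, 7)})

    def test_round_trip(self, engine, rng):
        seq = random_sequence(rng, 30)
        s = engine.mfe_structure(seq)
        assert SecondaryStructure.from_dotbracket(s.to_dotbracket()).pairs == s.pairs

    @pytest.mark.parametrize("bad", ["((.)", ".))", "(.x.)"])
    def test_malformed_strings_rejected(self, bad):
        with pytest.raises(ValueError):
            SecondaryStructure.from_dotbracket(bad)

    def test_validator_rejects_crossing_and_short_loops(self):
        with pytest.raises(ValueError, match="crossing"):
            SecondaryStructure(n=12, pairs={(1, 8), (4, 12)}).validate()
        with pytest.raises(ValueError, match="minimum loop"):
            SecondaryStructure(n=6, pairs={(1, 4)}).validate()

    def test_ensemble_file_round_trip_ignoring_headers(self, tmp_path, engine, rng):
        seq = random_sequence(rng, 14)
        ens = engine.sample_structures(seq, 25, seed=1)
        path = tmp_path / "ens.db"
        write_dotbracket_ensemble(ens, path)
        back = read_dotbracket_ensemble(path, seq)
        assert back.size == 25
        assert [s.pairs for s in back.structures] == [s.pairs for s in ens.structures]

    def test_ensemble_reader_tolerates_energy_columns(self, tmp_path):
        seq = RnaSequence(id="s", residues="GGGAAACCC")
        path = tmp_path / "e.db"
        path.write_text(">s\nGGGAAACCC\n(((...))) -9.00\n.(......)   1.0\n")
        ens = read_dotbracket_ensemble(path, seq)
        assert ens.size == 2

    def test_ensemble_reader_reports_line_numbers(self, tmp_path):
        seq = RnaSequence(id="s", residues="GGGAAACCC")
        path = tmp_path / "bad.db"
        path.write_text("(((...)))\n((...)\n")
        with pytest.raises(ValueError, match="line 2"):
            read_dotbracket_ensemble(path, seq)

    def test_length_mismatch_rejected(self, tmp_path):
        seq = RnaSequence(id="s", residues="GGGAAACCC")
        path = tmp_path / "short.db"
        path.write_text("((...))\n")
        with pytest.raises(ValueError, match="length"):
            read_dotbracket_ensemble(path, seq)


class TestSequenceType:
    def test_t_coerced_to_u(self):
        assert RnaSequence(id="s", residues="acgt").residues == "ACGU"

    def test_invalid_residue_rejected(self):
        with pytest.raises(ValueError, match="invalid"):
            RnaSequence(id="s", residues="ACGX")

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            RnaSequence(id="s", residues="")
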