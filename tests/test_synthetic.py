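"""The synthetic generator: structures, coordinates, planted attention."""

import filecmp
from pathlib import Path

import numpy as np
import pytest

from attnprobe import (
    MaskPolicy,
    SyntheticSpec,
    agreement_scores,
    coords_to_contact_map,
    dotbracket_to_pairs,
    gen_attention_stack,
    gen_coords,
    gen_corpus,
    gen_secondary,
    gen_tertiary_map,
    pairs_to_contact_map,
    pairs_to_dotbracket,
    write_corpus,
)
from attnprobe.contacts import PairList, apply_exclusion_band
from attnprobe.errors import GenerationError, ValidationError
from attnprobe.io import read_structure, write_structure_pdb
from attnprobe.synthetic import load_corpus


class TestGenSecondary:
    @pytest.mark.parametrize("seed", range(6))
    def test_output_parses_and_roundtrips_when_nested(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 100))
        db = gen_secondary(n, rng, pseudoknot_prob=0.0)
        pairs = dotbracket_to_pairs(db)  # must not raise
        assert pairs_to_dotbracket(pairs, n) == db

    def test_pseudoknot_adds_crossing_pairs(self):
        crossing_seen = False
        for seed in range(30):
            rng = np.random.default_rng(seed)
            db = gen_secondary(60, rng, pseudoknot_prob=1.0)
            if "[" not in db:
                continue
            pairs = sorted(dotbracket_to_pairs(db))
            crossing_seen = any(
                i < k < j < l or k < i < l < j
                for i, j in pairs
                for k, l in pairs
                if (i, j) < (k, l)
            )
            if crossing_seen:
                break
        assert crossing_seen

    def test_fixed_seed_reproduces_string(self):
        a = gen_secondary(50, np.random.default_rng(3), pseudoknot_prob=0.5)
        b = gen_secondary(50, np.random.default_rng(3), pseudoknot_prob=0.5)
        assert a == b

    def test_too_short_rejected(self):
        with pytest.raises(GenerationError):
            gen_secondary(5, np.random.default_rng(0))


class TestGenTertiaryMap:
    def test_zero_extras_equals_secondary_map(self):
        rng = np.random.default_rng(0)
        db = gen_secondary(40, rng)
        cmap = gen_tertiary_map(db, 0, rng, window=4)
        base = apply_exclusion_band(
            pairs_to_contact_map(dotbracket_to_pairs(db), 40), 4
        )
        assert np.array_equal(cmap.matrix, base.matrix)

    def test_extras_count_above_diagonal(self):
        rng = np.random.default_rng(1)
        db = gen_secondary(50, rng)
        base = apply_exclusion_band(
            pairs_to_contact_map(dotbracket_to_pairs(db), 50), 4
        )
        cmap = gen_tertiary_map(db, 3, rng, window=4)
        assert cmap.contact_count() == base.contact_count() + 3

    def test_fixed_seed_reproduces_map(self):
        db = gen_secondary(45, np.random.default_rng(2))
        a = gen_tertiary_map(db, 2, np.random.default_rng(7), window=4)
        b = gen_tertiary_map(db, 2, np.random.default_rng(7), window=4)
        assert np.array_equal(a.matrix, b.matrix)

    def test_impossible_extras_request_rejected(self):
        with pytest.raises(GenerationError):
            gen_tertiary_map("." * 12, 500, np.random.default_rng(0), window=4)


class TestGenCoords:
    def test_empty_matching_has_no_offband_contacts(self):
        s = gen_coords(PairList(frozenset()), 10)
        cmap = apply_exclusion_band(coords_to_contact_map(s, cutoff=9.5), 4)
        assert cmap.matrix.sum() == 0

    def test_single_pair_recovered_by_bruteforce_distances(self):
        s = gen_coords(PairList(frozenset({(1, 9)})), 12)
        cmap = apply_exclusion_band(coords_to_contact_map(s, cutoff=9.5), 4)
        expected = np.zeros((12, 12), dtype=np.int8)
        expected[1, 9] = expected[9, 1] = 1
        assert np.array_equal(cmap.matrix, expected)

    def test_contact_map_equals_band_filtered_matching(self):
        matching = PairList(frozenset({(0, 20), (3, 11), (5, 17)}))
        s = gen_coords(matching, 24)
        cmap = apply_exclusion_band(coords_to_contact_map(s, cutoff=9.5), 4)
        target = apply_exclusion_band(pairs_to_contact_map(matching, 24), 4)
        assert np.array_equal(cmap.matrix, target.matrix)

    def test_pdb_roundtrip(self, tmp_path):
        matching = PairList(frozenset({(1, 9)}))
        s = gen_coords(matching, 12)
        path = tmp_path / "toy.pdb"
        write_structure_pdb(s, path)
        back = read_structure(path, "rna", molecule_id="toy")
        cmap = apply_exclusion_band(coords_to_contact_map(back, cutoff=9.5), 4)
        assert cmap.matrix[1, 9] == 1
        assert cmap.contact_count() == 1

    def test_pair_inside_band_is_infeasible(self):
        with pytest.raises(GenerationError):
            gen_coords(PairList(frozenset({(2, 5)})), 12, window=4)


class TestGenAttentionStack:
    def _map(self, seed=0, n=40):
        rng = np.random.default_rng(seed)
        return gen_tertiary_map(gen_secondary(n, rng), 2, rng, window=4), rng

    def test_rows_sum_to_one(self):
        cmap, rng = self._map()
        stack = gen_attention_stack(cmap, SyntheticSpec(alpha=0.5), rng)
        assert np.allclose(stack.weights.sum(axis=3), 1.0, atol=1e-9)
        assert (stack.weights >= 0).all()

    def test_pure_signal_aware_head_scores_one_off_band(self):
        cmap, rng = self._map(seed=3)
        spec = SyntheticSpec(alpha=1.0)
        stack = gen_attention_stack(cmap, spec, rng)
        grid = agreement_scores(
            [stack], [cmap], theta=None, mask_policy=MaskPolicy.BAND_EXCLUDED
        )
        for l, h in spec.aware_heads:
            assert grid.scores[l, h] == pytest.approx(1.0)

    def test_alpha_zero_makes_aware_heads_indistinguishable(self):
        # Monte-Carlo null: with no planted signal, aware and unaware
        # heads score within noise of each other
        spec = SyntheticSpec(alpha=0.0, n_molecules=100, length_range=(25, 35), seed=8)
        corpus = gen_corpus(spec)
        grid = agreement_scores(corpus.stacks, corpus.maps, theta=None)
        aware = np.array([grid.scores[l, h] for l, h in spec.aware_heads])
        mask = np.ones_like(grid.scores, dtype=bool)
        for l, h in spec.aware_heads:
            mask[l, h] = False
        # compare against noise-dominated unaware heads pooled over the grid
        assert abs(aware.mean() - grid.scores[mask].mean()) < 0.05


class TestGenCorpus:
    def test_aligned_triplets(self):
        corpus = gen_corpus(SyntheticSpec(n_molecules=40, length_range=(20, 30), seed=1))
        assert len(corpus) == 40
        for mol, db, cmap, stack in zip(
            corpus.molecules, corpus.secondaries, corpus.maps, corpus.stacks
        ):
            assert len(mol) == len(db) == cmap.n == stack.n
            assert mol.id == stack.molecule_id

    def test_stem_bases_are_complementary(self):
        corpus = gen_corpus(SyntheticSpec(n_molecules=5, seed=2))
        wc = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
        for mol, db in zip(corpus.molecules, corpus.secondaries):
            for i, j in dotbracket_to_pairs(db):
                assert (mol.sequence[i], mol.sequence[j]) in wc

    def test_serialized_corpus_is_byte_identical_across_runs(self, tmp_path):
        spec = SyntheticSpec(n_molecules=4, length_range=(20, 30), seed=9)
        dir_a, dir_b = tmp_path / "a", tmp_path / "b"
        write_corpus(gen_corpus(spec), dir_a)
        write_corpus(gen_corpus(spec), dir_b)
        files_a = sorted(p.relative_to(dir_a) for p in dir_a.rglob("*") if p.is_file())
        files_b = sorted(p.relative_to(dir_b) for p in dir_b.rglob("*") if p.is_file())
        assert files_a == files_b
        for rel in files_a:
            assert filecmp.cmp(dir_a / rel, dir_b / rel, shallow=False), rel

    def test_corpus_roundtrips_through_disk(self, tmp_path):
        spec = SyntheticSpec(n_molecules=3, length_range=(20, 30), seed=4)
        corpus = gen_corpus(spec)
        write_corpus(corpus, tmp_path / "c")
        back = load_corpus(tmp_path / "c")
        assert back.spec == spec
        for a, b in zip(corpus.stacks, back.stacks):
            assert np.array_equal(a.weights, b.weights)
        for a, b in zip(corpus.maps, back.maps):
            assert np.array_equal(a.matrix, b.matrix)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValidationError):
            SyntheticSpec(alpha=1.5)
        with pytest.raises(ValidationError):
            SyntheticSpec(aware_heads=((9, 0),))
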