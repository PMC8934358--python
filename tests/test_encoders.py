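import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import metabind as mb
from metabind.encoders import EmbeddingMatrix, embed_drug_records

AA = st.sampled_from("ACDEFGHIKLMNPQRSTVWY")


class TestShiftedCorpus:
    def test_length_five_sequence(self):
        assert mb.build_shifted_corpus("MAFSA") == (["MAF"], ["AFS"], ["FSA"])

    def test_length_six_sequence(self):
        assert mb.build_shifted_corpus("ABCDEF") == (["ABC", "DEF"], ["BCD"], ["CDE"])

    def test_short_sequence_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            lists = mb.build_shifted_corpus("AB")
        assert lists == ([], [], [])

    @given(st.text(alphabet=AA, min_size=3, max_size=60))
    @settings(derandomize=True, max_examples=60)
    def test_concatenation_reconstructs_prefix(self, seq):
        for s, tokens in enumerate(mb.build_shifted_corpus(seq)):
            n = 3 * ((len(seq) - s) // 3)
            assert "".join(tokens) == seq[s : s + n]
            assert all(len(t) == 3 for t in tokens)


class TestKmerEmbeddings:
    def test_vocabulary_covers_corpus_tokens(self):
        corpus = [["AAA", "CCC"] * 5, ["CCC", "AAA"] * 5]
        vocab = mb.train_kmer_embeddings(corpus, dim=8, seed=0)
        assert "AAA" in vocab and "CCC" in vocab
        assert vocab.vector("AAA").shape == (8,)

    def test_deterministic_given_seed(self):
        corpus = [["AAA", "CCC", "GGG"] * 4]
        a = mb.train_kmer_embeddings(corpus, dim=6, seed=3)
        b = mb.train_kmer_embeddings(corpus, dim=6, seed=3)
        np.testing.assert_array_equal(a.vector("AAA"), b.vector("AAA"))

    def test_missing_token_is_explicit(self):
        vocab = mb.train_kmer_embeddings([["AAA", "CCC"] * 3], dim=4, seed=0)
        with pytest.raises(KeyError):
            vocab.vector("WWW")
        assert vocab.get("WWW") is None

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            mb.train_kmer_embeddings([], dim=4, seed=0)

    def test_word2vec_text_round_trip(self, tmp_path):
        vocab = mb.train_kmer_embeddings([["AAA", "CCC"] * 3], dim=4, seed=1)
        p = tmp_path / "vecs.txt"
        vocab.save(p)
        back = mb.KmerVocabulary.load(p)
        np.testing.assert_array_equal(back.vector("AAA"), vocab.vector("AAA"))


class TestEmbedProtein:
    def _vocab(self, tokens):
        return mb.train_kmer_embeddings([list(tokens) * 3], dim=5, seed=0)

    def test_two_window_sum(self):
        vocab = self._vocab(["ACD", "CDE"])
        vec, cov = mb.embed_protein("ACDE", vocab)
        np.testing.assert_allclose(vec, vocab.vector("ACD") + vocab.vector("CDE"))
        assert cov == 1.0

    def test_repeated_pattern_closed_form(self):
        vocab = self._vocab(["AAA"])
        L = 10
        vec, cov = mb.embed_protein("A" * L, vocab)
        np.testing.assert_allclose(vec, (L - 2) * vocab.vector("AAA"))
        assert cov == 1.0

    def test_unknown_kmers_give_zero_vector_and_zero_coverage(self):
        vocab = self._vocab(["AAA"])
        vec, cov = mb.embed_protein("WWWW", vocab)
        assert np.all(vec == 0) and cov == 0.0

    def test_too_short_rejected(self):
        vocab = self._vocab(["AAA"])
        with pytest.raises(ValueError):
            mb.embed_protein("AA", vocab)

    def test_anagram_sequences_embed_differently(self):
        vocab = self._vocab(["ACD", "CDA", "DAC", "ADC", "DCA", "CAD"])
        v1, _ = mb.embed_protein("ACDAC", vocab)
        v2, _ = mb.embed_protein("CADCA", vocab)  # same residue multiset
        assert not np.allclose(v1, v2)


class TestSmilesTokenizer:
    @pytest.mark.parametrize(
        "smiles, expected",
        [
            ("CCO", ["C", "C", "O"]),
            ("CCl", ["C", "Cl"]),
            ("BrC", ["Br", "C"]),
            ("c1cc[nH]c1", ["c", "1", "c", "c", "[nH]", "c", "1"]),
            ("C(=O)O", ["C", "(", "=", "O", ")", "O"]),
        ],
    )
    def test_tokens(self, smiles, expected):
        assert mb.tokenize_smiles(smiles) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mb.tokenize_smiles("")


class TestHashedSmilesEncoder:
    def test_declared_dimension_and_finite(self):
        enc = mb.HashedSmilesEncoder(dim=128, seed=0)
        v = mb.embed_drug("CC(=O)Oc1ccccc1C(=O)O", enc)
        assert v.shape == (128,) and np.all(np.isfinite(v))

    def test_deterministic(self):
        enc = mb.HashedSmilesEncoder(dim=32, seed=5)
        np.testing.assert_array_equal(enc.encode("CCO"), enc.encode("CCO"))
        enc2 = mb.HashedSmilesEncoder(dim=32, seed=5)
        np.testing.assert_array_equal(enc.encode("CCO"), enc2.encode("CCO"))

    def test_distinct_smiles_distinct_vectors(self):
        enc = mb.HashedSmilesEncoder(dim=64, seed=0)
        assert not np.allclose(enc.encode("CCO"), enc.encode("c1ccccc1"))


class TestGruAutoencoder:
    def test_toy_corpus_reconstruction(self):
        smiles = ["CCO", "CCN", "c1ccccc1", "CC(=O)O", "CNC"]
        enc = mb.GruSmilesAutoencoder(
            dim=48, n_layers=2, learning_rate=0.01, dropout=0.0, epochs=150, seed=0
        )
        enc.fit_corpus(smiles)
        acc = enc.reconstruction_accuracy(smiles)
        assert acc >= 0.8, f"reconstruction accuracy {acc:.2f}"
        v = enc.encode("CCO")
        assert v.shape == (48,) and np.all(np.isfinite(v))

    def test_loss_decreases(self):
        enc = mb.GruSmilesAutoencoder(dim=16, epochs=30, dropout=0.0, seed=1)
        enc.fit_corpus(["CCO", "CCN"])
        hist = enc.model_.loss_history_
        assert hist[-1] < hist[0]


class TestCosineSimilarity:
    def test_matches_bruteforce_dot_products(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((3, 4))
        emb = EmbeddingMatrix(["a", "b", "c"], X)
        raw = np.empty((3, 3))
        for i in range(3):
            for j in range(3):
                raw[i, j] = X[i] @ X[j] / (np.linalg.norm(X[i]) * np.linalg.norm(X[j]))
        sim = mb.cosine_similarity_matrix(emb, normalize=False)
        np.testing.assert_allclose(sim.values, (raw + raw.T) / 2, atol=1e-12)

    def test_identical_and_orthogonal_vectors(self):
        emb = EmbeddingMatrix(["a", "b", "c"], [[1.0, 0.0], [1.0, 0.0], [0.0, 2.0]])
        sim = mb.cosine_similarity_matrix(emb, normalize=False)
        assert sim.values[0, 1] == pytest.approx(1.0)
        assert sim.values[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_scale_invariance_before_minmax(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((4, 5))
        a = mb.cosine_similarity_matrix(EmbeddingMatrix(list("abcd"), X), normalize=False)
        X2 = X.copy()
        X2[1] *= 7.3
        b = mb.cosine_similarity_matrix(EmbeddingMatrix(list("abcd"), X2), normalize=False)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_zero_row_warns_and_gets_zero_similarity(self):
        emb = EmbeddingMatrix(["a", "b"], [[0.0, 0.0], [1.0, 1.0]])
        with pytest.warns(UserWarning):
            sim = mb.cosine_similarity_matrix(emb, normalize=False)
        assert sim.values[0, 1] == 0.0

    def test_normalized_output_in_unit_interval(self):
        rng = np.random.default_rng(2)
        emb = EmbeddingMatrix([f"e{i}" for i in range(6)], rng.standard_normal((6, 8)))
        sim = mb.cosine_similarity_matrix(emb)
        assert sim.values.min() >= 0.0 and sim.values.max() <= 1.0


def test_tanimoto_fallback_properties():
    recs = [
        mb.SequenceRecord("a", "CCO"),
        mb.SequenceRecord("b", "CCO"),
        mb.SequenceRecord("c", "c1ccccc1"),
    ]
    sim = mb.tanimoto_ngram_similarity(recs)
    assert sim.values[0, 1] == pytest.approx(1.0)  # identical SMILES
    assert sim.values[0, 2] < 1.0
    assert np.all(np.diagonal(sim.values) == 1.0)


def test_embed_drug_records_builds_matrix(small_synthetic):
    emb = embed_drug_records(small_synthetic.smiles[:5], mb.HashedSmilesEncoder(dim=16))
    assert emb.dim == 16 and len(emb.entity_ids) == 5
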