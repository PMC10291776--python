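"""Generator contracts: determinism, acronym structure, separability, tables."""

import numpy as np
import pytest

from disann.corpus import write_conll
from disann.evaluation import evaluate_corpus
from disann.synthetic import (
    DEFAULT_LEXICON,
    GeneratorConfig,
    build_entity_lexicon,
    corpus_vocabulary,
    entity_word_groups,
    generate_bilingual_tables,
    generate_corpus,
    generate_embeddings,
    generate_raw_text,
    lexicon_oracle_predict,
    translate_corpus,
    translate_word,
)


def is_acronym(tok: str) -> bool:
    return len(tok) >= 2 and tok.isalpha() and tok == tok.upper()


class TestCorpusGeneration:
    def test_fixed_seed_is_byte_identical(self, tmp_path):
        cfg = GeneratorConfig(seed=7, n_documents=20, acronym_rate=0.3)
        p1, p2 = tmp_path / "a.conll", tmp_path / "b.conll"
        write_conll(generate_corpus(cfg), p1)
        write_conll(generate_corpus(cfg), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_zero_acronym_rate_means_no_acronyms(self):
        corpus = generate_corpus(GeneratorConfig(seed=5, n_documents=20, acronym_rate=0.0))
        toks = [t.text for d in corpus for s in d.sentences for t in s]
        assert not any(is_acronym(t) for t in toks)

    def test_full_acronym_rate_structure(self):
        corpus = generate_corpus(GeneratorConfig(seed=5, n_documents=15, acronym_rate=1.0))
        saw_definition = False
        for doc in corpus:
            acros = []
            for sent, gold in zip(doc.sentences, doc.gold_spans):
                words = [t.text for t in sent]
                for sp in gold:
                    if sp.last_token > sp.first_token:  # multi-token: a definition
                        assert words[sp.last_token] == ")"
                        assert words[sp.last_token - 2] == "("
                        acro = words[sp.last_token - 1]
                        assert is_acronym(acro)
                        acros.append(acro)
                        saw_definition = True
            all_words = [t.text for s in doc.sentences for t in s]
            for acro in acros:  # at least one later bare occurrence
                assert all_words.count(acro) >= 2
        assert saw_definition

    def test_gold_spans_satisfy_document_invariants(self):
        # AnnotatedDocument.validate runs in the constructor; reaching here
        # with a few hundred spans means offsets and bounds are coherent
        corpus = generate_corpus(GeneratorConfig(seed=9, n_documents=30, acronym_rate=0.5))
        assert corpus.n_gold_entities() > 50

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="acronym_rate"):
            generate_corpus(GeneratorConfig(acronym_rate=1.5))
        with pytest.raises(ValueError, match="lexicon"):
            generate_corpus(GeneratorConfig(entity_lexicon=[]))

    def test_background_vocabulary_shared_across_splits(self):
        a = generate_corpus(GeneratorConfig(seed=1, n_documents=5, acronym_rate=0.0))
        b = generate_corpus(GeneratorConfig(seed=2, n_documents=5, acronym_rate=0.0,
                                            split="test"))
        lex_words = {w for p in DEFAULT_LEXICON for w in p.split()}
        va = set(corpus_vocabulary(a)) - lex_words - {"(", ")"}
        vb = set(corpus_vocabulary(b)) - lex_words - {"(", ")"}
        assert vb <= va or va <= vb or (va & vb)  # heavy overlap expected
        assert len(va & vb) / max(len(va), 1) > 0.5


class TestSeparabilityOracle:
    @pytest.mark.parametrize("rate", [0.0, 0.3, 1.0])
    def test_lexicon_oracle_reaches_perfect_f1(self, rate):
        corpus = generate_corpus(GeneratorConfig(seed=13, n_documents=15,
                                                 acronym_rate=rate))
        oracle = lexicon_oracle_predict(corpus, DEFAULT_LEXICON)
        assert evaluate_corpus(oracle).f1 == 1.0


class TestLexiconAndTranslation:
    def test_lexicon_average_length(self):
        lens = [len(p.split()) for p in build_entity_lexicon()]
        assert 2.0 <= sum(lens) / len(lens) <= 2.8

    def test_translate_keeps_acronyms_and_punctuation(self):
        assert translate_word("CP") == "CP"
        assert translate_word("(") == "("

    def test_translate_rotates_vowels_deterministically(self):
        assert translate_word("sordera") == translate_word("sordera")
        assert translate_word("sordera") != "sordera"

    def test_parallel_corpus_preserves_spans(self):
        src, tgt = generate_corpus(GeneratorConfig(seed=3, n_documents=5, bilingual=True))
        assert [d.gold_spans for d in src] == [d.gold_spans for d in tgt]
        assert src.n_sentences() == tgt.n_sentences()


class TestEmbeddingsGeneration:
    def test_unit_norm_rows(self):
        table = generate_embeddings([f"w{i}" for i in range(100)], 8, seed=4)
        assert np.allclose(np.linalg.norm(table.matrix, axis=1), 1.0, atol=1e-9)

    def test_same_seed_identical(self):
        v = [f"w{i}" for i in range(20)]
        t1 = generate_embeddings(v, 8, seed=4)
        t2 = generate_embeddings(v, 8, seed=4)
        assert np.array_equal(t1.matrix, t2.matrix)

    def test_group_structure_clusters_words(self):
        v = [f"w{i}" for i in range(40)]
        groups = {w: "dis" for w in v[:20]}
        table = generate_embeddings(v, 16, seed=4, groups=groups, cohesion=0.8)
        inside = table.matrix[:20] @ table.matrix[:20].T
        across = table.matrix[:20] @ table.matrix[20:].T
        assert inside[np.triu_indices(20, 1)].mean() > across.mean() + 0.3

    def test_dimension_floor(self):
        with pytest.raises(ValueError):
            generate_embeddings(["a"], 1)

    def test_bilingual_pair_planted_rotation_recoverable(self):
        from disann.crosslingual import BilingualLexicon, procrustes_align
        vocab = [f"palabra{i}" for i in range(60)]
        src, tgt, pairs, Q = generate_bilingual_tables(vocab, 8, seed=6, noise=0.0)
        m = procrustes_align(src, tgt, BilingualLexicon(pairs))
        assert np.abs(m.W - Q).max() < 1e-6


def test_raw_text_generator_is_long_enough_and_deterministic():
    cfg = GeneratorConfig(seed=8, n_documents=10)
    t1 = generate_raw_text(cfg, min_chars=5000)
    assert len(t1) >= 5000
    assert t1 == generate_raw_text(cfg, min_chars=5000)


def test_entity_word_groups_cover_lexicon():
    groups = entity_word_groups(["perdida de vision", "sordera"])
    assert set(groups) == {"perdida", "de", "vision", "sordera"}
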