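"""Reference synthetic study conditions for the pipeline's evaluations.

Each task fixes a generated corpus pair and embedding resources (the corpus
and tables play the role the annotated corpus and pre-trained embeddings play
in a real study: they are fixed inputs, not per-run randomness), while the
caller supplies the tagger initialization seed — variability across seeds is
part of what the protocol measures.  Problem sizes are chosen for a single
desktop CPU: ~180 training sentences, embedding dimensions 32-48, one
BiLSTM layer of 48 units per direction.

Tasks
-----
separable_task      acronym-free corpus whose mentions are exactly the
                    lexicon phrases: a trained tagger should recover them
                    nearly perfectly (entity-recovery benchmark).
acronym_task        mentions defined with parenthesized acronyms that
                    re-occur bare later in the abstract: the A+ condition
                    has recall headroom over A-.
stack_comparison_task  static-only vs contextual-character-only vs stacked
                    input representations on the acronym corpus.
bilingual_task      parallel pseudo-language corpora plus source/target
                    tables related by a planted rotation (optionally noised),
                    for alignment and zero-shot transfer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .charlm import CharLanguageModel, CharLMConfig, CharLMEmbedder, train_char_lm
from .corpus import Corpus
from .crosslingual import BilingualLexicon
from .embeddings import EmbeddingStack, StaticEmbeddingTable
from .synthetic import (GeneratorConfig, corpus_vocabulary, entity_word_groups,
                        generate_bilingual_tables, generate_corpus,
                        generate_embeddings, generate_raw_text)
from .tagger import TrainingConfig

__all__ = ["RECOVERY_TRAINING", "ACRONYM_TRAINING", "STACK_TRAINING",
           "BILINGUAL_TRAINING", "separable_task", "acronym_task",
           "charlm_pair", "stack_comparison_task", "bilingual_task"]

# Training settings per task (seed is supplied by the caller).
RECOVERY_TRAINING = TrainingConfig(epochs=35, hidden_size=48, batch_size=8,
                                   lr=0.02, dev_fraction=0.15)
ACRONYM_TRAINING = TrainingConfig(epochs=30, hidden_size=48, batch_size=8,
                                  lr=0.02, dev_fraction=0.15)
STACK_TRAINING = TrainingConfig(epochs=25, hidden_size=48, batch_size=8,
                                lr=0.02, dev_fraction=0.15)
BILINGUAL_TRAINING = TrainingConfig(epochs=20, hidden_size=32, batch_size=8,
                                    lr=0.02, dev_fraction=0.15)


@dataclass
class TaggingTask:
    train: Corpus
    test: Corpus
    stack: EmbeddingStack
    table: StaticEmbeddingTable


def _task(train_seed: int, test_seed: int, acronym_rate: float,
          dim: int, emb_seed: int = 5) -> TaggingTask:
    gc_train = GeneratorConfig(seed=train_seed, n_documents=40,
                               acronym_rate=acronym_rate, split="train")
    gc_test = GeneratorConfig(seed=test_seed, n_documents=11,
                              acronym_rate=acronym_rate, split="test")
    train = generate_corpus(gc_train)
    test = generate_corpus(gc_test)
    groups = entity_word_groups(gc_train.entity_lexicon)
    table = generate_embeddings(corpus_vocabulary(train, test), dim,
                                seed=emb_seed, groups=groups)
    return TaggingTask(train=train, test=test,
                       stack=EmbeddingStack([table]), table=table)


def separable_task() -> TaggingTask:
    """~180/50 train/test sentences, no acronyms, 48-dim static embeddings."""
    return _task(train_seed=11, test_seed=12, acronym_rate=0.0, dim=48)


def acronym_task() -> TaggingTask:
    """Same scale with 30% of mentions acronym-defined (A+ headroom)."""
    return _task(train_seed=21, test_seed=22, acronym_rate=0.3, dim=48)


def charlm_pair(seed: int = 3, hidden_dim: int = 24,
                steps: int = 250) -> tuple[CharLanguageModel, CharLanguageModel]:
    """Forward/backward character LMs pre-trained on generated raw text."""
    raw = generate_raw_text(GeneratorConfig(seed=77, n_documents=40), min_chars=20000)
    fwd = train_char_lm(raw, CharLMConfig("forward", char_dim=12, hidden_dim=hidden_dim,
                                          chars_per_batch=96, steps=steps, lr=8e-3,
                                          seed=seed))
    bwd = train_char_lm(raw, CharLMConfig("backward", char_dim=12, hidden_dim=hidden_dim,
                                          chars_per_batch=96, steps=steps, lr=8e-3,
                                          seed=seed))
    return fwd, bwd


def stack_comparison_task(lm_seed: int = 3) -> tuple[TaggingTask, dict[str, EmbeddingStack]]:
    """Acronym corpus with three input representations to compare.

    The static table here is 32-dimensional — weak enough that the contextual
    character component contributes complementary (subword-shape) signal, as
    in the full-scale finding that stacking embedding types helps.
    """
    base = _task(train_seed=21, test_seed=22, acronym_rate=0.3, dim=32)
    fwd, bwd = charlm_pair(seed=lm_seed)
    clm = CharLMEmbedder(fwd, bwd)
    stacks = {
        "static": EmbeddingStack([base.table]),
        "charlm": EmbeddingStack([clm]),
        "stacked": EmbeddingStack([base.table, clm]),
    }
    return base, stacks


@dataclass
class BilingualTask:
    train_src: Corpus
    test_src: Corpus
    test_tgt: Corpus
    src_table: StaticEmbeddingTable
    tgt_table: StaticEmbeddingTable
    lexicon: BilingualLexicon
    rotation: np.ndarray


def bilingual_task(noise: float = 0.1, dim: int = 32) -> BilingualTask:
    """Parallel corpora and rotated (optionally noised) embedding tables."""
    train_src, _ = generate_corpus(GeneratorConfig(seed=31, n_documents=30,
                                                   bilingual=True, split="train"))
    test_src, test_tgt = generate_corpus(GeneratorConfig(seed=32, n_documents=10,
                                                         bilingual=True, split="test"))
    vocab = corpus_vocabulary(train_src, test_src)
    groups = entity_word_groups(GeneratorConfig().entity_lexicon)
    src, tgt, pairs, Q = generate_bilingual_tables(vocab, dim, seed=9,
                                                   noise=noise, groups=groups)
    return BilingualTask(train_src=train_src, test_src=test_src, test_tgt=test_tgt,
                         src_table=src, tgt_table=tgt,
                         lexicon=BilingualLexicon(pairs), rotation=Q)
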