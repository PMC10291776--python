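"""Contextual character-level word embeddings.

Trains small forward and backward character LMs on generated raw text and
extracts per-token vectors: the forward hidden state after a word's last
character concatenated with the backward state at its first character.  The
same word gets different vectors in different sentences.
"""

import numpy as np

from disann import CharLMConfig, GeneratorConfig, extract_word_embeddings, tokenize, train_char_lm
from disann.synthetic import generate_raw_text

raw = generate_raw_text(GeneratorConfig(seed=77, n_documents=30), min_chars=15000)
fwd = train_char_lm(raw, CharLMConfig("forward", char_dim=12, hidden_dim=24,
                                      chars_per_batch=96, steps=200, lr=8e-3, seed=3))
bwd = train_char_lm(raw, CharLMConfig("backward", char_dim=12, hidden_dim=24,
                                      chars_per_batch=96, steps=200, lr=8e-3, seed=3))
print(f"held-out cross-entropy: fwd {fwd.cross_entropy(raw[-800:]):.3f}, "
      f"bwd {bwd.cross_entropy(raw[-800:]):.3f} nats/char")

s1 = tokenize("sordera neurosensorial ( SN ) severa")
s2 = tokenize("retraso global con SN bilateral")
e1 = extract_word_embeddings(fwd, bwd, s1)
e2 = extract_word_embeddings(fwd, bwd, s2)
print("embedding matrix shape:", e1.shape, "(tokens x 2*hidden)")
i1 = [t.text for t in s1].index("SN")
i2 = [t.text for t in s2].index("SN")
cos = float(e1[i1] @ e2[i2] / (np.linalg.norm(e1[i1]) * np.linalg.norm(e2[i2])))
print(f"cosine('SN' in context 1, 'SN' in context 2) = {cos:.3f}  (< 1: contextual)")
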