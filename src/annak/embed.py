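"""Deterministic fallback text embedder for tests and examples.

Real analyses consume document embeddings produced upstream by a
sentence-embedding model (e.g. a 768-dimensional SBERT vector per
subject); those vectors are inputs to this package. This module provides
only a synthetic stand-in — an L2-normalized term-frequency vector over a
fixed vocabulary — so that the semantic-dissimilarity code path can be
exercised end-to-end without any language model. It is NOT equivalent to
a sentence embedding and must not be used for substantive analyses.
"""

from __future__ import annotations

import re

import numpy as np

__all__ = ["TermFrequencyEmbedder"]

_TOKEN = re.compile(r"[a-z']+")


class TermFrequencyEmbedder:
    """L2-normalized term-frequency embedding over a fixed vocabulary.

    Out-of-vocabulary tokens are ignored; a document with no in-vocabulary
    tokens raises, since a zero vector has no cosine direction.
    """

    def __init__(self, vocabulary: list[str]):
        vocab = [w.lower() for w in vocabulary]
        if len(set(vocab)) != len(vocab):
            raise ValueError("vocabulary entries must be unique")
        if not vocab:
            raise ValueError("vocabulary must be non-empty")
        self.vocabulary = vocab
        self._index = {w: i for i, w in enumerate(vocab)}

    @property
    def dim(self) -> int:
        return len(self.vocabulary)

    def embed(self, text: str) -> np.ndarray:
        counts = np.zeros(self.dim)
        for tok in _TOKEN.findall(text.lower()):
            i = self._index.get(tok)
            if i is not None:
                counts[i] += 1.0
        norm = np.linalg.norm(counts)
        if norm == 0:
            raise ValueError("no in-vocabulary tokens; embedding undefined")
        return counts / norm
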