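"""Text embedding providers for the angular text-similarity metric.

The text similarity contract only needs a map from strings to fixed-length
nonzero vectors.  The default provider is a deterministic character
n-gram hashing embedder: it needs no model download, is stable across
runs, and maps similar strings to similar vectors (shared n-grams hash to
shared coordinates).  A sentence-transformer backend can be plugged in by
passing any object with the same ``embed`` method.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["HashingEmbedder"]


class HashingEmbedder:
    """Character n-gram hashing embedder.

    Each n-gram of the lowercased text is hashed (BLAKE2, keyed by
    ``seed``) into one of ``dim`` buckets with a ±1 sign; the vector of
    bucket counts is the embedding.  Identical texts embed identically;
    texts sharing many n-grams have high cosine similarity.
    """

    def __init__(self, dim: int = 256, ngram: int = 3, seed: int = 0):
        if dim < 2 or ngram < 1:
            raise ValueError("dim must be >= 2 and ngram >= 1")
        self.dim = dim
        self.ngram = ngram
        self._key = seed.to_bytes(8, "little", signed=True)

    def _bucket(self, gram: str) -> tuple[int, float]:
        h = hashlib.blake2b(gram.encode("utf-8"), key=self._key, digest_size=8)
        val = int.from_bytes(h.digest(), "little")
        return val % self.dim, 1.0 if (val >> 63) & 1 else -1.0

    def embed(self, text: str) -> np.ndarray:
        s = " ".join(text.lower().split())
        padded = f" {s} "
        vec = np.zeros(self.dim)
        grams = [padded[i : i + self.ngram] for i in range(max(1, len(padded) - self.ngram + 1))]
        for gram in grams:
            idx, sign = self._bucket(gram)
            vec[idx] += sign
        if not vec.any():
            # Degenerate text (e.g. empty string): a fixed unit vector keeps
            # the embedder total while identical texts still match exactly.
            vec[0] = 1.0
        return vec
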