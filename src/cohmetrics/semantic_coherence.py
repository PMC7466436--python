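"""TF-IDF-weighted sentence embeddings and the adjacent-sentence coherence metric.

A sentence S = {w_1, ..., w_n} of retained tokens is embedded as the mean of
its word vectors, each scaled by a TF-IDF weight a_i:

    S_v = (1/n) * sum_i  w_i * a_i

The default weighting scheme is the plain ratio a = tf / df — the number of
occurrences of the word in the sentence of interest over the number of
reference-corpus documents that contain it — which damps very frequent,
semantically poor words (articles, prepositions) to near-zero contribution.
The conventional logarithmic variant a = tf * ln(N / df) is available as an
alternative.

The transcript-level score (ACM, "automatically derived coherence metric") is
the mean cosine similarity between embeddings of *adjacent* sentences:

    Coherence(T) = (1/(n-1)) * sum_i  sim(S_vi, S_vi+1)

Sentences with no retained tokens are skipped and their neighbours re-linked,
so every surviving adjacency contributes exactly one similarity; skips are
counted and reported for audit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus_io import DocFrequencyTable, TranscriptDocument, WordVectorTable
from .preprocess import (
    PreprocessConfig,
    ProcessedSentence,
    filter_sentences,
    mark_oov,
)


class UndefinedSimilarityError(ValueError):
    """Cosine similarity is undefined for a zero-magnitude vector."""


class InsufficientContentError(ValueError):
    """Fewer than two embeddable sentences: no adjacent pair exists."""


@dataclass
class SentenceEmbedding:
    vector: np.ndarray
    contributing_n: int
    origin: tuple[int, int]


@dataclass
class SkippedSentence:
    origin: tuple[int, int]
    reason: str


@dataclass
class CoherenceProfile:
    """Per-adjacent-pair cosine similarities and their mean for one transcript."""

    pair_similarities: list[float]
    acm: float
    skipped: list[SkippedSentence] = field(default_factory=list)
    config_digest: str | None = None


def tfidf_weight(tf: int, df: int, N: int, scheme: str = "ratio") -> float:
    """Weight for a word occurring ``tf`` times in its sentence.

    ``df`` is the reference-corpus document count (0 = lemma absent from the
    table, treated as 1: a maximally informative word); ``N`` the corpus size.
    """
    if tf < 1:
        raise ValueError("tfidf_weight requires tf >= 1 (weights only for present words)")
    if N < 1:
        raise ValueError("corpus size N must be >= 1")
    if df < 0:
        raise ValueError("df must be >= 0")
    df_eff = max(df, 1)
    if scheme == "ratio":
        return tf / df_eff
    if scheme == "log-idf":
        return tf * math.log(N / df_eff)
    raise ValueError(f"unknown TF-IDF scheme {scheme!r}")


def embed_sentence(
    sentence: ProcessedSentence,
    vectors: WordVectorTable,
    df_table: DocFrequencyTable,
    scheme: str = "ratio",
) -> SentenceEmbedding | SkippedSentence:
    """S_v = (1/n) sum w_i a_i over the retained tokens; skip if n = 0.

    DF lookup is by lemma when the preprocessing configured a lemmatizer
    (tokens then carry lemmas), else by lowercased surface form.
    """
    retained = sentence.retained_tokens
    if not retained:
        return SkippedSentence(origin=sentence.origin, reason="no retained tokens")
    keys = [t.lemma if t.lemma is not None else t.key for t in retained]
    tf = {k: keys.count(k) for k in set(keys)}
    acc = np.zeros(vectors.dimension)
    for tok, key in zip(retained, keys):
        vec = vectors.get(tok.key)
        if vec is None:
            raise RuntimeError(
                f"token {tok.surface!r} retained but absent from the vector table; "
                "run mark_oov before embedding"
            )
        df = df_table.get(key)
        a = tfidf_weight(tf[key], df if df is not None else 0, df_table.total_documents, scheme)
        acc += vec * a
    vector = acc / len(retained)
    if not np.all(np.isfinite(vector)):
        raise RuntimeError(f"non-finite sentence embedding at {sentence.origin}")
    return SentenceEmbedding(vector=vector, contributing_n=len(retained), origin=sentence.origin)


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """(A.B)/(||A|| ||B||), clamped to [-1, 1] against rounding."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise UndefinedSimilarityError("cosine similarity undefined for zero-magnitude vector")
    return float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))


def coherence_score(
    embeddings: Sequence[SentenceEmbedding | SkippedSentence],
    participant_id: str = "?",
    config_digest: str | None = None,
) -> CoherenceProfile:
    """Mean cosine similarity between adjacent sentence embeddings.

    Skipped sentences are removed before pairing (their neighbours re-link);
    at least two embedded sentences are required.
    """
    kept = [e for e in embeddings if isinstance(e, SentenceEmbedding)]
    skipped = [e for e in embeddings if isinstance(e, SkippedSentence)]
    if len(kept) < 2:
        raise InsufficientContentError(
            f"participant {participant_id}: {len(kept)} embeddable sentence(s), "
            "need at least 2 for an adjacent pair"
        )
    sims = [
        cosine_similarity(a.vector, b.vector) for a, b in zip(kept, kept[1:])
    ]
    return CoherenceProfile(
        pair_similarities=sims,
        acm=float(np.mean(sims)),
        skipped=skipped,
        config_digest=config_digest,
    )


def analyze_transcript(
    doc: TranscriptDocument,
    vectors: WordVectorTable,
    df_table: DocFrequencyTable,
    config: PreprocessConfig | None = None,
    scheme: str = "ratio",
) -> CoherenceProfile:
    """Full chain: strip/filter -> OOV marking -> embed -> adjacent-pair score."""
    config = config or PreprocessConfig()
    sentences, _ = filter_sentences(doc, config)
    sentences, _ = mark_oov(sentences, vectors)
    embedded = [embed_sentence(s, vectors, df_table, scheme) for s in sentences]
    return coherence_score(embedded, doc.participant_id, config.digest())
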