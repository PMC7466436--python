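"""Cleaning and tokenization of interview transcripts.

The pipeline order is fixed: strip the interviewer's turns, tokenize,
remove verbal fillers and drop sentences that contain nothing but stop
words, then flag out-of-vocabulary tokens against the embedding table.
The interviewer is removed because their speech reduces to the fixed
interview questions; fillers and all-stopword sentences are removed because
they bias similarity-based coherence measures.

By default stop-word *tokens* inside mixed sentences are kept
(``remove_stopword_tokens=False``): only sentences consisting solely of stop
words are dropped.  The stricter variant that also removes stop-word tokens
from surviving sentences is available as a configuration switch.
"""

from __future__ import annotations

import hashlib
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Mapping

from .corpus_io import TranscriptDocument, WordVectorTable

log = logging.getLogger(__name__)

_TOKEN_RE = re.compile(r"\w+", re.UNICODE)


class EmptyDocumentError(ValueError):
    """Raised when an operation would leave no participant speech."""


@dataclass
class Token:
    surface: str
    lemma: str | None = None
    flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.surface:
            raise ValueError("token surface must be non-empty")

    @property
    def key(self) -> str:
        """Lowercased surface used for all lookups."""
        return self.surface.lower()


@dataclass
class ProcessedSentence:
    tokens: list[Token]
    retained_tokens: list[Token]
    origin: tuple[int, int]  # (utterance index, sentence index)


def _load_wordlist(name: str) -> frozenset[str]:
    text = resources.files("cohmetrics").joinpath("data", name).read_text(encoding="utf-8")
    return frozenset(w.strip() for w in text.splitlines() if w.strip() and not w.startswith("#"))


def load_default_stopwords() -> frozenset[str]:
    return _load_wordlist("stopwords_de.txt")


def load_default_fillers() -> frozenset[str]:
    return _load_wordlist("fillers_de.txt")


@dataclass
class PreprocessConfig:
    """Cleaning configuration; serialized (digested) into results for provenance.

    The lemmatizer is pluggable — a callable or a surface→lemma lookup table —
    and is used only for document-frequency lookups and dictionary matching;
    embedding lookup always uses lowercased surface forms.
    """

    stopword_list: frozenset[str] = field(default_factory=load_default_stopwords)
    filler_list: frozenset[str] = field(default_factory=load_default_fillers)
    remove_stopword_tokens: bool = False
    drop_interviewer: bool = True
    lemmatizer: Callable[[str], str] | Mapping[str, str] | None = None

    def lemma_of(self, surface: str) -> str | None:
        key = surface.lower()
        if self.lemmatizer is None:
            return None
        if callable(self.lemmatizer):
            return self.lemmatizer(key)
        return self.lemmatizer.get(key, key)

    def digest(self) -> str:
        payload = "|".join(
            [
                ",".join(sorted(self.stopword_list)),
                ",".join(sorted(self.filler_list)),
                str(self.remove_stopword_tokens),
                str(self.drop_interviewer),
                "lemmatized" if self.lemmatizer is not None else "surface",
            ]
        )
        return hashlib.sha1(payload.encode("utf-8")).hexdigest()[:12]


def strip_interviewer(doc: TranscriptDocument) -> TranscriptDocument:
    """Drop interviewer turns, keeping prompt metadata on participant turns."""
    kept = doc.participant_utterances()
    if not kept:
        raise EmptyDocumentError(
            f"{doc.participant_id}: no participant utterances after stripping interviewer"
        )
    return TranscriptDocument(
        participant_id=doc.participant_id, utterances=kept, metadata=dict(doc.metadata)
    )


def tokenize(sentence: str) -> list[Token]:
    """Whitespace/punctuation tokenization; punctuation is not a word."""
    if not sentence.strip():
        log.warning("tokenize called on empty/blank sentence")
        return []
    tokens = [Token(surface=m.group(0)) for m in _TOKEN_RE.finditer(sentence)]
    if not tokens:
        log.warning("sentence %r contains no word tokens", sentence)
    return tokens


def filter_sentences(
    doc: TranscriptDocument, config: PreprocessConfig | None = None
) -> tuple[list[ProcessedSentence], dict[str, int]]:
    """Apply the filler/stop-word filtering rules.

    Returns the surviving sentences (with per-category removal counts):
    filler tokens are removed everywhere; a sentence whose remaining tokens
    are all stop words is dropped entirely; stop-word tokens are additionally
    removed from surviving sentences only if ``remove_stopword_tokens``.
    """
    config = config or PreprocessConfig()
    if config.drop_interviewer:
        doc = strip_interviewer(doc)
    counts = {
        "fillers_removed": 0,
        "stopword_tokens_removed": 0,
        "sentences_dropped": 0,
        "tokens_in_dropped_sentences": 0,
        "tokens_raw": 0,
        "tokens_retained": 0,
    }
    out: list[ProcessedSentence] = []
    for ui, utt in enumerate(doc.utterances):
        for si, sent in enumerate(utt.sentences):
            tokens = tokenize(sent)
            counts["tokens_raw"] += len(tokens)
            for t in tokens:
                if t.key in config.filler_list:
                    t.flags.add("filler")
                elif t.key in config.stopword_list:
                    t.flags.add("stopword")
                if config.lemmatizer is not None:
                    t.lemma = config.lemma_of(t.surface)
            non_filler = [t for t in tokens if "filler" not in t.flags]
            counts["fillers_removed"] += len(tokens) - len(non_filler)
            if not non_filler or all("stopword" in t.flags for t in non_filler):
                counts["sentences_dropped"] += 1
                counts["tokens_in_dropped_sentences"] += len(non_filler)
                continue
            if config.remove_stopword_tokens:
                retained = [t for t in non_filler if "stopword" not in t.flags]
                counts["stopword_tokens_removed"] += len(non_filler) - len(retained)
            else:
                retained = non_filler
            counts["tokens_retained"] += len(retained)
            out.append(ProcessedSentence(tokens=tokens, retained_tokens=retained, origin=(ui, si)))
    if not out:
        log.warning("%s: no sentences survive filtering", doc.participant_id)
    return out, counts


@dataclass
class OovReport:
    """Out-of-vocabulary tokens, saved for later examination (neologism screening)."""

    misses: list[tuple[str, tuple[int, int], int]] = field(default_factory=list)
    # (surface, sentence origin, position within the sentence's token list)

    @property
    def surfaces(self) -> list[str]:
        return [m[0] for m in self.misses]

    def __len__(self) -> int:
        return len(self.misses)


def mark_oov(
    sentences: list[ProcessedSentence], vectors: WordVectorTable
) -> tuple[list[ProcessedSentence], OovReport]:
    """Flag retained tokens absent from the embedding table and exclude them.

    Lookup uses the lowercased surface form.  Misses are flagged ``oov``,
    removed from ``retained_tokens``, and listed with positions in the report.
    """
    report = OovReport()
    for sent in sentences:
        position = {id(t): i for i, t in enumerate(sent.tokens)}
        survivors = []
        for t in sent.retained_tokens:
            if t.key in vectors:
                survivors.append(t)
            else:
                t.flags.add("oov")
                report.misses.append((t.surface, sent.origin, position[id(t)]))
        sent.retained_tokens = survivors
    return sentences, report


def raw_participant_tokens(doc: TranscriptDocument) -> list[Token]:
    """All participant tokens before any filtering (the 'raw data set')."""
    tokens: list[Token] = []
    for utt in doc.participant_utterances():
        for sent in utt.sentences:
            tokens.extend(tokenize(sent))
    return tokens
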