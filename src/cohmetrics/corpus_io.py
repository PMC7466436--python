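"""Readers and writers for every external artifact the pipeline consumes.

Transcripts come in two dialects: *tagged text* (``I:`` / ``P:`` speaker
prefixes, one sentence per line, ``#emotion/question`` prompt markers) and
*records* (a JSON document with explicit fields).  Word vectors are read from
word2vec-style plain text, document frequencies from a two-column table with a
``#total_documents=N`` header, category dictionaries from the LIWC ``.dic``
dialect, and standoff annotations (ambiguous referents, curated neologisms)
from JSON records.  Everything is UTF-8; umlauts and "ß" are never normalised
away because embedding lookup is surface-form sensitive.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

EMOTIONS = ("sadness", "fear", "anger", "happiness")
QUESTIONS = (1, 2, 3)


class TranscriptParseError(ValueError):
    """Raised when a transcript file violates its declared dialect."""


class FormatError(ValueError):
    """Raised for malformed vector / table / dictionary files."""


class ValidationError(ValueError):
    """Raised when a parsed artifact breaks a domain invariant."""


class Speaker(str, Enum):
    INTERVIEWER = "interviewer"
    PARTICIPANT = "participant"


class Prompt(NamedTuple):
    """Position in the interview structure: emotion x question number."""

    emotion: str
    question: int

    @classmethod
    def parse(cls, marker: str, line_no: int | None = None) -> "Prompt":
        where = f" (line {line_no})" if line_no is not None else ""
        try:
            emotion, q = marker.split("/")
            question = int(q)
        except ValueError:
            raise ValidationError(f"malformed prompt marker {marker!r}{where}") from None
        if emotion not in EMOTIONS:
            raise ValidationError(f"unknown emotion code {emotion!r}{where}")
        if question not in QUESTIONS:
            raise ValidationError(f"question number must be 1-3, got {q!r}{where}")
        return cls(emotion, question)


@dataclass
class Utterance:
    speaker: Speaker
    sentences: list[str]
    prompt: Prompt | None = None

    def __post_init__(self) -> None:
        self.speaker = Speaker(self.speaker)
        if any(not s for s in self.sentences):
            raise ValidationError("utterance contains an empty sentence")


@dataclass
class TranscriptDocument:
    """One participant's interview: ordered utterances with speaker roles."""

    participant_id: str
    utterances: list[Utterance]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.participant_id:
            raise ValidationError("participant_id must be non-empty")

    def participant_utterances(self) -> list[Utterance]:
        return [u for u in self.utterances if u.speaker is Speaker.PARTICIPANT]


class WordVectorTable:
    """Embedding lookup table; absent words are a detectable miss (None)."""

    def __init__(self, dimension: int, entries: Mapping[str, np.ndarray]):
        if dimension < 1:
            raise ValidationError("dimension must be positive")
        self.dimension = int(dimension)
        self.entries: dict[str, np.ndarray] = {}
        for word, vec in entries.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (self.dimension,):
                raise ValidationError(
                    f"vector for {word!r} has shape {vec.shape}, expected ({self.dimension},)"
                )
            self.entries[word] = vec

    def get(self, word: str) -> np.ndarray | None:
        return self.entries.get(word)

    def __contains__(self, word: str) -> bool:
        return word in self.entries

    def __len__(self) -> int:
        return len(self.entries)


class DocFrequencyTable:
    """Reference-corpus document counts driving TF-IDF weights."""

    def __init__(self, total_documents: int, counts: Mapping[str, int]):
        if total_documents < 1:
            raise ValidationError("total_documents must be positive")
        self.total_documents = int(total_documents)
        self.counts: dict[str, int] = {}
        for lemma, df in counts.items():
            df = int(df)
            if not 1 <= df <= self.total_documents:
                raise ValidationError(
                    f"df({lemma!r})={df} outside [1, {self.total_documents}]"
                )
            self.counts[lemma] = df

    def get(self, lemma: str) -> int | None:
        """Document count, or None for a lemma absent from the table."""
        return self.counts.get(lemma)


class CategoryDictionary:
    """LIWC-style category dictionary: literal words plus trailing-``*`` stems."""

    def __init__(self, categories: Mapping[str, Sequence[str]]):
        self.categories: dict[str, list[str]] = {}
        for name, patterns in categories.items():
            if name in self.categories:
                raise ValidationError(f"duplicate category {name!r}")
            pats = []
            for p in patterns:
                if "*" in p[:-1]:
                    raise ValidationError(f"wildcard only allowed in final position: {p!r}")
                pats.append(p.lower())
            self.categories[name] = pats

    def match(self, token: str) -> set[str]:
        """Categories a (lowercased) token falls into; may be several."""
        token = token.lower()
        hit = set()
        for name, patterns in self.categories.items():
            for p in patterns:
                if p.endswith("*"):
                    if token.startswith(p[:-1]):
                        hit.add(name)
                        break
                elif token == p:
                    hit.add(name)
                    break
        return hit


@dataclass
class AnnotationSet:
    """Standoff annotations: ambiguous-referent spans and curated neologisms.

    Spans address token positions produced by :func:`cohmetrics.preprocess.tokenize`
    applied to the sentences of the addressed utterance, flattened in order.
    """

    participant_id: str
    ambiguous_referent_spans: list[tuple[int, tuple[int, int]]] = field(default_factory=list)
    neologism_tokens: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for utt, (start, end) in self.ambiguous_referent_spans:
            if start < 0 or end <= start:
                raise ValidationError(f"bad span ({start}, {end}) in utterance {utt}")
        by_utt: dict[int, list[tuple[int, int]]] = {}
        for utt, span in self.ambiguous_referent_spans:
            by_utt.setdefault(utt, []).append(span)
        for utt, spans in by_utt.items():
            spans = sorted(spans)
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                if s2 < e1:
                    raise ValidationError(
                        f"overlapping ambiguous-referent spans in utterance {utt}"
                    )

    def validate_against(self, doc: TranscriptDocument, token_counts: Sequence[int]) -> None:
        """Check every span/index addresses an existing token of *doc*.

        ``token_counts[i]`` is the token count of utterance ``i``.
        """
        n_utt = len(doc.utterances)
        for utt, (start, end) in self.ambiguous_referent_spans:
            if utt >= n_utt or end > token_counts[utt]:
                raise ValidationError(
                    f"ambiguous-referent span ({start},{end}) out of range in utterance {utt}"
                )
        for surface, utt, tok in self.neologism_tokens:
            if utt >= n_utt or tok >= token_counts[utt]:
                raise ValidationError(
                    f"neologism index {tok} out of range in utterance {utt} ({surface!r})"
                )


# ---------------------------------------------------------------------------
# transcripts

def read_transcript(path: str | Path, format: str = "tagged-text") -> TranscriptDocument:
    path = Path(path)
    if format == "tagged-text":
        return _read_tagged_text(path)
    if format == "records":
        return _read_records(path)
    raise ValueError(f"unknown transcript format {format!r}")


def _read_tagged_text(path: Path) -> TranscriptDocument:
    participant_id = path.stem
    utterances: list[Utterance] = []
    current: Utterance | None = None
    prompt: Prompt | None = None
    with open(path, encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("# participant:"):
                participant_id = line.split(":", 1)[1].strip()
                continue
            if line.startswith("#") and "/" not in line:
                continue  # comment
            try:
                tag, rest = line.split(":", 1)
            except ValueError:
                raise TranscriptParseError(f"missing speaker tag on line {line_no}")
            if tag == "I":
                speaker = Speaker.INTERVIEWER
            elif tag == "P":
                speaker = Speaker.PARTICIPANT
            else:
                raise TranscriptParseError(f"unknown speaker tag {tag + ':'!r} on line {line_no}")
            rest = rest.strip()
            if rest.startswith("#"):
                marker, _, rest = rest[1:].partition(" ")
                prompt = Prompt.parse(marker, line_no)
                rest = rest.strip()
            if not rest:
                raise TranscriptParseError(f"empty sentence on line {line_no}")
            if current is not None and current.speaker is speaker and current.prompt == prompt:
                current.sentences.append(rest)
            else:
                current = Utterance(speaker=speaker, sentences=[rest], prompt=prompt)
                utterances.append(current)
    if not utterances:
        raise TranscriptParseError(f"{path}: no utterances found")
    return TranscriptDocument(participant_id=participant_id, utterances=utterances)


def _read_records(path: Path) -> TranscriptDocument:
    with open(path, encoding="utf-8") as fh:
        rec = json.load(fh)
    utterances = []
    for i, u in enumerate(rec["utterances"]):
        prompt = None
        if u.get("prompt") is not None:
            p = u["prompt"]
            prompt = Prompt.parse(f"{p['emotion']}/{p['question']}")
        try:
            speaker = Speaker(u["speaker"])
        except ValueError:
            raise TranscriptParseError(
                f"unknown speaker {u['speaker']!r} in utterance {i}"
            ) from None
        utterances.append(Utterance(speaker=speaker, sentences=list(u["sentences"]), prompt=prompt))
    return TranscriptDocument(
        participant_id=rec["participant_id"],
        utterances=utterances,
        metadata=dict(rec.get("metadata", {})),
    )


def write_transcript(doc: TranscriptDocument, path: str | Path, format: str = "records") -> None:
    path = Path(path)
    if format == "records":
        rec = {
            "participant_id": doc.participant_id,
            "metadata": doc.metadata,
            "utterances": [
                {
                    "speaker": u.speaker.value,
                    "prompt": (
                        {"emotion": u.prompt.emotion, "question": u.prompt.question}
                        if u.prompt
                        else None
                    ),
                    "sentences": u.sentences,
                }
                for u in doc.utterances
            ],
        }
        path.write_text(json.dumps(rec, ensure_ascii=False, indent=1), encoding="utf-8")
    elif format == "tagged-text":
        lines = [f"# participant: {doc.participant_id}"]
        prev_prompt: Prompt | None = None
        for u in doc.utterances:
            tag = "I" if u.speaker is Speaker.INTERVIEWER else "P"
            for j, sent in enumerate(u.sentences):
                marker = ""
                if j == 0 and u.prompt is not None and u.prompt != prev_prompt:
                    marker = f"#{u.prompt.emotion}/{u.prompt.question} "
                lines.append(f"{tag}: {marker}{sent}")
            prev_prompt = u.prompt
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown transcript format {format!r}")


# ---------------------------------------------------------------------------
# vectors & document frequencies

def read_vectors(path: str | Path) -> WordVectorTable:
    """Read a word2vec-style text file (optional ``V D`` header line)."""
    path = Path(path)
    entries: dict[str, np.ndarray] = {}
    declared_dim: int | None = None
    dim: int | None = None
    with open(path, encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            parts = raw.split()
            if not parts:
                continue
            if line_no == 1 and len(parts) == 2:
                try:
                    declared_dim = int(parts[1])
                    int(parts[0])
                    continue
                except ValueError:
                    pass  # a 1-d vector line, not a header
            word, *vals = parts
            try:
                vec = np.array([float(v) for v in vals])
            except ValueError:
                raise FormatError(f"{path}: non-numeric vector component on line {line_no}")
            if dim is None:
                dim = len(vec)
                if declared_dim is not None and dim != declared_dim:
                    raise FormatError(
                        f"{path}: header declares dimension {declared_dim} "
                        f"but line {line_no} has {dim} components"
                    )
            elif len(vec) != dim:
                raise FormatError(
                    f"{path}: ragged row on line {line_no} ({len(vec)} components, expected {dim})"
                )
            if word in entries:
                log.warning("duplicate vector for %r (line %d); last occurrence wins", word, line_no)
            entries[word] = vec
    if not entries:
        raise FormatError(f"{path}: empty vector file")
    return WordVectorTable(dimension=dim, entries=entries)


def write_vectors(table: WordVectorTable, path: str | Path, header: bool = True) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(f"{len(table)} {table.dimension}\n")
        for word, vec in table.entries.items():
            fh.write(word + " " + " ".join(f"{v:.6g}" for v in vec) + "\n")


def read_df_table(path: str | Path) -> DocFrequencyTable:
    path = Path(path)
    total: int | None = None
    counts: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#total_documents="):
                total = int(line.split("=", 1)[1])
                continue
            if line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(f"{path}: expected 'lemma count' on line {line_no}")
            counts[parts[0]] = int(parts[1])
    if total is None:
        raise FormatError(f"{path}: missing '#total_documents=N' header")
    return DocFrequencyTable(total_documents=total, counts=counts)


def write_df_table(table: DocFrequencyTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#total_documents={table.total_documents}\n")
        for lemma, df in table.counts.items():
            fh.write(f"{lemma}\t{df}\n")


# ---------------------------------------------------------------------------
# dictionary, annotations, tables

def read_dictionary(path: str | Path) -> CategoryDictionary:
    """Read a LIWC ``.dic``-dialect dictionary.

    Layout: a ``%``-delimited header of ``id<TAB>name`` lines, then
    ``word id id ...`` entry lines; stems carry a trailing ``*``.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    names: dict[str, str] = {}
    categories: dict[str, list[str]] = {}
    in_header = False
    header_done = False
    for line_no, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line == "%":
            if not header_done:
                if in_header:
                    header_done = True
                in_header = not in_header
            continue
        if in_header:
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"{path}: malformed header line {line_no}")
            cat_id, name = parts[0], parts[1]
            if name in categories:
                raise ValidationError(f"{path}: duplicate category name {name!r}")
            names[cat_id] = name
            categories[name] = []
        else:
            word, *ids = line.split()
            if not ids:
                raise FormatError(f"{path}: entry without category ids on line {line_no}")
            for cat_id in ids:
                if cat_id not in names:
                    raise ValidationError(
                        f"{path}: category id {cat_id!r} referenced on line {line_no} "
                        "but never declared"
                    )
                categories[names[cat_id]].append(word.lower())
    return CategoryDictionary(categories)


def read_annotations(path: str | Path) -> AnnotationSet:
    with open(path, encoding="utf-8") as fh:
        rec = json.load(fh)
    return AnnotationSet(
        participant_id=rec["participant_id"],
        ambiguous_referent_spans=[
            (int(a["utterance"]), (int(a["start"]), int(a["end"])))
            for a in rec.get("ambiguous_referents", [])
        ],
        neologism_tokens=[
            (n["surface"], int(n["utterance"]), int(n["token"]))
            for n in rec.get("neologisms", [])
        ],
    )


def write_annotations(ann: AnnotationSet, path: str | Path) -> None:
    rec = {
        "participant_id": ann.participant_id,
        "ambiguous_referents": [
            {"utterance": u, "start": s, "end": e} for u, (s, e) in ann.ambiguous_referent_spans
        ],
        "neologisms": [
            {"surface": w, "utterance": u, "token": t} for w, u, t in ann.neologism_tokens
        ],
    }
    Path(path).write_text(json.dumps(rec, ensure_ascii=False, indent=1), encoding="utf-8")


#: fixed column order of the feature table; dictionary-category columns
#: (prefixed ``cat_``) follow in sorted order.
FEATURE_COLUMNS = [
    "participant_id",
    "group",
    "acm",
    "repetition_rate",
    "neologism_pct",
    "ambiguous_referent_rate",
]


def write_feature_table(rows: Iterable[Mapping], path: str | Path) -> None:
    df = pd.DataFrame(list(rows))
    cat_cols = sorted(c for c in df.columns if c.startswith("cat_"))
    cols = [c for c in FEATURE_COLUMNS if c in df.columns] + cat_cols
    extra = [c for c in df.columns if c not in cols]
    df[cols + extra].to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Per-participant clinical scores (SAPS items, CGI, ...) as a DataFrame."""
    return pd.read_csv(path)
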