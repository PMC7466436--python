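"""Seeded synthetic fixtures: embedding spaces, transcripts, whole cohorts.

The generator emits a token language, not German: topic words ("t3w12") drawn
around unit-norm topic centroids in a small embedding space, real German
function-word stand-ins with high document frequencies, emotion keywords tied
to one topic each, filler tokens, pronouns, and out-of-vocabulary forms
("xneo7").  Linguistic realism is a non-goal; the statistical structure is
the contract: a topic random walk whose jump probability controls semantic
coherence, keyword re-emission in the definition-question answers controlling
perseveration, and planted OOV/ambiguity/filler rates that the extraction
modules can recover exactly against the ground-truth record.

Default cohort: three groups of 20 (healthy controls; patients with positive
formal thought disorder: high topic-jump plus neologisms and ambiguous
referents; patients without: low jump but heavy keyword repetition), each
interviewed with the 4-emotion x 3-question structure.

All randomness flows from a single seed through one numpy Generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .corpus_io import (
    AnnotationSet,
    DocFrequencyTable,
    EMOTIONS,
    Prompt,
    Speaker,
    TranscriptDocument,
    Utterance,
    WordVectorTable,
    write_annotations,
    write_df_table,
    write_transcript,
    write_vectors,
)

EMOTION_TOPIC = {"sadness": 0, "fear": 1, "anger": 2, "happiness": 3}
EMOTION_KEYWORD = {"sadness": "trauer", "fear": "angst", "anger": "wut", "happiness": "freude"}
FUNCTION_WORDS = (
    "und", "der", "die", "das", "ist", "ein", "eine", "nicht", "ich", "es",
    "auch", "dann", "so", "wie", "aber", "wenn", "mit", "auf", "für", "zu",
)
PRONOUNS = ("er", "sie")
FILLERS = ("ähm", "äh")
#: cohesive differentiation markers among the function words; their usage
#: frequency is a group-level parameter (reduced in disorganized speech)
DIFFERENTIATION_WORDS = ("wenn", "aber", "doch", "obwohl")


@dataclass
class SpeakerParams:
    """Per-speaker generating parameters."""

    topic_jump_prob: float = 0.1
    keyword_repeat_rate: float = 1.0  # expected keyword emissions per Q1 answer
    oov_rate: float = 0.0
    ambiguous_ref_rate: float = 0.0
    filler_rate: float = 0.05
    #: relative sampling weight of differentiation markers among function
    #: words (1 = neutral; < 1 under-uses them)
    differentiation_weight: float = 1.0

    def __post_init__(self) -> None:
        for name in ("topic_jump_prob", "oov_rate", "ambiguous_ref_rate", "filler_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.keyword_repeat_rate < 0:
            raise ValueError("keyword_repeat_rate must be >= 0")
        if self.differentiation_weight < 0:
            raise ValueError("differentiation_weight must be >= 0")


def default_group_params() -> dict[str, SpeakerParams]:
    return {
        "HC": SpeakerParams(topic_jump_prob=0.12, keyword_repeat_rate=1.0,
                            oov_rate=0.006, ambiguous_ref_rate=0.08, filler_rate=0.05,
                            differentiation_weight=1.08),
        "NAP_FTD": SpeakerParams(topic_jump_prob=0.34, keyword_repeat_rate=1.0,
                                 oov_rate=0.012, ambiguous_ref_rate=0.16, filler_rate=0.08,
                                 differentiation_weight=0.88),
        "NAP_noFTD": SpeakerParams(topic_jump_prob=0.12, keyword_repeat_rate=3.5,
                                   oov_rate=0.008, ambiguous_ref_rate=0.10, filler_rate=0.08,
                                   differentiation_weight=1.0),
    }


@dataclass
class SimConfig:
    seed: int = 0
    embedding_dim: int = 16
    n_topics: int = 6
    words_per_topic: int = 30
    cluster_spread: float = 0.25
    total_documents: int = 10_000
    sentences_per_answer: int = 5
    tokens_per_sentence: int = 8
    function_word_frac: float = 0.3
    pronoun_prob: float = 0.3
    #: between-speaker heterogeneity: per-participant parameters are drawn
    #: around the group-level settings (0 = every speaker exactly at the
    #: group parameters).  Real cohorts overlap; without this the groups
    #: separate perfectly and cohort-level ML estimates diverge.
    heterogeneity: float = 1.0
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"HC": 20, "NAP_FTD": 20, "NAP_noFTD": 20}
    )
    group_params: dict[str, SpeakerParams] = field(default_factory=default_group_params)

    def __post_init__(self) -> None:
        if self.n_topics < len(EMOTIONS):
            raise ValueError("need at least one topic per emotion")
        if self.words_per_topic < 1:
            raise ValueError("vocabulary smaller than topics")
        if not 0 <= self.function_word_frac < 1:
            raise ValueError("function_word_frac outside [0, 1)")


@dataclass
class SyntheticCohort:
    config: SimConfig
    vectors: WordVectorTable
    df_table: DocFrequencyTable
    transcripts: list[TranscriptDocument]
    annotations: dict[str, AnnotationSet]
    clinical: pd.DataFrame
    truth: dict[str, dict]


# ---------------------------------------------------------------------------

def make_vector_space(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[WordVectorTable, DocFrequencyTable]:
    """Topic-clustered word vectors plus a document-frequency table.

    Words sit around unit-norm topic centroids with Gaussian spread, so
    within-topic cosine similarity exceeds between-topic similarity in
    expectation.  Function-word stand-ins get high document counts, topic
    words low ones, so TF-IDF damps the former.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    d = config.embedding_dim
    centroids = rng.normal(size=(config.n_topics, d))
    centroids /= np.linalg.norm(centroids, axis=1, keepdims=True)

    entries: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for k in range(config.n_topics):
        for j in range(config.words_per_topic):
            word = f"t{k}w{j}"
            entries[word] = centroids[k] + config.cluster_spread * rng.normal(size=d) / np.sqrt(d)
            counts[word] = int(rng.integers(5, 200))
    for emotion, topic in EMOTION_TOPIC.items():
        word = EMOTION_KEYWORD[emotion]
        entries[word] = centroids[topic] + config.cluster_spread * rng.normal(size=d) / np.sqrt(d)
        counts[word] = int(rng.integers(50, 400))
    for word in FUNCTION_WORDS + PRONOUNS:
        entries[word] = 0.1 * rng.normal(size=d) / np.sqrt(d)
        counts[word] = int(rng.integers(4000, 9000))
    return (
        WordVectorTable(dimension=d, entries=entries),
        DocFrequencyTable(total_documents=config.total_documents, counts=counts),
    )


def _make_sentence(
    config: SimConfig, params: SpeakerParams, topic: int, rng: np.random.Generator,
    oov_counter: list[int],
) -> tuple[list[tuple[str, bool]], dict]:
    """One sentence as (token, is_ambiguous) pairs, plus per-sentence counts."""
    counts = {"fillers": 0, "oov": 0, "ambiguous": 0}
    fw_weights = np.array(
        [params.differentiation_weight if w in DIFFERENTIATION_WORDS else 1.0
         for w in FUNCTION_WORDS]
    )
    fw_weights = fw_weights / fw_weights.sum()
    tokens: list[tuple[str, bool]] = []
    for _ in range(config.tokens_per_sentence):
        if rng.random() < params.filler_rate:
            tokens.append((FILLERS[rng.integers(len(FILLERS))], False))
            counts["fillers"] += 1
        if rng.random() < config.function_word_frac:
            tokens.append((FUNCTION_WORDS[rng.choice(len(FUNCTION_WORDS), p=fw_weights)], False))
        else:
            word = f"t{topic}w{rng.integers(config.words_per_topic)}"
            if rng.random() < params.oov_rate:
                word = f"xneo{oov_counter[0]}"
                oov_counter[0] += 1
                counts["oov"] += 1
            tokens.append((word, False))
    if rng.random() < config.pronoun_prob:
        pos = int(rng.integers(len(tokens) + 1))
        ambiguous = rng.random() < params.ambiguous_ref_rate
        tokens.insert(pos, (PRONOUNS[rng.integers(len(PRONOUNS))], ambiguous))
        if ambiguous:
            counts["ambiguous"] += 1
    return tokens, counts


def simulate_transcript(
    config: SimConfig,
    params: SpeakerParams,
    participant_id: str,
    rng: np.random.Generator,
) -> tuple[TranscriptDocument, AnnotationSet, dict]:
    """One interview (4 emotions x 3 questions) with its annotations and truth.

    Participant answers follow a topic random walk: the walk starts at the
    prompted emotion's topic and jumps to a uniformly different topic between
    sentences with probability ``topic_jump_prob``.  Emotion keywords are
    re-emitted in question-1 answers at ``keyword_repeat_rate`` (Poisson).
    """
    truth = {
        "params": asdict(params),
        "fillers": 0,
        "oov": 0,
        "ambiguous": 0,
        "keywords_q1": 0,
        "q1_tokens": 0,
        "participant_tokens": 0,
        "participant_sentences": 0,
    }
    oov_counter = [0]
    utterances: list[Utterance] = []
    ambiguous_spans: list[tuple[int, tuple[int, int]]] = []
    neologisms: list[tuple[str, int, int]] = []

    for emotion in EMOTIONS:
        keyword = EMOTION_KEYWORD[emotion]
        for question in (1, 2, 3):
            prompt = Prompt(emotion, question)
            utterances.append(
                Utterance(
                    speaker=Speaker.INTERVIEWER,
                    sentences=[f"erzählen sie von {keyword} frage {question}"],
                    prompt=prompt,
                )
            )
            topic = EMOTION_TOPIC[emotion]
            answer: list[list[tuple[str, bool]]] = []
            for s in range(config.sentences_per_answer):
                if s > 0 and rng.random() < params.topic_jump_prob:
                    others = [t for t in range(config.n_topics) if t != topic]
                    topic = int(rng.choice(others))
                sent, counts = _make_sentence(config, params, topic, rng, oov_counter)
                answer.append(sent)
                truth["fillers"] += counts["fillers"]
                truth["oov"] += counts["oov"]
                truth["ambiguous"] += counts["ambiguous"]
            if question == 1:
                n_kw = int(rng.poisson(params.keyword_repeat_rate))
                for _ in range(n_kw):
                    si = int(rng.integers(len(answer)))
                    pos = int(rng.integers(len(answer[si]) + 1))
                    answer[si].insert(pos, (keyword, False))
                truth["keywords_q1"] += n_kw

            utt_index = len(utterances)
            sentences = [" ".join(w for w, _ in sent) for sent in answer]
            utterances.append(
                Utterance(speaker=Speaker.PARTICIPANT, sentences=sentences, prompt=prompt)
            )
            flat = 0
            for sent in answer:
                for w, ambiguous in sent:
                    if ambiguous:
                        ambiguous_spans.append((utt_index, (flat, flat + 1)))
                    if w.startswith("xneo"):
                        neologisms.append((w, utt_index, flat))
                    flat += 1
            truth["participant_tokens"] += flat
            if question == 1:
                truth["q1_tokens"] += flat
            truth["participant_sentences"] += len(answer)

    doc = TranscriptDocument(participant_id=participant_id, utterances=utterances)
    ann = AnnotationSet(
        participant_id=participant_id,
        ambiguous_referent_spans=ambiguous_spans,
        neologism_tokens=neologisms,
    )
    return doc, ann, truth


def _saps_for_group(group: str, rng: np.random.Generator) -> dict:
    if group == "HC":
        return {"is_patient": False, "saps_global_positive_ftd": 0,
                "saps_incoherence": 0, "saps_tangentiality": 0,
                "cgi": 1}
    if group == "NAP_FTD":
        glob = int(rng.integers(2, 6))
        inc = int(rng.integers(0, 6))
        tang = int(rng.integers(2, 6)) if inc < 2 else int(rng.integers(0, 6))
        cgi = int(np.clip(round(rng.normal(5.2, 1.3)), 1, 7))
    else:  # NAP_noFTD: rule must fail
        if rng.random() < 0.6:
            glob = int(rng.integers(0, 2))
            inc = int(rng.integers(0, 2))
            tang = int(rng.integers(0, 2))
        else:
            glob = int(rng.integers(2, 6))
            inc = int(rng.integers(0, 2))
            tang = int(rng.integers(0, 2))
        cgi = int(np.clip(round(rng.normal(3.65, 1.3)), 1, 7))
    return {"is_patient": True, "saps_global_positive_ftd": glob,
            "saps_incoherence": inc, "saps_tangentiality": tang, "cgi": cgi}


def _individual_params(
    base: SpeakerParams, heterogeneity: float, rng: np.random.Generator
) -> SpeakerParams:
    """Per-participant parameters drawn around the group-level settings.

    A latent per-speaker severity factor v ~ N(0,1) jointly scales the
    OOV and ambiguous-referent rates (log-normal multiplicative), so the two
    comprehensibility features are positively correlated within a group, as
    severity-driven features are in real cohorts.  The topic jump probability
    varies independently (additive normal jitter), and keyword repetition
    independently again (gamma with the group value as mean).
    heterogeneity = 0 returns the group values exactly.
    """
    if heterogeneity == 0:
        return SpeakerParams(**asdict(base))
    v = rng.normal()

    def lognormal_around(median: float, cap: float = 1.0) -> float:
        if median == 0:
            return 0.0
        return min(median * float(np.exp(0.45 * v + 0.3 * rng.normal())), cap)

    return SpeakerParams(
        topic_jump_prob=float(
            np.clip(
                base.topic_jump_prob + heterogeneity * 0.10 * rng.normal(),
                0.0,
                1.0,
            )
        ),
        keyword_repeat_rate=float(rng.gamma(2.0, base.keyword_repeat_rate / 2.0))
        if base.keyword_repeat_rate > 0
        else 0.0,
        oov_rate=lognormal_around(base.oov_rate),
        ambiguous_ref_rate=lognormal_around(base.ambiguous_ref_rate),
        filler_rate=base.filler_rate,
        differentiation_weight=base.differentiation_weight
        * float(np.exp(0.15 * heterogeneity * rng.normal())),
    )


def simulate_cohort(config: SimConfig | None = None) -> SyntheticCohort:
    """Full cohort: vector space, transcripts, annotations, clinical scores."""
    config = config or SimConfig()
    for g, n in config.group_sizes.items():
        if n < 2:
            raise ValueError(f"group {g} size {n} < 2")
    rng = np.random.default_rng(config.seed)
    vectors, df_table = make_vector_space(config, rng)
    transcripts: list[TranscriptDocument] = []
    annotations: dict[str, AnnotationSet] = {}
    truth: dict[str, dict] = {}
    clinical_rows = []
    for group, n in config.group_sizes.items():
        base = config.group_params[group]
        for i in range(n):
            pid = f"{group}_{i:02d}"
            params = _individual_params(base, config.heterogeneity, rng)
            doc, ann, t = simulate_transcript(config, params, pid, rng)
            t["group"] = group
            transcripts.append(doc)
            annotations[pid] = ann
            truth[pid] = t
            clinical_rows.append({"participant_id": pid, **_saps_for_group(group, rng)})
    clinical = pd.DataFrame(clinical_rows)
    return SyntheticCohort(
        config=config,
        vectors=vectors,
        df_table=df_table,
        transcripts=transcripts,
        annotations=annotations,
        clinical=clinical,
        truth=truth,
    )


def write_fixture_dir(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Serialize a cohort as a plain-text fixture directory."""
    outdir = Path(outdir)
    (outdir / "transcripts").mkdir(parents=True, exist_ok=True)
    (outdir / "annotations").mkdir(exist_ok=True)
    write_vectors(cohort.vectors, outdir / "vectors.txt")
    write_df_table(cohort.df_table, outdir / "df_table.tsv")
    for doc in cohort.transcripts:
        write_transcript(doc, outdir / "transcripts" / f"{doc.participant_id}.txt",
                         format="tagged-text")
    for pid, ann in cohort.annotations.items():
        write_annotations(ann, outdir / "annotations" / f"{pid}.json")
    cohort.clinical.to_csv(outdir / "clinical.csv", index=False)
    (outdir / "truth.json").write_text(
        json.dumps(cohort.truth, ensure_ascii=False, indent=1), encoding="utf-8"
    )
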