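"""Bias and comprehensibility features, grouping rule, and feature assembly.

Similarity-based coherence scores are biased upward by perseveration (a
transcript repeating the same keyword is maximally "coherent") and biased by
vocabulary exclusions (neologisms fall out of the embedding table).  This
module quantifies those biases — emotion-keyword repetition in the
definition-question answers, neologism percentage among out-of-vocabulary
tokens, ambiguous-referent rate from standoff annotations — plus dictionary
category percentages over the raw token stream, and assembles everything into
one feature row per participant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .corpus_io import (
    AnnotationSet,
    CategoryDictionary,
    EMOTIONS,
    Speaker,
    TranscriptDocument,
    ValidationError,
)
from .preprocess import OovReport, raw_participant_tokens, tokenize

log = logging.getLogger(__name__)

GROUPS = ("HC", "NAP_FTD", "NAP_noFTD")


class EmotionKeywordLexicon:
    """Per-emotion keyword sets (lowercase literals, inflectional variants listed)."""

    def __init__(self, keywords: Mapping[str, Iterable[str]]):
        self.keywords = {emo: frozenset(w.lower() for w in ws) for emo, ws in keywords.items()}
        for emo, ws in self.keywords.items():
            if not ws:
                raise ValidationError(f"empty keyword set for emotion {emo!r}")

    @classmethod
    def default_german(cls) -> "EmotionKeywordLexicon":
        text = (
            resources.files("cohmetrics")
            .joinpath("data", "emotion_keywords_de.txt")
            .read_text(encoding="utf-8")
        )
        table: dict[str, set[str]] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            emo, word = line.split("\t")
            table.setdefault(emo, set()).add(word)
        return cls(table)


@dataclass
class SapsItems:
    """SAPS ratings relevant to the grouping rule (ordinal 0-5 each)."""

    global_positive_ftd: int | None
    incoherence: int | None
    tangentiality: int | None
    other: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("global_positive_ftd", "incoherence", "tangentiality"):
            v = getattr(self, name)
            if v is not None and not 0 <= v <= 5:
                raise ValidationError(f"SAPS item {name} = {v} outside 0-5")


@dataclass
class FeatureRow:
    """One participant's assembled predictors; None marks a missing feature."""

    participant_id: str
    acm: float | None
    repetition_rate: float | None
    neologism_pct: float | None
    ambiguous_referent_rate: float | None
    category_pcts: dict[str, float] = field(default_factory=dict)
    group: str = "unknown"
    provenance: str | None = None

    def as_record(self) -> dict:
        rec = {
            "participant_id": self.participant_id,
            "group": self.group,
            "acm": self.acm,
            "repetition_rate": self.repetition_rate,
            "neologism_pct": self.neologism_pct,
            "ambiguous_referent_rate": self.ambiguous_referent_rate,
        }
        for cat, pct in sorted(self.category_pcts.items()):
            rec[f"cat_{cat}"] = pct
        return rec


def repetition_rate(
    doc: TranscriptDocument,
    lexicon: EmotionKeywordLexicon | None = None,
    mode: str = "all",
    denominator: str = "q1",
) -> float | None:
    """Emotion-keyword repetition in the question-1 (definition) answers.

    For each emotion, occurrences of that emotion's keywords are counted in
    the participant's question-1 answer; the rate is the summed count over
    the four emotions divided by the summed token count of those answers
    (``denominator="transcript"`` divides by the whole-transcript count
    instead).  ``mode="beyond_first"`` counts only occurrences beyond the
    first per emotion, treating one mention as adequate.

    Returns None (feature missing, never zero) when no question-1 answers
    are present.
    """
    lexicon = lexicon or EmotionKeywordLexicon.default_german()
    if mode not in ("all", "beyond_first"):
        raise ValueError(f"unknown counting mode {mode!r}")
    total_count = 0
    q1_tokens = 0
    seen_q1 = False
    for utt in doc.participant_utterances():
        if utt.prompt is None or utt.prompt.question != 1:
            continue
        seen_q1 = True
        keywords = lexicon.keywords.get(utt.prompt.emotion, frozenset())
        tokens = [t for sent in utt.sentences for t in tokenize(sent)]
        q1_tokens += len(tokens)
        n = sum(1 for t in tokens if t.key in keywords)
        if mode == "beyond_first":
            n = max(n - 1, 0)
        total_count += n
    if not seen_q1 or q1_tokens == 0:
        log.warning("%s: no question-1 answers; repetition feature missing", doc.participant_id)
        return None
    if denominator == "transcript":
        denom = len(raw_participant_tokens(doc))
    elif denominator == "q1":
        denom = q1_tokens
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return total_count / denom


def neologism_pct(
    doc: TranscriptDocument,
    oov_report: OovReport,
    curated: AnnotationSet | None = None,
    known_words: Iterable[str] = (),
) -> float:
    """Percentage of participant tokens characterized as neologisms.

    Candidates are the out-of-vocabulary tokens minus a curated known-word
    list (uncommon but real words).  When curated neologism annotations are
    present they define the final set — designation is human-in-the-loop;
    an annotation referencing a token the model did know is kept with a
    warning (human override).
    """
    total = len(raw_participant_tokens(doc))
    if total == 0:
        return 0.0
    if curated is not None and curated.neologism_tokens:
        oov_surfaces = {s.lower() for s in oov_report.surfaces}
        n = 0
        for surface, _, _ in curated.neologism_tokens:
            if surface.lower() not in oov_surfaces:
                log.warning(
                    "%s: annotated neologism %r is not OOV (human override kept)",
                    doc.participant_id,
                    surface,
                )
            n += 1
    else:
        known = {w.lower() for w in known_words}
        n = sum(1 for s in oov_report.surfaces if s.lower() not in known)
    return 100.0 * n / total


def ambiguous_referent_rate(doc: TranscriptDocument, annotations: AnnotationSet) -> float:
    """Relative frequency of ambiguous referents (annotated spans per token)."""
    token_counts = [
        sum(len(tokenize(s)) for s in utt.sentences) for utt in doc.utterances
    ]
    annotations.validate_against(doc, token_counts)
    participant_total = sum(
        c for c, utt in zip(token_counts, doc.utterances) if utt.speaker is Speaker.PARTICIPANT
    )
    if participant_total == 0:
        return 0.0
    return len(annotations.ambiguous_referent_spans) / participant_total


def category_percentages(
    doc: TranscriptDocument,
    dictionary: CategoryDictionary,
    selected: Sequence[str] | None = None,
) -> dict[str, float]:
    """Percentage of raw participant tokens matching each dictionary category.

    Runs on the raw (unfiltered) token stream; a token may count toward
    several categories.
    """
    if selected is None:
        selected = list(dictionary.categories)
    else:
        for cat in selected:
            if cat not in dictionary.categories:
                raise KeyError(f"category {cat!r} absent from dictionary")
    if not dictionary.categories:
        log.warning("empty category dictionary: all percentages zero")
    tokens = raw_participant_tokens(doc)
    counts = {cat: 0 for cat in selected}
    for t in tokens:
        for cat in dictionary.match(t.key):
            if cat in counts:
                counts[cat] += 1
    total = len(tokens)
    if total == 0:
        return {cat: 0.0 for cat in selected}
    return {cat: 100.0 * c / total for cat, c in counts.items()}


def assign_group(items: SapsItems, is_patient: bool) -> str:
    """Grouping rule on SAPS ratings.

    Patients belong to the positive-FTD group iff global positive FTD is at
    least mild (>= 2) AND incoherence or tangentiality is at least mild
    (>= 2); other patients are NAP_noFTD; non-patients are HC.
    """
    if not is_patient:
        return "HC"
    required = (items.global_positive_ftd, items.incoherence, items.tangentiality)
    if any(v is None for v in required):
        log.warning("missing SAPS item; group unknown")
        return "unknown"
    if items.global_positive_ftd >= 2 and (items.incoherence >= 2 or items.tangentiality >= 2):
        return "NAP_FTD"
    return "NAP_noFTD"


def assemble_features(
    participant_id: str,
    acm: float | None,
    repetition: float | None,
    neologisms: float | None,
    ambiguous_referents: float | None,
    category_pcts: Mapping[str, float] | None = None,
    group: str = "unknown",
    provenance: str | None = None,
) -> FeatureRow:
    """One row per participant; missing features stay None, never imputed."""
    for name, v in [
        ("acm", acm),
        ("repetition_rate", repetition),
        ("neologism_pct", neologisms),
        ("ambiguous_referent_rate", ambiguous_referents),
    ]:
        if v is not None and not np.isfinite(v):
            raise ValidationError(f"{participant_id}: non-finite feature {name}={v}")
    return FeatureRow(
        participant_id=participant_id,
        acm=acm,
        repetition_rate=repetition,
        neologism_pct=neologisms,
        ambiguous_referent_rate=ambiguous_referents,
        category_pcts=dict(category_pcts or {}),
        group=group,
        provenance=provenance,
    )


def build_feature_table(rows: Iterable[FeatureRow]) -> pd.DataFrame:
    rows = list(rows)
    ids = [r.participant_id for r in rows]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValidationError(f"duplicate participant_id(s): {sorted(dupes)}")
    return pd.DataFrame([r.as_record() for r in rows])


def extract_feature_row(
    doc: TranscriptDocument,
    vectors,
    df_table,
    annotations: AnnotationSet | None = None,
    dictionary: CategoryDictionary | None = None,
    lexicon: EmotionKeywordLexicon | None = None,
    config=None,
    group: str = "unknown",
    scheme: str = "ratio",
) -> FeatureRow:
    """Run the full per-participant pipeline and assemble one feature row.

    Missing inputs produce missing features (None), never silent zeros: no
    annotation file means the referent feature is absent, and too little
    embeddable speech leaves the coherence metric absent.
    """
    from .preprocess import PreprocessConfig, filter_sentences, mark_oov
    from .semantic_coherence import (
        InsufficientContentError,
        coherence_score,
        embed_sentence,
    )

    config = config or PreprocessConfig()
    sentences, _ = filter_sentences(doc, config)
    sentences, oov_report = mark_oov(sentences, vectors)
    try:
        embedded = [embed_sentence(s, vectors, df_table, scheme) for s in sentences]
        acm = coherence_score(embedded, doc.participant_id, config.digest()).acm
    except InsufficientContentError:
        log.warning("%s: too little embeddable speech; ACM missing", doc.participant_id)
        acm = None
    rep = repetition_rate(doc, lexicon)
    neo = neologism_pct(doc, oov_report, curated=annotations)
    amb = ambiguous_referent_rate(doc, annotations) if annotations is not None else None
    cats = category_percentages(doc, dictionary) if dictionary is not None else {}
    return assemble_features(
        doc.participant_id, acm, rep, neo, amb, cats, group, provenance=config.digest()
    )


def extract_cohort_features(
    transcripts,
    vectors,
    df_table,
    annotations: Mapping[str, AnnotationSet] | None = None,
    clinical: pd.DataFrame | None = None,
    dictionary: CategoryDictionary | None = None,
    lexicon: EmotionKeywordLexicon | None = None,
    config=None,
) -> pd.DataFrame:
    """Feature table for a whole cohort, with groups from the clinical table."""
    groups: dict[str, str] = {}
    if clinical is not None:
        for _, row in clinical.iterrows():
            items = SapsItems(
                global_positive_ftd=row.get("saps_global_positive_ftd"),
                incoherence=row.get("saps_incoherence"),
                tangentiality=row.get("saps_tangentiality"),
            )
            groups[row["participant_id"]] = assign_group(items, bool(row["is_patient"]))
    rows = []
    for doc in transcripts:
        ann = (annotations or {}).get(doc.participant_id)
        rows.append(
            extract_feature_row(
                doc,
                vectors,
                df_table,
                annotations=ann,
                dictionary=dictionary,
                lexicon=lexicon,
                config=config,
                group=groups.get(doc.participant_id, "unknown"),
            )
        )
    return build_feature_table(rows)


def select_significant_categories(
    features: pd.DataFrame, alpha: float = 0.05
) -> list[str]:
    """Gate for the full regression model: keep dictionary categories whose
    percentages differ across the three groups (one-way ANOVA, p < alpha).

    The decision is logged per category.
    """
    selected = []
    cat_cols = [c for c in features.columns if c.startswith("cat_")]
    for col in cat_cols:
        groups = [
            features.loc[features["group"] == g, col].dropna().to_numpy()
            for g in GROUPS
        ]
        groups = [g for g in groups if len(g) >= 2]
        if len(groups) < 2:
            continue
        if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
            log.info("category %s constant; not selected", col)
            continue
        _, p = stats.f_oneway(*groups)
        keep = bool(p < alpha)
        log.info("category %s: ANOVA p=%.4f -> %s", col, p, "selected" if keep else "dropped")
        if keep:
            selected.append(col)
    return selected
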