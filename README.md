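# cohmetrics

Automated incoherence analysis for clinical interview speech, with the
cohort statistics needed to relate it to ratings of formal thought disorder
(FTD).

Incoherent speech — loosened associations, derailment, tangentiality — is a
core symptom of non-affective psychosis, but clinicians rate it by
impression. `cohmetrics` implements the standard computational
operationalization: represent each sentence of a transcript as the
TF-IDF-weighted mean of its word embeddings,

&nbsp;&nbsp;&nbsp;&nbsp;*S*ᵥ = (1/n) Σᵢ *w*ᵢ·*a*ᵢ,&nbsp;&nbsp; *a*ᵢ = tf(*w*ᵢ)/df(*w*ᵢ),

and score the transcript by the mean cosine similarity between *adjacent*
sentence embeddings,

&nbsp;&nbsp;&nbsp;&nbsp;Coherence(*T*) = (1/(n−1)) Σᵢ sim(*S*ᵥᵢ, *S*ᵥᵢ₊₁),

the *automatically derived coherence metric* (ACM). Lower values mean the
speaker jumps between semantically distant content from sentence to
sentence. Because this similarity measure is biased by perseveration and
blind to comprehensibility, the package also extracts the companion
features used in this literature — emotion-keyword repetition in
definition-question answers, neologism percentage among out-of-vocabulary
tokens, manually annotated ambiguous-referent rates, and LIWC-style
dictionary category percentages — and provides the statistical layer:
group tests (t, χ², ANOVA/Welch with a Levene gate), linear regression
with residual diagnostics, a three-model multinomial logistic regression
ladder with odds ratios, Nagelkerke R², AIC and likelihood-ratio tests,
VIF, and noncentral-F power analysis.

It is written for computational-psychiatry and clinical-linguistics
researchers working with transcribed semi-structured interviews (the
Narrative of Emotions Task structure — three questions about each of four
emotions — is modelled explicitly), pre-trained word vectors in word2vec
text format, and a document-frequency table from a reference corpus.

## Worked example

Score a tiny three-sentence transcript against a toy semantic space in
which "angst/furcht/panik" cluster together and "urlaub/meer" form a second
cluster, while the copula "ist" is damped by its document frequency:

```python
import numpy as np
from cohmetrics import (TranscriptDocument, Utterance, WordVectorTable,
                        DocFrequencyTable, analyze_transcript)

vectors = WordVectorTable(2, {
    "angst":  np.array([0.9, 0.1]), "furcht": np.array([0.8, 0.2]),
    "panik":  np.array([0.85, 0.3]), "urlaub": np.array([0.1, 0.9]),
    "meer":   np.array([0.2, 0.8]), "ist":    np.array([0.5, 0.5]),
})
df = DocFrequencyTable(1000, {"angst": 20, "furcht": 10, "panik": 8,
                              "urlaub": 25, "meer": 30, "ist": 900})
doc = TranscriptDocument("demo", [Utterance(
    speaker="participant",
    sentences=["angst ist furcht", "panik ist angst", "urlaub ist meer"],
)])

profile = analyze_transcript(doc, vectors, df)
print([round(s, 4) for s in profile.pair_similarities])   # [0.9971, 0.4368]
print(round(profile.acm, 4))                              # 0.717
```

The first adjacent pair stays inside the fear cluster (similarity 0.9971);
the second jumps to the holiday cluster (0.4368); the transcript's ACM is
their mean, 0.717. Power analysis for a three-group one-way design uses the
noncentral F with λ = f²·N:

```python
from cohmetrics import PowerSpec, power_oneway, required_n
power_oneway(PowerSpec(k=3, n_total=60, effect_f=0.325))  # 0.585
required_n(3, 0.325, target_power=0.8)                    # 96
```

At the medium-to-large effect f = 0.325 observed for coherence metrics in
this design, 20 participants per group yields only 0.585 power; 96 in total
are needed to reach 0.80.

## Command line

A thin CLI wraps the library. `simulate` writes a complete seeded synthetic
cohort (transcripts in a tagged-text dialect, a vector table, a
document-frequency table, standoff annotations, clinical scores, and the
generating ground truth), which the other commands can consume end to end:

```bash
cohmetrics --seed 7 simulate fixtures/demo --n-per-group 20
cohmetrics score    --transcripts fixtures/demo/transcripts \
                    --vectors fixtures/demo/vectors.txt \
                    --df-table fixtures/demo/df_table.tsv --out scores.csv
cohmetrics features --transcripts fixtures/demo/transcripts \
                    --vectors fixtures/demo/vectors.txt \
                    --df-table fixtures/demo/df_table.tsv \
                    --annotations fixtures/demo/annotations \
                    --clinical fixtures/demo/clinical.csv --out features.csv
cohmetrics cohort   --features features.csv --out models.json
cohmetrics power    --k 3 --n 60 --f 0.325
```

`docs/methods.md` documents the model, the statistical conventions, the
synthetic generator's design, and known limitations.

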