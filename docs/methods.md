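# Methods

`cohmetrics` quantifies semantic incoherence in free interview speech and
provides the cohort-level statistics used to relate that measure to clinical
ratings of formal thought disorder (FTD). This note documents the model, the
numerical conventions, the synthetic-data generator, and the choices made
where the design was genuinely open.

## The coherence model

A transcript is an ordered sequence of participant sentences (sentence
boundaries are the transcriber's; the package never re-segments).
Preprocessing removes the interviewer's turns (they reduce to the fixed
interview questions), removes verbal filler tokens everywhere, and drops
sentences that consist solely of stop words. Both removals exist because
similarity-based coherence is biased by semantically empty material.

Each surviving sentence S = {w_1, …, w_n} is embedded as the TF-IDF-weighted
mean of its word vectors:

    a_i = tf(w_i) / df(w_i)              (default "ratio" scheme)
    S_v = (1/n) Σ_i  w_i · a_i

where tf is the word's count within the sentence and df the number of
documents in a large reference corpus containing its lemma (surface form
when no lemmatizer is configured). A word absent from the DF table gets
df = 1 — absent words are rare and therefore maximally informative. The
conventional logarithmic variant a = tf · ln(N/df) is available as
`scheme="log-idf"`. With the ratio scheme, function words with df in the
thousands contribute weights of order 10⁻³ and are effectively silenced
without being removed, which is why stop-word *tokens* inside mixed
sentences are kept by default (`remove_stopword_tokens=False`); the stricter
behaviour is one switch away and both are tested.

The coherence score of a transcript (ACM, *automatically derived coherence
metric*) is the mean cosine similarity between adjacent sentence embeddings:

    Coherence(T) = (1/(n−1)) Σ_i  sim(S_vi, S_vi+1),
    sim(A, B) = A·B / (‖A‖‖B‖)  clamped to [−1, 1].

Sentences with no retained tokens (all out-of-vocabulary, or emptied by
filtering) are *skipped*: their neighbours are re-linked so each surviving
adjacency contributes exactly one similarity, and skips are counted in the
output for audit. Similarities may be negative; no non-negativity floor is
imposed. A transcript needs at least two embeddable sentences, otherwise an
explicit insufficient-content error names the participant.

## Bias and comprehensibility features

Similarity-based coherence is biased upward by perseveration and distorted
by vocabulary exclusion, and clinical impressions of incoherence also track
comprehensibility. Four auxiliary features address this, each a rate over a
documented denominator so that duplicating a transcript leaves it unchanged:

* **Keyword repetition** — occurrences of the prompted emotion's keywords in
  the answers to the definition question (question 1), divided by the token
  count of those answers. Counting all occurrences is the default ("fear is
  fear is fear" scores 3/5 = 0.6); counting only occurrences beyond the
  first, and normalizing by whole-transcript length, are config switches.
  The shipped German emotion-keyword lexicon (Trauer/Angst/Wut/Freude plus
  inflections) is an editable data file.
* **Neologism percentage** — 100 × neologism tokens / participant tokens.
  Candidate extraction is automatic (tokens missing from the embedding
  vocabulary, minus a known-word list), but the designation is
  human-in-the-loop: curated annotations, when present, define the final
  set, and an annotation disagreeing with the OOV screen is kept with a
  logged warning.
* **Ambiguous-referent rate** — manually annotated pronoun/name spans whose
  antecedent is unclear, per participant token. Automated coreference is
  deliberately out of scope.
* **Dictionary category percentages** — LIWC-style matching (literal words
  and trailing-asterisk stems, one token may hit several categories) over
  the *raw* token stream. The dictionary content is user-supplied; the
  package ships only a small demonstration dictionary. Categories enter the
  regression ladder only if they differ across groups (one-way ANOVA,
  α = .05), an explicit, logged filter.

**Grouping rule.** Patients belong to the positive-FTD group iff global
positive FTD ≥ 2 (at least mild) AND (incoherence ≥ 2 OR tangentiality ≥ 2)
on the SAPS; other patients form the no-FTD group; non-patients are healthy
controls. Missing items yield an explicit `unknown`, never a default group.

## Statistical layer

Conventions match the clinical-statistics software the field reports with:

* Pearson χ² without continuity correction; Student's pooled-variance t for
  two-group rows (Welch optional).
* One-way ANOVA with a Levene gate (absolute deviations from group means,
  α = .05) selecting Welch's heteroscedastic F when variances differ; the
  choice is logged per call.
* OLS for predicting clinical ratings from ACM, with Wald 95% CIs, R²,
  overall F, and a Lilliefors residual-normality check whose p-value is
  reported as the bound "≥ .2" beyond the table range.
* Multinomial logistic regression by Newton-type maximum likelihood with
  healthy controls as the reference outcome. Standard errors come from the
  observed information; odds-ratio CIs are Wald, exp(b ± 1.96·SE); profile
  CIs are out of scope. Reported alongside: AIC = 2k − 2lnL, Nagelkerke
  R² = [1 − (L0/L1)^(2/N)] / [1 − L0^(2/N)], the likelihood-ratio χ²
  against the intercept-only model, and an argmax classification table.
  Newton occasionally overshoots on ill-conditioned designs and is then
  retried with BFGS; a fit that still fails to converge, has non-finite
  standard errors, or has |b| > 30 on z-scored predictors raises an explicit
  separation diagnostic rather than returning numbers.
* The model ladder fits three nested predictor sets on identical rows
  (listwise deletion, count logged): (1) ACM; (2) ACM, repetition, and
  their interaction (the product of the z-scored columns); (3) ACM,
  repetition, neologisms, ambiguous referents, and the gate-passing
  dictionary categories. All predictors are z-scored (ddof = 1) over the
  analysed rows with an invertible scaling record.
* Power for the one-way fixed-effects design uses the noncentral F with
  λ = f²·N_total and df2 = N − k (the G*Power omnibus convention);
  `required_n` returns the smallest total N on the equal-group grid meeting
  a target power. At f = 0, power equals α exactly and a target above α is
  reported as an impossible design.

## The synthetic-data generator

No interview recordings are distributable, so the package ships a seeded
generator whose *statistical structure* — not linguistic realism — is the
contract. Vocabulary is a token language: topic words drawn around unit-norm
topic centroids in a 16-dimensional space (Gaussian spread 0.25, so
within-topic cosine ≈ 0.9 against near-zero between topics), real German
function words with high document frequencies near the origin, one emotion
keyword per prompted emotion tied to its own topic, filler tokens, pronouns,
and out-of-vocabulary forms.

A participant's answer is a topic random walk: the walk starts at the
prompted emotion's topic and jumps to a uniformly different topic between
sentences with probability `topic_jump_prob` — the single dial that moves
ACM, and the generator's operationalization of derailment. Keywords are
re-emitted in question-1 answers at a Poisson `keyword_repeat_rate`
(perseveration); OOV forms are injected per content token at `oov_rate`;
pronouns are marked ambiguous at `ambiguous_ref_rate` with matching standoff
annotations; fillers are sprinkled at `filler_rate`. Every planted count is
recorded in a ground-truth record, and the extraction modules recover the
planted filler/OOV/ambiguity counts *exactly* — the recovery tests are exact
equalities, not tolerances.

The default cohort is the study design: three groups of 20, interviewed
with the 4-emotion × 3-question structure (~480 participant tokens per
transcript). Group-level parameters mirror the direction of the reported
contrasts: controls (low jump, neutral elsewhere), patients with positive
FTD (high jump, more OOV forms, more ambiguous referents, fewer
differentiation markers), patients without positive FTD (low jump, heavy
keyword repetition). SAPS-like items are generated consistently with the
grouping rule, so `assign_group` reproduces the intended labels for every
row.

Between-speaker heterogeneity is essential, not decorative: per-participant
parameters are drawn around the group settings (normal jitter, SD 0.10, on
the jump probability; a shared log-normal severity factor scaling the OOV
and ambiguity rates, which makes the two comprehensibility features
positively correlated within groups as severity-driven features are in real
cohorts; an independent gamma for repetition). Without this overlap the
groups separate perfectly in feature space and the multinomial MLE diverges
— the generator would produce cohorts no logistic model can be estimated
on. Even with it, a 60-row cohort with the full five-predictor set sits
near quasi-separation a few percent of the time; real data of this size
lives at the same edge, which the very wide published odds-ratio intervals
for small-sample studies of this design reflect. The test-suite therefore
checks the coherence-only detection property at the design size of 20 per
group, and the AIC model-comparison property at 40 per group where the
comparison is stable; null-calibration sweeps use 12 per group with 3
sentences per answer to keep many replicates cheap. These sizes are the
package's simulation choices and are stated in the tests themselves.

What the generator does *not* emulate: German morphology and spelling
variation, disfluency structure beyond a filler list, topic structure more
graded than a hard random walk, interviewer back-channel, and rater noise in
the SAPS items. Passing tests therefore demonstrate correctness of the
pipeline's mechanics and statistics on data with known structure — not that
the coherence metric validly measures thought disorder in real speech.

## Numerical details and degenerate inputs

* Cosine similarities are clamped to [−1, 1] against rounding; zero-norm
  embeddings raise an undefined-similarity error (they cannot arise from
  retained tokens unless vectors cancel exactly).
* Duplicate words in a vector file: last occurrence wins, with a warning.
* Document frequencies must satisfy 1 ≤ df ≤ N at load time; lookups of
  absent lemmas are an explicit miss (`None`), never a silent zero.
* z-scoring refuses constant columns by name; VIF reports exact collinearity
  as infinity.
* Transcripts, annotations and tables are UTF-8 throughout; umlauts and "ß"
  are never normalized away, because embedding lookup is surface-form
  sensitive.
* All generator randomness flows from one `numpy` Generator seeded by
  `SimConfig.seed`; identical configurations produce byte-identical
  serialized fixture directories.

## Known limitations

* The repetition feature counts only emotion-keyword repetition in
  definition answers; other perseveration goes unmeasured.
* Neologism designation requires human screening; the automatic candidate
  set conflates neologisms with rare real words.
* Lemmatization is a lookup-table hook; without a table, DF lookups fall
  back to surface forms, which under-weights inflected German forms.
* The multinomial model reports observed-information standard errors;
  software using Fisher scoring can differ in far decimal places.
* At 20 participants per group, the full five-predictor multinomial model
  is close to the data's separation boundary; its estimates are reported
  with the usual maximum-likelihood caveats and very wide intervals.
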