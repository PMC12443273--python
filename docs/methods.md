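# Methods

This note documents the models and procedures implemented in `ncd_listener`,
the parameter choices that matter, and what the synthetic-data evidence does
and does not show.

## Preprocessing rules

Cleaning applies three rules in a fixed order — deduplicate, drop short
comments, anonymize:

* **Duplicate** means identical comment text after trimming and collapsing
  internal whitespace runs, case-sensitively. Exact matching is conservative
  and reproducible; near-duplicate detection (edit distance, shingling)
  would remove genuine reposts-with-commentary and is deliberately avoided.
  Deduplication runs before the short-comment filter.
* **Short** means ≤ 5 word tokens. "Word" is defined per language: Thai has
  no inter-word spacing, so Thai text is counted in dictionary-segmentation
  tokens; English (and unknown-language text, with a warning) in
  punctuation-stripped whitespace tokens.
* **Anonymization** replaces every author name with the literal `Name(n)`.
  Sequence numbers are assigned once at parse/read time and never
  renumbered, so `Name(17)` always refers to the 17th scraped comment even
  after filtering — traceability is worth more than dense numbering.
  Rendered counts such as `1.2K` are parsed to integers (K = 10³, M = 10⁶).

## Bilingual NLP

* **Language detection** is script-based: the fraction of Thai-block
  characters among alphabetic characters above 0.5 → Thai; Latin majority →
  English; no alphabetic content → unknown. Code-switched comments get the
  majority script. This is crude but total, deterministic and offline.
* **Thai segmentation** is longest-match (maximal-munch) against a curated
  domain dictionary shipped as a plain-text resource (~170 entries covering
  NCD vocabulary, kinship/pronoun cues, question particles and
  high-frequency function words). Unknown character runs become single
  tokens. A statistical segmenter would generalize better to open-domain
  text; for lexicon-driven extraction the dictionary approach is exact on
  the vocabulary that matters and trivially extensible.
* **English lemmatization** is rule-based: an irregular-form table plus
  suffix rules (plural `-s/-es/-ies`, `-ing`, `-ed` with consonant
  undoubling), iterated to a fixed point so normalization is idempotent.
  Thai normalization is orthographic only (NFC, zero-width removal,
  doubled combining-mark collapse) — Thai has no inflectional morphology to
  lemmatize.
* **Stopword lists** ship per language and are user-overridable. The English
  list deliberately keeps personal pronouns, possessives and wh-words:
  extraction matches gender/source cues ("my mother", "he") and the
  rule-based classifier inspects interrogatives on the stopword-removed
  stream, so removing them would destroy signal. Emoji and URLs are stripped
  before tokenization as they pollute keyword matching.

## Knowledge extraction

The lexicon maps canonical labels to surface terms per category and
language. English terms are normalized with the same pipeline as comments
and matched as contiguous subsequences of the normalized token stream (so
"cigarettes" matches a "cigarette" term). Thai terms are matched as
substrings of the raw, unsegmented text, because segmentation can split a
lexicon term across token boundaries. Ambiguous short Thai cues are
excluded from the shipped lexicon (e.g. the kin term that collides with
common words as a substring).

Gender is inferred from explicit cue words only — pronouns, kin terms,
self-descriptors; cues for both genders in one comment yield `unknown`.
No name-based guessing: it is unreliable and re-identifying. The opinion
source taxonomy is {self, family_member, acquaintance, general, unknown};
when several cues occur, the earliest in the comment wins, and cue-free
comments default to `general`.

The include/exclude adjustment keeps a comment iff (the include set is
empty OR it mentions an included disease/symptom) AND it mentions no
excluded label. The operation is a filter: surviving records are unchanged,
so it is idempotent and commutes with chart aggregation.

## Classification

Three backends implement `classify(text) → label`:

* **rule_based** (default): question mark, sentence-initial wh-word or Thai
  question particle → inquiring; else first-person/experience cues →
  sharing_experience; else non_informative. Total and deterministic.
* **linear_bow**: bag-of-words over the bilingual tokenizer + multinomial
  logistic regression, seeded. Training applies minority-class oversampling
  (seeded duplication up to the majority count) by default. This is the
  desk-scale trainable reference; it separates template-distinct classes
  essentially perfectly and exists to validate the training/evaluation
  plumbing, not to claim real-world accuracy.
* **transformer**: carries the fine-tuning recipe parameters — stratified
  70/30 split, oversampling, maximum sequence length 200, learning rate
  2×10⁻⁵, early stopping (patience 3 epochs on validation loss, 10%
  stratified validation carve-out) — for a BERT-family encoder
  (`wangchanberta-base-att-spm-uncased` for Thai, `bert-large-uncased` for
  English as configuration defaults). It requires the optional
  `transformers` dependency plus downloadable weights and is therefore
  never exercised in the test suite. The "maximum sequence length of 200"
  is interpreted in tokenizer units and is configurable.

Evaluation computes the 3×3 confusion matrix (rows = true) and one-vs-rest
precision/recall/F1 with 0-denominator conventions P = R = F1 = 0, accuracy
= trace/N; a scikit-learn cross-check runs in the tests against the same
definitions.

## Retrieval-augmented summarization

Comments are embedded, indexed, and the top-k (default k = 20,
configurable — retrieval depth is a free parameter) most cosine-similar to
the fixed question of the chosen approach are placed into the prompt.
Two approaches exist, each with a fixed English question (general
characteristics vs. diseases/symptoms/other information); summaries are
always English regardless of comment language. Ties in similarity break
toward the lower comment number.

The shipped backends are deterministic and offline: `HashEmbedBackend`
(keyed BLAKE2b feature hashing of normalized tokens into a 256-dimension
L2-normalized vector; the key is a seed, so embeddings are stable across
processes) and `MockLLMBackend` (echoes a digest: context-comment count
plus sorted lexicon-matched disease labels). Remote embedding/generation
services implement the same two-method contracts. Chunking and
context-length management are left to the backend configuration; no default
is asserted.

## Dashboard model

Eight chart specs are aggregated from per-comment knowledge. Default
visibility follows the user-validation rule that variables rated ≥ 4.21
mean on the 1–5 Likert scale are shown: gender (pie), diseases, symptoms,
treatments, behaviours (bars) visible; opinion source, categorized comments
(pies) and the top-20 word-frequency bar hidden but retrievable. A comment
contributes once per label to a bar chart regardless of repeat mentions
(so bar totals conserve per-comment label counts); comments with unknown
gender are excluded from the gender pie but stay in the table. Bars sort
descending by count with lexicographic tie-breaks. Reports are JSON; PDF
rendering is presentation-layer and out of scope.

## Evaluation statistics

* **Power analysis**: noncentrality δ = d·√(n₁n₂/(n₁+n₂)), df = n₁+n₂−2,
  critical t from the central t distribution (upper α, or α/2 two-tailed),
  achieved power from the noncentral t CDF (scipy's `nct`; a Monte-Carlo
  simulation cross-checks it in the tests). `required_sample_size` searches
  n₁ = 2, 3, … with n₂ = ⌈ratio·n₁⌉ until the target power is met; the
  tests verify minimality (n−1 fails) across a grid of designs. A zero
  effect size is rejected as unreachable.
* **Mann-Whitney U**: midranks over the pooled sample, U counted for group
  1 (ties = ½), per-group mean ranks reported. For n₁·n₂ ≤ 64 the p-value
  is the exact conditional permutation probability
  P(|U−n₁n₂/2| ≥ |u−n₁n₂/2|) over all C(n₁+n₂, n₁) assignments — tie-aware
  by construction. Larger samples use the normal approximation with
  tie-corrected variance and a 0.5 continuity correction. All-identical
  pooled values return p = 1 with the tie flag set. Two-tailed by default;
  the tail is a parameter.
* **Likert interpretation**: the mean is rounded half-up to 2 decimals
  (half-up, not banker's, so 4.205 → 4.21) and mapped through the five bins
  1.00–1.80 Very Poor, 1.81–2.60 Poor, 2.61–3.40 Moderate, 3.41–4.20 Good,
  4.21–5.00 Very Good, which partition [1, 5] exactly at 2-dp resolution.

## Synthetic data

`generate_corpus` builds bilingual corpora from class-specific template
banks: sharing templates carry first-person/kin cues plus lexicon terms,
inquiring templates carry interrogative cues, non-informative templates
carry neither. Defaults: 200 comments, 50% Thai, class mixture
(0.45, 0.15, 0.40) for sharing/inquiring/non-informative — questions kept
deliberately scarce, mirroring their minority role in health comment
threads — and 10% planted duplicate and 10% short-comment rates. Every
planted label, mention, duplicate and short flag is recorded as ground
truth, and generation is a pure function of the spec and seed.

`generate_fixture_html` renders records into pages that parse back
field-for-field under the same selector config (simple `tag.class`
selectors only). `generate_likert_responses` draws 1–5 ordinal samples by
cutting latent normals (sd 1, cuts at 1.5/2.5/3.5/4.5); group 1's latent
mean is 3 + shift, so shift 0 gives exchangeable groups (used for the
type-I-error simulation) and growing shift gives stochastic dominance.

**What passing tests show** — that the mechanics are correct: cleaning
removes exactly the planted noise, extraction equals a brute-force term
scan, the classifier plumbing is leak-free, retrieval equals brute-force
cosine ranking, the statistics match exact enumeration and Monte-Carlo
oracles. **What they do not show** — real-world accuracy: template text is
far more separable and regular than actual social-media language, the
starter lexicon is a small stand-in for a production keyword list, and the
dictionary segmenter will fragment open-domain Thai. Published accuracy
figures for large fine-tuned models are not reproducible at desk scale and
are not claimed.

## Problem sizes used in the checks

The bundled verification runs use 100–1,000-comment synthetic corpora, a
1,000-vector retrieval index, exhaustive permutation enumeration for group
sizes up to 6, and 1,000 replicates for the rank-test size simulation —
sizes at which the exact oracles are still cheap while estimates are
stable.

## Known limitations

* Substring matching for Thai terms can false-positive on short terms
  embedded in longer words; the shipped lexicon avoids the known offenders,
  but user-supplied lexicons should prefer multi-character terms.
* Language detection assigns one language per comment; heavily code-mixed
  comments are processed under the majority script only.
* Negation and hypotheticals are not detected ("no sign of cancer" counts
  as a cancer mention) — semantic matching is explicitly out of scope.
* The exact Mann-Whitney path enumerates C(n₁+n₂, n₁) assignments and is
  only used below the 64-pair threshold by design.
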