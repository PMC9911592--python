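# Methods

This note documents the models and procedures implemented in `reportal`,
the choices made where the design was genuinely open, and what the
synthetic test bed does and does not demonstrate.

## Annotation model

A corpus is a set of reports; a report is raw text plus standoff
annotations. All offsets are 0-based half-open character positions into the
raw text — the brat convention — and token offsets are document-absolute.
An entity is a typed contiguous character span whose stored surface must
equal the text slice (checked on every read). A relation is an *undirected*
binary link between two entities; it is stored canonically with the span
that starts earlier as the first argument, and no code path ever depends on
argument order. Relations crossing a sentence boundary, overlapping entity
spans, and entity spans not aligned to token boundaries are all rejected
into validation issues rather than silently repaired: within-sentence pair
enumeration, IOB round-tripping and strict-span scoring each break
invisibly if such inputs are let through.

The default schema covers general radiology reporting: 20 entity classes
(central clinical concepts, descriptors, specifications) and 15 relation
classes plus the reserved `no_relation` label. Relation argument rules are
encoded as sets of unordered entity-class pairs where the class definitions
name concrete arguments (e.g. `Has_dosing` links `Dosing` with
`Non_anatomical_substance`); relations defined over "various terms" carry
an empty rule set, which means unrestricted. Rule enforcement during sample
generation is relabel-only by default: rule-violating gold pairs surface as
validation issues, but candidate pairs are never deleted, so the pair count
of a sentence with $k$ entities is exactly $\binom{k}{2}$. A strict mode
that drops pairs allowed by no rule exists for training-set reduction; it
changes the pair-count arithmetic and is therefore opt-in.

## Sample encoding

NER uses IOB encoding over corpus tokens. Decoding repairs an orphan
`I-c` tag to `B-c` (logged); encoding of a span that does not align with
token boundaries is a hard error, not a clip — silent truncation corrupts
the encode/decode round trip, which is property-tested. RE samples are the
$\binom{k}{2}$ unordered entity pairs per sentence; gold pairs keep their
label, the rest are `no_relation`. Because negatives dominate (in the
worked six-entity example, 11 of 15), positives can be duplicated an
integer number of times on the train split (default factor 4). The test
split is never oversampled, so evaluation reflects the true label
distribution, and duplicates carry a copy index for downstream
deduplication. Batch statistics are always computed pre-oversampling.

## Pseudo-perplexity acquisition

For a tokenized sentence $X = (x_1, \dots, x_n)$ and a masked language
model $p_\theta$,

$$\mathrm{PPL}(X) = \exp\Big(-\tfrac{1}{n} \sum_{i=1}^n \log p_\theta(x_i \mid X_{-i})\Big),$$

each token masked in turn and predicted from the rest. Natural logarithms
pair with the exponential; probabilities are floored at a configurable
$\varepsilon = 10^{-12}$ before the log, since the score is undefined at
zero. PPL is intrinsic: it needs only a self-supervised model of raw text,
so the acquisition function survives schema changes and works before any
task labels exist — the practical advantage over uncertainty- or
margin-based sampling, which must be rebuilt whenever the label set
changes.

Sentence length is measured in corpus tokens, not model subwords, keeping
scores comparable across backends. Percentiles are empirical ranks with
stable tie-breaking and no interpolation (selection needs index sets, not
interpolated values): index $i$ is in band $(\ell, h]$ iff
$\ell < \mathrm{rank}_i / N \le h$. Strategic sampling draws uniformly from
the *intersection* of the PPL band and the length band — the strictest
reading of selecting on both scores; union and sequential-filter variants
would admit short-but-surprising or long-but-predictable sentences. When
the intersection is smaller than the batch, the batch is topped up from the
union of the bands, then from the full pool (a logged fallback ladder).
The default band is the upper 75th–90th percentile: high enough to be
informative, capped to exclude outliers (degenerate boilerplate and
pathological run-ons both live in the top decile). Percentile thresholds
are recomputed over the shrinking unlabeled pool at each iteration.

## Backends

Three contracts isolate all learning machinery: a masked LM
(`conditional_prob`), a sequence tagger (`fit`/`predict` over IOB
sequences) and a relation classifier (`fit`/`predict` over pair samples).
Transformer models fit behind these contracts as registered adapters; the
shipped reference backends are deliberately small so the full cycle runs at
desk scale:

- **Unigram masked LM** — additively smoothed,
  $p(t) = (c(t) + \alpha)/(N + \alpha V)$ with $V$ the observed vocabulary,
  default $\alpha = 1$. Context-free by construction, which makes it a
  transparent oracle for PPL behavior: surprise is exactly token rarity.
- **Window tagger** — multinomial logistic regression (SGD, log loss,
  $\alpha_{\text{reg}} = 10^{-6}$, 12 epochs with seeded shuffling) over
  hashed features of the token, its neighbors, character shape, suffix and
  casing ($2^{16}$ hashed dimensions).
- **Pair classifier** — the same linear machinery over the unordered
  entity-class pair, both surfaces, log character distance and the bag of
  tokens between the spans ($2^{15}$ dimensions). Features are computed on
  the offset-ordered pair, so predictions are symmetric in argument order
  by construction.

These reference models exist to exercise the loop and the acquisition
logic, not to approach transformer accuracy. All backends are deterministic
under a fixed seed, and all support warm starting: `fit(data, init=prev)`
continues SGD from the previous parameters, which is how source-domain
knowledge transfers in the domain-adaptation experiments. MLM training
pairs are produced by masking $\lceil 0.15\,n \rceil$ tokens per sentence
(no 80/10/10 replacement split — masked positions always become the mask
symbol).

## The active-learning cycle

Phase 1 draws a seeded uniform sample of the pool (default 268 sentences),
annotates it and fits the task models once. Each iteration then (2)
selects a batch (default 100) by the scheduled strategy and pre-annotates
it with the current tagger and relation classifier — these *soft labels*
are presentation-only, shown to the annotator for correction; training
always uses the corrected gold — and (3) retrains both models on the full
labeled set (not incrementally on the batch), applying positive
oversampling inside each retraining call. The default schedule runs random
sampling for seven iterations and switches to strategic sampling at
iteration 8. Iteration stops when a held-out metric reaches its threshold,
the pool is exhausted, or a max-iteration guard (default 50) trips. The
scoring MLM is fixed during the loop (refreshing it is configurable). The
fraction of soft labels the annotator accepts unchanged is logged per
iteration — the observable proxy for annotation cost saved. Per-iteration
seeds derive from one base seed, so a full run is bit-reproducible.

## Evaluation

Macro-F1 — the unweighted mean of per-class F1 — is the headline metric
for both tasks, treating every class as equally important regardless of
support. NER matching is strict by default: a true positive requires an
exact (start, end, class) match; token-level matching is available by
flag. For RE, `no_relation` is excluded from the macro mean by default:
the negative class dominates the pair universe, and including it would
mask exactly the minority relation classes the metric is meant to protect.
A flag includes it, and both conventions can be reported to bracket the
ambiguity. Classes with neither gold nor predicted support are excluded
from the mean; reports carry their raw confusion counts so every number is
recomputable. Cohen's kappa, $\kappa = (p_o - p_e)/(1 - p_e)$ with
marginal-product chance agreement, is provided for double-annotation
agreement studies; the degenerate case $p_e = 1$ is defined as
$\kappa = 1$ when observed agreement is also perfect and an error
otherwise.

## Synthetic test bed

Real clinical corpora cannot be shipped, so all simulations run on
generated pseudo-clinical corpora: grammar-free slot-filler templates over
German-like nonsense tokens. No real clinical text or PHI is involved. The
generator is engineered to reproduce the statistical structure the method
exploits, with everything explicit in configuration rather than emergent:

- **Zipf vocabularies** (exponent 1.2) within each entity class: rare
  types exist, and sentences containing them are high-surprise under any
  frequency-sensitive language model. Word suffixes are drawn from a pool
  shared across classes so that a word's ending does not reveal its class
  — otherwise tagging degenerates into a suffix lookup and rare classes
  would need no labeled examples, removing the phenomenon strategic
  sampling exploits.
- **Length-stratified templates**: ~60% short (0–3 entities), ~15% medium,
  ~15% long and ~10% extra-long outlier sentences. The twelve minority
  entity classes appear only in the long templates (three per template),
  so minority mentions concentrate in sentences the length band selects;
  minority mentions are ~14% of all entity mentions. The weights place
  long templates in roughly the 75th–90th length percentile and the
  outliers above it, so the capped band genuinely excludes something.
- **Six active relation classes** instantiated by the templates, all
  schema-legal by construction; each template relation is annotated with
  probability 0.9, leaving some legal pairs negative.
- **Domain pairs**: domain B keeps each of A's word types and templates
  independently with probability `overlap`, replacing the rest; overlap 1
  gives identical generative distributions, overlap 0 disjoint content
  vocabularies.

The default corpus is 2,000 sentences. Held-out evaluation uses an iid
split of one generated corpus; a corpus from a different generator seed
has a different vocabulary and is therefore a different *domain*, which is
exercised separately through the domain-pair generator.

What passing simulations show: the acquisition arithmetic, loop mechanics
and evaluation are correct, and the engineered statistical structure
(rare-term surprise, minority-length affinity, overlap-dependent transfer)
is sufficient for strategic sampling and warm starting to help. What they
do not show: effect sizes on real clinical text, where entity surface
forms are ambiguous, sentence structure is not template-bound, and the
masked LM is a contextual transformer rather than a unigram model.

## Problem sizes and numerical choices

The canned experiments (`reportal.experiments`) use 2,000-sentence corpora
for enrichment measurements; a 1,000-sentence pool with a 300-sentence
held-out split, a 100-sentence seed and five batches of 50 for the
learning-curve comparison; and 700-sentence domains with 200 fine-tuning
and 300 test sentences for the transfer study — sizes at which the
reference backends make each experiment a matter of seconds while leaving
the compared conditions clearly separated. Each experiment averages five
seeded replicates derived from one base seed. Ties in percentile ranking
are broken by stable input order; batch selection draws without
replacement from sorted candidate lists, so results are independent of set
iteration order. Degenerate inputs are defined explicitly: empty sentences
cannot be scored, empty pools cannot be sampled, single-class training
sets yield a constant classifier, and an empty proposed batch signals
completion rather than an error.

## Known limitations

- The reference backends are linear models over hashed features; their
  absolute F1 values on the synthetic corpus say nothing about transformer
  performance on clinical text.
- Nested and discontinuous entities, brat attribute (A) and note (#)
  records, and cross-sentence or directed relations are out of scope.
- The rule-based sentence splitter is a fallback; for real German clinical
  text a dedicated splitter should be plugged in via the splitter
  interface.
- Pseudo-perplexity under the unigram reference backend reduces to token
  rarity; contextual surprise (rare constructions of common words) needs a
  contextual masked LM behind the same contract.
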