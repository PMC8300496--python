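# Methods

## The extraction model

`causaltext` treats causal-relation extraction as pure pattern matching
over POS-tagged sentences: no parsing, no semantics, no machine learning.
The unit of processing is the sentence; a sentence contributes at most one
link, anchored at the **first** token whose lower-cased lemma is in the
effect lexicon. Matching is deliberately POS-agnostic: nominal keyword uses
("an increase in productivity") are real causal signals in abstracts, and
restricting to verbs would silently discard them. The cost is a class of
nonsense links (e.g. *results → productivity*) that the harmonization layer
exists to remove — extraction is recall-oriented, curation restores
precision.

### Concept assembly

From the keyword (or from the agent marker *by*, in the passive), the
algorithm scans outward, skipping every token not tagged NOUN —
determiners, verbs, adpositions, adverbs, punctuation — until the head
NOUN, then extends one token further outward when that token is NOUN or
ADJ. This yields 1–2-token compounds whose ADJ slot is always the *outer*
position: the relaxation exists because taggers routinely mis-label the
first of two nouns (and some lone nominals like *herbivory*) as
adjectives. With three or more consecutive nouns, the two nearest the
keyword are kept, preserving the head closest to it. The keyword token can
never be a constituent, and concepts never cross the keyword. A
`skip_scan=False` mode demands strict adjacency instead, for comparing the
two readings of "immediately before and after"; the skip-scan reading is
the default because it is the only one consistent with extracting
*results → productivity* from "our results show an increase in
productivity".

A consequence worth knowing: for a 3-token noun run the active and passive
phrasings keep different 2-token spans (the two tokens nearest the keyword
lie at the start of the phrase when it follows the keyword, at its end when
it precedes it). Voice invariance of the full tuple therefore holds exactly
for components of at most two tokens.

### Voice and weighting

Passive voice is detected heuristically — the original rule statement
("component B is affected by component A") does not fix a mechanism — as:
an auxiliary with lemma *be* within **3 tokens** left of the keyword
(window sized to span "are often significantly increased") *and* the first
non-adverb token right of the keyword being the agent marker *by*. A
passive signal without a *by*-agent produces **no** link: the driver is
unknowable, and a half-link would poison aggregation. The drop is logged
with its rule name so curators can audit it.

The link weight is the keyword's signed base weight times the multiplier of
the single ADV immediately left of the keyword, when that adverb is in the
modifier table (*slightly* → 0.5 in all examples here); multipliers never
compound. Defaults ship exactly the four strong causation indicators
(*increase*, *promote* → +1; *decrease*, *decline* → −1) with an **empty**
modifier table — keywords and modifiers are study choices, declared
explicitly in config before processing.

## Tagging

Extraction consumes only (lemma, UPOS) per token, behind a backend
contract; sentence segmentation belongs to the backend and is never
re-done. Tag quality directly shapes the network, so UD backends must be
pinned by model name — there is no silent default. The bundled
`LexiconTagger` is a deterministic lexicon tagger: sentences split on
`./!/?` + whitespace, whitespace tokens with boundary punctuation split
off, tags looked up in a closed-class base lexicon plus user entries, and
unknown open-class words defaulting to NOUN. The NOUN default is test-only
behaviour that keeps the tagger total over synthetic corpora; it is not a
substitute for a trained model on real prose, where the same mechanism is
available via `LexiconTagger(user_lexicon)` for planting deliberate
mis-tags in tests.

## Harmonization and networks

Cleanup operates on the extracted link table, never on the raw text, so
provenance survives. The concept map is one-step (values are fixed points
of the map, validated eagerly) which makes application idempotent;
substring pooling matches whole-word phrases only, so *rein* never captures
*reindeer* while *reindeer* captures *reindeer grazing*. Drop-lists and
symbol stripping (e.g. `%`, ubiquitous in effect-size phrasing) only remove
links; harmonization can never change a weight or invent evidence.

Aggregation groups by the exact directed (driver, target) pair: the edge
weight is the arithmetic **mean** of the pooled link weights — opposing
reports cancel toward zero — and the evidence count is kept so users can
re-weight. Mean-zero edges are retained and flagged rather than deleted: a
contested interaction is information. Self-loops are permitted and flagged.
Ego subnetworks default to undirected reachability (components affecting
*and* affected by the focal concept), with `out`/`in` modes for directed
questions; the edge set is every original directed edge between retained
nodes. GraphML export carries mean weight, evidence count and a
JSON-encoded provenance list, and round-trips the network exactly; DOT and
edge-list CSV are one-way conveniences.

## Synthetic corpora

The generator emulates the sentence shapes the rules target, over
tundra-flavoured vocabulary pools (10 driver and 10 target phrases of 1–2
tokens, all tokens tagged NOUN): active `<D> <kw+s> <T>.`, passive
`<T> are <kw+ed> by <D>.`, optionally with a modifier adverb immediately
before the keyword, plus nominal-keyword stressors
(`Our results show an increase in <T>.`) that pin the skip-scan decision,
and keyword-free distractor filler. Default mix: voice 0.3 passive,
modifier rate 0.2, distractor rate 0.3, stressor rate 0.1. Every
non-distractor sentence plants exactly one gold tuple whose weight includes
the planted modifier, and the generator returns the word→(lemma, POS)
lexicon covering its output, so the lexicon tagger is total over it. The
RNG is a local `random.Random(seed)`; generation is byte-deterministic per
seed.

Vocabulary phrases never put an ADJ in a target's first slot: the outward
extension rule cannot reach an adjective on the keyword side of a
right-hand compound, so such gold tuples would be unsatisfiable by
construction; the ADJ relaxation is exercised by direct unit tests instead.

What passing the recovery gate (precision = recall = 1.0 across seeds and
mixes) shows is that the implementation realizes its own rules exactly. It
says nothing about real abstracts, where tagger errors, negation ("did not
increase"), hedging, coreference and clause structure all degrade both
precision and recall — none of which the rules model, by design.

## Numerical and design choices

* Weights are plain floats; aggregation means are sums/counts, bounded by
  the extreme constituent weights. No tolerances are needed anywhere —
  every comparison in the package is exact.
* Determinism: extraction has no RNG at all; generation is seeded; readers
  are byte-stable; re-running a pipeline config reproduces identical link
  and edge tables (asserted in tests via byte comparison).
* Degenerate inputs: empty documents, keyword-at-boundary sentences
  ("Increases occur."), targets missing in active voice ("Temperatures
  increased.") all yield zero links rather than errors; empty corpora
  produce valid empty outputs.
* Input encodings other than UTF-8 are rejected with the byte offset, never
  guessed; duplicate document ids are a hard error.
* Problem sizes in the test suite (e.g. 10 × 500-sentence corpora for the
  recovery gate, 10,000 random sentences for the concept-window
  enumeration check) were chosen as the smallest sizes at which the checked
  properties are exercised across all sentence shapes; all are exact
  checks, so size buys coverage, not statistical power.

## Known limitations

* No negation, hedging/uncertainty, or coreference handling; dependency
  parses are not consulted. These are outside the rule set on purpose.
* One link per sentence caps recall on sentences reporting several effects.
* The passive heuristic misses agentless passives (by design) and long
  aux–participle gaps (> 3 tokens); it can also suppress a genuine active
  reading when an unrelated *be* sits within the window.
* Ambiguous short tokens (the letter *c* as carbon vs °C) are not
  special-cased; the two-token compound usually supplies the disambiguating
  context ("degree c", "tons c"), and the rest is curator work.
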