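"""Grammatical causal-link extraction.

The algorithm works sentence by sentence. It locates the first effect
keyword (a user-declared lemma such as *increase* or *decline*, each
carrying a signed base weight), then reads the noun-phrase components on
either side of it:

* active voice — ``component A <keyword> component B`` — the left concept
  is the driver and the right concept the target;
* passive voice — ``component B is <keyword>-ed by component A`` — roles
  swap, with the driver read to the right of the agent marker *by*.

Concepts are one- or two-token noun compounds. Scanning outward from the
keyword, tokens that are not nouns (determiners, verbs, adpositions,
adverbs, punctuation, ...) are skipped until the head NOUN; the concept then
extends one token further outward when that token is a NOUN or an ADJ — the
ADJ relaxation absorbs taggers that mis-label the first of two nouns (e.g.
*herbivory*) as an adjective. With three or more consecutive nouns, the two
nearest the keyword are kept.

The link weight is the keyword's signed base weight times an optional
adverbial multiplier (*slightly increase* → +0.5). Matching is by
lower-cased lemma and deliberately ignores the keyword's own POS tag:
nominal uses ("an increase in productivity") are real signals in abstracts
even when they yield links a curator will later drop.

Everything here is deterministic; there is no randomness in extraction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .annotation import TaggedSentence, TaggerBackend, Token, annotate
from .corpus import Corpus
from .errors import ValidationError

logger = logging.getLogger(__name__)

#: the four strong causation indicators used as the default effect lexicon
DEFAULT_KEYWORDS: Mapping[str, float] = {
    "increase": 1.0,
    "promote": 1.0,
    "decrease": -1.0,
    "decline": -1.0,
}

#: tokens a concept head may extend over (the "(NOUN/ADJ)-NOUN" compound)
_EXTEND_TAGS = frozenset({"NOUN", "ADJ"})
_AGENT_MARKER = "by"
_PASSIVE_AUX_WINDOW = 3  # tokens left of the keyword searched for "be"


@dataclass(frozen=True)
class EffectLexicon:
    """Effect keywords with signed base weights, adverbial multipliers and
    the auxiliary lemmas that signal passive voice."""

    keyword_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_KEYWORDS))
    modifier_weights: Mapping[str, float] = field(default_factory=dict)
    passive_aux_lemmas: frozenset[str] = frozenset({"be"})

    def __post_init__(self) -> None:
        if not self.keyword_weights:
            raise ValidationError("effect lexicon needs at least one keyword")
        for kw, w in self.keyword_weights.items():
            if not math.isfinite(w) or w == 0:
                raise ValidationError(
                    f"keyword {kw!r} has invalid base weight {w!r}")
        for adv, m in self.modifier_weights.items():
            if not math.isfinite(m) or m <= 0:
                raise ValidationError(
                    f"modifier {adv!r} has invalid multiplier {m!r}")


@dataclass(frozen=True)
class Concept:
    """A 1–2-token noun compound; text is the space-joined lemmas in
    surface order."""

    tokens: tuple[Token, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.tokens) <= 2:
            raise ValidationError("a concept has one or two constituents")
        if all(t.upos != "NOUN" for t in self.tokens):
            raise ValidationError("a concept needs at least one NOUN")

    @property
    def text(self) -> str:
        return " ".join(t.lemma for t in self.tokens)


@dataclass(frozen=True)
class CausalLink:
    """One extracted signed causal relation with full provenance."""

    driver: str
    target: str
    keyword: str
    weight: float
    voice: str
    doc_id: str
    sentence_index: int
    sentence_text: str
    keyword_index: int

    def __post_init__(self) -> None:
        if not self.driver or not self.target:
            raise ValidationError("driver and target must be non-empty")
        if self.voice not in ("active", "passive"):
            raise ValidationError(f"invalid voice {self.voice!r}")


def find_keyword(sentence: TaggedSentence, lexicon: EffectLexicon) -> int | None:
    """Index of the left-most token whose lemma is an effect keyword,
    regardless of POS tag; None when the sentence has none. Only this first
    occurrence is ever extracted from a sentence."""
    for tok in sentence.tokens:
        if tok.lemma in lexicon.keyword_weights:
            return tok.index
    return None


def nearest_concept(sentence: TaggedSentence, from_index: int, direction: str,
                    *, skip_scan: bool = True) -> Concept | None:
    """The 1–2-token concept nearest ``from_index`` on the given side.

    Scans outward, skipping non-NOUN tokens, until the head NOUN; extends one
    token further outward when that token is NOUN or ADJ. Returns None when
    no NOUN occurs before the sentence boundary. With ``skip_scan=False``
    the head must be strictly adjacent to ``from_index`` (comparison mode;
    the skip-scan is what recovers e.g. "results ... increase in
    productivity").
    """
    if direction not in ("left", "right"):
        raise ValueError(f"direction must be left or right, got {direction!r}")
    step = -1 if direction == "left" else 1
    tokens = sentence.tokens
    i = from_index + step
    while 0 <= i < len(tokens):
        if tokens[i].upos == "NOUN":
            break
        if not skip_scan:
            return None
        i += step
    else:
        return None
    head = tokens[i]
    j = i + step
    if 0 <= j < len(tokens) and tokens[j].upos in _EXTEND_TAGS:
        pair = (tokens[j], head) if step == -1 else (head, tokens[j])
        return Concept(pair)
    return Concept((head,))


def _passive_aux_index(sentence: TaggedSentence, keyword_index: int,
                       lexicon: EffectLexicon) -> int | None:
    lo = max(0, keyword_index - _PASSIVE_AUX_WINDOW)
    for i in range(keyword_index - 1, lo - 1, -1):
        if sentence.tokens[i].lemma in lexicon.passive_aux_lemmas:
            return i
    return None


def _agent_marker_index(sentence: TaggedSentence, keyword_index: int) -> int | None:
    """Index of the agent marker "by" immediately right of the keyword,
    looking through intervening adverbs."""
    for tok in sentence.tokens[keyword_index + 1:]:
        if tok.upos == "ADV":
            continue
        return tok.index if tok.lemma == _AGENT_MARKER else None
    return None


def detect_voice(sentence: TaggedSentence, keyword_index: int,
                 lexicon: EffectLexicon) -> str:
    """Passive iff a passive auxiliary (*be*) occurs within three tokens left
    of the keyword AND the next non-adverb token right of it is the agent
    marker *by*; active otherwise."""
    if (_passive_aux_index(sentence, keyword_index, lexicon) is not None
            and _agent_marker_index(sentence, keyword_index) is not None):
        return "passive"
    return "active"


def modifier_multiplier(sentence: TaggedSentence, keyword_index: int,
                        lexicon: EffectLexicon) -> float:
    """Multiplier from the single ADV immediately left of the keyword, if it
    is in the modifier table; 1.0 otherwise. Multipliers never compound."""
    if keyword_index > 0:
        tok = sentence.tokens[keyword_index - 1]
        if tok.upos == "ADV" and tok.lemma in lexicon.modifier_weights:
            return lexicon.modifier_weights[tok.lemma]
    return 1.0


def extract_link(sentence: TaggedSentence, lexicon: EffectLexicon,
                 *, skip_scan: bool = True) -> CausalLink | None:
    """Extract at most one causal link from a tagged sentence.

    Composes keyword search, voice detection, concept assembly on both sides
    and adverbial weighting. A passive construction without a *by*-agent
    yields no link (the driver is unknowable), rather than a half-link.
    """
    kw_idx = find_keyword(sentence, lexicon)
    if kw_idx is None:
        return None
    keyword = sentence.tokens[kw_idx].lemma
    voice = detect_voice(sentence, kw_idx, lexicon)
    if voice == "passive":
        by_idx = _agent_marker_index(sentence, kw_idx)
        driver = nearest_concept(sentence, by_idx, "right", skip_scan=skip_scan)
        target = nearest_concept(sentence, kw_idx, "left", skip_scan=skip_scan)
    else:
        if _passive_aux_index(sentence, kw_idx, lexicon) is not None:
            # passive signal without a "by"-agent: driver unknowable
            logger.debug(
                "dropped (passive-without-agent): %s sentence %d: %r",
                sentence.doc_id, sentence.sentence_index, sentence.raw_text)
            return None
        driver = nearest_concept(sentence, kw_idx, "left", skip_scan=skip_scan)
        target = nearest_concept(sentence, kw_idx, "right", skip_scan=skip_scan)
    if driver is None or target is None:
        return None
    weight = (lexicon.keyword_weights[keyword]
              * modifier_multiplier(sentence, kw_idx, lexicon))
    return CausalLink(
        driver=driver.text,
        target=target.text,
        keyword=keyword,
        weight=weight,
        voice=voice,
        doc_id=sentence.doc_id,
        sentence_index=sentence.sentence_index,
        sentence_text=sentence.raw_text,
        keyword_index=kw_idx,
    )


def extract_sentences(sentences: Iterable[TaggedSentence],
                      lexicon: EffectLexicon,
                      *, skip_scan: bool = True) -> list[CausalLink]:
    links = []
    for sent in sentences:
        link = extract_link(sent, lexicon, skip_scan=skip_scan)
        if link is not None:
            links.append(link)
    return links


def extract_corpus(corpus: Corpus, lexicon: EffectLexicon,
                   backend: TaggerBackend,
                   *, skip_scan: bool = True) -> list[CausalLink]:
    """Annotate and extract every document, in document order; at most one
    link per sentence, each with full provenance."""
    links: list[CausalLink] = []
    for doc in corpus:
        links.extend(extract_sentences(annotate(doc, backend), lexicon,
                                       skip_scan=skip_scan))
    return links


def count_sentences(corpus: Corpus, backend: TaggerBackend) -> int:
    return sum(len(annotate(doc, backend)) for doc in corpus)


def effect_lexicon_from_config(cfg: Mapping) -> EffectLexicon:
    """Build an EffectLexicon from config mappings
    (``keywords: {increase: 1, ...}``, ``modifiers: {slightly: 0.5}``)."""
    keywords = {str(k).lower(): float(v)
                for k, v in (cfg.get("keywords") or DEFAULT_KEYWORDS).items()}
    modifiers = {str(k).lower(): float(v)
                 for k, v in (cfg.get("modifiers") or {}).items()}
    aux = frozenset(str(a).lower() for a in cfg.get("passive_aux", ["be"]))
    return EffectLexicon(keywords, modifiers, aux)
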