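"""Seeded synthetic corpora with planted gold causal tuples.

Emulates the sentence shapes the extractor is built for — active and
passive causal statements over 1–2-token tundra-flavoured noun phrases,
optional adverbial modifiers, nominal-keyword "stressor" sentences ("Our
results show an increase in <T>."), and keyword-free distractor filler —
while planting, for every causal sentence, the gold (driver, keyword,
target, signed weight, voice) tuple it realizes. The generator also returns
the word→(lemma, POS) lexicon covering every generated token, so the
deterministic lexicon tagger is total over its output and recovery can be
scored exactly. It makes no attempt at realistic scientific prose or at
matching any real literature's corpus statistics.
"""

from __future__ import annotations

import random
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .corpus import Corpus, Document
from .errors import ValidationError
from .extraction import CausalLink, EffectLexicon

DEFAULT_DRIVERS: tuple[str, ...] = (
    "grazing", "reindeer", "fire", "warming", "fertilization", "herbivores",
    "snow cover", "permafrost thaw", "nutrient addition", "lemming density",
)
DEFAULT_TARGETS: tuple[str, ...] = (
    "lichens", "shrub biomass", "soil nitrogen", "plant productivity",
    "root density", "soil carbon", "moss cover", "microbial activity",
    "species richness", "litter decomposition",
)

#: keyword-free filler sentences, with the tags needed to cover their words
_DISTRACTORS: tuple[tuple[str, tuple[tuple[str, str, str], ...]], ...] = (
    ("Researchers study the tundra landscape.",
     (("researchers", "researchers", "NOUN"), ("study", "study", "VERB"),
      ("tundra", "tundra", "NOUN"), ("landscape", "landscape", "NOUN"))),
    ("The field season was short.",
     (("field", "field", "NOUN"), ("season", "season", "NOUN"),
      ("short", "short", "ADJ"))),
    ("Sampling occurred during summer.",
     (("sampling", "sampling", "NOUN"), ("occurred", "occur", "VERB"),
      ("summer", "summer", "NOUN"))),
    ("The weather remained stable.",
     (("weather", "weather", "NOUN"), ("remained", "remain", "VERB"),
      ("stable", "stable", "ADJ"))),
)

#: keywords with a usable nominal form for the stressor template
_NOMINAL_KEYWORDS = frozenset({"increase", "decrease", "decline"})


def _third_person(lemma: str) -> str:
    if lemma.endswith(("s", "x", "z", "ch", "sh")):
        return lemma + "es"
    if lemma.endswith("y") and lemma[-2:-1] not in "aeiou":
        return lemma[:-1] + "ies"
    return lemma + "s"


def _participle(lemma: str) -> str:
    return lemma + "d" if lemma.endswith("e") else lemma + "ed"


def _article(word: str) -> str:
    return "an" if word[0] in "aeiou" else "a"


def _cap(sentence: str) -> str:
    return sentence[0].upper() + sentence[1:]


@dataclass(frozen=True)
class TemplateSpec:
    """Study conditions for corpus generation: vocabulary pools, effect
    lexicon, voice mix, modifier/distractor/stressor rates and the RNG
    seed."""

    driver_vocab: tuple[str, ...] = DEFAULT_DRIVERS
    target_vocab: tuple[str, ...] = DEFAULT_TARGETS
    keywords: EffectLexicon = field(
        default_factory=lambda: EffectLexicon(
            modifier_weights={"slightly": 0.5}))
    voice_mix: float = 0.3
    modifier_rate: float = 0.2
    distractor_rate: float = 0.3
    stressor_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("voice_mix", "modifier_rate", "distractor_rate",
                     "stressor_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v!r}")
        if self.distractor_rate + self.stressor_rate > 1.0:
            raise ValidationError(
                "distractor_rate + stressor_rate must not exceed 1")
        if not self.driver_vocab or not self.target_vocab:
            raise ValidationError("vocabulary pools must be non-empty")
        kw = set(self.keywords.keyword_weights)
        vocab_tokens = {tok for phrase in self.driver_vocab + self.target_vocab
                        for tok in phrase.split()}
        clash = vocab_tokens & kw
        if clash:
            raise ValidationError(
                f"vocabulary overlaps keyword lemmas: {sorted(clash)}")


@dataclass(frozen=True)
class GoldLink:
    """A planted gold tuple; mirrors CausalLink minus provenance text."""

    doc_id: str
    sentence_index: int
    driver: str
    target: str
    keyword: str
    weight: float
    voice: str


def _build_lexicon(spec: TemplateSpec) -> dict[str, tuple[str, str]]:
    lex: dict[str, tuple[str, str]] = {
        "the": ("the", "DET"), "a": ("a", "DET"), "an": ("an", "DET"),
        "our": ("our", "DET"), "several": ("several", "DET"),
        "in": ("in", "ADP"), "by": ("by", "ADP"), "at": ("at", "ADP"),
        "during": ("during", "ADP"),
        "are": ("be", "AUX"), "was": ("be", "AUX"), "were": ("be", "AUX"),
        "show": ("show", "VERB"), "results": ("results", "NOUN"),
        "collected": ("collect", "VERB"), "sites": ("sites", "NOUN"),
    }
    for _, triples in _DISTRACTORS:
        for surface, lemma, upos in triples:
            lex[surface] = (lemma, upos)
    for phrase in spec.driver_vocab + spec.target_vocab:
        for tok in phrase.split():
            lex[tok.lower()] = (tok.lower(), "NOUN")
    for kw in spec.keywords.keyword_weights:
        lex[_third_person(kw)] = (kw, "VERB")
        lex[_participle(kw)] = (kw, "VERB")
        lex[kw] = (kw, "NOUN")  # nominal use in the stressor template
    for adv in spec.keywords.modifier_weights:
        lex[adv] = (adv, "ADV")
    return lex


def generate(n_docs: int, sentences_per_doc: int, spec: TemplateSpec
             ) -> tuple[Corpus, list[GoldLink], dict[str, tuple[str, str]]]:
    """Generate a corpus with its gold tuples and covering tag lexicon.

    Deterministic for a fixed spec (including its seed); the RNG is a local
    ``random.Random`` — no global state. Each non-distractor sentence
    realizes exactly one gold tuple.
    """
    if n_docs < 0 or sentences_per_doc < 0:
        raise ValidationError("n_docs and sentences_per_doc must be >= 0")
    rng = random.Random(spec.seed)
    keywords = sorted(spec.keywords.keyword_weights)
    modifiers = sorted(spec.keywords.modifier_weights)
    stressor_kws = sorted(set(keywords) & _NOMINAL_KEYWORDS)

    docs: list[Document] = []
    gold: list[GoldLink] = []
    for d in range(n_docs):
        doc_id = f"doc{d + 1:04d}"
        sentences: list[str] = []
        for s in range(sentences_per_doc):
            r = rng.random()
            if r < spec.distractor_rate:
                sentences.append(rng.choice(_DISTRACTORS)[0])
                continue
            if (r < spec.distractor_rate + spec.stressor_rate
                    and stressor_kws):
                kw = rng.choice(stressor_kws)
                target = rng.choice(spec.target_vocab)
                sentences.append(
                    f"Our results show {_article(kw)} {kw} in {target}.")
                gold.append(GoldLink(doc_id, s, "results", target, kw,
                                     spec.keywords.keyword_weights[kw],
                                     "active"))
                continue
            kw = rng.choice(keywords)
            driver = rng.choice(spec.driver_vocab)
            target = rng.choice(spec.target_vocab)
            passive = rng.random() < spec.voice_mix
            modified = modifiers and rng.random() < spec.modifier_rate
            adv = rng.choice(modifiers) if modified else None
            mult = spec.keywords.modifier_weights[adv] if adv else 1.0
            advtok = f"{adv} " if adv else ""
            if passive:
                sentences.append(
                    _cap(f"{target} are {advtok}{_participle(kw)} by {driver}."))
            else:
                sentences.append(
                    _cap(f"{driver} {advtok}{_third_person(kw)} {target}."))
            gold.append(GoldLink(
                doc_id, s, driver, target, kw,
                spec.keywords.keyword_weights[kw] * mult,
                "passive" if passive else "active"))
        docs.append(Document(doc_id, " ".join(sentences), "synthetic"))
    return Corpus(tuple(docs)), gold, _build_lexicon(spec)


def _key(doc_id: str, sentence_index: int, driver: str, target: str,
         keyword: str, weight: float) -> tuple:
    return (doc_id, int(sentence_index), driver, target, keyword,
            round(float(weight), 9))


def score(predicted: Iterable[CausalLink],
          gold: Iterable[GoldLink]) -> tuple[float, float]:
    """(precision, recall) of predicted links against gold tuples, matching
    on (doc_id, sentence_index, driver, target, keyword, weight). Both are
    1.0 on an empty denominator."""
    pred = Counter(_key(p.doc_id, p.sentence_index, p.driver, p.target,
                        p.keyword, p.weight) for p in predicted)
    gld = Counter(_key(g.doc_id, g.sentence_index, g.driver, g.target,
                       g.keyword, g.weight) for g in gold)
    matched = sum((pred & gld).values())
    precision = matched / sum(pred.values()) if pred else 1.0
    recall = matched / sum(gld.values()) if gld else 1.0
    return precision, recall


def corpus_to_frame(corpus: Corpus) -> pd.DataFrame:
    return pd.DataFrame(
        [{"doc_id": d.doc_id, "text": d.text} for d in corpus],
        columns=["doc_id", "text"])


def gold_to_frame(gold: Sequence[GoldLink]) -> pd.DataFrame:
    cols = ["doc_id", "sentence_index", "driver", "target", "keyword",
            "weight", "voice"]
    return pd.DataFrame([vars(g) for g in gold], columns=cols)
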