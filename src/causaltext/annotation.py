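"""Sentence segmentation and Universal-Dependencies POS tagging.

Extraction only needs, per token, a lower-cased lemma and a UPOS tag. Any
tagger that can produce those fits the :class:`TaggerBackend` contract; the
shipped :class:`LexiconTagger` is a deterministic lexicon-based tagger that
works with no model download, which makes the grammatical extraction rules
testable offline and reproducible to the byte. Production corpora should use
a UD-trained model (spaCy, Stanza, udpipe), pinned by name and version —
tagging quality directly shapes the extracted network, so the model is never
silently defaulted.
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Protocol, runtime_checkable

from .corpus import Document
from .errors import ConfigurationError, ValidationError

#: the 17-tag Universal Dependencies POS inventory
UD_TAGS = frozenset({
    "ADJ", "ADP", "ADV", "AUX", "CCONJ", "DET", "INTJ", "NOUN", "NUM",
    "PART", "PRON", "PROPN", "PUNCT", "SCONJ", "SYM", "VERB", "X",
})


@dataclass(frozen=True)
class Token:
    """One tagged token: 0-based sentence position, surface form,
    lower-cased lemma and UPOS tag."""

    index: int
    surface: str
    lemma: str
    upos: str

    def __post_init__(self) -> None:
        if self.upos not in UD_TAGS:
            raise ValidationError(f"{self.upos!r} is not a UD POS tag")


@dataclass(frozen=True)
class TaggedSentence:
    doc_id: str
    sentence_index: int
    tokens: tuple[Token, ...]
    raw_text: str

    def __post_init__(self) -> None:
        for i, tok in enumerate(self.tokens):
            if tok.index != i:
                raise ValidationError("token indices must be contiguous from 0")


@runtime_checkable
class TaggerBackend(Protocol):
    """Maps raw document text to sentences of (surface, lemma, upos) triples.

    Implementations must be deterministic for a fixed input and model
    version, and must own sentence segmentation: the pipeline never
    re-splits.
    """

    name: str

    def tag_text(self, text: str) -> list[tuple[str, list[tuple[str, str, str]]]]:
        """Return ``[(sentence_raw_text, [(surface, lemma, upos), ...]), ...]``."""
        ...


def annotate(document: Document, backend: TaggerBackend) -> tuple[TaggedSentence, ...]:
    """Segment and tag one document into :class:`TaggedSentence` records."""
    sentences = []
    for s_idx, (raw, triples) in enumerate(backend.tag_text(document.text)):
        tokens = tuple(
            Token(i, surface, lemma, upos)
            for i, (surface, lemma, upos) in enumerate(triples)
        )
        sentences.append(TaggedSentence(document.doc_id, s_idx, tokens, raw))
    return tuple(sentences)


# ---------------------------------------------------------------------------
# Deterministic lexicon tagger
# ---------------------------------------------------------------------------

def _family(upos: str, lemma: str, *words: str) -> dict[str, tuple[str, str]]:
    return {w: (lemma, upos) for w in words}


#: Closed-class English function words plus a few verbs common in abstracts.
#: Unknown open-class words default to NOUN (documented test-only behaviour:
#: it keeps the tagger total over synthetic corpora).
BASE_LEXICON: dict[str, tuple[str, str]] = {
    **{w: (w, "DET") for w in (
        "the", "a", "an", "this", "these", "those", "our", "its", "their",
        "some", "all", "both", "each", "any", "such", "no", "other")},
    **{w: (w, "PRON") for w in (
        "we", "it", "they", "them", "us", "which", "who", "what", "i", "you")},
    **{w: (w, "ADP") for w in (
        "in", "on", "at", "by", "of", "for", "with", "from", "to", "into",
        "over", "under", "between", "among", "across", "near", "within",
        "without", "during", "after", "before", "through", "per", "via")},
    **_family("AUX", "be", "is", "are", "was", "were", "be", "been", "being", "am"),
    **_family("AUX", "have", "has", "have", "had"),
    **_family("AUX", "do", "do", "does", "did"),
    **{w: (w, "AUX") for w in (
        "can", "could", "may", "might", "will", "would", "shall", "should",
        "must")},
    **{w: (w, "CCONJ") for w in ("and", "or", "but", "nor")},
    **{w: (w, "SCONJ") for w in (
        "because", "although", "while", "if", "when", "as", "than", "that",
        "whether")},
    **{w: (w, "ADV") for w in (
        "not", "also", "often", "very", "however", "significantly",
        "slightly", "strongly", "greatly", "highly", "moreover", "therefore",
        "thus", "here", "only", "more", "most", "rapidly", "markedly")},
    **_family("VERB", "show", "show", "shows", "showed", "shown"),
    **_family("VERB", "find", "find", "finds", "found"),
    **_family("VERB", "suggest", "suggest", "suggests", "suggested"),
    **_family("VERB", "indicate", "indicate", "indicates", "indicated"),
    **_family("VERB", "observe", "observe", "observes", "observed"),
    **_family("VERB", "study", "studied", "studies"),
    **_family("VERB", "report", "report", "reports", "reported"),
    **_family("VERB", "affect", "affect", "affects", "affected"),
    **_family("VERB", "remain", "remain", "remains", "remained"),
    **_family("VERB", "occur", "occur", "occurs", "occurred"),
    **_family("VERB", "measure", "measure", "measures", "measured"),
    **_family("VERB", "use", "use", "uses", "used"),
    # inflected effect keywords; the bare forms are nouns in running text
    # ("an increase in ..."), which keyword matching handles by lemma
    **_family("VERB", "increase", "increases", "increased", "increasing"),
    **_family("VERB", "decrease", "decreases", "decreased", "decreasing"),
    **_family("VERB", "decline", "declines", "declined", "declining"),
    **_family("VERB", "promote", "promote", "promotes", "promoted", "promoting"),
    "increase": ("increase", "NOUN"),
    "decrease": ("decrease", "NOUN"),
    "decline": ("decline", "NOUN"),
}

_SENTENCE_SPLIT = re.compile(r"(?<=[.!?])\s+")
_STRIP_CHARS = string.punctuation
_NUM = re.compile(r"^[+-]?\d+([.,]\d+)*$")


class LexiconTagger:
    """Deterministic lexicon-based tagger.

    Sentences split on ``. ! ?`` followed by whitespace; tokens split on
    whitespace with leading/trailing punctuation separated into their own
    PUNCT (or SYM, for ``%$+<>=~``) tokens. Each word is tagged from the
    lexicon (word → (lemma, upos)); unknown words default to NOUN with the
    lower-cased surface as lemma.
    """

    SYM_CHARS = set("%$+<>=~")

    def __init__(self, lexicon: Mapping[str, tuple[str, str]] | None = None,
                 *, extend_base: bool = True, name: str = "lexicon") -> None:
        merged: dict[str, tuple[str, str]] = dict(BASE_LEXICON) if extend_base else {}
        for word, entry in (lexicon or {}).items():
            merged[word.lower()] = (entry[0].lower(), entry[1])
        for word, (lemma, upos) in merged.items():
            if upos not in UD_TAGS:
                raise ValidationError(
                    f"lexicon entry {word!r} has non-UD tag {upos!r}")
        self.lexicon = merged
        self.name = name

    # -- tokenization ------------------------------------------------------
    def _split_chunk(self, chunk: str) -> list[str]:
        head: list[str] = []
        tail: list[str] = []
        while chunk and chunk[0] in _STRIP_CHARS:
            head.append(chunk[0])
            chunk = chunk[1:]
        while chunk and chunk[-1] in _STRIP_CHARS:
            tail.append(chunk[-1])
            chunk = chunk[:-1]
        return head + ([chunk] if chunk else []) + tail[::-1]

    def _tag_word(self, word: str) -> tuple[str, str]:
        low = word.lower()
        if len(word) == 1 and word in _STRIP_CHARS:
            return (word, "SYM" if word in self.SYM_CHARS else "PUNCT")
        if low in self.lexicon:
            return self.lexicon[low]
        if _NUM.match(word):
            return (low, "NUM")
        if all(c in _STRIP_CHARS for c in word):
            return (word, "PUNCT")
        return (low, "NOUN")

    def tag_text(self, text: str) -> list[tuple[str, list[tuple[str, str, str]]]]:
        out = []
        for raw in _SENTENCE_SPLIT.split(text):
            raw = raw.strip()
            if not raw:
                continue
            triples = []
            for chunk in raw.split():
                for piece in self._split_chunk(chunk):
                    lemma, upos = self._tag_word(piece)
                    triples.append((piece, lemma, upos))
            if triples:
                out.append((raw, triples))
        return out


def lexicon_tag(text: str,
                lexicon: Mapping[str, tuple[str, str]] | None = None,
                doc_id: str = "doc") -> tuple[TaggedSentence, ...]:
    """One-shot convenience: tag raw text with :class:`LexiconTagger`."""
    return annotate(Document(doc_id, text), LexiconTagger(lexicon))


def load_lexicon_tsv(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read a tagging lexicon from TSV: ``word<TAB>upos[<TAB>lemma]``.

    Lemma defaults to the lower-cased word. Blank lines and ``#`` comments
    are skipped.
    """
    lexicon: dict[str, tuple[str, str]] = {}
    for lineno, line in enumerate(Path(path).read_text("utf-8").splitlines(), 1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValidationError(
                f"{path}:{lineno}: expected word<TAB>upos[<TAB>lemma]")
        word, upos = parts[0].strip(), parts[1].strip()
        lemma = parts[2].strip() if len(parts) > 2 and parts[2].strip() else word
        lexicon[word.lower()] = (lemma.lower(), upos)
    return lexicon


def write_lexicon_tsv(lexicon: Mapping[str, tuple[str, str]],
                      path: str | Path) -> Path:
    path = Path(path)
    lines = [f"{word}\t{upos}\t{lemma}"
             for word, (lemma, upos) in sorted(lexicon.items())]
    path.write_text("\n".join(lines) + "\n", "utf-8")
    return path


# ---------------------------------------------------------------------------
# Backend registry
# ---------------------------------------------------------------------------

class SpacyBackend:
    """UD tagging through a pinned spaCy pipeline (lazy import)."""

    def __init__(self, model: str) -> None:
        try:
            import spacy  # noqa: F401
        except ImportError as exc:
            raise ConfigurationError(
                "tagger backend 'spacy' requires the spacy package and a "
                f"UD-trained model; install spacy and `python -m spacy "
                f"download {model}`"
            ) from exc
        try:
            self._nlp = spacy.load(model)
        except OSError as exc:
            raise ConfigurationError(
                f"spaCy model {model!r} is not installed; run "
                f"`python -m spacy download {model}`"
            ) from exc
        self.name = f"spacy:{model}"

    def tag_text(self, text: str):
        doc = self._nlp(text)
        return [
            (sent.text,
             [(t.text, t.lemma_.lower(), t.pos_) for t in sent if not t.is_space])
            for sent in doc.sents
        ]


class StanzaBackend:
    """UD tagging through a pinned Stanza pipeline (lazy import)."""

    def __init__(self, model: str = "en") -> None:
        try:
            import stanza
        except ImportError as exc:
            raise ConfigurationError(
                "tagger backend 'stanza' requires the stanza package; "
                f"install stanza and `stanza.download({model!r})`"
            ) from exc
        self._nlp = stanza.Pipeline(model, processors="tokenize,pos,lemma")
        self.name = f"stanza:{model}"

    def tag_text(self, text: str):
        doc = self._nlp(text)
        return [
            (sent.text,
             [(w.text, (w.lemma or w.text).lower(), w.upos) for w in sent.words])
            for sent in doc.sentences
        ]


def get_backend(backend: str, model: str | Path | None = None) -> TaggerBackend:
    """Instantiate a tagger backend by config name.

    ``lexicon`` takes an optional TSV path as its model; ``spacy`` and
    ``stanza`` require their packages and a pinned model name.
    """
    if backend == "lexicon":
        lex = load_lexicon_tsv(model) if model else None
        return LexiconTagger(lex)
    if backend == "spacy":
        if not model:
            raise ConfigurationError(
                "tagger.model must name a pinned spaCy model (e.g. "
                "en_core_web_sm); results are tagger-dependent, so the model "
                "is never defaulted")
        return SpacyBackend(str(model))
    if backend == "stanza":
        return StanzaBackend(str(model) if model else "en")
    raise ConfigurationError(f"unknown tagger backend {backend!r}")
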