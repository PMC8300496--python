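"""Post-extraction concept cleanup.

Raw link tables need curation before network building: synonyms and closely
related concepts are pooled under one canonical name (e.g. every mention of
*reindeer population* or *reindeer grazing* → *reindeer*), nonsense concepts
that arise from word placement (*results*, from "our results show an
increase in ...") are dropped, and bare symbols such as ``%`` — frequent in
effect-size phrasing — are stripped. Cleanup is curated, not automatic, and
operates on the extracted link table so the provenance text is untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import ValidationError
from .extraction import CausalLink

logger = logging.getLogger(__name__)

MATCH_MODES = ("exact", "substring")


def _contains_phrase(text: str, phrase: str) -> bool:
    """Whole-word (token-boundary) containment: 'rein' never matches
    'reindeer', but 'reindeer' matches 'reindeer grazing'."""
    toks, sub = text.split(), phrase.split()
    n = len(sub)
    return any(toks[i:i + n] == sub for i in range(len(toks) - n + 1))


@dataclass(frozen=True)
class ConceptMap:
    """Synonym → canonical relabeling plus a drop-list.

    ``match_mode="exact"`` rewrites only exact concept texts;
    ``"substring"`` rewrites any concept containing a key as a whole-word
    phrase to that key's canonical value (the pooling used for *reindeer*).
    The map is one-step: applying it twice equals applying it once, which is
    validated eagerly at construction.
    """

    rename: Mapping[str, str] = field(default_factory=dict)
    drop: frozenset[str] = frozenset()
    match_mode: str = "exact"

    def __post_init__(self) -> None:
        if self.match_mode not in MATCH_MODES:
            raise ValidationError(
                f"match_mode must be one of {MATCH_MODES}, got {self.match_mode!r}")
        object.__setattr__(self, "drop", frozenset(self.drop))
        overlap = self.drop & set(self.rename)
        if overlap:
            raise ValidationError(
                f"concepts cannot be both renamed and dropped: {sorted(overlap)}")
        for key, value in self.rename.items():
            if not key or not value:
                raise ValidationError("empty rename key/value")
            if self.canonical(value) != value:
                raise ValidationError(
                    f"rename is not one-step: value {value!r} (for key "
                    f"{key!r}) would itself be rewritten to "
                    f"{self.canonical(value)!r}")

    def canonical(self, text: str) -> str:
        if self.match_mode == "exact":
            return self.rename.get(text, text)
        # longest key first so the most specific pooling rule wins
        for key in sorted(self.rename, key=lambda k: (-len(k.split()), k)):
            if _contains_phrase(text, key):
                return self.rename[key]
        return text


def apply_concept_map(links: Iterable[CausalLink],
                      cmap: ConceptMap) -> list[CausalLink]:
    """Rewrite driver/target texts per the map and remove links whose
    driver or target lands in the drop-list. Provenance fields untouched."""
    out = []
    for link in links:
        driver = cmap.canonical(link.driver)
        target = cmap.canonical(link.target)
        if driver in cmap.drop or target in cmap.drop:
            logger.debug("dropped (drop-list): %s sentence %d: %s -> %s",
                         link.doc_id, link.sentence_index, driver, target)
            continue
        if driver != link.driver or target != link.target:
            link = replace(link, driver=driver, target=target)
        out.append(link)
    return out


def strip_symbols(links: Iterable[CausalLink],
                  symbols: Iterable[str]) -> list[CausalLink]:
    """Remove links whose driver or target equals, or contains as a
    constituent token, a listed symbol (e.g. ``%``)."""
    symset = set(symbols)
    if not symset:
        return list(links)

    def hit(text: str) -> bool:
        return text in symset or any(tok in symset for tok in text.split())

    out = []
    for link in links:
        if hit(link.driver) or hit(link.target):
            logger.debug("dropped (symbol): %s sentence %d: %s -> %s",
                         link.doc_id, link.sentence_index,
                         link.driver, link.target)
            continue
        out.append(link)
    return out


def load_concept_map(path: str | Path, match_mode: str = "exact") -> ConceptMap:
    """Read a concept map from 2-column TSV ``from<TAB>to``; an empty ``to``
    means drop. Validated eagerly (cycles, overlaps) at load."""
    rename: dict[str, str] = {}
    drop: set[str] = set()
    for lineno, line in enumerate(Path(path).read_text("utf-8").splitlines(), 1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValidationError(f"{path}:{lineno}: expected from<TAB>to")
        src, dst = parts[0].strip().lower(), parts[1].strip().lower()
        if not src:
            raise ValidationError(f"{path}:{lineno}: empty source concept")
        if dst:
            rename[src] = dst
        else:
            drop.add(src)
    return ConceptMap(rename, frozenset(drop), match_mode)
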