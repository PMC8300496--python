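import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from causaltext.annotation import TaggedSentence, Token, lexicon_tag
from causaltext.errors import ValidationError
from causaltext.extraction import (DEFAULT_KEYWORDS, EffectLexicon,
                                   detect_voice, extract_corpus, extract_link,
                                   find_keyword, modifier_multiplier,
                                   nearest_concept)
from causaltext.corpus import Corpus, Document
from causaltext.annotation import LexiconTagger


def link_tuple(link):
    return (link.driver, link.keyword, link.target, link.weight, link.voice)


class TestFindKeyword:
    def test_first_occurrence_wins(self, tag_one, effect_lexicon):
        sent = tag_one("Grazing increases lichens and increases shrubs.")
        assert find_keyword(sent, effect_lexicon) == 1

    def test_no_keyword_returns_none(self, tag_one, effect_lexicon):
        assert find_keyword(tag_one("Lichens cover rocks."),
                            effect_lexicon) is None

    def test_matches_noun_tagged_keyword_by_lemma(self, tag_one,
                                                  effect_lexicon):
        sent = tag_one("Our results show an increase in productivity.")
        idx = find_keyword(sent, effect_lexicon)
        assert idx == 4
        assert sent.tokens[idx].upos == "NOUN"


class TestNearestConcept:
    def test_leftward_skips_non_nouns(self, tag_one):
        sent = tag_one("Our results show an increase in productivity.")
        concept = nearest_concept(sent, 4, "left")
        assert concept.text == "results"

    def test_rightward_skips_adpositions(self, tag_one):
        sent = tag_one("Our results show an increase in productivity.")
        assert nearest_concept(sent, 4, "right").text == "productivity"

    def test_two_noun_compound_extends_outward(self, tag_one):
        sent = tag_one("Grazing increases soil nitrogen.")
        assert nearest_concept(sent, 1, "right").text == "soil nitrogen"

    def test_sentence_boundary_yields_none(self, tag_one):
        sent = tag_one("Increases occur.")
        assert nearest_concept(sent, 0, "left") is None

    def test_three_nouns_keep_two_nearest_keyword(self, tag_one):
        sent = tag_one("Grazing increases soil nutrient concentration.")
        assert nearest_concept(sent, 1, "right").text == "soil nutrient"
        sent = tag_one("Soil nutrient concentrations are increased by grazing.")
        assert nearest_concept(sent, 4, "left").text == "nutrient concentrations"

    def test_adj_allowed_only_in_outer_slot(self, tag_one):
        lex = {"arctic": ("arctic", "ADJ")}
        sent = tag_one("Arctic vegetation increases soil carbon.", lex)
        assert nearest_concept(sent, 2, "left").text == "arctic vegetation"

    def test_strict_adjacency_mode_refuses_skip_scan(self, tag_one):
        sent = tag_one("Our results show an increase in productivity.")
        assert nearest_concept(sent, 4, "left", skip_scan=False) is None
        assert nearest_concept(sent, 4, "right", skip_scan=False) is None


class TestDetectVoice:
    def test_passive_rule_example(self, tag_one, effect_lexicon):
        sent = tag_one("Soil nutrients are increased by grazing.")
        assert detect_voice(sent, 3, effect_lexicon) == "passive"

    def test_active_rule_example(self, tag_one, effect_lexicon):
        sent = tag_one("Grazing increases soil nitrogen.")
        assert detect_voice(sent, 1, effect_lexicon) == "active"

    def test_aux_without_by_agent_is_not_passive(self, tag_one,
                                                 effect_lexicon):
        sent = tag_one("Nutrients are increased near camps.")
        assert detect_voice(sent, 2, effect_lexicon) == "active"

    def test_adverb_between_keyword_and_by_is_transparent(self, tag_one,
                                                          effect_lexicon):
        sent = tag_one("Lichens are often decreased significantly by grazing.")
        idx = find_keyword(sent, effect_lexicon)
        assert detect_voice(sent, idx, effect_lexicon) == "passive"


class TestModifierMultiplier:
    def test_known_adverb_scales(self, tag_one, effect_lexicon):
        sent = tag_one("Fire slightly increased shrubs.")
        assert modifier_multiplier(sent, 2, effect_lexicon) == 0.5

    def test_no_modifier_is_unity(self, tag_one, effect_lexicon):
        sent = tag_one("Fire increased shrubs.")
        assert modifier_multiplier(sent, 1, effect_lexicon) == 1.0

    def test_unknown_adverb_ignored(self, tag_one, effect_lexicon):
        sent = tag_one("Fire greatly increased shrubs.")
        assert modifier_multiplier(sent, 2, effect_lexicon) == 1.0


class TestExtractLink:
    def test_nominal_keyword_worked_example(self, tag_one, effect_lexicon):
        link = extract_link(tag_one("Our results show an increase in "
                                    "productivity."), effect_lexicon)
        assert link_tuple(link) == ("results", "increase", "productivity",
                                    1.0, "active")

    def test_passive_roles_swap(self, tag_one, effect_lexicon):
        link = extract_link(
            tag_one("Soil nutrient concentrations are increased by grazing."),
            effect_lexicon)
        assert link.driver == "grazing"
        assert link.target == "nutrient concentrations"
        assert link.voice == "passive"
        assert link.weight == 1.0

    def test_no_right_concept_yields_none(self, tag_one, effect_lexicon):
        assert extract_link(tag_one("Temperatures increased."),
                            effect_lexicon) is None

    def test_passive_without_agent_yields_no_link(self, tag_one,
                                                  effect_lexicon):
        assert extract_link(tag_one("Nutrients are increased near camps."),
                            effect_lexicon) is None

    def test_modifier_weight_composes_with_sign(self, tag_one):
        lex = EffectLexicon(modifier_weights={"slightly": 0.5})
        link = extract_link(tag_one("Warming slightly decreased lichens."),
                            lex)
        assert link.weight == -0.5

    def test_mistagged_head_breaks_extraction(self, tag_one, effect_lexicon):
        # a lone ADJ-mistagged driver has no NOUN head, so no link
        link = extract_link(
            tag_one("Herbivory increased biomass.",
                    {"herbivory": ("herbivory", "ADJ")}), effect_lexicon)
        assert link is None

    @pytest.mark.parametrize("keyword,sign", [
        ("increases", 1.0), ("promotes", 1.0),
        ("decreases", -1.0), ("declines", -1.0)])
    def test_default_lexicon_signs(self, tag_one, effect_lexicon,
                                   keyword, sign):
        link = extract_link(tag_one(f"Grazing {keyword} shrub biomass."),
                            effect_lexicon)
        assert link.weight == sign


class TestExtractCorpus:
    def test_empty_corpus_yields_no_links(self, tagger, effect_lexicon):
        assert extract_corpus(Corpus(), effect_lexicon, tagger) == []

    def test_one_link_per_sentence_with_provenance(self, tagger,
                                                   effect_lexicon):
        corpus = Corpus((Document(
            "d1", "Grazing increases lichens. Fire decreases shrubs."),))
        links = extract_corpus(corpus, effect_lexicon, tagger)
        assert [(l.doc_id, l.sentence_index) for l in links] == [
            ("d1", 0), ("d1", 1)]
        assert links[1].sentence_text == "Fire decreases shrubs."

    def test_repeated_keyword_still_single_link(self, tagger, effect_lexicon):
        corpus = Corpus((Document(
            "d1", "Grazing increases lichens and increases shrubs."),))
        links = extract_corpus(corpus, effect_lexicon, tagger)
        assert len(links) == 1
        assert links[0].target == "lichens"


class TestLexiconValidation:
    def test_zero_base_weight_rejected(self):
        with pytest.raises(ValidationError):
            EffectLexicon({"increase": 0.0})

    def test_negative_multiplier_rejected(self):
        with pytest.raises(ValidationError):
            EffectLexicon(modifier_weights={"slightly": -0.5})


# ---------------------------------------------------------------------------
# Properties
# ---------------------------------------------------------------------------

PHRASES = ["grazing", "reindeer", "soil nitrogen", "shrub biomass",
           "lichens", "root density"]


def participle(kw):
    return kw + "d" if kw.endswith("e") else kw + "ed"


@settings(deadline=None, derandomize=True)
@given(driver=st.sampled_from(PHRASES), target=st.sampled_from(PHRASES),
       keyword=st.sampled_from(sorted(DEFAULT_KEYWORDS)),
       modified=st.booleans())
def test_voice_equivalence_on_mechanical_transforms(driver, target, keyword,
                                                    modified):
    """An active sentence and its mechanical passive yield the same
    (driver, target, keyword, weight)."""
    lex = EffectLexicon(modifier_weights={"slightly": 0.5})
    adv = "slightly " if modified else ""
    active = f"{driver} {adv}{keyword}s {target}.".capitalize()
    passive = f"{target} are {adv}{participle(keyword)} by {driver}.".capitalize()
    a = extract_link(lexicon_tag(active)[0], lex)
    p = extract_link(lexicon_tag(passive)[0], lex)
    assert a is not None and p is not None
    assert (a.driver, a.target, a.keyword, a.weight) == \
           (p.driver, p.target, p.keyword, p.weight)
    assert (a.voice, p.voice) == ("active", "passive")


@settings(deadline=None, derandomize=True, max_examples=200)
@given(st.text(alphabet="abcdefgh .", max_size=80), st.integers(0, 2 ** 31))
def test_at_most_one_link_and_sign_preserved(text, salt):
    """Any sentence yields 0 or 1 links, and the link sign matches the
    keyword's base weight sign."""
    rng = random.Random(salt)
    words = text.split()
    if words and rng.random() < 0.7:
        words.insert(rng.randrange(len(words) + 1),
                     rng.choice(["increases", "declines", "promotes"]))
    lex = EffectLexicon(modifier_weights={"slightly": 0.5})
    sentences = lexicon_tag(" ".join(words))
    for sent in sentences:
        link = extract_link(sent, lex)
        if link is not None:
            base = lex.keyword_weights[link.keyword]
            assert (link.weight > 0) == (base > 0)


# ---------------------------------------------------------------------------
# Brute-force concept-window oracle
# ---------------------------------------------------------------------------

def brute_force_window(tokens, from_index, direction):
    """Enumerate all contiguous 1-2 token windows on the given side whose
    keyword-nearest constituent (the head) is NOUN and whose other
    constituent, if any, is NOUN or ADJ; pick the window with the head
    closest to from_index, preferring the longer window on ties."""
    n = len(tokens)
    candidates = []
    for i in range(n):
        for j in (i, i + 1):
            if j >= n:
                continue
            window = tokens[i:j + 1]
            if direction == "left":
                if j >= from_index:
                    continue
                head, outer = window[-1], window[0]
            else:
                if i <= from_index:
                    continue
                head, outer = window[0], window[-1]
            if head.upos != "NOUN":
                continue
            if len(window) == 2 and outer.upos not in ("NOUN", "ADJ"):
                continue
            candidates.append((abs(head.index - from_index), -len(window),
                               tuple(t.lemma for t in window)))
    if not candidates:
        return None
    return min(candidates)[2]


def random_sentence(rng):
    tags = ["NOUN", "ADJ", "VERB", "DET", "ADP", "ADV", "AUX", "PUNCT"]
    n = rng.randint(1, 12)
    tokens = tuple(
        Token(i, f"w{i}", f"w{i}", rng.choice(tags)) for i in range(n))
    return TaggedSentence("d", 0, tokens, " ".join(t.surface for t in tokens))


def test_nearest_concept_matches_brute_force_enumeration():
    rng = random.Random(20260929)
    checked = 0
    for _ in range(10_000):
        sent = random_sentence(rng)
        from_index = rng.randrange(len(sent.tokens))
        for direction in ("left", "right"):
            expected = brute_force_window(sent.tokens, from_index, direction)
            got = nearest_concept(sent, from_index, direction)
            got_lemmas = tuple(t.lemma for t in got.tokens) if got else None
            assert got_lemmas == expected, (sent.tokens, from_index, direction)
            checked += 1
    assert checked == 20_000
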