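# causaltext

Extract signed causal links from unstructured scientific text — abstracts,
full texts, grey literature — and assemble them into a directed interaction
network for evidence synthesis and data-driven hypothesis building.

Reading thousands of abstracts to map which ecosystem drivers are reported
to affect which components is slow and exhausting. `causaltext` automates
the first pass: it finds user-declared *effect keywords* (by default
*increase*, *promote* → +1; *decrease*, *decline* → −1) in POS-tagged
sentences and reads the noun-phrase components on either side with two
grammatical rules:

* **active voice** — `A increases B` → driver A, target B;
* **passive voice** — `B is increased by A` → driver A, target B.

Components are 1–2-token noun compounds ("soil carbon"); scanning outward
from the keyword skips non-nouns, and the compound's outer slot also admits
an adjective to absorb tagger mis-labels. Only the first keyword per
sentence is extracted. An adverbial modifier table scales the weight
(*slightly increase* → +0.5). After a curated cleanup (synonym pooling,
drop-lists, symbol stripping), repeated links between the same directed
concept pair are pooled by **averaging** their signed weights — opposing
reports cancel toward zero — while an evidence count is retained. The
result is a signed directed network; ego subnetworks around a focal concept
(all components affecting and affected by it, within *k* steps) support
stepwise hypothesis building.

Every link carries provenance (document id, sentence index, sentence text),
so curators can always audit the source sentence.

## Worked example

```python
from causaltext import EffectLexicon, extract_link, lexicon_tag

lex = EffectLexicon(modifier_weights={"slightly": 0.5})
for text in [
    "Reindeer grazing decreased lichen cover.",
    "Soil nutrient concentrations are increased by grazing.",
    "Our results show an increase in productivity.",
    "Fire slightly increased shrub biomass.",
]:
    link = extract_link(lexicon_tag(text)[0], lex)
    print(f"{link.driver!r} -[{link.keyword} {link.weight:+g}]-> "
          f"{link.target!r} ({link.voice})")
```

prints

```
'reindeer grazing' -[decrease -1]-> 'lichen cover' (active)
'grazing' -[increase +1]-> 'nutrient concentrations' (passive)
'results' -[increase +1]-> 'productivity' (active)
'fire' -[increase +0.5]-> 'shrub biomass' (active)
```

The first two lines show the active/passive role assignment and the
two-token compounds; the third is the classic nonsense link that word
placement produces ("results" would go on a curator's drop-list); the
fourth shows adverbial down-weighting. From the shell, the same machinery
runs end to end against a seeded synthetic corpus with planted gold tuples:

```sh
causaltext synth --n-docs 50 --seed 7 --out corpus.csv \
    --gold gold.csv --lexicon lex.tsv
causaltext extract --input corpus.csv --format csv --model lex.tsv \
    --modifier slightly=0.5 --out links.csv
causaltext score --links links.csv --gold gold.csv
causaltext network --links links.csv --edges-out edges.csv \
    --graph-out ego.graphml --focal reindeer --depth 1
```

```
50 docs, 168 gold links
168 links -> links.csv
precision: 1.0000
recall: 1.0000
10 nodes, 9 edges
```

Extraction recovers every planted (driver, keyword, target, weight, voice)
tuple exactly; the final command exports the ego network around *reindeer*
(the focal node plus everything it affects or is affected by) as GraphML.
`causaltext run --config cfg.yaml` drives the whole workflow from one
declarative file and writes a run manifest beside the outputs.

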