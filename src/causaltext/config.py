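"""Declarative pipeline configuration (YAML).

One config file drives the whole workflow so a run is reproducible from a
single artifact; every CLI flag mirrors a config key. Referenced input
paths are checked at validation time, and the tagger model must be named
explicitly for non-lexicon backends.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigurationError
from .extraction import EffectLexicon, effect_lexicon_from_config

INPUT_FORMATS = ("plaintext", "plaintext-lines", "csv", "tsv", "ris")


@dataclass
class PipelineConfig:
    input_path: Path
    input_format: str = "csv"
    id_col: str = "doc_id"
    text_col: str = "text"
    tagger_backend: str = "lexicon"
    tagger_model: str | None = None
    lexicon: EffectLexicon = field(default_factory=EffectLexicon)
    concept_map_path: Path | None = None
    match_mode: str = "exact"
    symbols: tuple[str, ...] = ()
    focal: str | None = None
    depth: int = 1
    reachability: str = "both"
    skip_scan: bool = True
    links_out: Path = Path("links.csv")
    edges_out: Path = Path("edges.csv")
    graph_out: Path | None = None
    graph_format: str = "graphml"
    log_level: str = "INFO"
    raw: Mapping[str, Any] = field(default_factory=dict, repr=False)

    def validate(self) -> None:
        if self.input_format not in INPUT_FORMATS:
            raise ConfigurationError(
                f"input.format must be one of {INPUT_FORMATS}, "
                f"got {self.input_format!r}")
        if not Path(self.input_path).exists():
            raise ConfigurationError(
                f"input path does not exist: {self.input_path}")
        if self.concept_map_path and not Path(self.concept_map_path).exists():
            raise ConfigurationError(
                f"concept map does not exist: {self.concept_map_path}")
        if not self.lexicon.keyword_weights:
            raise ConfigurationError("effect lexicon must be non-empty")

    def digest(self) -> str:
        """Stable hash of the configuration, for the run manifest."""
        payload = {
            "input": [str(self.input_path), self.input_format,
                      self.id_col, self.text_col],
            "tagger": [self.tagger_backend, self.tagger_model],
            "keywords": dict(self.lexicon.keyword_weights),
            "modifiers": dict(self.lexicon.modifier_weights),
            "harmonization": [str(self.concept_map_path),
                              self.match_mode, list(self.symbols)],
            "network": [self.focal, self.depth, self.reachability],
            "skip_scan": self.skip_scan,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a pipeline config from YAML."""
    raw = yaml.safe_load(Path(path).read_text("utf-8")) or {}
    inp = raw.get("input") or {}
    tagger = raw.get("tagger") or {}
    harm = raw.get("harmonization") or {}
    net = raw.get("network") or {}
    outputs = raw.get("outputs") or {}
    if "path" not in inp:
        raise ConfigurationError("config needs input.path")
    cfg = PipelineConfig(
        input_path=Path(inp["path"]),
        input_format=inp.get("format", "csv"),
        id_col=inp.get("id_col", "doc_id"),
        text_col=inp.get("text_col", "text"),
        tagger_backend=tagger.get("backend", "lexicon"),
        tagger_model=tagger.get("model"),
        lexicon=effect_lexicon_from_config(raw.get("lexicon") or {}),
        concept_map_path=(Path(harm["map"]) if harm.get("map") else None),
        match_mode=harm.get("match_mode", "exact"),
        symbols=tuple(harm.get("symbols") or ()),
        focal=net.get("focal"),
        depth=int(net.get("depth", 1)),
        reachability=net.get("reachability", "both"),
        skip_scan=bool(raw.get("skip_scan", True)),
        links_out=Path(outputs.get("links", "links.csv")),
        edges_out=Path(outputs.get("edges", "edges.csv")),
        graph_out=(Path(outputs["graph"]) if outputs.get("graph") else None),
        graph_format=outputs.get("graph_format", "graphml"),
        log_level=raw.get("log_level", "INFO"),
        raw=raw,
    )
    cfg.validate()
    return cfg
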