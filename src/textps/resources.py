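"""Bundled default resources: ATC class map, drug-name lexicon, stop words."""

from __future__ import annotations

from importlib import resources

import yaml


def default_atc_class_map() -> dict[str, list[str]]:
    """ATC code lists for the two NSAID exposure classes (COX2 / NSNSAID)."""
    text = resources.files("textps.data").joinpath("atc_classes.yaml").read_text()
    return yaml.safe_load(text)


def default_lexicon() -> set[str]:
    """Lowercase NSAID drug names used to detect free-text drug mentions."""
    text = resources.files("textps.data").joinpath("nsaid_lexicon.txt").read_text()
    return {line.strip().lower() for line in text.splitlines() if line.strip()}


def default_stop_words() -> set[str]:
    """Default Dutch stop-word list (articles, common function words)."""
    text = resources.files("textps.data").joinpath("stopwords_nl.txt").read_text()
    return {line.strip().lower() for line in text.splitlines() if line.strip()}
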