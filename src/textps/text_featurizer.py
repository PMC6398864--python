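"""Note-text normalization and episode-level bag-of-words feature matrices.

Normalization: lowercase, strip special characters (anything that is not a
letter, digit or whitespace), tokenize on whitespace, drop stop words and any
token that does not start with a letter or digit. Features are unigram
presence (binary) per episode over a fixed lookback window before episode
start; a count mode is retained behind a flag.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.io
import scipy.sparse as sp
import yaml

__all__ = ["FeatureMatrix", "normalize_text", "build_bow", "notes_from_records"]

# Strip everything that is not a word character or whitespace; underscores are
# not letters/digits so they go too.
_SPECIALS = re.compile(r"[^\w\s]|_", re.UNICODE)


def normalize_text(raw: str, stop_words: set[str] | frozenset[str] = frozenset()) -> list[str]:
    """Normalize free text to a clean token list, preserving order."""
    cleaned = _SPECIALS.sub(" ", raw.lower())
    return [
        tok
        for tok in cleaned.split()
        if tok not in stop_words and tok[0].isalnum()
    ]


@dataclass
class FeatureMatrix:
    """Sparse episode x covariate matrix with aligned label vectors."""

    episode_ids: list[str]
    covariate_labels: list[str]
    values: sp.csr_matrix
    lookback_days: int
    binary: bool = True

    def __post_init__(self) -> None:
        if len(set(self.covariate_labels)) != len(self.covariate_labels):
            raise ValueError("duplicate covariate labels")
        if self.values.shape != (len(self.episode_ids), len(self.covariate_labels)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.episode_ids)} episodes x {len(self.covariate_labels)} labels"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def document_frequency(self) -> np.ndarray:
        """Number of episodes in which each covariate is present."""
        return np.asarray((self.values != 0).sum(axis=0)).ravel()

    def select(self, labels: Sequence[str]) -> "FeatureMatrix":
        """Column-subset in the given label order; unknown labels are an error."""
        index = {lab: j for j, lab in enumerate(self.covariate_labels)}
        try:
            cols = [index[lab] for lab in labels]
        except KeyError as exc:
            raise KeyError(f"unknown covariate label {exc.args[0]!r}") from exc
        return FeatureMatrix(
            self.episode_ids,
            list(labels),
            self.values[:, cols].tocsr(),
            self.lookback_days,
            self.binary,
        )

    def hstack(self, other: "FeatureMatrix") -> "FeatureMatrix":
        if other.episode_ids != self.episode_ids:
            raise ValueError("episode ids differ")
        return FeatureMatrix(
            self.episode_ids,
            self.covariate_labels + other.covariate_labels,
            sp.hstack([self.values, other.values]).tocsr(),
            self.lookback_days,
            self.binary and other.binary,
        )

    # -- persistence (MatrixMarket + sidecar label files) --------------------

    def save(self, directory: str | Path, stem: str = "features") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(directory / f"{stem}.mtx"), self.values.tocoo())
        (directory / f"{stem}.episode_ids.txt").write_text(
            "".join(e + "\n" for e in self.episode_ids)
        )
        (directory / f"{stem}.labels.txt").write_text(
            "".join(lab + "\n" for lab in self.covariate_labels)
        )
        with open(directory / f"{stem}.meta.yaml", "w") as fh:
            yaml.safe_dump({"lookback_days": self.lookback_days, "binary": self.binary}, fh)

    @classmethod
    def load(cls, directory: str | Path, stem: str = "features") -> "FeatureMatrix":
        directory = Path(directory)
        values = sp.csr_matrix(scipy.io.mmread(str(directory / f"{stem}.mtx")))
        episode_ids = (directory / f"{stem}.episode_ids.txt").read_text().splitlines()
        labels = (directory / f"{stem}.labels.txt").read_text().splitlines()
        with open(directory / f"{stem}.meta.yaml") as fh:
            meta = yaml.safe_load(fh)
        return cls(episode_ids, labels, values, int(meta["lookback_days"]), bool(meta["binary"]))


def notes_from_records(records: Iterable) -> dict[str, list[tuple[date, str]]]:
    """Collect ``patient_id -> [(date, text), ...]`` from patient records."""
    return {r.patient_id: [(n.date, n.text) for n in r.notes] for r in records}


def build_bow(
    episodes: Sequence,
    notes_by_patient: Mapping[str, Sequence[tuple[date, str]]],
    stop_words: set[str] | frozenset[str] = frozenset(),
    lookback_days: int = 183,
    binary: bool = True,
) -> FeatureMatrix:
    """Bag-of-words matrix over each episode's lookback window.

    For each episode, tokens are pooled from every note of that patient dated
    in the half-open window ``[start - lookback_days, start)``. Covariates that
    occur in zero episodes are dropped (the vocabulary is built from in-window
    tokens only); episodes with no in-window notes keep an all-zero row.
    """
    counts_per_episode: list[Counter] = []
    for ep in episodes:
        window_start = ep.start_date - timedelta(days=lookback_days)
        counter: Counter = Counter()
        for note_date, text in notes_by_patient.get(ep.patient_id, ()):
            if window_start <= note_date < ep.start_date:
                counter.update(normalize_text(text, stop_words))
        counts_per_episode.append(counter)

    vocab = sorted({tok for c in counts_per_episode for tok in c})
    col_of = {tok: j for j, tok in enumerate(vocab)}
    rows, cols, data = [], [], []
    for i, counter in enumerate(counts_per_episode):
        for tok, n in counter.items():
            rows.append(i)
            cols.append(col_of[tok])
            data.append(1 if binary else n)
    values = sp.csr_matrix(
        (data, (rows, cols)),
        shape=(len(counts_per_episode), len(vocab)),
        dtype=np.float64,
    )
    return FeatureMatrix(
        [ep.episode_id for ep in episodes], vocab, values, lookback_days, binary
    )
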