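"""Covariate selection for the propensity model.

Three methods:

1. FREQUENCY — keep covariates whose document frequency in the cohort is at or
   above a threshold, with no further selection.
2. CHISQ — keep covariates whose 2x2 presence-by-outcome Pearson chi-square
   test (df = 1, no continuity correction) gives p < alpha.
3. ESTABLISHED — ignore the text and build indicators for the established
   confounders only: one indicator per observed integer age in years, a sex
   indicator, and a low-dose-aspirin indicator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import yaml
from scipy.stats import chi2

from .text_featurizer import FeatureMatrix

__all__ = [
    "SelectionResult",
    "filter_by_frequency",
    "chisq_statistic",
    "filter_by_association",
    "established_confounders",
]


@dataclass
class SelectionResult:
    method: str  # FREQUENCY | CHISQ | ESTABLISHED
    threshold_or_alpha: float
    selected_labels: list[str]

    @property
    def n_selected(self) -> int:
        return len(self.selected_labels)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "method": self.method,
                    "threshold_or_alpha": float(self.threshold_or_alpha),
                    "n_selected": self.n_selected,
                    "selected_labels": list(self.selected_labels),
                },
                fh,
                sort_keys=False,
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SelectionResult":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(d["method"], float(d["threshold_or_alpha"]), list(d["selected_labels"]))


def filter_by_frequency(matrix: FeatureMatrix, threshold: int) -> SelectionResult:
    """Keep covariates with document frequency >= threshold (inclusive)."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    df = matrix.document_frequency()
    labels = [lab for lab, f in zip(matrix.covariate_labels, df) if f >= threshold]
    return SelectionResult("FREQUENCY", float(threshold), labels)


def chisq_statistic(table) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, df = 1, no continuity correction.

    Returns ``(statistic, p)`` where p is the upper tail of the chi-square(1)
    distribution. Raises ``ValueError`` for a zero row or column margin.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (obs < 0).any():
        raise ValueError("counts must be nonnegative")
    total = obs.sum()
    if total <= 0:
        raise ValueError("grand total must be > 0")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero margin: statistic undefined")
    expected = np.outer(row, col) / total
    stat = float(((obs - expected) ** 2 / expected).sum())
    return stat, float(chi2.sf(stat, df=1))


def filter_by_association(
    matrix: FeatureMatrix, outcome_flags: Sequence[bool], alpha: float = 0.05
) -> SelectionResult:
    """Keep covariates whose presence-by-outcome chi-square gives p < alpha.

    Covariates with a degenerate 2x2 table (zero margin: constant presence or
    constant outcome) are skipped. Vectorized over columns.
    """
    y = np.asarray(outcome_flags, dtype=bool)
    n = matrix.shape[0]
    if y.shape[0] != n:
        raise ValueError("outcome_flags not aligned to matrix rows")
    present = (matrix.values != 0).astype(np.float64)
    df_col = np.asarray(present.sum(axis=0)).ravel()            # present margin
    a = np.asarray(present[y.nonzero()[0], :].sum(axis=0)).ravel()  # present & event
    n_event = float(y.sum())

    b = df_col - a               # present, no event
    c = n_event - a              # absent, event
    d = n - df_col - c           # absent, no event

    valid = (df_col > 0) & (df_col < n)
    if n_event == 0 or n_event == n:
        valid &= False
    with np.errstate(divide="ignore", invalid="ignore"):
        e_a = df_col * n_event / n
        e_b = df_col * (n - n_event) / n
        e_c = (n - df_col) * n_event / n
        e_d = (n - df_col) * (n - n_event) / n
        stat = (
            (a - e_a) ** 2 / e_a
            + (b - e_b) ** 2 / e_b
            + (c - e_c) ** 2 / e_c
            + (d - e_d) ** 2 / e_d
        )
    p = chi2.sf(stat, df=1)
    keep = valid & (p < alpha)
    labels = [lab for lab, k in zip(matrix.covariate_labels, keep) if k]
    return SelectionResult("CHISQ", float(alpha), labels)


def established_confounders(episodes: Sequence) -> FeatureMatrix:
    """Indicator matrix for the established confounders.

    One column per observed integer age in years (``age=<y>``), a ``sex=F``
    indicator and an ``aspirin`` indicator; zero-variance columns are dropped.
    """
    ages = np.array([e.age_at_start for e in episodes], dtype=int)
    sex_f = np.array([e.sex == "F" for e in episodes], dtype=float)
    aspirin = np.array([bool(e.aspirin_exposed) for e in episodes], dtype=float)

    columns: list[tuple[str, np.ndarray]] = [
        (f"age={age}", (ages == age).astype(float)) for age in sorted(set(ages))
    ]
    if 0.0 < sex_f.mean() < 1.0:
        columns.append(("sex=F", sex_f))
    if 0.0 < aspirin.mean() < 1.0:
        columns.append(("aspirin", aspirin))

    labels = [lab for lab, _ in columns]
    if columns:
        values = sp.csr_matrix(np.column_stack([col for _, col in columns]))
    else:
        values = sp.csr_matrix((len(ages), 0))
    return FeatureMatrix(
        [e.episode_id for e in episodes], labels, values, lookback_days=0, binary=True
    )
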