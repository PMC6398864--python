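"""Hazard-ratio estimation for COX-2 vs nsNSAID episodes.

Designs: crude (unmatched), age-matched (tolerance +/- 2 years), and
PS-matched (one per propensity model), each optionally adjusted for subsets of
{age, sex, aspirin}. The matched analyses fit an unstratified Cox
proportional-hazards model on the matched sample (Efron tie handling, Wald
95% CIs); time axis is days since episode start, events are censored at the
episode end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from .cohort_builder import TreatmentEpisode
from .ps_matcher import MatchedCohort, greedy_match

__all__ = [
    "HazardEstimate",
    "match_on_age",
    "fit_cox",
    "run_analysis_suite",
    "results_to_frame",
]

logger = logging.getLogger(__name__)

ADJUSTMENT_COVARIATES = ("age", "sex", "aspirin")

# Table-shaped default grid: rows of (design, adjustment sets)
DEFAULT_PS_ADJUSTMENTS: tuple[frozenset, ...] = (
    frozenset(),
    frozenset({"age"}),
    frozenset({"sex"}),
    frozenset({"age", "sex"}),
    frozenset({"sex", "aspirin"}),
    frozenset({"age", "sex", "aspirin"}),
)
DEFAULT_AGE_ADJUSTMENTS: tuple[frozenset, ...] = (
    frozenset(),
    frozenset({"sex"}),
    frozenset({"sex", "aspirin"}),
)


@dataclass
class HazardEstimate:
    design: str  # CRUDE | AGE_MATCHED | PS_FREQ | PS_CHISQ | ...
    adjustment_set: frozenset
    hr: float
    ci_low: float
    ci_high: float
    n_treated: int
    n_control: int
    n_events: int
    error: str | None = None


def match_on_age(
    treated: Sequence[TreatmentEpisode],
    controls: Sequence[TreatmentEpisode],
    tolerance_years: float = 2.0,
) -> MatchedCohort:
    """Greedy one-to-many matching on age with |delta age| <= tolerance."""
    return greedy_match(
        [(e.episode_id, float(e.age_at_start)) for e in treated],
        [(e.episode_id, float(e.age_at_start)) for e in controls],
        caliper=float(tolerance_years),
    )


def _episodes_frame(episodes: Iterable[TreatmentEpisode]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "episode_id": [e.episode_id for e in episodes],
            "treatment": [1 if e.class_label == "COX2" else 0 for e in episodes],
            "duration": [e.follow_up_days for e in episodes],
            "event": [int(e.event) for e in episodes],
            "age": [float(e.age_at_start) for e in episodes],
            "sex": [1.0 if e.sex == "F" else 0.0 for e in episodes],
            "aspirin": [1.0 if e.aspirin_exposed else 0.0 for e in episodes],
        }
    )


def fit_cox(
    episodes: Sequence[TreatmentEpisode],
    adjustment_set: Iterable[str] = (),
    design: str = "CRUDE",
) -> HazardEstimate:
    """Cox PH hazard ratio of COX-2 vs nsNSAID with optional adjustment.

    Time axis is days since episode start; events are outcomes within the
    episode, censoring at episode end. Adjustment covariates: continuous age,
    sex indicator, aspirin indicator. Zero-variance adjustment covariates are
    dropped with a log message (common in small matched subsets).
    """
    adjustment = frozenset(adjustment_set)
    unknown = adjustment - set(ADJUSTMENT_COVARIATES)
    if unknown:
        raise ValueError(f"unknown adjustment covariates: {sorted(unknown)}")
    df = _episodes_frame(episodes)
    if len(df) == 0:
        raise ValueError("no episodes")
    if (df["duration"] <= 0).any():
        raise ValueError("all episodes must have follow_up_days > 0")
    if df["event"].sum() == 0:
        raise ValueError("at least one event required")
    if df["treatment"].nunique() < 2:
        raise ValueError("both treatment classes required")

    cols = ["duration", "event", "treatment"]
    for cov in ADJUSTMENT_COVARIATES:
        if cov in adjustment:
            if df[cov].nunique() < 2:
                logger.info("dropping zero-variance adjustment covariate %r", cov)
            else:
                cols.append(cov)

    cph = CoxPHFitter()
    cph.fit(df[cols], duration_col="duration", event_col="event")
    summary = cph.summary.loc["treatment"]
    return HazardEstimate(
        design=design,
        adjustment_set=adjustment,
        hr=float(summary["exp(coef)"]),
        ci_low=float(summary["exp(coef) lower 95%"]),
        ci_high=float(summary["exp(coef) upper 95%"]),
        n_treated=int(df["treatment"].sum()),
        n_control=int((1 - df["treatment"]).sum()),
        n_events=int(df["event"].sum()),
    )


def _matched_subset(
    episodes: Sequence[TreatmentEpisode], cohort: MatchedCohort
) -> list[TreatmentEpisode]:
    keep = set(cohort.matched_treated) | set(cohort.matched_controls)
    return [e for e in episodes if e.episode_id in keep]


def run_analysis_suite(
    episodes: Sequence[TreatmentEpisode],
    ps_by_model: Mapping[str, Sequence[float]] | None = None,
    caliper: float = 0.01,
    age_tolerance: float = 2.0,
    ps_adjustments: Sequence[frozenset] = DEFAULT_PS_ADJUSTMENTS,
    age_adjustments: Sequence[frozenset] = DEFAULT_AGE_ADJUSTMENTS,
) -> list[HazardEstimate]:
    """Full analysis grid: crude, age-matched, and one PS-matched block per
    propensity model (scores aligned to ``episodes``).

    A failing cell is recorded with its error message and the suite continues.
    """
    ps_by_model = ps_by_model or {}
    results: list[HazardEstimate] = []

    def run_cell(design: str, subset, adjustment: frozenset) -> None:
        try:
            results.append(fit_cox(subset, adjustment, design=design))
        except Exception as exc:  # noqa: BLE001 - cell failures are data, not bugs
            logger.warning("cell %s / %s failed: %s", design, sorted(adjustment), exc)
            results.append(
                HazardEstimate(
                    design,
                    adjustment,
                    float("nan"),
                    float("nan"),
                    float("nan"),
                    n_treated=0,
                    n_control=0,
                    n_events=0,
                    error=str(exc),
                )
            )

    run_cell("CRUDE", episodes, frozenset())

    treated = [e for e in episodes if e.class_label == "COX2"]
    controls = [e for e in episodes if e.class_label != "COX2"]

    age_cohort = match_on_age(treated, controls, age_tolerance)
    age_subset = _matched_subset(episodes, age_cohort)
    for adjustment in age_adjustments:
        run_cell("AGE_MATCHED", age_subset, adjustment)

    for name, scores in ps_by_model.items():
        scores = np.asarray(scores, dtype=float)
        if scores.shape[0] != len(episodes):
            raise ValueError(f"scores for {name!r} not aligned to episodes")
        by_id = dict(zip((e.episode_id for e in episodes), scores))
        cohort = greedy_match(
            [(e.episode_id, by_id[e.episode_id]) for e in treated],
            [(e.episode_id, by_id[e.episode_id]) for e in controls],
            caliper=caliper,
        )
        subset = _matched_subset(episodes, cohort)
        for adjustment in ps_adjustments:
            run_cell(name, subset, adjustment)

    return results


def results_to_frame(results: Sequence[HazardEstimate]) -> pd.DataFrame:
    """Results table mirroring the matching x adjustment grid."""
    return pd.DataFrame(
        {
            "matching": [r.design for r in results],
            "adjustment": ["+".join(sorted(r.adjustment_set)) or "none" for r in results],
            "hazard_ratio": [r.hr for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "n_treated": [r.n_treated for r in results],
            "n_control": [r.n_control for r in results],
            "n_events": [r.n_events for r in results],
            "error": [r.error or "" for r in results],
        }
    )
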