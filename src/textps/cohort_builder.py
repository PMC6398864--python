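"""New-user NSAID treatment-episode construction.

Rules, applied per patient on date-sorted prescriptions:

* eligibility at episode start: age >= 18; >= 365 days enrolled before start;
  >= 183 days of data before start (enforced independently); no NSAID
  prescription of either class and no free-text drug-name mention in the
  half-open washout window ``[start - 183 d, start)``;
* duration of a prescription = quantity / daily dose, rounded half up to whole
  days, clamped to >= 1;
* consecutive same-class prescriptions chain into one episode when the next
  starts within 30 days of the running end of the chain; the episode ends at
  the end of the last chained prescription;
* an opposite-class prescription ends the episode at the switch date (or at the
  natural chain end if the switch falls in the 30-day grace after it);
* same-day first prescriptions of both classes are ambiguous: no episode is
  created at that date (logged), although the prescriptions still count as
  exposure for later washout checks;
* the first outcome event inside the closed episode interval is attached;
  follow-up is censored at the episode end.

Episodes are the analytic unit; a patient may contribute several episodes and
both classes across episodes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .text_featurizer import normalize_text

__all__ = [
    "TreatmentEpisode",
    "prescription_duration",
    "detect_drug_mentions",
    "build_episodes",
    "episodes_to_frame",
    "episodes_from_frame",
    "MIN_AGE_YEARS",
    "MIN_ENROLLMENT_DAYS",
    "MIN_HISTORY_DAYS",
    "WASHOUT_DAYS",
    "GRACE_DAYS",
]

logger = logging.getLogger(__name__)

MIN_AGE_YEARS = 18
MIN_ENROLLMENT_DAYS = 365   # "enrolled for at least one year"
MIN_HISTORY_DAYS = 183      # "at least six months of data available"
WASHOUT_DAYS = 183          # six-month drug-free / mention-free window
GRACE_DAYS = 30             # refill grace period for chaining


@dataclass
class TreatmentEpisode:
    episode_id: str
    patient_id: str
    class_label: str  # "COX2" or "NSNSAID"
    start_date: date
    end_date: date
    age_at_start: int
    sex: str
    aspirin_exposed: bool
    outcome_date: date | None
    event: bool
    follow_up_days: int


def prescription_duration(quantity: float, daily_dose: float) -> int:
    """Days covered by a prescription: quantity / daily dose, rounded half up,
    clamped to at least one day."""
    if quantity <= 0 or daily_dose <= 0:
        raise ValueError(
            f"quantity and daily_dose must be positive, got {quantity}, {daily_dose}"
        )
    days = math.floor(quantity / daily_dose + 0.5)
    return max(1, days)


def detect_drug_mentions(
    notes: Iterable[tuple[date, str]],
    lexicon: set[str] | frozenset[str],
    window_start: date,
    window_end: date,
) -> bool:
    """True iff any normalized note token in ``[window_start, window_end)``
    equals a lexicon entry."""
    for note_date, text in notes:
        if window_start <= note_date < window_end:
            if any(tok in lexicon for tok in normalize_text(text)):
                return True
    return False


def _mention_dates(
    notes: Sequence[tuple[date, str]], lexicon: set[str] | frozenset[str]
) -> list[date]:
    return [
        d for d, text in notes if any(tok in lexicon for tok in normalize_text(text))
    ]


def build_episodes(
    records: Iterable,
    atc_class_map: Mapping[str, Sequence[str]],
    lexicon: set[str] | frozenset[str] = frozenset(),
) -> list[TreatmentEpisode]:
    """Construct all eligible new-user episodes from patient records."""
    class_of = {}
    for label, codes in atc_class_map.items():
        for code in codes:
            class_of[code] = label

    episodes: list[TreatmentEpisode] = []
    for record in records:
        episodes.extend(_episodes_for_patient(record, class_of, lexicon))
    for k, ep in enumerate(episodes):
        ep.episode_id = f"E{k:06d}"
    return episodes


def _episodes_for_patient(
    record, class_of: Mapping[str, str], lexicon
) -> list[TreatmentEpisode]:
    rx = []
    for p in record.prescriptions:
        label = class_of.get(p.atc_code)
        if label is None:
            # Non-NSAID codes are simply not exposure; warn only for codes in
            # the NSAID anatomical group that the class map does not cover.
            if p.atc_code.startswith("M01A"):
                logger.warning(
                    "patient %s: unknown NSAID ATC code %s skipped",
                    record.patient_id,
                    p.atc_code,
                )
            continue
        end = p.date + timedelta(days=prescription_duration(p.quantity, p.daily_dose))
        rx.append((p.date, label, end))
    rx.sort(key=lambda t: (t[0], t[1]))
    if not rx:
        return []

    notes = [(n.date, n.text) for n in record.notes]
    mention_dates = sorted(_mention_dates(notes, lexicon)) if lexicon else []
    rx_dates = [t[0] for t in rx]

    def washout_clear(start: date) -> bool:
        lo = start - timedelta(days=WASHOUT_DAYS)
        if any(lo <= d < start for d in rx_dates):
            return False
        if any(lo <= d < start for d in mention_dates):
            return False
        return True

    def eligible(start: date) -> bool:
        age = start.year - record.birth_year
        if age < MIN_AGE_YEARS:
            return False
        days_enrolled = (start - record.enrollment_start).days
        if days_enrolled < MIN_ENROLLMENT_DAYS:
            return False
        if days_enrolled < MIN_HISTORY_DAYS:
            return False
        return washout_clear(start)

    out: list[TreatmentEpisode] = []
    i = 0
    n = len(rx)
    while i < n:
        start, label, _ = rx[i]
        same_day_classes = {r[1] for r in rx if r[0] == start}
        if len(same_day_classes) > 1:
            logger.info(
                "patient %s: same-day prescriptions of both classes on %s; "
                "no episode created",
                record.patient_id,
                start,
            )
            while i < n and rx[i][0] == start:
                i += 1
            continue
        if not eligible(start):
            i += 1
            continue

        # chain forward over date groups; same-class extensions are applied
        # before an opposite-class switch on the same date
        chain_end = max(r[2] for r in rx if r[0] == start)
        j = i
        while j < n and rx[j][0] == start:
            j += 1
        end = chain_end
        while j < n:
            d = rx[j][0]
            if d > chain_end + timedelta(days=GRACE_DAYS):
                end = chain_end
                break
            group = [r for r in rx if r[0] == d]
            for r in group:
                if r[1] == label:
                    chain_end = max(chain_end, r[2])
            while j < n and rx[j][0] == d:
                j += 1
            if any(r[1] != label for r in group):
                # switch: episode ends at the switch date if the switch falls
                # inside the chain, else at the natural chain end
                end = min(chain_end, d)
                break
            end = chain_end
        out.append(_finalize_episode(record, label, start, end))
        i = j
    return out


def _finalize_episode(record, label: str, start: date, end: date) -> TreatmentEpisode:
    outcome_date = None
    for d in sorted(record.outcome_events):
        if start <= d <= end:
            outcome_date = d
            break
    event = outcome_date is not None
    stop = outcome_date if event else end
    return TreatmentEpisode(
        episode_id="",
        patient_id=record.patient_id,
        class_label=label,
        start_date=start,
        end_date=end,
        age_at_start=start.year - record.birth_year,
        sex=record.sex,
        aspirin_exposed=bool(record.aspirin_exposed),
        outcome_date=outcome_date,
        event=event,
        follow_up_days=(stop - start).days,
    )


# ---------------------------------------------------------------------------
# episodes.csv round-trip
# ---------------------------------------------------------------------------

def episodes_to_frame(episodes: Sequence[TreatmentEpisode]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "episode_id": [e.episode_id for e in episodes],
            "patient_id": [e.patient_id for e in episodes],
            "class_label": [e.class_label for e in episodes],
            "start_date": [e.start_date.isoformat() for e in episodes],
            "end_date": [e.end_date.isoformat() for e in episodes],
            "age_at_start": [e.age_at_start for e in episodes],
            "sex": [e.sex for e in episodes],
            "aspirin_exposed": [int(e.aspirin_exposed) for e in episodes],
            "outcome_date": [
                e.outcome_date.isoformat() if e.outcome_date else "" for e in episodes
            ],
            "event": [int(e.event) for e in episodes],
            "follow_up_days": [e.follow_up_days for e in episodes],
        }
    )


def episodes_from_frame(frame: pd.DataFrame) -> list[TreatmentEpisode]:
    episodes = []
    for row in frame.itertuples(index=False):
        outcome = (
            date.fromisoformat(row.outcome_date)
            if isinstance(row.outcome_date, str) and row.outcome_date
            else None
        )
        episodes.append(
            TreatmentEpisode(
                episode_id=str(row.episode_id),
                patient_id=str(row.patient_id),
                class_label=str(row.class_label),
                start_date=date.fromisoformat(row.start_date),
                end_date=date.fromisoformat(row.end_date),
                age_at_start=int(row.age_at_start),
                sex=str(row.sex),
                aspirin_exposed=bool(row.aspirin_exposed),
                outcome_date=outcome,
                event=bool(row.event),
                follow_up_days=int(row.follow_up_days),
            )
        )
    return episodes


def load_episodes_csv(path: str | Path) -> list[TreatmentEpisode]:
    return episodes_from_frame(
        pd.read_csv(path, dtype={"outcome_date": str}, keep_default_na=False)
    )
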