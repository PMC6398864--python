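"""Synthetic EHR generator with known channeling and a known true treatment effect.

Emits patient-level records (demographics, ATC-coded prescriptions, dated
free-text notes, outcome events) in the same delimited/JSON-lines schema the
analysis pipeline consumes, together with a ground-truth sidecar (per-patient
latent risk, assigned class, true log hazard ratio) that the pipeline never
reads.

Generative structure
--------------------
Each patient draws a latent gastrointestinal risk (standard normal, shifted by
age and low-dose-aspirin use). Treatment class at first exposure follows a
logistic model in the latent risk (channeling), note word frequencies for a
designated block of "proxy" words follow log-linear rates in the latent risk
(so text carries confounder proxies), and the outcome event time is exponential
with log-hazard = log(baseline) + true_log_hr * 1[COX2] + confounder_log_hr *
risk, observed only while the patient is on treatment.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml

from .resources import default_atc_class_map

__all__ = [
    "SimConfig",
    "Prescription",
    "Note",
    "PatientRecord",
    "GroundTruth",
    "ConfigError",
    "generate_cohort",
    "write_dataset",
    "read_dataset",
]

BASE_DATE = date(1996, 1, 1)

# Fixed structural constants of the generative model (not exposed in SimConfig).
_AGE_RISK_PER_DECADE = 0.25   # latent-risk shift per decade of age over 50
_ASPIRIN_RISK_SHIFT = 0.5     # latent-risk shift for low-dose aspirin users
_COX2_BASE_LOGIT = -2.2       # intercept of the channeling model
_REFILL_PROB = 0.35
_SECOND_REFILL_PROB = 0.15
_SWITCH_PROB = 0.04
_DIRTY_NOTE_PROB = 0.3
_POST_INDEX_NOTE_PROB = 0.2
_DIRTY_TOKENS = ["de", "het", "!!", "#pijn", "??", "--", "~koorts"]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic EHR generative model.

    ``proxy_strength`` is the log-rate shift of each proxy word per unit latent
    risk; ``channeling_strength`` the log-odds shift of COX-2 assignment per
    unit latent risk; ``true_log_hr`` the log hazard ratio of COX-2 vs nsNSAID
    on the outcome; ``baseline_hazard`` is per day.
    """

    n_patients: int = 2000
    seed: int = 0
    vocab_size: int = 500
    n_proxy_words: int = 50
    proxy_strength: float = 0.8
    channeling_strength: float = 1.0
    true_log_hr: float = math.log(0.5)
    confounder_log_hr: float = 0.8
    baseline_hazard: float = 5e-4
    notes_per_patient_mean: float = 3.0
    words_per_note_mean: float = 40.0
    rx_duration_days: int = 30
    aspirin_prevalence: float = 0.08
    pre_exposure_mention_fraction: float = 0.05

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if not (self.vocab_size >= self.n_proxy_words >= 0):
            raise ConfigError("need vocab_size >= n_proxy_words >= 0")
        for name in (
            "proxy_strength",
            "channeling_strength",
            "true_log_hr",
            "confounder_log_hr",
            "baseline_hazard",
            "notes_per_patient_mean",
            "words_per_note_mean",
            "aspirin_prevalence",
            "pre_exposure_mention_fraction",
        ):
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ConfigError(f"{name} must be finite, got {value!r}")
        if self.baseline_hazard <= 0:
            raise ConfigError("baseline_hazard must be > 0")
        if not 0.0 <= self.aspirin_prevalence <= 1.0:
            raise ConfigError("aspirin_prevalence must lie in [0, 1]")
        if not 0.0 <= self.pre_exposure_mention_fraction <= 1.0:
            raise ConfigError("pre_exposure_mention_fraction must lie in [0, 1]")
        if self.rx_duration_days < 1:
            raise ConfigError("rx_duration_days must be >= 1")


class Prescription(NamedTuple):
    date: date
    atc_code: str
    quantity: float
    daily_dose: float


class Note(NamedTuple):
    date: date
    text: str


@dataclass
class PatientRecord:
    patient_id: str
    birth_year: int
    sex: str  # "M" or "F"
    enrollment_start: date
    enrollment_end: date
    aspirin_exposed: bool
    latent_risk: float  # simulation-only ground truth; never read by the pipeline
    prescriptions: list[Prescription] = field(default_factory=list)
    notes: list[Note] = field(default_factory=list)
    outcome_events: list[date] = field(default_factory=list)


@dataclass
class GroundTruth:
    """Simulation truth kept separate from the pipeline-facing exports."""

    true_log_hr: float
    latent_risk: dict[str, float]
    assigned_class: dict[str, str]  # class at first exposure, "COX2"/"NSNSAID"


# Drug names for the free-text mention notes, keyed by ATC code.
_ATC_NAMES = {
    "M01AH01": "celecoxib",
    "M01AH02": "rofecoxib",
    "M01AH03": "valdecoxib",
    "M01AH04": "parecoxib",
    "M01AH05": "etoricoxib",
    "M01AB01": "indometacine",
    "M01AB05": "diclofenac",
    "M01AC06": "meloxicam",
    "M01AE01": "ibuprofen",
    "M01AE02": "naproxen",
    "M01AE03": "ketoprofen",
}


def _word_probs(config: SimConfig, risk: float) -> np.ndarray:
    w = np.ones(config.vocab_size)
    if config.n_proxy_words:
        w[: config.n_proxy_words] = np.exp(config.proxy_strength * risk)
    return w / w.sum()


def generate_cohort(config: SimConfig) -> tuple[list[PatientRecord], GroundTruth]:
    """Simulate a cohort of patients; deterministic given ``config`` (incl. seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    atc_map = default_atc_class_map()
    cox2_codes = atc_map["COX2"]
    ns_codes = atc_map["NSNSAID"]

    records: list[PatientRecord] = []
    truth = GroundTruth(config.true_log_hr, {}, {})

    for i in range(config.n_patients):
        pid = f"P{i:06d}"
        z = rng.normal()
        age = float(np.clip(rng.normal(52.0, 16.0), 18.0, 92.0))
        sex = "F" if rng.random() < 0.55 else "M"
        aspirin = bool(rng.random() < config.aspirin_prevalence)
        risk = (
            z
            + _AGE_RISK_PER_DECADE * (age - 50.0) / 10.0
            + _ASPIRIN_RISK_SHIFT * aspirin
        )
        p_cox2 = 1.0 / (1.0 + math.exp(-(_COX2_BASE_LOGIT + config.channeling_strength * risk)))
        is_cox2 = bool(rng.random() < p_cox2)
        class_label = "COX2" if is_cox2 else "NSNSAID"
        own_codes = cox2_codes if is_cox2 else ns_codes
        other_codes = ns_codes if is_cox2 else cox2_codes

        enroll_start = BASE_DATE + timedelta(days=int(rng.integers(0, 5000)))
        index = enroll_start + timedelta(days=365 + int(rng.integers(0, 1460)))
        birth_year = index.year - int(age)

        dur = config.rx_duration_days
        daily_dose = float(rng.choice([1.0, 2.0, 3.0]))
        code = str(rng.choice(own_codes))
        prescriptions = [Prescription(index, code, dur * daily_dose, daily_dose)]
        exposure_end = index + timedelta(days=dur)

        # Refills chain the episode when they start within the 30-day grace.
        if rng.random() < _REFILL_PROB:
            gap = int(rng.integers(-10, 31))
            start2 = max(exposure_end + timedelta(days=gap), index + timedelta(days=1))
            prescriptions.append(
                Prescription(start2, str(rng.choice(own_codes)), dur * daily_dose, daily_dose)
            )
            if (start2 - exposure_end).days <= 30:
                exposure_end = max(exposure_end, start2 + timedelta(days=dur))
            if rng.random() < _SECOND_REFILL_PROB:
                start3 = start2 + timedelta(days=dur + int(rng.integers(0, 25)))
                prescriptions.append(
                    Prescription(start3, str(rng.choice(own_codes)), dur * daily_dose, daily_dose)
                )
                if (start3 - exposure_end).days <= 30:
                    exposure_end = max(exposure_end, start3 + timedelta(days=dur))

        switch_date: date | None = None
        if rng.random() < _SWITCH_PROB and dur > 4:
            switch_date = index + timedelta(days=int(rng.integers(3, dur)))
            prescriptions.append(
                Prescription(switch_date, str(rng.choice(other_codes)), dur * daily_dose, daily_dose)
            )
        effective_end = exposure_end
        if switch_date is not None and switch_date < effective_end:
            effective_end = switch_date

        # Outcome time from the exponential hazard model; observed only on treatment.
        rate = config.baseline_hazard * math.exp(
            config.true_log_hr * is_cox2 + config.confounder_log_hr * risk
        )
        t_days = rng.exponential(1.0 / rate)
        event_offset = max(1, math.ceil(t_days))
        outcome_events: list[date] = []
        if event_offset <= (effective_end - index).days:
            outcome_events.append(index + timedelta(days=event_offset))

        notes: list[Note] = []
        n_notes = int(rng.poisson(config.notes_per_patient_mean))
        for _ in range(n_notes):
            note_date = index - timedelta(days=int(rng.integers(1, 184)))
            n_words = max(1, int(rng.poisson(config.words_per_note_mean)))
            idx = rng.choice(config.vocab_size, size=n_words, p=_word_probs(config, risk))
            tokens = [f"w{j:05d}" for j in idx]
            if rng.random() < _DIRTY_NOTE_PROB:
                tokens.extend(rng.choice(_DIRTY_TOKENS, size=2))
            notes.append(Note(note_date, " ".join(tokens)))
        if rng.random() < _POST_INDEX_NOTE_PROB:
            note_date = index + timedelta(days=int(rng.integers(0, 30)))
            idx = rng.choice(config.vocab_size, size=5, p=_word_probs(config, risk))
            notes.append(Note(note_date, " ".join(f"w{j:05d}" for j in idx)))
        if rng.random() < config.pre_exposure_mention_fraction:
            mention_date = index - timedelta(days=int(rng.integers(1, 184)))
            drug = _ATC_NAMES[str(rng.choice(own_codes))]
            notes.append(Note(mention_date, f"patient kreeg eerder {drug} voorgeschreven"))
        notes.sort(key=lambda n: (n.date, n.text))

        last_date = max(
            [exposure_end, index] + [n.date for n in notes] + outcome_events
        )
        enroll_end = last_date + timedelta(days=int(rng.integers(200, 1200)))

        records.append(
            PatientRecord(
                patient_id=pid,
                birth_year=birth_year,
                sex=sex,
                enrollment_start=enroll_start,
                enrollment_end=enroll_end,
                aspirin_exposed=aspirin,
                latent_risk=risk,
                prescriptions=sorted(prescriptions, key=lambda r: (r.date, r.atc_code)),
                notes=notes,
                outcome_events=outcome_events,
            )
        )
        truth.latent_risk[pid] = risk
        truth.assigned_class[pid] = class_label

    return records, truth


# ---------------------------------------------------------------------------
# Dataset serialization (pipeline-facing schema + ground-truth sidecar)
# ---------------------------------------------------------------------------

def write_dataset(
    records: list[PatientRecord],
    ground_truth: GroundTruth,
    directory: str | Path,
    config: SimConfig | None = None,
) -> None:
    """Write the four pipeline files plus the ground-truth sidecar.

    Files: patients.csv, prescriptions.csv, notes.jsonl, outcomes.csv,
    ground_truth.csv, truth.yaml. Dates are ISO-8601.
    """
    if not records:
        raise ValueError("records must be nonempty")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "birth_year": [r.birth_year for r in records],
            "sex": [r.sex for r in records],
            "enrollment_start": [r.enrollment_start.isoformat() for r in records],
            "enrollment_end": [r.enrollment_end.isoformat() for r in records],
            "aspirin_exposed": [int(r.aspirin_exposed) for r in records],
        }
    ).to_csv(directory / "patients.csv", index=False)

    rx_rows = [
        (r.patient_id, p.date.isoformat(), p.atc_code, repr(p.quantity), repr(p.daily_dose))
        for r in records
        for p in r.prescriptions
    ]
    pd.DataFrame(
        rx_rows, columns=["patient_id", "date", "atc_code", "quantity", "daily_dose"]
    ).to_csv(directory / "prescriptions.csv", index=False)

    with open(directory / "notes.jsonl", "w") as fh:
        for r in records:
            for note in r.notes:
                fh.write(
                    json.dumps(
                        {"patient_id": r.patient_id, "date": note.date.isoformat(), "text": note.text}
                    )
                    + "\n"
                )

    out_rows = [
        (r.patient_id, d.isoformat()) for r in records for d in r.outcome_events
    ]
    pd.DataFrame(out_rows, columns=["patient_id", "event_date"]).to_csv(
        directory / "outcomes.csv", index=False
    )

    pd.DataFrame(
        {
            "patient_id": list(ground_truth.latent_risk),
            "latent_risk": [repr(v) for v in ground_truth.latent_risk.values()],
            "assigned_class": [
                ground_truth.assigned_class.get(pid, "") for pid in ground_truth.latent_risk
            ],
        }
    ).to_csv(directory / "ground_truth.csv", index=False)

    sidecar: dict = {"true_log_hr": float(ground_truth.true_log_hr)}
    if config is not None:
        sidecar["config"] = dataclasses.asdict(config)
    with open(directory / "truth.yaml", "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=False)


def read_dataset(directory: str | Path) -> tuple[list[PatientRecord], GroundTruth | None]:
    """Read a dataset written by :func:`write_dataset`.

    The ground-truth sidecar is loaded only if present; latent risks are then
    folded back into the records so write→read round-trips exactly.
    """
    directory = Path(directory)
    patients = pd.read_csv(directory / "patients.csv", dtype={"patient_id": str})
    rx = pd.read_csv(
        directory / "prescriptions.csv",
        dtype={"patient_id": str, "atc_code": str, "quantity": float, "daily_dose": float},
        float_precision="round_trip",
    )
    outcomes = pd.read_csv(
        directory / "outcomes.csv", dtype={"patient_id": str, "event_date": str}
    )

    notes_by_pid: dict[str, list[Note]] = {}
    notes_path = directory / "notes.jsonl"
    if notes_path.exists():
        with open(notes_path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                row = json.loads(line)
                notes_by_pid.setdefault(row["patient_id"], []).append(
                    Note(date.fromisoformat(row["date"]), row["text"])
                )

    rx_by_pid: dict[str, list[Prescription]] = {}
    for row in rx.itertuples(index=False):
        rx_by_pid.setdefault(row.patient_id, []).append(
            Prescription(
                date.fromisoformat(row.date), row.atc_code, float(row.quantity), float(row.daily_dose)
            )
        )
    events_by_pid: dict[str, list[date]] = {}
    for row in outcomes.itertuples(index=False):
        events_by_pid.setdefault(row.patient_id, []).append(date.fromisoformat(row.event_date))

    truth: GroundTruth | None = None
    gt_path = directory / "ground_truth.csv"
    if gt_path.exists():
        gt = pd.read_csv(
            gt_path,
            dtype={"patient_id": str, "assigned_class": str},
            float_precision="round_trip",
        )
        true_log_hr = float("nan")
        truth_path = directory / "truth.yaml"
        if truth_path.exists():
            with open(truth_path) as fh:
                true_log_hr = float(yaml.safe_load(fh)["true_log_hr"])
        truth = GroundTruth(
            true_log_hr,
            dict(zip(gt["patient_id"], gt["latent_risk"].astype(float))),
            dict(zip(gt["patient_id"], gt["assigned_class"].fillna(""))),
        )

    records = []
    for row in patients.itertuples(index=False):
        pid = row.patient_id
        records.append(
            PatientRecord(
                patient_id=pid,
                birth_year=int(row.birth_year),
                sex=str(row.sex),
                enrollment_start=date.fromisoformat(row.enrollment_start),
                enrollment_end=date.fromisoformat(row.enrollment_end),
                aspirin_exposed=bool(row.aspirin_exposed),
                latent_risk=truth.latent_risk.get(pid, float("nan")) if truth else float("nan"),
                prescriptions=sorted(rx_by_pid.get(pid, []), key=lambda r: (r.date, r.atc_code)),
                notes=sorted(notes_by_pid.get(pid, []), key=lambda n: (n.date, n.text)),
                outcome_events=sorted(events_by_pid.get(pid, [])),
            )
        )
    return records, truth
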