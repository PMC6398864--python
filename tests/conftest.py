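from __future__ import annotations

from datetime import date, timedelta

import numpy as np
import pytest

from textps.synthetic_ehr import Note, PatientRecord, Prescription

ATC_MAP = {
    "COX2": ["M01AH01", "M01AH05"],
    "NSNSAID": ["M01AE01", "M01AE02", "M01AB05"],
}
LEXICON = frozenset({"ibuprofen", "naproxen", "diclofenac", "celecoxib"})


def make_record(
    pid="P0",
    birth_year=1960,
    sex="M",
    start="2000-01-01",
    end="2006-12-31",
    aspirin=False,
    rx=(),
    notes=(),
    events=(),
) -> PatientRecord:
    """Hand-built patient: rx = [(iso_date, atc, quantity, daily_dose)],
    notes = [(iso_date, text)], events = [iso_date]."""
    return PatientRecord(
        patient_id=pid,
        birth_year=birth_year,
        sex=sex,
        enrollment_start=date.fromisoformat(start),
        enrollment_end=date.fromisoformat(end),
        aspirin_exposed=aspirin,
        latent_risk=0.0,
        prescriptions=[
            Prescription(date.fromisoformat(d), atc, float(q), float(dd))
            for d, atc, q, dd in rx
        ],
        notes=[Note(date.fromisoformat(d), text) for d, text in notes],
        outcome_events=[date.fromisoformat(d) for d in events],
    )


def random_patients(rng: np.random.Generator, n: int) -> list[PatientRecord]:
    """Random small prescription/note streams for oracle equivalence tests."""
    codes = ATC_MAP["COX2"] + ATC_MAP["NSNSAID"] + ["N02BE01"]  # last is non-NSAID
    drugs = sorted(LEXICON)
    records = []
    for i in range(n):
        start = date(1998, 1, 1) + timedelta(days=int(rng.integers(0, 300)))
        birth_year = int(rng.integers(1930, 1995))
        n_rx = int(rng.integers(0, 6))
        rx = []
        for _ in range(n_rx):
            d = start + timedelta(days=int(rng.integers(0, 1200)))
            code = codes[int(rng.integers(0, len(codes)))]
            quantity = float(rng.integers(5, 90))
            daily_dose = float(rng.integers(1, 4))
            rx.append(Prescription(d, code, quantity, daily_dose))
        rx.sort(key=lambda p: (p.date, p.atc_code))
        notes = []
        for _ in range(int(rng.integers(0, 3))):
            d = start + timedelta(days=int(rng.integers(0, 1200)))
            if rng.random() < 0.5:
                text = f"klachten na {drugs[int(rng.integers(0, len(drugs)))]} gebruik"
            else:
                text = "algemene controle geen bijzonderheden"
            notes.append(Note(d, text))
        notes.sort(key=lambda nn: (nn.date, nn.text))
        events = []
        if rng.random() < 0.3:
            events.append(start + timedelta(days=int(rng.integers(300, 1300))))
        last = start + timedelta(days=1500)
        records.append(
            PatientRecord(
                patient_id=f"R{i:04d}",
                birth_year=birth_year,
                sex="F" if rng.random() < 0.5 else "M",
                enrollment_start=start,
                enrollment_end=last,
                aspirin_exposed=bool(rng.random() < 0.2),
                latent_risk=0.0,
                prescriptions=rx,
                notes=notes,
                outcome_events=sorted(events),
            )
        )
    return records


@pytest.fixture(scope="session")
def small_sim():
    """One modest simulated dataset shared across read-only tests."""
    from textps.synthetic_ehr import SimConfig, generate_cohort

    config = SimConfig(n_patients=1500, seed=42)
    records, truth = generate_cohort(config)
    return config, records, truth
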