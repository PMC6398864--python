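"""Independent brute-force oracles used to verify the package implementations.

Each oracle is deliberately naive (exhaustive loops, re-sorting, dense grid
search) and shares no code with the implementation paths it checks.
"""

from __future__ import annotations

import math
import re
from datetime import date, timedelta

import numpy as np

# ---------------------------------------------------------------------------
# greedy matching: re-sorting brute force
# ---------------------------------------------------------------------------

def brute_force_greedy(treated, controls, caliper):
    """Pass-based greedy matching that re-sorts the full candidate list after
    every single acceptance."""
    avail = dict(controls)
    pairs = []
    pass_idx = 0
    while True:
        pass_idx += 1
        used = set()
        accepted_this_pass = False
        while True:
            cands = []
            for tid, tv in treated:
                if tid in used:
                    continue
                for cid, cv in avail.items():
                    d = abs(tv - cv)
                    if d <= caliper:
                        cands.append((d, tid, cid))
            if not cands:
                break
            cands.sort()
            d, tid, cid = cands[0]
            pairs.append((tid, cid, pass_idx, d))
            del avail[cid]
            used.add(tid)
            accepted_this_pass = True
        if not accepted_this_pass:
            break
    matched = {p[0] for p in pairs}
    unmatched = [tid for tid, _ in treated if tid not in matched]
    return pairs, unmatched


# ---------------------------------------------------------------------------
# AUC: all-pairs enumeration
# ---------------------------------------------------------------------------

def all_pairs_auc(scores, labels):
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# 2x2 chi-square from the definition
# ---------------------------------------------------------------------------

def chisq_from_definition(table):
    (a, b), (c, d) = table
    n = a + b + c + d
    row = (a + b, c + d)
    col = (a + c, b + d)
    stat = 0.0
    for i, obs_row in enumerate(((a, b), (c, d))):
        for j, obs in enumerate(obs_row):
            e = row[i] * col[j] / n
            stat += (obs - e) ** 2 / e
    return stat


# ---------------------------------------------------------------------------
# penalized logistic objective: dense refined grid search
# ---------------------------------------------------------------------------

def penalized_objective_dense(X, y, beta, intercept, lam):
    z = X @ beta + intercept
    nll = float(np.sum(np.logaddexp(0.0, z) - y * z))
    return nll + lam * float(np.abs(beta).sum())


def grid_search_objective(X, y, lam, span=5.0, steps=21, rounds=8):
    """Iteratively refined dense grid search over (beta1, beta2, intercept)
    for a 2-covariate problem. Returns the best objective found."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    center = np.zeros(3)
    width = span
    best_obj = math.inf
    for _ in range(rounds):
        axes = [np.linspace(c - width, c + width, steps) for c in center]
        B1, B2, B0 = np.meshgrid(*axes, indexing="ij")
        Z = (
            X[:, 0][:, None] * B1.ravel()[None, :]
            + X[:, 1][:, None] * B2.ravel()[None, :]
            + B0.ravel()[None, :]
        )
        nll = np.sum(np.logaddexp(0.0, Z) - y[:, None] * Z, axis=0)
        obj = nll + lam * (np.abs(B1.ravel()) + np.abs(B2.ravel()))
        k = int(np.argmin(obj))
        best_obj = min(best_obj, float(obj[k]))
        center = np.array([B1.ravel()[k], B2.ravel()[k], B0.ravel()[k]])
        width = 2.0 * width / (steps - 1)
    return best_obj


# ---------------------------------------------------------------------------
# Cox partial likelihood, one binary covariate, grid search (no ties)
# ---------------------------------------------------------------------------

def cox_grid_hr(durations, events, x, lo=-6.0, hi=6.0, steps=2001, rounds=4):
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=bool)
    x = np.asarray(x, dtype=float)

    def negloglik(b):
        ll = 0.0
        for i in np.flatnonzero(events):
            at_risk = durations >= durations[i]
            ll += b * x[i] - math.log(np.sum(np.exp(b * x[at_risk])))
        return -ll

    a, z = lo, hi
    best = 0.0
    for _ in range(rounds):
        grid = np.linspace(a, z, steps)
        vals = [negloglik(b) for b in grid]
        k = int(np.argmin(vals))
        best = grid[k]
        step = grid[1] - grid[0]
        a, z = best - step, best + step
    return math.exp(best)


# ---------------------------------------------------------------------------
# bag-of-words: nested-loop tokenize and tally
# ---------------------------------------------------------------------------

def naive_tokenize(text, stop_words):
    out = []
    for raw_tok in text.lower().split():
        tok = re.sub(r"[^\w\s]|_", " ", raw_tok)
        for piece in tok.split():
            if piece in stop_words:
                continue
            if not (piece[0].isalpha() or piece[0].isdigit()):
                continue
            out.append(piece)
    return out


def naive_bow(episodes, notes_by_patient, stop_words, lookback_days=183, binary=True):
    """Dict-of-dicts bag of words: {episode_id: {token: value}}."""
    table = {}
    for ep in episodes:
        tally = {}
        for note_date, text in notes_by_patient.get(ep.patient_id, ()):
            delta = (ep.start_date - note_date).days
            if 0 < delta <= lookback_days:
                for tok in naive_tokenize(text, stop_words):
                    tally[tok] = tally.get(tok, 0) + 1
        if binary:
            tally = {k: 1 for k in tally}
        table[ep.episode_id] = tally
    return table


# ---------------------------------------------------------------------------
# episode construction: day-by-day state machine
# ---------------------------------------------------------------------------

def day_by_day_episodes(record, class_of, lexicon):
    """Simulate the episode rules one calendar day at a time.

    Returns a list of (class_label, start, end) tuples.
    """
    rx = []
    for p in record.prescriptions:
        label = class_of.get(p.atc_code)
        if label is None:
            continue
        duration = max(1, math.floor(p.quantity / p.daily_dose + 0.5))
        rx.append((p.date, label, p.date + timedelta(days=duration)))
    if not rx:
        return []
    rx_dates = sorted({r[0] for r in rx})
    all_rx_dates = [r[0] for r in rx]

    mention_dates = []
    for n in record.notes:
        toks = naive_tokenize(n.text, set())
        if any(t in lexicon for t in toks):
            mention_dates.append(n.date)

    def eligible(d):
        if d.year - record.birth_year < 18:
            return False
        if (d - record.enrollment_start).days < 365:
            return False
        if (d - record.enrollment_start).days < 183:
            return False
        lo = d - timedelta(days=183)
        if any(lo <= rd < d for rd in all_rx_dates):
            return False
        if any(lo <= md < d for md in mention_dates):
            return False
        return True

    episodes = []
    open_ep = None  # (label, start, chain_end)
    day = min(rx_dates)
    last_day = max(r[2] for r in rx) + timedelta(days=31)
    while day <= last_day:
        todays = [r for r in rx if r[0] == day]
        if open_ep is not None:
            label, start, chain_end = open_ep
            if day > chain_end + timedelta(days=30):
                episodes.append((label, start, chain_end))
                open_ep = None
            else:
                for r in todays:
                    if r[1] == label and r[2] > chain_end:
                        chain_end = r[2]
                if any(r[1] != label for r in todays):
                    episodes.append((label, start, min(chain_end, day)))
                    open_ep = None
                    day += timedelta(days=1)
                    continue
                open_ep = (label, start, chain_end)
                day += timedelta(days=1)
                continue
        if open_ep is None and todays:
            classes = {r[1] for r in todays}
            if len(classes) == 1 and eligible(day):
                label = classes.pop()
                open_ep = (label, day, max(r[2] for r in todays))
        day += timedelta(days=1)
    if open_ep is not None:
        episodes.append((open_ep[0], open_ep[1], open_ep[2]))
    return episodes


# ---------------------------------------------------------------------------
# marginal crude association of the generative model, by direct Monte Carlo
# ---------------------------------------------------------------------------

def monte_carlo_crude_log_rr(config, n=200_000, seed=12345, horizon=None):
    """Marginal event-rate ratio (COX2 vs NSNSAID) implied by the generative
    model, estimated by sampling the model equations directly."""
    rng = np.random.default_rng(seed)
    z = rng.normal(size=n)
    age = np.clip(rng.normal(52.0, 16.0, size=n), 18.0, 92.0)
    aspirin = rng.random(n) < config.aspirin_prevalence
    risk = z + 0.25 * (age - 50.0) / 10.0 + 0.5 * aspirin
    p = 1.0 / (1.0 + np.exp(-(-2.2 + config.channeling_strength * risk)))
    cox2 = rng.random(n) < p
    rate = config.baseline_hazard * np.exp(
        config.true_log_hr * cox2 + config.confounder_log_hr * risk
    )
    t = rng.exponential(1.0 / rate)
    if horizon is None:
        horizon = float(config.rx_duration_days)
    event = t <= horizon
    dur = np.minimum(t, horizon)
    rate_cox2 = event[cox2].sum() / dur[cox2].sum()
    rate_ns = event[~cox2].sum() / dur[~cox2].sum()
    return math.log(rate_cox2 / rate_ns)
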