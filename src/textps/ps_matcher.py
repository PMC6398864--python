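"""Greedy iterative one-to-many caliper matching.

Pass algorithm: within a pass, all admissible (treated, available control)
pairs — those with absolute score difference at most the caliper — are
consumed in ascending difference order. Accepting a pair removes the control
permanently and the treated member for the remainder of the pass. Passes
repeat (each treated member may gain one more control per pass) until no
admissible pair remains. Ties in the difference are broken by (treated id,
control id) lexicographic order, which makes the output deterministic.

The same machinery serves propensity-score matching (caliper 0.01) and age
matching (caliper 2 years) — only the value column differs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = ["MatchPair", "MatchedCohort", "greedy_match"]


class MatchPair(NamedTuple):
    treated_id: str
    control_id: str
    pass_index: int  # 1-based
    difference: float


@dataclass
class MatchedCohort:
    pairs: list[MatchPair]
    unmatched_treated: list[str]
    caliper: float

    @property
    def matched_treated(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.pairs:
            seen.setdefault(p.treated_id, None)
        return list(seen)

    @property
    def matched_controls(self) -> list[str]:
        return [p.control_id for p in self.pairs]

    def n_passes(self) -> int:
        return max((p.pass_index for p in self.pairs), default=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "treated_id": [p.treated_id for p in self.pairs],
                "control_id": [p.control_id for p in self.pairs],
                "pass": [p.pass_index for p in self.pairs],
                "ps_diff": [p.difference for p in self.pairs],
            }
        )

    def save(self, csv_path: str | Path, summary_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        if summary_path is not None:
            per_pass: dict[int, int] = {}
            for p in self.pairs:
                per_pass[p.pass_index] = per_pass.get(p.pass_index, 0) + 1
            with open(summary_path, "w") as fh:
                yaml.safe_dump(
                    {
                        "caliper": float(self.caliper),
                        "n_pairs": len(self.pairs),
                        "n_matched_treated": len(self.matched_treated),
                        "n_unmatched_treated": len(self.unmatched_treated),
                        "pairs_per_pass": {int(k): v for k, v in sorted(per_pass.items())},
                    },
                    fh,
                    sort_keys=False,
                )


def greedy_match(
    treated: Sequence[tuple[str, float]],
    controls: Sequence[tuple[str, float]],
    caliper: float = 0.01,
) -> MatchedCohort:
    """Match treated members to controls with the iterative pass algorithm."""
    if caliper <= 0:
        raise ValueError("caliper must be > 0")
    if not treated or not controls:
        return MatchedCohort([], [t[0] for t in treated], caliper)

    t_ids = [t[0] for t in treated]
    t_vals = np.asarray([t[1] for t in treated], dtype=float)
    # controls sorted by value for windowed candidate generation
    order = sorted(range(len(controls)), key=lambda i: (controls[i][1], controls[i][0]))
    c_ids = [controls[i][0] for i in order]
    c_vals = np.asarray([controls[i][1] for i in order], dtype=float)
    available = np.ones(len(c_ids), dtype=bool)

    pairs: list[MatchPair] = []
    ever_matched: set[str] = set()
    pass_index = 0
    while True:
        pass_index += 1
        avail_idx = np.flatnonzero(available)
        if avail_idx.size == 0:
            break
        avail_vals = c_vals[avail_idx]
        # pad the search window: (t - caliper) in fp can land just above a
        # control whose recomputed |diff| is still <= caliper; the exact
        # check below discards any extras
        pad = 1e-9 * (1.0 + caliper) + 1e-12
        lo = np.searchsorted(avail_vals, t_vals - caliper - pad, side="left")
        hi = np.searchsorted(avail_vals, t_vals + caliper + pad, side="right")
        candidates: list[tuple[float, str, str, int]] = []
        for ti in range(len(t_ids)):
            for pos in range(lo[ti], hi[ti]):
                ci = avail_idx[pos]
                diff = abs(t_vals[ti] - c_vals[ci])
                if diff <= caliper:
                    candidates.append((diff, t_ids[ti], c_ids[ci], ci))
        if not candidates:
            break
        candidates.sort(key=lambda c: (c[0], c[1], c[2]))
        used_treated: set[str] = set()
        matched_any = False
        for diff, tid, cid, ci in candidates:
            if not available[ci] or tid in used_treated:
                continue
            available[ci] = False
            used_treated.add(tid)
            ever_matched.add(tid)
            pairs.append(MatchPair(tid, cid, pass_index, float(diff)))
            matched_any = True
        if not matched_any:
            break

    unmatched = [tid for tid in t_ids if tid not in ever_matched]
    return MatchedCohort(pairs, unmatched, caliper)
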