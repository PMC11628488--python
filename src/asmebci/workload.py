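"""NASA-TLX weighted workload (WWL).

Six subscales (mental, physical, temporal, performance, effort,
frustration) are rated 0–100; fifteen pairwise comparisons between the
subscales yield per-subscale tallies summing to 15.  The weighted workload
is the tally-weighted mean of the ratings: ``WWL = Σ tally_i · score_i / 15``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["DIMENSIONS", "TlxRecord", "weighted_workload", "tallies_from_pairs",
           "read_tlx_csv", "score_tlx_table"]

DIMENSIONS = ("mental", "physical", "temporal", "performance", "effort", "frustration")
N_PAIRS = 15  # C(6, 2)


@dataclass(frozen=True)
class TlxRecord:
    """One questionnaire response: six 0–100 scores and pairwise tallies."""

    scores: tuple[float, ...]
    tallies: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.scores) != 6 or len(self.tallies) != 6:
            raise ValueError("need six scores and six tallies")
        if any(not 0 <= s <= 100 for s in self.scores):
            raise ValueError("scores must lie in [0, 100]")
        if any(t < 0 for t in self.tallies):
            raise ValueError("tallies must be non-negative")
        if sum(self.tallies) != N_PAIRS:
            raise ValueError(f"tallies must sum to {N_PAIRS}, got {sum(self.tallies)}")

    @property
    def wwl(self) -> float:
        return weighted_workload(self)


def weighted_workload(rec: TlxRecord) -> float:
    """Tally-weighted mean of the six subscale scores."""
    return float(np.dot(rec.scores, rec.tallies) / N_PAIRS)


def tallies_from_pairs(choices: Sequence[str]) -> tuple[int, ...]:
    """Count pairwise-comparison wins; expects all 15 choices."""
    if len(choices) != N_PAIRS:
        raise ValueError(f"need {N_PAIRS} pairwise choices, got {len(choices)}")
    counts = {d: 0 for d in DIMENSIONS}
    for c in choices:
        key = c.strip().lower()
        if key not in counts:
            raise ValueError(f"unknown dimension {c!r}")
        counts[key] += 1
    return tuple(counts[d] for d in DIMENSIONS)


def read_tlx_csv(path: str | Path) -> pd.DataFrame:
    """Read responses: columns subject, paradigm, the six scores, and either
    six tally columns (``w_<dim>``) or fifteen choice columns (``pair_1``..)."""
    df = pd.read_csv(path)
    required = {"subject", "paradigm", *DIMENSIONS}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    return df


def score_tlx_table(df: pd.DataFrame) -> pd.DataFrame:
    """Compute WWL per row of a response table."""
    out = []
    pair_cols = [c for c in df.columns if c.startswith("pair_")]
    for _, row in df.iterrows():
        scores = tuple(float(row[d]) for d in DIMENSIONS)
        if pair_cols:
            tallies = tallies_from_pairs([str(row[c]) for c in pair_cols])
        else:
            tallies = tuple(int(row[f"w_{d}"]) for d in DIMENSIONS)
        rec = TlxRecord(scores=scores, tallies=tallies)
        out.append(
            {"subject": row["subject"], "paradigm": row["paradigm"], "wwl": rec.wwl}
        )
    return pd.DataFrame(out)
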