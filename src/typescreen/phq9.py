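"""PHQ-9 scoring and group assignment.

The PHQ-9 is a nine-item self-report depression questionnaire; each item is
answered 0-3, so the compound score spans 0-27.  Subjects at or above the
chosen cutoff are labelled DT (depressive tendency), the rest HC (healthy
control).  Two standard cutoffs ship as presets: 5 (mild or worse symptoms)
and 10 (the usual threshold for major depression).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

PHQ9_MIN, PHQ9_MAX = 0, 27

#: Named cutoff presets: mild or worse (5) and moderate/major (10).
CUTOFF_PRESETS = {"mild": 5, "major": 10}

DT, HC = "DT", "HC"


@dataclass(frozen=True)
class GroupLabel:
    label: str  # "DT" or "HC"
    cutoff_used: int

    @property
    def is_dt(self) -> bool:
        return self.label == DT


def score_phq9(items: Sequence[int]) -> int:
    """Compound PHQ-9 score: the sum of the nine item responses."""
    if len(items) != 9:
        raise ValueError(f"PHQ-9 requires exactly 9 items, got {len(items)}")
    for i, item in enumerate(items, start=1):
        if not (0 <= int(item) <= 3):
            raise ValueError(f"PHQ-9 item {i} out of range [0, 3]: {item}")
    return int(sum(items))


def assign_group(score: int, cutoff: int = 5) -> GroupLabel:
    """DT iff ``score >= cutoff``; monotone in the score for a fixed cutoff."""
    if not (PHQ9_MIN <= score <= PHQ9_MAX):
        raise ValueError(f"PHQ-9 score out of range [0, 27]: {score}")
    return GroupLabel(label=DT if score >= cutoff else HC, cutoff_used=cutoff)


def label_table(subjects: Iterable, cutoff: int = 5) -> pd.DataFrame:
    """Labels for a cohort: columns subject_id, phq9, label, cutoff.

    Accepts any iterable of objects with ``subject_id`` and either
    ``phq9_score`` or ``phq9_items``.
    """
    rows = []
    for s in subjects:
        score = s.phq9_score if s.phq9_score is not None else score_phq9(s.phq9_items)
        g = assign_group(score, cutoff)
        rows.append(
            {"subject_id": s.subject_id, "phq9": score,
             "label": g.label, "cutoff": cutoff}
        )
    return pd.DataFrame(rows, columns=["subject_id", "phq9", "label", "cutoff"])
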