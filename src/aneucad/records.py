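"""Case records: one screening examination with physician and detector calls.

A :class:`CaseRecord` carries the physician's three-category diagnosis
(``none`` / ``suspicion`` / ``definite`` — a suspicion reading cannot be
ruled out as an aneurysm and is counted as positive in every accuracy
computation), the detector's candidate outputs each labeled true positive
(TP, hit a real lesion) or false positive (FP), and the count of missed
true lesions (false negatives).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import isnan
from typing import NamedTuple

import pandas as pd

__all__ = [
    "PHYSICIAN_LABELS",
    "CaseCandidate",
    "CaseRecord",
    "save_case_csv",
    "save_candidate_csv",
    "load_case_csv",
]

PHYSICIAN_LABELS = ("none", "suspicion", "definite")


class CaseCandidate(NamedTuple):
    """One detector output: classifier score and its TP/FP adjudication."""

    score: float
    label: str  # "TP" or "FP"


@dataclass
class CaseRecord:
    case_id: str
    physician_label: str
    candidates: list[CaseCandidate] = field(default_factory=list)
    n_fn: int = 0

    def __post_init__(self) -> None:
        if self.physician_label not in PHYSICIAN_LABELS:
            raise ValueError(
                f"physician_label must be one of {PHYSICIAN_LABELS}, "
                f"got {self.physician_label!r}"
            )
        if self.n_fn < 0:
            raise ValueError("n_fn must be >= 0")
        for cand in self.candidates:
            if cand.label not in ("TP", "FP"):
                raise ValueError(f"candidate label must be TP or FP, got {cand.label!r}")
        if self.physician_label == "none" and (self.n_tp > 0 or self.n_fn > 0):
            raise ValueError("a physician-negative case cannot carry TPs or FNs")

    @property
    def n_tp(self) -> int:
        return sum(1 for c in self.candidates if c.label == "TP")

    @property
    def n_fp(self) -> int:
        return sum(1 for c in self.candidates if c.label == "FP")

    @property
    def physician_positive(self) -> bool:
        """Suspicion and definite readings both count as positive."""
        return self.physician_label in ("suspicion", "definite")

    @property
    def ai_positive(self) -> bool:
        """Case-level detector call: at least one candidate of any label."""
        return len(self.candidates) > 0

    def has_scores(self) -> bool:
        return all(not isnan(c.score) for c in self.candidates)

    @classmethod
    def from_counts(
        cls, case_id: str, physician_label: str, n_tp: int, n_fp: int, n_fn: int
    ) -> "CaseRecord":
        """Build a record from summary counts; candidate scores are unknown (NaN)."""
        candidates = [CaseCandidate(float("nan"), "TP")] * n_tp
        candidates = candidates + [CaseCandidate(float("nan"), "FP")] * n_fp
        return cls(case_id, physician_label, candidates, n_fn)


def save_case_csv(records: list[CaseRecord], path) -> None:
    """One row per case: case_id, physician_label, n_tp, n_fp, n_fn."""
    pd.DataFrame(
        {
            "case_id": [r.case_id for r in records],
            "physician_label": [r.physician_label for r in records],
            "n_tp": [r.n_tp for r in records],
            "n_fp": [r.n_fp for r in records],
            "n_fn": [r.n_fn for r in records],
        }
    ).to_csv(path, index=False)


def save_candidate_csv(records: list[CaseRecord], path) -> None:
    """Long format, one row per candidate: case_id, candidate_id, score, label."""
    rows = [
        (r.case_id, i, c.score, c.label)
        for r in records
        for i, c in enumerate(r.candidates)
    ]
    pd.DataFrame(rows, columns=["case_id", "candidate_id", "score", "label"]).to_csv(
        path, index=False
    )


def load_case_csv(path, candidate_path=None) -> list[CaseRecord]:
    """Read case records from the summary CSV, optionally with per-candidate scores.

    Raises
    ------
    ValueError
        On schema violations, reporting the offending row number.
    """
    df = pd.read_csv(path, dtype={"case_id": str})
    required = {"case_id", "physician_label", "n_tp", "n_fp", "n_fn"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")

    by_case: dict[str, list[CaseCandidate]] = {}
    if candidate_path is not None:
        cdf = pd.read_csv(candidate_path, dtype={"case_id": str})
        creq = {"case_id", "score", "label"}
        if creq - set(cdf.columns):
            raise ValueError(f"{candidate_path}: missing columns {sorted(creq - set(cdf.columns))}")
        for i, row in cdf.iterrows():
            if row["label"] not in ("TP", "FP"):
                raise ValueError(f"{candidate_path} row {i}: bad label {row['label']!r}")
            by_case.setdefault(row["case_id"], []).append(
                CaseCandidate(float(row["score"]), str(row["label"]))
            )

    records = []
    for i, row in df.iterrows():
        try:
            if row["case_id"] in by_case:
                rec = CaseRecord(
                    str(row["case_id"]),
                    str(row["physician_label"]),
                    by_case[row["case_id"]],
                    int(row["n_fn"]),
                )
                if rec.n_tp != int(row["n_tp"]) or rec.n_fp != int(row["n_fp"]):
                    raise ValueError("candidate rows disagree with summary counts")
            else:
                rec = CaseRecord.from_counts(
                    str(row["case_id"]),
                    str(row["physician_label"]),
                    int(row["n_tp"]),
                    int(row["n_fp"]),
                    int(row["n_fn"]),
                )
        except ValueError as err:
            raise ValueError(f"{path} row {i}: {err}") from err
        records.append(rec)
    return records
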